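"""Survey data containers, validation and tabular I/O.

The survey design behind these containers: a set of 1-km line transects is
walked repeatedly (J visits, nominally 3, within one closure window) in each
year of a monitoring programme, and the number of singing males recorded per
visit is the observation.  Habitat structure on each transect is summarised as
the proportion of the transect falling in each of four ordered categories of
vegetation height, water depth and litter cover (measured at five equally
spaced field points, hence proportions in multiples of 0.2).  Daily weather
(rain, temperature, wind) and the day of season are visit-level covariates.

File formats are plain UTF-8 CSV with a header row:

``counts.csv``
    ``transect,year,visit,count`` — ``count`` empty for a missing visit.
``site_covariates.csv``
    ``transect,year,veg1..veg4,water1..water4,litter1..litter4``
``obs_covariates.csv``
    ``transect,year,visit,rain_mm,temp_c,wind,day_of_season``
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SchemaError",
    "ValidationError",
    "CategoryProfile",
    "SurveyDataset",
    "read_survey_dataset",
    "write_survey_dataset",
    "COUNT_COLUMNS",
    "SITE_COV_COLUMNS",
    "OBS_COV_COLUMNS",
]


class SchemaError(ValueError):
    """A required column is missing or has the wrong type."""


class ValidationError(ValueError):
    """A row violates a dataset invariant."""


COUNT_COLUMNS = ["transect", "year", "visit", "count"]
SITE_COV_COLUMNS = (
    ["transect", "year"]
    + [f"veg{k}" for k in range(1, 5)]
    + [f"water{k}" for k in range(1, 5)]
    + [f"litter{k}" for k in range(1, 5)]
)
OBS_COV_COLUMNS = ["transect", "year", "visit", "rain_mm", "temp_c", "wind", "day_of_season"]

#: Ordered category labels, for reference and for plotting.
CATEGORY_LABELS = {
    "vegetation height": ("<40 cm", "41-80 cm", "81-120 cm", ">120 cm"),
    "water depth": ("dry", "wet after trampling", "<15 cm", ">15 cm"),
    "litter cover": ("<10%", "10-50%", "50-100%", "100% and >15 cm"),
}

_COV_PREFIX = {"vegetation height": "veg", "water depth": "water", "litter cover": "litter"}


@dataclasses.dataclass(frozen=True)
class CategoryProfile:
    """Proportions of a transect in each of four ordered habitat categories.

    Proportions must sum to 1 (within 1e-9).  Profiles produced by the
    five-point field protocol are multiples of 0.2, but arbitrary proportions
    are accepted.
    """

    proportions: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.proportions) != 4:
            raise ValidationError("CategoryProfile needs exactly 4 proportions")
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < -1e-12) or np.any(p > 1 + 1e-12):
            raise ValidationError(f"proportions outside [0, 1]: {self.proportions}")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {p.sum()!r}, not 1")

    @classmethod
    def from_points(cls, category_counts: Sequence[int], n_points: int = 5) -> "CategoryProfile":
        """Build a profile from the number of field points per category."""
        c = np.asarray(category_counts, dtype=float)
        if c.sum() != n_points:
            raise ValidationError(f"category counts {category_counts} do not sum to {n_points}")
        return cls(tuple(c / n_points))


def _require_columns(df: pd.DataFrame, cols: Sequence[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{name}: missing column(s) {missing}")


class SurveyDataset:
    """Aligned counts, site covariates and observation covariates.

    Parameters
    ----------
    counts : DataFrame with columns transect, year, visit, count.  ``count``
        uses pandas' nullable Int64 dtype; NA marks a missing visit.
    site_cov : DataFrame with one row per (transect, year) holding the twelve
        habitat proportion columns.
    obs_cov : DataFrame with one row per (transect, year, visit).

    Rows are sorted canonically by (transect, year, visit) on construction and
    all invariants are checked: counts are non-negative integers, every
    (transect, year) has exactly J visit rows, covariates cover every count
    row, and each habitat profile sums to 1.
    """

    def __init__(self, counts: pd.DataFrame, site_cov: pd.DataFrame, obs_cov: pd.DataFrame):
        _require_columns(counts, COUNT_COLUMNS, "counts")
        _require_columns(site_cov, SITE_COV_COLUMNS, "site_covariates")
        _require_columns(obs_cov, OBS_COV_COLUMNS, "obs_covariates")

        counts = counts.loc[:, COUNT_COLUMNS].copy()
        site_cov = site_cov.loc[:, SITE_COV_COLUMNS].copy()
        obs_cov = obs_cov.loc[:, OBS_COV_COLUMNS].copy()

        counts["count"] = self._as_nullable_count(counts["count"])
        for df in (counts, site_cov, obs_cov):
            df["year"] = df["year"].astype(int)
        counts["visit"] = counts["visit"].astype(int)
        obs_cov["visit"] = obs_cov["visit"].astype(int)

        self.counts = counts.sort_values(["transect", "year", "visit"], kind="mergesort").reset_index(drop=True)
        self.site_cov = site_cov.sort_values(["transect", "year"], kind="mergesort").reset_index(drop=True)
        self.obs_cov = obs_cov.sort_values(["transect", "year", "visit"], kind="mergesort").reset_index(drop=True)
        self._validate()

    @staticmethod
    def _as_nullable_count(col: pd.Series) -> pd.Series:
        raw = pd.to_numeric(col, errors="coerce")
        # distinguish genuinely missing cells from unparseable junk
        bad = raw.isna() & col.notna() & (col.astype(str).str.strip() != "")
        if bad.any():
            raise ValidationError(f"counts: non-numeric count at row(s) {list(col.index[bad])}")
        frac = raw.notna() & (raw != raw.round())
        if frac.any():
            raise ValidationError(f"counts: non-integer count at row(s) {list(col.index[frac])}")
        neg = raw.notna() & (raw < 0)
        if neg.any():
            raise ValidationError(f"counts: negative count at row(s) {list(col.index[neg])}")
        return raw.round().astype("Int64")

    # ------------------------------------------------------------------
    def _validate(self) -> None:
        sizes = self.counts.groupby(["transect", "year"], sort=False).size()
        j = int(sizes.iloc[0]) if len(sizes) else 0
        if len(sizes) and not (sizes == j).all():
            bad = sizes[sizes != j]
            raise ValidationError(
                f"every (transect, year) must have exactly J={j} visit rows; offending: {bad.index.tolist()}"
            )
        self._J = j

        for tr, yr, grp in ((k[0], k[1], g) for k, g in self.counts.groupby(["transect", "year"], sort=False)):
            visits = sorted(grp["visit"].tolist())
            if visits != list(range(1, j + 1)):
                raise ValidationError(f"({tr}, {yr}): visits {visits} are not 1..{j}")

        site_keys = set(map(tuple, self.site_cov[["transect", "year"]].itertuples(index=False)))
        for key in self.site_years:
            if key not in site_keys:
                raise ValidationError(f"missing site covariates for (transect, year)={key}")

        obs_keys = set(map(tuple, self.obs_cov[["transect", "year", "visit"]].itertuples(index=False)))
        for row in self.counts.itertuples(index=False):
            key = (row.transect, row.year, row.visit)
            if key not in obs_keys:
                raise ValidationError(f"missing observation covariates for (transect, year, visit)={key}")

        for prefix in ("veg", "water", "litter"):
            cols = [f"{prefix}{k}" for k in range(1, 5)]
            block = self.site_cov[cols].to_numpy(dtype=float)
            if np.any(block < -1e-12) or np.any(block > 1 + 1e-12):
                raise ValidationError(f"{prefix} proportions outside [0, 1]")
            sums = block.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                idx = int(np.flatnonzero(bad)[0])
                raise ValidationError(
                    f"{prefix} proportions sum to {sums[idx]!r} (not 1) at site-cov row {idx}"
                )

    # ------------------------------------------------------------------
    @property
    def visits_per_site(self) -> int:
        """J, the number of replicate visits per (transect, year)."""
        return self._J

    @property
    def years(self) -> list[int]:
        return sorted(self.counts["year"].unique().tolist())

    @property
    def transects(self) -> list:
        return sorted(self.counts["transect"].unique().tolist())

    @property
    def site_years(self) -> list[tuple]:
        """Distinct (transect, year) pairs in canonical order."""
        return list(
            self.counts[["transect", "year"]].drop_duplicates().itertuples(index=False, name=None)
        )

    @property
    def max_count(self) -> int:
        c = self.counts["count"]
        return int(c.max()) if c.notna().any() else 0

    def site_profiles(self, transect, year) -> Mapping[str, CategoryProfile]:
        """The three habitat profiles for one (transect, year)."""
        row = self.site_cov[(self.site_cov["transect"] == transect) & (self.site_cov["year"] == year)]
        if row.empty:
            raise KeyError((transect, year))
        row = row.iloc[0]
        return {
            name: CategoryProfile(tuple(float(row[f"{pref}{k}"]) for k in range(1, 5)))
            for name, pref in _COV_PREFIX.items()
        }

    def count_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """Counts as an (S, J) int array plus an observed-visit mask.

        Missing visits appear as 0 with mask False; rows follow
        :attr:`site_years` order, columns follow visit order 1..J.
        """
        s = len(self.site_years)
        y = self.counts["count"].to_numpy(dtype=object).reshape(s, self._J)
        mask = ~pd.isna(y)
        y_int = np.where(mask, y, 0).astype(np.int64)
        return y_int, mask.astype(bool)

    def round_totals(self) -> pd.DataFrame:
        """Per-year totals of counts summed over transects, one column per visit round."""
        piv = self.counts.pivot_table(
            index="year", columns="visit", values="count", aggfunc="sum", observed=True
        )
        piv.columns = [f"round{int(v)}" for v in piv.columns]
        return piv.astype(float)

    # ------------------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SurveyDataset):
            return NotImplemented
        return (
            self.counts.equals(other.counts)
            and self.site_cov.equals(other.site_cov)
            and self.obs_cov.equals(other.obs_cov)
        )

    def __repr__(self) -> str:
        return (
            f"SurveyDataset({len(self.transects)} transects, years {self.years}, "
            f"J={self._J}, {len(self.counts)} count rows)"
        )


def read_survey_dataset(counts_path, site_cov_path, obs_cov_path) -> SurveyDataset:
    """Load and validate a survey dataset from its three CSV files."""
    counts = pd.read_csv(counts_path, float_precision="round_trip")
    site_cov = pd.read_csv(site_cov_path, float_precision="round_trip")
    obs_cov = pd.read_csv(obs_cov_path, float_precision="round_trip")
    return SurveyDataset(counts, site_cov, obs_cov)


def write_survey_dataset(dataset: SurveyDataset, out_dir) -> dict[str, Path]:
    """Write the three CSV files into ``out_dir``; returns the paths written."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "counts": out / "counts.csv",
        "site_covariates": out / "site_covariates.csv",
        "obs_covariates": out / "obs_covariates.csv",
    }
    dataset.counts.to_csv(paths["counts"], index=False)
    dataset.site_cov.to_csv(paths["site_covariates"], index=False)
    dataset.obs_cov.to_csv(paths["obs_covariates"], index=False)
    return paths
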