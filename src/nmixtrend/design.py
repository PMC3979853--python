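"""Model specifications and design-matrix construction.

A candidate model pairs one habitat covariate on abundance (log link) with a
detection structure (logit link).  Every model carries an abundance intercept
and a linear year trend; four-category habitat covariates enter through
reference-cell coding (first category dropped, three columns), so the
coefficients are contrasts against the first category, exactly as the
published effect tables are laid out.

The 45-model candidate set crosses the three abundance covariates with 15
detection structures::

    {Year + B, B + vegetation height, Year + B + vegetation height}
    with B in {constant, rain, temperature, wind, date}

Detection structures without vegetation height always include year-specific
detection intercepts; the conventional short labels for those structures
("constant", "rain", ...) omit the year term, but their parameter counts
include it (3 detection intercepts for a 3-year study: e.g. k=8 for
water depth | constant).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SurveyDataset

__all__ = [
    "ModelSpec",
    "DesignMatrices",
    "build_design",
    "build_candidate_set",
    "ABUNDANCE_COVARIATES",
    "WEATHER_TERMS",
]

ABUNDANCE_COVARIATES = ("water depth", "litter cover", "vegetation height")
WEATHER_TERMS = ("rain", "temperature", "wind", "date")

_SITE_PREFIX = {"vegetation height": "veg", "water depth": "water", "litter cover": "litter"}
_OBS_COLUMN = {"rain": "rain_mm", "temperature": "temp_c", "wind": "wind", "date": "day_of_season"}


class SpecError(ValueError):
    """Unknown covariate or malformed model specification."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One candidate model: abundance covariate + detection terms.

    ``detection_terms`` is the explicit term tuple ("Year", weather terms,
    "vegetation height"); ``label`` is the display name, which may use the
    conventional short form for year-only structures.
    """

    abundance_covariate: str | None
    detection_terms: tuple[str, ...]
    label: str = ""

    def __post_init__(self) -> None:
        if self.abundance_covariate is not None and self.abundance_covariate not in ABUNDANCE_COVARIATES:
            raise SpecError(f"unknown abundance covariate {self.abundance_covariate!r}")
        allowed = {"Year", "vegetation height", *WEATHER_TERMS}
        for term in self.detection_terms:
            if term not in allowed:
                raise SpecError(f"unknown detection term {term!r}")
        if not self.label:
            ab = self.abundance_covariate or "intercept + trend"
            object.__setattr__(self, "label", f"{ab} | {self.detection_label}")

    @property
    def detection_label(self) -> str:
        terms = list(self.detection_terms)
        if "vegetation height" not in terms:
            # year-only structures are conventionally labelled by their
            # weather term (or "constant"); the year intercepts are implicit
            weather = [t for t in terms if t != "Year"]
            return weather[0] if weather else "constant"
        return " + ".join(terms)

    @property
    def has_year_detection(self) -> bool:
        return "Year" in self.detection_terms


@dataclasses.dataclass
class DesignMatrices:
    """Abundance design X (site-years) and detection design W (site-year-visits).

    ``W`` is stored as an (S, J, Pw) array aligned with
    :meth:`SurveyDataset.count_matrix`; ``W2d`` flattens it to (S*J, Pw).
    Continuous observation covariates are z-standardized over all visit
    records; the constants used are kept in ``standardization``.
    """

    X: np.ndarray
    W: np.ndarray
    x_columns: list[str]
    w_columns: list[str]
    site_years: list[tuple]
    years: list[int]
    standardization: dict[str, tuple[float, float]]
    spec: ModelSpec

    @property
    def W2d(self) -> np.ndarray:
        s, j, p = self.W.shape
        return self.W.reshape(s * j, p)

    @property
    def k(self) -> int:
        """Number of free parameters of the fixed-effects (ML) model."""
        return len(self.x_columns) + len(self.w_columns)

    @property
    def n_site_years(self) -> int:
        return self.X.shape[0]


def _habitat_block(dataset: SurveyDataset, covariate: str) -> tuple[np.ndarray, list[str]]:
    """Columns 2..4 of a habitat covariate (reference-cell coding)."""
    pref = _SITE_PREFIX[covariate]
    cols = [f"{pref}{k}" for k in range(2, 5)]
    site = dataset.site_cov.set_index(["transect", "year"])
    block = site.loc[dataset.site_years, cols].to_numpy(dtype=float)
    return block, cols


def build_design(dataset: SurveyDataset, spec: ModelSpec) -> DesignMatrices:
    """Build X and W for one model specification.

    X always holds an intercept plus a year-trend column coded 0, 1, 2, ...
    from the first year, then the three reference-coded habitat columns.  W
    holds year indicators when the spec includes Year (otherwise a single
    intercept), one z-scored column per weather term, and the three
    vegetation-height columns when the spec includes vegetation height.
    """
    years = dataset.years
    site_years = dataset.site_years
    year_index = {y: i for i, y in enumerate(years)}

    trend = np.array([year_index[y] for _, y in site_years], dtype=float)
    if spec.abundance_covariate is not None:
        hab, hab_cols = _habitat_block(dataset, spec.abundance_covariate)
        X = np.column_stack([np.ones_like(trend), trend, hab])
    else:
        hab_cols = []
        X = np.column_stack([np.ones_like(trend), trend])
    x_columns = ["(Intercept)", "trend"] + hab_cols

    s = len(site_years)
    j = dataset.visits_per_site
    w_blocks: list[np.ndarray] = []
    w_columns: list[str] = []
    standardization: dict[str, tuple[float, float]] = {}

    if spec.has_year_detection:
        yi = np.array([year_index[y] for _, y in site_years])
        ind = np.zeros((s, len(years)))
        ind[np.arange(s), yi] = 1.0
        w_blocks.append(np.repeat(ind[:, None, :], j, axis=1))
        w_columns += [f"year[{y}]" for y in years]
    else:
        w_blocks.append(np.ones((s, j, 1)))
        w_columns.append("(Intercept)")

    obs = dataset.obs_cov
    for term in WEATHER_TERMS:
        if term in spec.detection_terms:
            col = obs[_OBS_COLUMN[term]].to_numpy(dtype=float)
            mu, sd = float(np.nanmean(col)), float(np.nanstd(col))
            if sd == 0.0:
                sd = 1.0
            z = ((col - mu) / sd).reshape(s, j, 1)
            w_blocks.append(z)
            w_columns.append(term)
            standardization[term] = (mu, sd)

    if "vegetation height" in spec.detection_terms:
        veg, veg_cols = _habitat_block(dataset, "vegetation height")
        w_blocks.append(np.repeat(veg[:, None, :], j, axis=1))
        w_columns += veg_cols

    W = np.concatenate(w_blocks, axis=2)
    return DesignMatrices(
        X=X,
        W=W,
        x_columns=x_columns,
        w_columns=w_columns,
        site_years=site_years,
        years=years,
        standardization=standardization,
        spec=spec,
    )


def build_candidate_set() -> list[ModelSpec]:
    """The 45 candidate models: 3 abundance covariates x 15 detection structures."""
    weather_options: list[tuple[str, ...]] = [()] + [(w,) for w in WEATHER_TERMS]
    structures: list[tuple[str, ...]] = []
    for b in weather_options:
        structures.append(("Year", *b))                       # Year + B (short label)
        structures.append((*b, "vegetation height"))          # B + veg
        structures.append(("Year", *b, "vegetation height"))  # Year + B + veg
    specs = [
        ModelSpec(abundance_covariate=a, detection_terms=d)
        for a in ABUNDANCE_COVARIATES
        for d in structures
    ]
    assert len(specs) == 45
    return specs


def candidate_table(specs: Sequence[ModelSpec]) -> pd.DataFrame:
    """Tabulate a candidate set for display."""
    return pd.DataFrame(
        {
            "abundance": [s.abundance_covariate for s in specs],
            "detection": [s.detection_label for s in specs],
            "label": [s.label for s in specs],
        }
    )
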