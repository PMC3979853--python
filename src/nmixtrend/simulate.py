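"""Synthetic survey generation emulating the monitoring design.

The generator reproduces the statistical structure of the field protocol:
50 transects, 3 evening visits per transect-year inside a one-week closure
window, habitat profiles measured at 5 points per transect (proportions in
multiples of 0.2), daily weather per visit, and counts produced by the
Poisson-abundance / binomial-detection hierarchy with a transect random
effect and year-specific detection intercepts.

Every generated dataset is paired with a :class:`TruthRecord` holding all
latent quantities (random effects, latent abundances, per-visit detection
probabilities), which is what the oracle and recovery tests run against.

Effect sizes default to the published posterior means for the water-depth
abundance contrasts (0.51, 0.36, 0.26), the rain effect (0.01) and the
vegetation-height detection contrasts (0.65, 0.70, 0.15).  Intercepts and
variance components are not published; the defaults here are calibrated so
that simulated counts match the printed survey summaries (mean ~12 per
transect-visit, SD ~9, range 0-51, detection ~0.55-0.75).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .data import SurveyDataset

__all__ = [
    "StudyParameters",
    "GeneratorConfig",
    "TruthRecord",
    "default_study_parameters",
    "generate_dataset",
    "make_goldens",
]


@dataclasses.dataclass(frozen=True)
class StudyParameters:
    """Generating parameters of the abundance/detection hierarchy.

    Abundance (log link): ``log lambda = beta0 + b_i + trend*t + water
    contrasts``; detection (logit link): ``logit p = alpha_year[t] +
    alpha_rain*z(rain) + vegetation contrasts`` with ``alpha_year[t] ~
    Normal(alpha_det, sigma_year)`` drawn once per year.
    """

    beta0: float = 2.5
    trend: float = 0.0
    beta_water: tuple[float, float, float] = (0.51, 0.36, 0.26)
    sigma_b: float = 0.6
    alpha_det: float = 0.25
    sigma_year: float = 0.3
    alpha_rain: float = 0.01
    alpha_veg: tuple[float, float, float] = (0.65, 0.70, 0.15)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_study_parameters() -> StudyParameters:
    """Published effect sizes plus calibrated (non-published) intercepts."""
    params = StudyParameters()
    for v in (
        params.beta0,
        params.trend,
        *params.beta_water,
        params.sigma_b,
        params.alpha_det,
        params.sigma_year,
        params.alpha_rain,
        *params.alpha_veg,
    ):
        assert np.isfinite(v) and -5 < v < 5
    return params


@dataclasses.dataclass(frozen=True)
class GeneratorConfig:
    """Survey design + generating parameters + nuisance-covariate models.

    ``habitat_probs`` gives the per-category probabilities used to place the
    five field points (multinomial), one 4-vector per covariate.  Rain is
    zero-inflated exponential (P(dry), mean when wet, in mm).
    """

    seed: int
    n_transects: int = 50
    n_years: int = 3
    n_visits: int = 3
    params: StudyParameters = dataclasses.field(default_factory=default_study_parameters)
    habitat_probs: dict = dataclasses.field(
        default_factory=lambda: {
            "veg": (0.25, 0.25, 0.25, 0.25),
            "water": (0.25, 0.25, 0.25, 0.25),
            "litter": (0.25, 0.25, 0.25, 0.25),
        }
    )
    n_points: int = 5
    p_dry: float = 0.6
    rain_mean_mm: float = 4.0
    temp_mean_c: float = 17.0
    temp_sd_c: float = 4.0
    first_year: int = 1

    def __post_init__(self) -> None:
        for key, probs in self.habitat_probs.items():
            if abs(sum(probs) - 1.0) > 1e-9:
                raise ValueError(f"habitat probabilities for {key!r} must sum to 1")
        if self.n_transects < 1 or self.n_years < 1 or self.n_visits < 1:
            raise ValueError("design sizes must be positive")


@dataclasses.dataclass
class TruthRecord:
    """All latent quantities behind one generated dataset."""

    params: StudyParameters
    alpha_year: np.ndarray  # (T,) realized year detection intercepts
    b: np.ndarray  # (n_transects,)
    site_years: list[tuple]  # (transect, year) in canonical order
    lam: np.ndarray  # (S,)
    N: np.ndarray  # (S,)
    p: np.ndarray  # (S, J)
    rain_z: np.ndarray  # (S, J) standardized rain actually used for p

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.as_dict(),
            "alpha_year": self.alpha_year.tolist(),
            "b": self.b.tolist(),
            "site_years": [list(k) for k in self.site_years],
            "lam": self.lam.tolist(),
            "N": self.N.tolist(),
            "p": self.p.tolist(),
            "rain_z": self.rain_z.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path) -> "TruthRecord":
        d = json.loads(Path(path).read_text())
        return cls(
            params=StudyParameters(
                **{
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d["params"].items()
                }
            ),
            alpha_year=np.asarray(d["alpha_year"]),
            b=np.asarray(d["b"]),
            site_years=[tuple(k) for k in d["site_years"]],
            lam=np.asarray(d["lam"]),
            N=np.asarray(d["N"], dtype=np.int64),
            p=np.asarray(d["p"]),
            rain_z=np.asarray(d["rain_z"]),
        )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def generate_dataset(config: GeneratorConfig) -> tuple[SurveyDataset, TruthRecord]:
    """Generate one survey dataset plus its latent truth record.

    Deterministic given ``config.seed``; the returned dataset passes all
    :class:`~nmixtrend.data.SurveyDataset` invariants by construction.
    """
    rng = np.random.default_rng(config.seed)
    pars = config.params
    n_tr, n_yr, J = config.n_transects, config.n_years, config.n_visits
    transects = [f"T{i + 1:03d}" for i in range(n_tr)]
    years = [config.first_year + t for t in range(n_yr)]

    b = rng.normal(0.0, pars.sigma_b, size=n_tr)
    alpha_year = rng.normal(pars.alpha_det, pars.sigma_year, size=n_yr)

    # habitat: 5 field points per covariate per (transect, year)
    hab = {}
    for pref in ("veg", "water", "litter"):
        pts = rng.multinomial(config.n_points, config.habitat_probs[pref], size=(n_tr, n_yr))
        hab[pref] = pts / config.n_points  # (n_tr, n_yr, 4)

    # weather / season covariates per (transect, year, visit)
    wet = rng.random((n_tr, n_yr, J)) >= config.p_dry
    rain = np.where(wet, rng.exponential(config.rain_mean_mm, size=(n_tr, n_yr, J)), 0.0)
    temp = rng.normal(config.temp_mean_c, config.temp_sd_c, size=(n_tr, n_yr, J))
    wind = rng.gamma(2.0, 1.5, size=(n_tr, n_yr, J))
    day0 = rng.integers(1, 31, size=(n_tr, n_yr))
    day = day0[:, :, None] + np.array([0, 2, 5])[None, None, :J]  # within one week

    rain_sd = rain.std()
    rain_z = (rain - rain.mean()) / (rain_sd if rain_sd > 0 else 1.0)

    t_idx = np.arange(n_yr)
    log_lam = (
        pars.beta0
        + b[:, None]
        + pars.trend * t_idx[None, :]
        + np.tensordot(hab["water"][:, :, 1:], np.asarray(pars.beta_water), axes=([2], [0]))
    )
    lam = np.exp(log_lam)  # (n_tr, n_yr)
    N = rng.poisson(lam)

    logit_p = (
        alpha_year[None, :, None]
        + pars.alpha_rain * rain_z
        + np.tensordot(hab["veg"][:, :, 1:], np.asarray(pars.alpha_veg), axes=([2], [0]))[:, :, None]
    )
    p = _sigmoid(logit_p)  # (n_tr, n_yr, J)
    y = rng.binomial(N[:, :, None], p)

    # ---- assemble tables in canonical (transect, year, visit) order ----
    ti, yi, ji = np.meshgrid(np.arange(n_tr), np.arange(n_yr), np.arange(J), indexing="ij")
    counts = pd.DataFrame(
        {
            "transect": np.array(transects)[ti.ravel()],
            "year": np.array(years)[yi.ravel()],
            "visit": ji.ravel() + 1,
            "count": y.ravel(),
        }
    )
    ti2, yi2 = np.meshgrid(np.arange(n_tr), np.arange(n_yr), indexing="ij")
    site = {
        "transect": np.array(transects)[ti2.ravel()],
        "year": np.array(years)[yi2.ravel()],
    }
    for pref in ("veg", "water", "litter"):
        for k in range(4):
            site[f"{pref}{k + 1}"] = hab[pref][:, :, k].ravel()
    site_cov = pd.DataFrame(site)
    obs_cov = pd.DataFrame(
        {
            "transect": np.array(transects)[ti.ravel()],
            "year": np.array(years)[yi.ravel()],
            "visit": ji.ravel() + 1,
            "rain_mm": rain.ravel(),
            "temp_c": temp.ravel(),
            "wind": wind.ravel(),
            "day_of_season": day.ravel(),
        }
    )
    dataset = SurveyDataset(counts, site_cov, obs_cov)

    site_years = [(tr, yr) for tr in transects for yr in years]
    truth = TruthRecord(
        params=pars,
        alpha_year=alpha_year,
        b=b,
        site_years=site_years,
        lam=lam.reshape(-1),
        N=N.reshape(-1).astype(np.int64),
        p=p.reshape(n_tr * n_yr, J),
        rain_z=rain_z.reshape(n_tr * n_yr, J),
    )
    return dataset, truth


GOLDEN_SEED = 20110520
GOLDEN_CONFIG = GeneratorConfig(seed=GOLDEN_SEED, n_transects=5, n_years=2, n_visits=3)


def make_goldens(out_dir) -> dict[str, Path]:
    """Write the small frozen fixture dataset (5 transects, 2 years) + truth.

    Regenerating with :data:`GOLDEN_SEED` must reproduce the committed copy
    bit-for-bit; a test enforces this.
    """
    from .data import write_survey_dataset

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, truth = generate_dataset(GOLDEN_CONFIG)
    paths = write_survey_dataset(dataset, out)
    truth_path = out / "truth.json"
    truth.to_json(truth_path)
    paths["truth"] = truth_path
    return paths
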