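"""Shared fixtures: small datasets and independent oracle implementations."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import nmixtrend as nt


def brute_force_site_loglik(lam: float, p, y, K: int) -> float:
    """Independent linear-space oracle for the site marginal likelihood.

    Sums Poisson(N; lam) * prod_j C(N, y_j) p^y (1-p)^(N-y) term by term
    with exact integer binomial coefficients and fsum accumulation — no
    log-sum-exp, no log-gamma, no shared code with the implementation.
    """
    y = [int(v) for v in y]
    p = list(p)
    terms = []
    for n in range(max(y), K + 1):
        pois = math.exp(-lam) * lam**n / math.factorial(n)
        prod = 1.0
        for yj, pj in zip(y, p):
            prod *= math.comb(n, yj) * pj**yj * (1 - pj) ** (n - yj)
        terms.append(pois * prod)
    return math.log(math.fsum(terms))


def toy_dataset(counts_by_site: dict, seed: int = 0, J: int = 3) -> nt.SurveyDataset:
    """Tiny hand-built dataset; ``counts_by_site`` maps (transect, year) -> counts."""
    rng = np.random.default_rng(seed)
    count_rows, site_rows, obs_rows = [], [], []
    for (tr, yr), cs in counts_by_site.items():
        assert len(cs) == J
        profile = {}
        for pref in ("veg", "water", "litter"):
            pts = rng.multinomial(5, [0.25] * 4) / 5
            for k in range(4):
                profile[f"{pref}{k + 1}"] = pts[k]
        site_rows.append({"transect": tr, "year": yr, **profile})
        for j, c in enumerate(cs, start=1):
            count_rows.append({"transect": tr, "year": yr, "visit": j, "count": c})
            obs_rows.append(
                {
                    "transect": tr,
                    "year": yr,
                    "visit": j,
                    "rain_mm": float(rng.exponential(2.0)),
                    "temp_c": float(rng.normal(17, 3)),
                    "wind": float(rng.gamma(2, 1.5)),
                    "day_of_season": int(rng.integers(1, 30)),
                }
            )
    return nt.SurveyDataset(pd.DataFrame(count_rows), pd.DataFrame(site_rows), pd.DataFrame(obs_rows))


@pytest.fixture(scope="session")
def study_dataset():
    """One study-scale synthetic dataset (50 transects x 3 years x 3 visits)."""
    return nt.generate_dataset(nt.GeneratorConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """A small synthetic dataset for fast model fits."""
    return nt.generate_dataset(nt.GeneratorConfig(seed=5, n_transects=12, n_years=3))


@pytest.fixture(scope="session")
def desk_fit(study_dataset):
    """One converged desk-profile Bayesian fit, shared across tests."""
    import warnings

    ds, _ = study_dataset
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return nt.TrendModel(ds).fit(nt.TrendModelConfig.desk(seed=11))
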