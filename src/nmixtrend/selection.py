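"""AIC model selection over the candidate set: ranking, ΔAIC, Akaike weights."""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .data import SurveyDataset
from .design import ModelSpec, build_candidate_set
from .nmixture import ConvergenceError, NMixtureModel, NMixtureResults

__all__ = ["selection_table", "akaike_weights", "fit_candidate_set", "selection_table_from_aic"]


def akaike_weights(aic: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """ΔAIC to the best model and the normalized evidence weights."""
    aic = np.asarray(aic, dtype=float)
    delta = aic - aic.min()
    w = np.exp(-delta / 2.0)
    return delta, w / w.sum()


def selection_table(fits: Sequence[NMixtureResults]) -> pd.DataFrame:
    """Rank fitted models by AIC, mirroring a standard model-selection table.

    Columns: abundance, detection, k, AIC, dAIC, wAIC — sorted ascending by
    AIC; weights sum to 1.
    """
    if not fits:
        raise ValueError("selection_table needs at least one fit result")
    rows = pd.DataFrame(
        {
            "abundance": [f.spec.abundance_covariate for f in fits],
            "detection": [f.spec.detection_label for f in fits],
            "k": [f.k for f in fits],
            "AIC": [f.aic for f in fits],
            "loglik": [f.loglik for f in fits],
            "converged": [f.converged for f in fits],
        }
    )
    return _finalize(rows)


def selection_table_from_aic(table: pd.DataFrame) -> pd.DataFrame:
    """Selection table computed from externally supplied AIC values.

    ``table`` needs an ``AIC`` column; any identifier columns are carried
    through.  Useful for re-deriving ΔAIC and Akaike weights from a printed
    model-selection table.
    """
    if "AIC" not in table.columns:
        raise ValueError("need an 'AIC' column")
    return _finalize(table.copy())


def _finalize(rows: pd.DataFrame) -> pd.DataFrame:
    delta, w = akaike_weights(rows["AIC"].to_numpy())
    rows["dAIC"] = delta
    rows["wAIC"] = w
    rows = rows.sort_values(["AIC"], kind="mergesort").reset_index(drop=True)
    return rows


def fit_candidate_set(
    dataset: SurveyDataset,
    specs: Sequence[ModelSpec] | None = None,
    K: int | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[pd.DataFrame, list[NMixtureResults]]:
    """Fit every candidate model and tabulate the AIC ranking.

    Non-converged fits are kept (flagged in the table) rather than dropped,
    so the ranking is complete; a fit that fails outright is recorded with
    its best attempt.
    """
    specs = list(specs) if specs is not None else build_candidate_set()
    fits: list[NMixtureResults] = []
    for spec in specs:
        model = NMixtureModel(dataset, spec, K=K)
        try:
            fits.append(model.fit(n_starts=n_starts, seed=seed))
        except ConvergenceError as err:  # keep the best attempt, flagged
            if err.best is not None:
                fits.append(err.best)
    return selection_table(fits), fits
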