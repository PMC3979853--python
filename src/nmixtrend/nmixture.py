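"""Maximum-likelihood fitting of fixed-effects binomial mixture models.

This is the model-screening stage: no transect random effect, abundance on a
log link with intercept + year trend + one habitat covariate, detection on a
logit link per the candidate grammar.  The marginal likelihood surface of
N-mixture models is known to be multimodal in awkward corners of parameter
space, so fits run from several starting points and keep the best.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .data import SurveyDataset
from .design import DesignMatrices, ModelSpec, build_design
from .likelihood import MarginalLikelihood, default_truncation

__all__ = ["NMixtureModel", "NMixtureResults", "ConvergenceError"]


class ConvergenceError(RuntimeError):
    """No optimizer start converged; carries the best attempt."""

    def __init__(self, message: str, best: "NMixtureResults | None" = None):
        super().__init__(message)
        self.best = best


class NMixtureModel:
    """Binomial mixture (N-mixture) model for one candidate specification.

    Parameters
    ----------
    dataset : validated :class:`~nmixtrend.data.SurveyDataset`.
    spec : the candidate :class:`~nmixtrend.design.ModelSpec`.
    K : truncation bound for the latent-abundance sum; defaults to the
        maximum observed count + 100.
    """

    def __init__(self, dataset: SurveyDataset, spec: ModelSpec, K: int | None = None):
        self.dataset = dataset
        self.spec = spec
        self.K = default_truncation(dataset.max_count) if K is None else int(K)
        self.dm: DesignMatrices = build_design(dataset, spec)
        y, mask = dataset.count_matrix()
        self._ml = MarginalLikelihood(self.dm, y, mask, self.K)
        self._y, self._mask = y, mask

    # ------------------------------------------------------------------
    @property
    def k(self) -> int:
        return self.dm.k

    def _default_start(self) -> np.ndarray:
        """Crude moment start: log mean count / nominal detection, logit 0.5."""
        ybar = float(np.where(self._mask, self._y, 0).sum() / max(self._mask.sum(), 1))
        theta = np.zeros(self.k)
        theta[0] = np.log(max(ybar, 0.5) / 0.5)
        px = len(self.dm.x_columns)
        if self.spec.has_year_detection:
            theta[px : px + len(self.dm.years)] = 0.0
        return theta

    def negloglik(self, theta: np.ndarray) -> float:
        px = len(self.dm.x_columns)
        beta = np.asarray(theta[:px], dtype=float)
        alpha = np.asarray(theta[px:], dtype=float)
        if np.any(np.abs(self.dm.X @ beta) > 30):
            return 1e10
        val = self._ml.loglik(beta, alpha)
        if not np.isfinite(val):
            return 1e10
        return -val

    def fit(self, n_starts: int = 5, seed: int = 0, gtol: float = 1e-8) -> "NMixtureResults":
        """Maximize the marginal likelihood from multiple starting points.

        Start 1 is the moment-based default; the rest perturb it with seeded
        Gaussian noise (sd 0.5).  Raises :class:`ConvergenceError` when no
        start converges, carrying the best attempt.
        """
        rng = np.random.default_rng(seed)
        base = self._default_start()
        starts = [base] + [base + rng.normal(0, 0.5, size=self.k) for _ in range(n_starts - 1)]

        best = None
        any_converged = False
        for x0 in starts:
            res = minimize(
                self.negloglik,
                x0,
                method="L-BFGS-B",
                options={"maxiter": 2000, "ftol": 1e-12, "gtol": gtol},
            )
            if best is None or res.fun < best.fun:
                best = res
            any_converged = any_converged or bool(res.success)

        loglik = -float(best.fun)
        results = NMixtureResults(
            model=self,
            params=np.asarray(best.x, dtype=float),
            loglik=loglik,
            k=self.k,
            aic=2 * self.k - 2 * loglik,
            converged=any_converged,
        )
        if not any_converged:
            raise ConvergenceError(f"no start converged for {self.spec.label}", best=results)
        return results


@dataclasses.dataclass
class NMixtureResults:
    """MLEs and fit statistics for one candidate model.

    ``params`` concatenates abundance coefficients (``model.dm.x_columns``)
    and detection coefficients (``model.dm.w_columns``).  ``aic`` satisfies
    AIC = 2k - 2 loglik exactly.
    """

    model: NMixtureModel
    params: np.ndarray
    loglik: float
    k: int
    aic: float
    converged: bool

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec

    @property
    def beta(self) -> np.ndarray:
        return self.params[: len(self.model.dm.x_columns)]

    @property
    def alpha(self) -> np.ndarray:
        return self.params[len(self.model.dm.x_columns):]

    @property
    def standardization(self) -> dict[str, tuple[float, float]]:
        """Z-scoring constants applied to continuous detection covariates."""
        return self.model.dm.standardization

    def params_series(self) -> pd.Series:
        names = self.model.dm.x_columns + [f"det:{c}" for c in self.model.dm.w_columns]
        return pd.Series(self.params, index=names)

    def summary(self) -> pd.DataFrame:
        s = self.params_series().to_frame("estimate")
        s.attrs["label"] = self.spec.label
        s.attrs["loglik"] = self.loglik
        s.attrs["AIC"] = self.aic
        return s

    def __repr__(self) -> str:
        return (
            f"<NMixtureResults {self.spec.label!r}: k={self.k}, "
            f"logL={self.loglik:.2f}, AIC={self.aic:.2f}, converged={self.converged}>"
        )
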