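"""Bayesian hierarchical trend model with a random transect effect.

The final inference model for multi-year monitoring data:

    N_it ~ Poisson(lambda_it)
    log lambda_it = beta0 + b_i + r * t + habitat contrasts
    b_i ~ Normal(0, sigma_b^2)
    y_itj | N_it ~ Binomial(N_it, p_itj)
    logit p_itj = alpha_year[t] + alpha_rain * z(rain_itj) + vegetation contrasts

with vague priors: Normal(0, 10^2) on every regression coefficient and year
intercept, Uniform(0, 10) on sigma_b.  Inference marginalizes the latent
abundances out of the likelihood (log-sum-exp up to K) and samples the
hyperparameters by adaptive random-walk Metropolis; N_it is then drawn from
its discrete full conditional at retained iterations, which is what the
derived quantities (annual totals, correction factors) are built from.

Derived quantities follow the monitoring use of the model: per-year
super-population totals sum N_it over transects; the correction factor
divides that total by the largest single-round raw count of the year; the
trend is reported both on the log scale and as percent change per year.
"""

from __future__ import annotations

import dataclasses
import warnings

import arviz as az
import numpy as np
import pandas as pd
from scipy.special import expit, gammaln
from scipy.stats import linregress

from . import _kernels
from .data import SurveyDataset
from .design import DesignMatrices, ModelSpec, build_design
from .likelihood import TruncationError, default_truncation

__all__ = [
    "TrendModelConfig",
    "TrendModel",
    "TrendResults",
    "PPCResult",
    "correction_factor_draws",
    "extrapolate_population",
]

RHAT_THRESHOLD = 1.1


@dataclasses.dataclass(frozen=True)
class TrendModelConfig:
    """MCMC settings.  ``paper()`` mirrors the published run (3 chains of
    350k iterations, 50k burn-in); ``desk()`` is the short profile used for
    tests and simulation studies."""

    n_chains: int = 3
    n_iter: int = 350_000
    n_burnin: int = 50_000
    thin: int = 300
    seed: int = 0
    K: int | None = None
    coef_prior_sd: float = 10.0
    sigma_b_upper: float = 10.0

    def __post_init__(self) -> None:
        if self.n_burnin >= self.n_iter:
            raise ValueError("n_burnin must be < n_iter")
        if self.n_chains < 2:
            raise ValueError("need >= 2 chains for convergence diagnostics")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    @classmethod
    def paper(cls, seed: int = 0, **kw) -> "TrendModelConfig":
        return cls(n_iter=350_000, n_burnin=50_000, thin=300, seed=seed, **kw)

    @classmethod
    def desk(cls, seed: int = 0, **kw) -> "TrendModelConfig":
        return cls(n_iter=20_000, n_burnin=4_000, thin=16, seed=seed, **kw)


class TrendModel:
    """Hierarchical N-mixture trend model bound to one dataset.

    Parameters
    ----------
    dataset : validated survey dataset.
    abundance_covariate : habitat covariate on abundance (default
        ``"water depth"``, the selected structure); ``None`` drops habitat
        terms, leaving intercept + trend.
    detection_terms : detection structure (default Year + rain + vegetation
        height, the selected structure).
    """

    def __init__(
        self,
        dataset: SurveyDataset,
        abundance_covariate: str | None = "water depth",
        detection_terms: tuple[str, ...] = ("Year", "rain", "vegetation height"),
    ):
        self.dataset = dataset
        self.spec = ModelSpec(abundance_covariate, tuple(detection_terms))
        self.dm: DesignMatrices = build_design(dataset, self.spec)
        self._y, self._mask = dataset.count_matrix()
        transects = dataset.transects
        t_index = {t: i for i, t in enumerate(transects)}
        self._tix = np.array([t_index[t] for t, _ in dataset.site_years], dtype=np.int64)
        self.n_transects = len(transects)

    @property
    def param_names(self) -> list[str]:
        return self.dm.x_columns + [f"det:{c}" for c in self.dm.w_columns] + ["sigma_b"]

    def _init_theta(self, sigma_b_upper: float = 10.0) -> np.ndarray:
        px, pw = len(self.dm.x_columns), len(self.dm.w_columns)
        theta = np.zeros(px + pw + 1)
        ybar = float(np.where(self._mask, self._y, 0).sum() / max(self._mask.sum(), 1))
        theta[0] = np.log(max(ybar, 0.5) / 0.6)
        if self.spec.has_year_detection:
            theta[px : px + len(self.dm.years)] = 0.4
        # start log sigma_b well inside the prior support
        theta[-1] = min(np.log(0.3), np.log(sigma_b_upper) - 1.0)
        return theta

    def fit(
        self,
        config: TrendModelConfig | None = None,
        chain_seeds: list[int] | None = None,
    ) -> "TrendResults":
        """Run the MCMC and return posterior draws with diagnostics.

        ``chain_seeds`` overrides the per-chain seeds derived from
        ``config.seed`` (passing identical seeds produces identical chains,
        which the diagnostics flag as degenerate initialization).
        Non-convergence (any split-R-hat >= 1.1) is flagged on the result
        and warned about, never silently dropped.
        """
        config = config or TrendModelConfig.desk()
        K = config.K if config.K is not None else default_truncation(self.dataset.max_count)
        if K < self.dataset.max_count:
            raise TruncationError(f"K={K} below max observed count {self.dataset.max_count}")

        if chain_seeds is None:
            chain_seeds = [(config.seed * 1009 + 7919 * c + 1) % (2**31) for c in range(config.n_chains)]
        if len(chain_seeds) != config.n_chains:
            raise ValueError("need one seed per chain")

        X = np.ascontiguousarray(self.dm.X, dtype=float)
        W = np.ascontiguousarray(self.dm.W, dtype=float)
        y = np.ascontiguousarray(self._y, dtype=np.int64)
        mask = np.ascontiguousarray(self._mask, dtype=np.bool_)
        ymax = np.where(mask, y, 0).max(axis=1).astype(np.int64)
        lgam = gammaln(np.arange(K + 2, dtype=float))
        binco = _kernels.precompute_binco(y, mask, ymax, lgam, K)

        tyx = np.ascontiguousarray(self.dm.X[:, 1], dtype=np.int64)  # trend column = year index
        if self.spec.has_year_detection:
            year_start, n_year_cols = 0, len(self.dm.years)
        else:
            year_start, n_year_cols = 0, 0

        base = self._init_theta(config.sigma_b_upper)
        thetas, bs, Ns = [], [], []
        accs = []
        for c, cs in enumerate(chain_seeds):
            rng = np.random.default_rng(cs)
            theta0 = base + rng.normal(0, 0.1, size=base.size)
            theta0[-1] = min(theta0[-1], np.log(config.sigma_b_upper) - 0.5)
            b0 = rng.normal(0, 0.1, size=self.n_transects)
            th, bb, nn, at, ab_ = _kernels.run_chain(
                X,
                W,
                self._tix,
                tyx,
                year_start,
                n_year_cols,
                y,
                mask,
                ymax,
                binco,
                lgam,
                K,
                self.n_transects,
                config.n_iter,
                config.n_burnin,
                config.thin,
                int(cs),
                theta0,
                b0,
                config.coef_prior_sd,
                config.sigma_b_upper,
            )
            thetas.append(th)
            bs.append(bb)
            Ns.append(nn)
            accs.append((at, ab_))

        theta_draws = np.stack(thetas)  # (chains, kept, D)
        b_draws = np.stack(bs)
        n_draws = np.stack(Ns)

        results = TrendResults(
            model=self,
            config=config,
            K=K,
            theta_draws=theta_draws,
            b_draws=b_draws,
            n_draws=n_draws,
            accept_rates=accs,
            chain_seeds=list(chain_seeds),
        )
        if results.degenerate:
            warnings.warn(
                "chains are identical draw-for-draw: degenerate initialization "
                "(identical chain seeds); between-chain diagnostics carry no information",
                RuntimeWarning,
                stacklevel=2,
            )
        elif not results.converged:
            bad = {k: round(float(v), 3) for k, v in results.rhat.items() if v >= RHAT_THRESHOLD}
            warnings.warn(f"MCMC may not have converged; R-hat >= {RHAT_THRESHOLD}: {bad}", RuntimeWarning, stacklevel=2)
        return results


class TrendResults:
    """Posterior draws, diagnostics and derived monitoring quantities."""

    def __init__(self, model, config, K, theta_draws, b_draws, n_draws, accept_rates, chain_seeds):
        self.model = model
        self.config = config
        self.K = K
        self.theta_draws = theta_draws  # (chains, kept, D); last column is log sigma_b
        self.b_draws = b_draws
        self.n_draws = n_draws  # (chains, kept, S) latent abundances
        self.accept_rates = accept_rates
        self.chain_seeds = chain_seeds
        self.param_names = model.param_names
        self._rhat: dict[str, float] | None = None

    # ------------------------------------------------------------------
    @property
    def posterior(self) -> dict[str, np.ndarray]:
        """Named draws, (chains, kept) per parameter; sigma_b on its natural scale."""
        out = {}
        for i, name in enumerate(self.param_names[:-1]):
            out[name] = self.theta_draws[:, :, i]
        out["sigma_b"] = np.exp(self.theta_draws[:, :, -1])
        return out

    def to_inference_data(self) -> az.InferenceData:
        post = {k.replace(":", "_"): v for k, v in self.posterior.items()}
        post["b"] = self.b_draws
        post["N"] = self.n_draws
        return az.from_dict(posterior=post)

    @property
    def degenerate(self) -> bool:
        """True when any two chains are identical draw-for-draw."""
        ch = self.theta_draws
        for i in range(ch.shape[0]):
            for j in range(i + 1, ch.shape[0]):
                if np.array_equal(ch[i], ch[j]):
                    return True
        return False

    @property
    def rhat(self) -> dict[str, float]:
        """Split-R-hat per hyperparameter (identical chains report exactly 1)."""
        if self._rhat is None:
            if self.degenerate:
                # identical chains: between-chain variance is zero by
                # construction; report 1 and rely on the degenerate flag
                self._rhat = {name: 1.0 for name in self.param_names}
            else:
                ds = az.from_dict(posterior={"theta": self.theta_draws})
                r = az.rhat(ds)["theta"].values
                self._rhat = {name: float(r[i]) for i, name in enumerate(self.param_names)}
        return self._rhat

    @property
    def converged(self) -> bool:
        return (not self.degenerate) and all(v < RHAT_THRESHOLD for v in self.rhat.values())

    # ------------------------------------------------------------------
    def _flat(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(-1, *arr.shape[2:])

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, 95% CrI and R-hat per hyperparameter."""
        flat = self._flat(self.theta_draws).copy()
        flat[:, -1] = np.exp(flat[:, -1])
        q = np.quantile(flat, [0.025, 0.975], axis=0)
        return pd.DataFrame(
            {
                "mean": flat.mean(axis=0),
                "sd": flat.std(axis=0, ddof=1),
                "lcl": q[0],
                "ucl": q[1],
                "rhat": [self.rhat[n] for n in self.param_names],
            },
            index=self.param_names,
        )

    # ------------------------------------------------------------------
    def annual_total_draws(self) -> pd.DataFrame:
        """Posterior draws of the per-year super-population total, sum_i N_it."""
        years = self.model.dm.years
        year_of_site = np.array([y for _, y in self.model.dm.site_years])
        flat_n = self._flat(self.n_draws)  # (M, S)
        cols = {y: flat_n[:, year_of_site == y].sum(axis=1) for y in years}
        return pd.DataFrame(cols)

    def annual_totals(self) -> pd.DataFrame:
        """Posterior mean, sd and 95% CrI of the annual totals."""
        draws = self.annual_total_draws()
        q = draws.quantile([0.025, 0.975])
        return pd.DataFrame(
            {
                "mean": draws.mean(),
                "sd": draws.std(ddof=1),
                "lcl": q.loc[0.025],
                "ucl": q.loc[0.975],
            }
        ).rename_axis("year")

    def correction_factor_draws(self) -> pd.DataFrame:
        """Per-year posterior of (annual total) / (max single-round raw count)."""
        totals = self.annual_total_draws()
        max_round = self.model.dataset.round_totals().max(axis=1)
        return correction_factor_draws(totals, max_round)

    def correction_factors(self) -> pd.DataFrame:
        draws = self.correction_factor_draws()
        q = draws.quantile([0.025, 0.975])
        return pd.DataFrame(
            {"mean": draws.mean(), "lcl": q.loc[0.025], "ucl": q.loc[0.975]}
        ).rename_axis("year")

    def extrapolate_population(self, full_count: int, year) -> pd.Series:
        """Scale an uncorrected full count by the year's correction factor."""
        factor = self.correction_factor_draws()[year].to_numpy()
        return extrapolate_population(full_count, factor)

    def trend_summary(self) -> pd.Series:
        """Trend posterior and the implied percent change per year."""
        r = self._flat(self.theta_draws)[:, self.param_names.index("trend")]
        lcl, ucl = np.quantile(r, [0.025, 0.975])
        return pd.Series(
            {
                "mean": r.mean(),
                "sd": r.std(ddof=1),
                "lcl": lcl,
                "ucl": ucl,
                "pct_change_per_year": 100 * (np.exp(r.mean()) - 1),
                "pct_change_lcl": 100 * (np.exp(lcl) - 1),
                "pct_change_ucl": 100 * (np.exp(ucl) - 1),
            }
        )

    # ------------------------------------------------------------------
    def detection_prob_draws(self, max_draws: int | None = None) -> np.ndarray:
        """Per-draw detection probabilities p_itj, shape (M, S, J)."""
        px, pw = len(self.model.dm.x_columns), len(self.model.dm.w_columns)
        alpha = self._flat(self.theta_draws)[:, px : px + pw]
        if max_draws is not None and alpha.shape[0] > max_draws:
            alpha = alpha[:: max(alpha.shape[0] // max_draws, 1)][:max_draws]
        wlin = np.einsum("mq,sjq->msj", alpha, self.model.dm.W)
        return expit(wlin)

    def posterior_predictive_check(self, seed: int = 0, max_draws: int = 1000) -> "PPCResult":
        """Posterior predictive check with a Pearson chi-square discrepancy.

        For each retained draw, counts are re-simulated from Binomial(N, p)
        and T = sum (y - Np)^2 / (Np + 0.5) is compared between replicate
        and observed data; the Bayesian p-value is P(T_rep >= T_obs).  Also
        reports the least-squares slope of observed counts on posterior-mean
        predicted counts as a secondary fit summary.
        """
        rng = np.random.default_rng(seed)
        y, mask = self.model._y, self.model._mask
        flat_n = self._flat(self.n_draws)
        m_total = flat_n.shape[0]
        step = max(m_total // max_draws, 1)
        idx = np.arange(0, m_total, step)[:max_draws]

        px, pw = len(self.model.dm.x_columns), len(self.model.dm.w_columns)
        alpha = self._flat(self.theta_draws)[idx, px : px + pw]
        wlin = np.einsum("mq,sjq->msj", alpha, self.model.dm.W)
        p = expit(wlin)  # (M, S, J)
        n = flat_n[idx][:, :, None]  # (M, S, 1)

        ey = n * p
        denom = ey + 0.5
        obs = mask[None, :, :]
        t_obs = np.where(obs, (y[None, :, :] - ey) ** 2 / denom, 0.0).sum(axis=(1, 2))
        y_rep = rng.binomial(np.broadcast_to(n, p.shape), p)
        t_rep = np.where(obs, (y_rep - ey) ** 2 / denom, 0.0).sum(axis=(1, 2))

        p_value = float(np.mean(t_rep >= t_obs))
        pred_mean = ey.mean(axis=0)[mask]
        slope = float(linregress(pred_mean, y[mask]).slope)
        return PPCResult(p_value=p_value, slope=slope, n_draws=len(idx))

    # ------------------------------------------------------------------
    def plot_annual_totals(self, ax=None):
        """Posterior means and 95% CrIs of the annual totals."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        tab = self.annual_totals()
        ax.errorbar(
            tab.index,
            tab["mean"],
            yerr=[tab["mean"] - tab["lcl"], tab["ucl"] - tab["mean"]],
            fmt="o",
            capsize=3,
        )
        ax.set_xlabel("year")
        ax.set_ylabel("estimated singing males (super-population)")
        return ax

    def __repr__(self) -> str:
        return (
            f"<TrendResults {self.theta_draws.shape[0]} chains x {self.theta_draws.shape[1]} draws, "
            f"converged={self.converged}>"
        )


@dataclasses.dataclass(frozen=True)
class PPCResult:
    p_value: float
    slope: float
    n_draws: int


def correction_factor_draws(totals: pd.DataFrame, max_round_totals: pd.Series) -> pd.DataFrame:
    """Divide annual-total draws (columns = years) by per-year max round counts."""
    out = {}
    for year in totals.columns:
        denom = float(max_round_totals[year])
        if denom <= 0:
            raise ZeroDivisionError(f"year {year}: maximum raw round total is zero; ratio undefined")
        out[year] = totals[year].to_numpy() / denom
    return pd.DataFrame(out)


def extrapolate_population(full_count: int, factor_draws: np.ndarray) -> pd.Series:
    """Posterior of full_count x correction factor, rounded to whole birds."""
    if full_count <= 0:
        raise ValueError("full_count must be a positive integer")
    draws = np.asarray(factor_draws, dtype=float) * full_count
    lcl, ucl = (np.quantile(draws, [0.025, 0.975]) if draws.size > 1 else (draws[0], draws[0]))
    return pd.Series(
        {
            "mean": int(round(draws.mean())),
            "lcl": int(round(float(lcl))),
            "ucl": int(round(float(ucl))),
        }
    )
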