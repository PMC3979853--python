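"""Numba-compiled hot paths: marginal likelihood sums and the MCMC inner loop.

The latent abundance N at each site-year is summed out of the
Poisson(lambda) x prod_j Binomial(y_j | N, p_j) hierarchy up to a truncation
bound K.  Writing w = logit p, the per-site log marginal is

    log sum_{N=ymax}^{K} exp( N*(eta + c0) - lgamma(N+1) + binco[N] )
        - lambda + c1

with eta = log lambda, c0 = sum_j log(1-p_j), c1 = sum_j y_j * w_j, and
binco[N] = sum_j log C(N, y_j) a data-only table precomputed once.  The
summand is log-concave in N, so the streaming log-sum-exp breaks out once
terms fall 45 log-units below the running maximum past the mode.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_BREAK = 45.0


@njit(cache=True)
def _softplus(x):
    if x > 30.0:
        return x
    if x < -30.0:
        return np.exp(x)
    return np.log1p(np.exp(x))


@njit(cache=True)
def precompute_binco(y, mask, ymax, lgam, K):
    """Data-only table binco[s, N] = sum over observed visits of log C(N, y_sj)."""
    S, J = y.shape
    out = np.zeros((S, K + 1))
    for s in range(S):
        for N in range(ymax[s], K + 1):
            v = 0.0
            for j in range(J):
                if mask[s, j]:
                    v += lgam[N + 1] - lgam[y[s, j] + 1] - lgam[N - y[s, j] + 1]
            out[s, N] = v
    return out


@njit(cache=True)
def det_consts(wlin, y, mask, c0, c1):
    """Detection constants c0 (sum log(1-p)) and c1 (sum y*logit p) per site."""
    S, J = wlin.shape
    for s in range(S):
        a = 0.0
        b = 0.0
        for j in range(J):
            if mask[s, j]:
                a -= _softplus(wlin[s, j])
                b += y[s, j] * wlin[s, j]
        c0[s] = a
        c1[s] = b


@njit(cache=True)
def site_logliks(eta, c0, c1, ymax, binco, lgam, K, out):
    """Per-site marginal log-likelihoods; returns their sum."""
    S = eta.shape[0]
    total = 0.0
    for s in range(S):
        lam = np.exp(eta[s])
        u = eta[s] + c0[s]
        m = -1.0e308
        acc = 0.0
        prev = -1.0e308
        for N in range(ymax[s], K + 1):
            t = N * u - lgam[N + 1] + binco[s, N]
            if t > m:
                acc = acc * np.exp(m - t) + 1.0
                m = t
            else:
                acc += np.exp(t - m)
                if t < prev and t < m - _BREAK:
                    break
            prev = t
        ll = m + np.log(acc) - lam + c1[s]
        out[s] = ll
        total += ll
    return total


@njit(cache=True)
def sample_latent_n(eta, c0, c1, ymax, binco, lgam, K, unif, out):
    """Draw N_s from its discrete full conditional, one uniform per site."""
    S = eta.shape[0]
    for s in range(S):
        u = eta[s] + c0[s]
        m = -1.0e308
        prev = -1.0e308
        n_hi = K
        for N in range(ymax[s], K + 1):
            t = N * u - lgam[N + 1] + binco[s, N]
            if t > m:
                m = t
            elif t < prev and t < m - _BREAK:
                n_hi = N
                break
            prev = t
        z = 0.0
        for N in range(ymax[s], n_hi + 1):
            z += np.exp(N * u - lgam[N + 1] + binco[s, N] - m)
        target = unif[s] * z
        acc = 0.0
        pick = n_hi
        for N in range(ymax[s], n_hi + 1):
            acc += np.exp(N * u - lgam[N + 1] + binco[s, N] - m)
            if acc >= target:
                pick = N
                break
        out[s] = pick


@njit(cache=True)
def _linpreds(X, W, beta, alpha, b, tix, eta, wlin):
    S = X.shape[0]
    J = W.shape[1]
    for s in range(S):
        v = b[tix[s]]
        for q in range(X.shape[1]):
            v += X[s, q] * beta[q]
        eta[s] = v
        for j in range(J):
            w = 0.0
            for q in range(W.shape[2]):
                w += W[s, j, q] * alpha[q]
            wlin[s, j] = w


@njit(cache=True)
def run_chain(
    X,
    W,
    tix,
    tyx,
    year_start,
    n_years,
    y,
    mask,
    ymax,
    binco,
    lgam,
    K,
    n_transects,
    n_iter,
    n_burn,
    thin,
    seed,
    theta0,
    b0,
    coef_prior_sd,
    sigma_upper,
):
    """One blocked-Metropolis chain for the hierarchical trend model.

    Parameter vector theta = [beta (Px), alpha (Pw), log sigma_b].  Updates
    per iteration:

    1. fixed-effect block (everything except year-specific detection
       intercepts) by adaptive random-walk Metropolis: global scale tuned to
       acceptance 0.234 and, during burn-in, the empirical covariance of the
       block (frozen afterwards, so retained draws come from a fixed kernel);
    2. year-specific detection intercepts (columns ``year_start ..
       year_start+n_years-1`` of alpha, when ``n_years > 0``) by independent
       scalar Metropolis per year — valid jointly because site-years
       partition by year and priors are independent;
    3. transect random effects b by independent scalar Metropolis per
       transect (same argument, partition by transect);
    4. a likelihood-invariant translation move beta0 -> beta0 + d,
       b_i -> b_i - d, accepted on the prior ratio alone, which decouples
       the abundance intercept from the random-effect mean.

    Latent N is drawn from its discrete full conditional at retained
    iterations only.  Returns (thetas, bs, Ns, accept_fixed, accept_b).
    """
    np.random.seed(seed)
    Px = X.shape[1]
    Pw = W.shape[2]
    D = Px + Pw + 1
    S = X.shape[0]
    J = W.shape[1]

    log10 = np.log(10.0)
    log_sigma_upper = np.log(sigma_upper)

    # indices of the adaptive fixed-effect block: all of theta except the
    # year-intercept columns of alpha
    n_free = D - n_years
    free_idx = np.empty(n_free, dtype=np.int64)
    pos = 0
    for q in range(D):
        in_year = n_years > 0 and Px + year_start <= q < Px + year_start + n_years
        if not in_year:
            free_idx[pos] = q
            pos += 1

    def _logprior(th):
        lp = 0.0
        for q in range(D - 1):
            lp -= 0.5 * (th[q] / coef_prior_sd) ** 2
        lsig = th[D - 1]
        if lsig >= log_sigma_upper:
            return -np.inf
        lp += lsig - log10  # Jacobian: Uniform(0, upper) prior on sigma_b
        return lp

    def _b_logprior(th, bb):
        sig = np.exp(th[D - 1])
        lp = 0.0
        for i in range(n_transects):
            lp -= 0.5 * (bb[i] / sig) ** 2
        lp -= n_transects * th[D - 1]
        return lp

    theta = theta0.copy()
    b = b0.copy()

    eta = np.empty(S)
    wlin = np.empty((S, J))
    wlin_prop = np.empty((S, J))
    c0 = np.empty(S)
    c1 = np.empty(S)
    c0_prop = np.empty(S)
    c1_prop = np.empty(S)
    site_ll = np.empty(S)
    site_ll_prop = np.empty(S)
    eta_prop = np.empty(S)
    theta_prop = np.empty(D)
    z = np.empty(n_free)
    b_prop = np.empty(n_transects)
    b_acc_flag = np.empty(n_transects, dtype=np.bool_)
    ll_tr = np.zeros(n_transects)
    ll_tr_prop = np.zeros(n_transects)
    ll_yr = np.zeros(max(n_years, 1))
    ll_yr_prop = np.zeros(max(n_years, 1))
    dyear = np.zeros(max(n_years, 1))
    year_acc = np.empty(max(n_years, 1), dtype=np.bool_)

    _linpreds(X, W, theta[:Px], theta[Px : Px + Pw], b, tix, eta, wlin)
    det_consts(wlin, y, mask, c0, c1)
    cur_ll = site_logliks(eta, c0, c1, ymax, binco, lgam, K, site_ll)
    cur_lp = cur_ll + _logprior(theta) + _b_logprior(theta, b)

    scale = 0.3 / np.sqrt(n_free)
    chol = np.eye(n_free)
    use_chol = False
    mean_acc = np.zeros(n_free)
    cov_acc = np.zeros((n_free, n_free))
    n_cov = 0
    b_scale = 0.3
    yr_scale = 0.1

    n_kept = (n_iter - n_burn) // thin
    thetas = np.empty((n_kept, D))
    bs = np.empty((n_kept, n_transects))
    Ns = np.empty((n_kept, S), dtype=np.int64)

    acc_fixed_total = 0.0
    acc_b_total = 0.0
    kept = 0

    for it in range(n_iter):
        # ---- 1. fixed-effect block ----
        for q in range(n_free):
            z[q] = np.random.normal()
        for q in range(D):
            theta_prop[q] = theta[q]
        if use_chol:
            for q in range(n_free):
                v = 0.0
                for r in range(q + 1):
                    v += chol[q, r] * z[r]
                theta_prop[free_idx[q]] += scale * v
        else:
            for q in range(n_free):
                theta_prop[free_idx[q]] += scale * z[q]

        acc_flag = 0.0
        lp_prior = _logprior(theta_prop)
        if np.isfinite(lp_prior):
            _linpreds(X, W, theta_prop[:Px], theta_prop[Px : Px + Pw], b, tix, eta_prop, wlin_prop)
            det_consts(wlin_prop, y, mask, c0_prop, c1_prop)
            prop_ll = site_logliks(eta_prop, c0_prop, c1_prop, ymax, binco, lgam, K, site_ll_prop)
            prop_lp = prop_ll + lp_prior + _b_logprior(theta_prop, b)
            if np.log(np.random.random()) < prop_lp - cur_lp:
                for q in range(D):
                    theta[q] = theta_prop[q]
                cur_ll = prop_ll
                cur_lp = prop_lp
                for s in range(S):
                    site_ll[s] = site_ll_prop[s]
                    eta[s] = eta_prop[s]
                    c0[s] = c0_prop[s]
                    c1[s] = c1_prop[s]
                    for j in range(J):
                        wlin[s, j] = wlin_prop[s, j]
                acc_flag = 1.0
        acc_fixed_total += acc_flag

        if it < n_burn:
            gamma = 2.0 / (100.0 + it) ** 0.6
            scale *= np.exp(gamma * (acc_flag - 0.234))
            if it >= 100:
                n_cov += 1
                for q in range(n_free):
                    mean_acc[q] += theta[free_idx[q]]
                    for r in range(n_free):
                        cov_acc[q, r] += theta[free_idx[q]] * theta[free_idx[r]]
                if n_cov >= max(200, 2 * n_free) and it % 100 == 0:
                    cov = cov_acc / n_cov
                    for q in range(n_free):
                        mq = mean_acc[q] / n_cov
                        for r in range(n_free):
                            cov[q, r] -= mq * (mean_acc[r] / n_cov)
                    for q in range(n_free):
                        cov[q, q] += 1.0e-6
                    chol = np.linalg.cholesky(cov)
                    if not use_chol:
                        use_chol = True
                        scale = 2.38 / np.sqrt(n_free)

        # ---- 2. year-specific detection intercepts ----
        if n_years > 0:
            for t in range(n_years):
                dyear[t] = yr_scale * np.random.normal()
                ll_yr[t] = 0.0
                ll_yr_prop[t] = 0.0
            for s in range(S):
                d = dyear[tyx[s]]
                for j in range(J):
                    wlin_prop[s, j] = wlin[s, j] + d
            det_consts(wlin_prop, y, mask, c0_prop, c1_prop)
            site_logliks(eta, c0_prop, c1_prop, ymax, binco, lgam, K, site_ll_prop)
            for s in range(S):
                ll_yr[tyx[s]] += site_ll[s]
                ll_yr_prop[tyx[s]] += site_ll_prop[s]
            n_yr_acc = 0
            for t in range(n_years):
                q = Px + year_start + t
                a_old = theta[q]
                a_new = a_old + dyear[t]
                dlp = (
                    ll_yr_prop[t]
                    - ll_yr[t]
                    - 0.5 * (a_new / coef_prior_sd) ** 2
                    + 0.5 * (a_old / coef_prior_sd) ** 2
                )
                if np.log(np.random.random()) < dlp:
                    theta[q] = a_new
                    year_acc[t] = True
                    n_yr_acc += 1
                else:
                    year_acc[t] = False
            for s in range(S):
                if year_acc[tyx[s]]:
                    site_ll[s] = site_ll_prop[s]
                    c0[s] = c0_prop[s]
                    c1[s] = c1_prop[s]
                    for j in range(J):
                        wlin[s, j] = wlin_prop[s, j]
            if it < n_burn:
                gamma = 2.0 / (100.0 + it) ** 0.6
                yr_scale *= np.exp(gamma * (n_yr_acc / n_years - 0.44))

        # ---- 3. transect random effects ----
        sig = np.exp(theta[D - 1])
        for i in range(n_transects):
            ll_tr[i] = 0.0
            ll_tr_prop[i] = 0.0
        for s in range(S):
            ll_tr[tix[s]] += site_ll[s]
        for i in range(n_transects):
            b_prop[i] = b[i] + b_scale * np.random.normal()
        for s in range(S):
            eta_prop[s] = eta[s] - b[tix[s]] + b_prop[tix[s]]
        site_logliks(eta_prop, c0, c1, ymax, binco, lgam, K, site_ll_prop)
        for s in range(S):
            ll_tr_prop[tix[s]] += site_ll_prop[s]
        n_b_acc = 0
        for i in range(n_transects):
            dlp = (
                ll_tr_prop[i]
                - ll_tr[i]
                - 0.5 * (b_prop[i] / sig) ** 2
                + 0.5 * (b[i] / sig) ** 2
            )
            if np.log(np.random.random()) < dlp:
                b[i] = b_prop[i]
                b_acc_flag[i] = True
                n_b_acc += 1
            else:
                b_acc_flag[i] = False
        for s in range(S):
            if b_acc_flag[tix[s]]:
                eta[s] = eta_prop[s]
                site_ll[s] = site_ll_prop[s]
        rate_b = n_b_acc / n_transects
        acc_b_total += rate_b
        if it < n_burn:
            gamma = 2.0 / (100.0 + it) ** 0.6
            b_scale *= np.exp(gamma * (rate_b - 0.44))

        # ---- 4. intercept/random-effect translation (likelihood-invariant) ----
        d = (sig / np.sqrt(n_transects + 1.0)) * np.random.normal()
        beta0_new = theta[0] + d
        dlp = -0.5 * (beta0_new / coef_prior_sd) ** 2 + 0.5 * (theta[0] / coef_prior_sd) ** 2
        sb = 0.0
        for i in range(n_transects):
            sb += b[i]
        # sum((b-d)^2) - sum(b^2) = -2 d sum(b) + n d^2
        dlp -= (-2.0 * d * sb + n_transects * d * d) / (2.0 * sig * sig)
        if np.log(np.random.random()) < dlp:
            theta[0] = beta0_new
            for i in range(n_transects):
                b[i] -= d
            # eta is unchanged: beta0 shift cancels the b shift exactly

        cur_ll = 0.0
        for s in range(S):
            cur_ll += site_ll[s]
        cur_lp = cur_ll + _logprior(theta) + _b_logprior(theta, b)

        # ---- record ----
        if it >= n_burn and (it - n_burn) % thin == 0 and kept < n_kept:
            for q in range(D):
                thetas[kept, q] = theta[q]
            for i in range(n_transects):
                bs[kept, i] = b[i]
            unif = np.random.random(S)
            nvec = np.empty(S, dtype=np.int64)
            sample_latent_n(eta, c0, c1, ymax, binco, lgam, K, unif, nvec)
            for s in range(S):
                Ns[kept, s] = nvec[s]
            kept += 1

    return thetas, bs, Ns, acc_fixed_total / n_iter, acc_b_total / n_iter
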