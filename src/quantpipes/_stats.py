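"""Shared numerics: cyclic-loess normalization and moderated t-statistics.

Both the SILAC and the BioID pipelines normalize log2 intensity matrices
with a fast cyclic loess against a per-feature mean reference and test
with an empirical-Bayes moderated t in which per-feature variances are
shrunk toward a pooled prior. The prior (d0, s0^2) is a scaled inverse
chi-square fitted by matching the moments of log sample variances
(digamma/trigamma moment equations), the classical variance-moderation
scheme for small-replicate omics designs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

# ---------------------------------------------------------------------------
# Cyclic loess normalization
# ---------------------------------------------------------------------------


def loess_normalize(
    matrix: np.ndarray,
    span: float = 0.7,
    iterations: int = 3,
    min_complete: int = 10,
) -> np.ndarray:
    """Fast cyclic loess of a features x channels log2 matrix to its mean.

    Per iteration the reference A is the per-feature mean of observed
    channels; each channel's deviation M = x - A is smoothed against A on
    complete-case features and the fitted trend subtracted wherever the
    channel is observed. Missing values (NaN) are left untouched. With
    fewer than ``min_complete`` complete features the fit is unreliable
    and the matrix is median-centered instead (with a warning).
    """
    x = np.array(matrix, dtype=float, copy=True)
    if x.ndim != 2 or x.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 channels")
    complete = ~np.isnan(x).any(axis=1)
    if complete.sum() < min_complete:
        warnings.warn(
            f"only {int(complete.sum())} complete features; falling back to "
            "median centering",
            stacklevel=2,
        )
        col_med = np.nanmedian(x, axis=0)
        return x - (col_med - np.mean(col_med))

    for _ in range(iterations):
        with warnings.catch_warnings():
            # all-NaN feature rows legitimately yield a NaN reference
            warnings.simplefilter("ignore", category=RuntimeWarning)
            ref = np.nanmean(x, axis=1)
        for j in range(x.shape[1]):
            a = ref[complete]
            m = x[complete, j] - a
            fitted = lowess(m, a, frac=span, return_sorted=True)
            observed = ~np.isnan(x[:, j])
            # evaluate the smooth at every observed feature's reference value
            corr = np.interp(ref[observed], fitted[:, 0], fitted[:, 1])
            x[observed, j] -= corr
    return x


def median_center(matrix: np.ndarray) -> np.ndarray:
    """Subtract per-column medians, preserving the grand level."""
    x = np.array(matrix, dtype=float, copy=True)
    col_med = np.nanmedian(x, axis=0)
    return x - (col_med - np.mean(col_med))


# ---------------------------------------------------------------------------
# Empirical-Bayes variance moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton on the inverse scale)."""
    if not np.isfinite(y) or y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if -dif / x < 1e-8:
            break
    return float(x)


@dataclass
class VariancePrior:
    """Fitted prior of the variance distribution: s^2 ~ s0^2 * chi2_d0 / d0."""

    d0: float
    s0_squared: float


def fit_variance_prior(s2: np.ndarray, df: np.ndarray | float) -> VariancePrior:
    """Moment-match (d0, s0^2) from per-feature sample variances.

    Works on the log scale: for s^2 with df residual degrees of freedom,
    e = log s^2 - digamma(df/2) + log(df/2) has mean log s0^2 +
    digamma(d0/2) - log(d0/2) and excess variance trigamma(d0/2); the
    trigamma equation is inverted numerically. An excess variance <= 0
    means no evidence of variance heterogeneity and yields d0 = inf
    (complete shrinkage to s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape)
    ok = np.isfinite(s2) & (s2 > 0) & (df > 0)
    if ok.sum() < 2:
        raise ValueError("need >= 2 positive variances to fit the prior")
    z = np.log(s2[ok])
    e = z - special.digamma(df[ok] / 2.0) + np.log(df[ok] / 2.0)
    emean = e.mean()
    evar = e.var(ddof=1) - np.mean(special.polygamma(1, df[ok] / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0_sq = np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
    else:
        # no excess spread: complete shrinkage to the plain mean variance
        d0 = np.inf
        s0_sq = float(np.mean(s2[ok]))
    return VariancePrior(d0=float(d0), s0_squared=float(s0_sq))


def squeeze_variances(s2: np.ndarray, df: np.ndarray | float, prior: VariancePrior) -> np.ndarray:
    """Posterior variances (d0*s0^2 + df*s^2) / (d0 + df)."""
    s2 = np.asarray(s2, dtype=float)
    df = np.broadcast_to(np.asarray(df, dtype=float), s2.shape).astype(float)
    if np.isinf(prior.d0):
        return np.full_like(s2, prior.s0_squared)
    out = (prior.d0 * prior.s0_squared + df * np.nan_to_num(s2)) / (prior.d0 + df)
    out[df == 0] = prior.s0_squared
    return out


@dataclass
class ModeratedTestResult:
    """Vectorized result of a moderated t-test over features."""

    effect: np.ndarray
    t: np.ndarray
    p: np.ndarray
    df_residual: np.ndarray
    df_total: np.ndarray
    n_used: np.ndarray
    prior: VariancePrior | None


def _t_pvalues(t: np.ndarray, df_total: np.ndarray) -> np.ndarray:
    p = np.full(t.shape, np.nan)
    finite = np.isfinite(t) & (df_total > 0)
    inf_df = finite & np.isinf(df_total)
    p[inf_df] = 2.0 * stats.norm.sf(np.abs(t[inf_df]))
    fin_df = finite & ~np.isinf(df_total)
    p[fin_df] = 2.0 * stats.t.sf(np.abs(t[fin_df]), df_total[fin_df])
    return np.clip(p, np.nextafter(0, 1), 1.0)


def moderated_one_sample_t(
    diffs: np.ndarray, moderated: bool = True, min_replicates: int = 2
) -> ModeratedTestResult:
    """Moderated one-sample t-test of paired differences against zero.

    ``diffs`` is features x replicates with NaN for missing. Features
    with fewer than ``min_replicates`` finite values get an effect (if
    n >= 1) but no p-value. With ``moderated=False`` this is the ordinary
    one-sample t-test (the d0 -> 0 limit).
    """
    d = np.asarray(diffs, dtype=float)
    n = np.sum(np.isfinite(d), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(np.where(np.isfinite(d), d, np.nan), axis=1)
        s2 = np.nanvar(d, axis=1, ddof=1)
    mean[n == 0] = np.nan
    df_res = np.maximum(n - 1, 0).astype(float)
    testable = n >= max(min_replicates, 2)

    if moderated:
        fit_mask = testable & (df_res > 0) & np.isfinite(s2) & (s2 > 0)
        prior = fit_variance_prior(s2[fit_mask], df_res[fit_mask]) if fit_mask.sum() >= 2 else None
    else:
        prior = None

    if prior is not None:
        s2_post = squeeze_variances(s2, df_res, prior)
        # posterior df, capped at the pooled residual df of the prior fit
        df_total = np.minimum(df_res + prior.d0, float(df_res[fit_mask].sum()))
    else:
        s2_post = s2
        df_total = df_res.copy()

    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / np.sqrt(s2_post / np.maximum(n, 1))
    t[~testable] = np.nan
    df_total = np.where(testable, df_total, np.nan)
    p = _t_pvalues(t, np.nan_to_num(df_total, nan=-1.0))
    p[~testable] = np.nan
    return ModeratedTestResult(
        effect=mean, t=t, p=p, df_residual=df_res, df_total=df_total, n_used=n, prior=prior
    )


def moderated_lm(
    y: np.ndarray, design: np.ndarray, coef: int, moderated: bool = True
) -> ModeratedTestResult:
    """Moderated t on one coefficient of a per-feature linear model.

    Fits ``y[i, :] ~ design`` by least squares for every feature i on a
    complete matrix (no NaN), shrinks residual variances, and tests
    ``design`` column ``coef``. Raises if the design is rank deficient
    (e.g. a block factor confounded with the condition).
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(design, dtype=float)
    n_samples, n_coef = X.shape
    if np.linalg.matrix_rank(X) < n_coef:
        raise ValueError("design matrix is rank deficient (confounded factors)")
    if np.isnan(y).any():
        raise ValueError("moderated_lm requires a complete matrix (impute first)")
    df_res = float(n_samples - n_coef)
    if df_res <= 0:
        raise ValueError("no residual degrees of freedom")
    xtx_inv = np.linalg.inv(X.T @ X)
    pinv = xtx_inv @ X.T
    beta = y @ pinv.T
    resid = y - beta @ X.T
    s2 = (resid**2).sum(axis=1) / df_res
    unscaled_sd = np.sqrt(xtx_inv[coef, coef])

    df_arr = np.full(y.shape[0], df_res)
    if moderated:
        prior = fit_variance_prior(s2, df_arr)
        s2_post = squeeze_variances(s2, df_arr, prior)
        # posterior df, capped at the pooled residual df across features
        df_total = np.minimum(df_arr + prior.d0, float(df_arr.sum()))
    else:
        prior = None
        s2_post = s2
        df_total = df_arr

    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, coef] / (unscaled_sd * np.sqrt(s2_post))
    p = _t_pvalues(t, df_total)
    return ModeratedTestResult(
        effect=beta[:, coef],
        t=t,
        p=p,
        df_residual=df_arr,
        df_total=df_total,
        n_used=np.full(y.shape[0], n_samples),
        prior=prior,
    )


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up adjusted p-values; NaNs propagate."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = np.isfinite(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def bonferroni(p: np.ndarray, m: int | None = None) -> np.ndarray:
    """Bonferroni adjustment: min(1, p * m) with m = number of tests."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = int(np.isfinite(p).sum())
    return np.minimum(p * m, 1.0)
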