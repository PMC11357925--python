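"""The five causal estimators of the two-sample MR suite.

All estimators consume a :class:`~mrmediate.instruments.HarmonizedDataset`
and return an :class:`MREstimate` whose confidence interval, odds-ratio
transform and p-value follow one convention throughout: 95% CI = β ± 1.96·se,
OR = exp(β), two-sided p from the normal reference distribution.

IVW and MR-Egger report multiplicative random-effects standard errors: the
fixed-effect (weighted least squares) SE is scaled by the residual standard
deviation, floored at 1 so the SE is never deflated below the fixed-effect
value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

from .instruments import HarmonizedDataset

Z95 = 1.96


class InsufficientInstrumentsError(ValueError):
    """Too few SNPs for the requested estimator."""


@dataclass(frozen=True)
class MREstimate:
    """One method's causal estimate, one row of a results table."""

    method: str
    n_snp: int
    beta: float
    se: float
    lo_ci: float
    up_ci: float
    or_: float
    or_lci95: float
    or_uci95: float
    pval: float
    intercept: float | None = None
    intercept_se: float | None = None
    intercept_p: float | None = None


def finalize(beta: float, se: float, method: str, n_snp: int, **extra) -> MREstimate:
    """Fill the CI / OR / p fields from (beta, se) under the package conventions."""
    if not se > 0:
        raise ValueError("se must be positive")
    beta = float(beta)
    se = float(se)
    lo = beta - Z95 * se
    up = beta + Z95 * se
    pval = normal_p(beta, se)
    with np.errstate(over="ignore"):  # extreme CIs exponentiate to inf, harmlessly
        ors = float(np.exp(beta)), float(np.exp(lo)), float(np.exp(up))
    return MREstimate(
        method=method,
        n_snp=int(n_snp),
        beta=beta,
        se=se,
        lo_ci=lo,
        up_ci=up,
        or_=ors[0],
        or_lci95=ors[1],
        or_uci95=ors[2],
        pval=pval,
        **extra,
    )


def normal_p(beta: float, se: float) -> float:
    """Two-sided p-value under the normal reference distribution."""
    return float(2.0 * sps.norm.sf(abs(beta) / se))


def wald_ratios(data: HarmonizedDataset) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-SNP Wald ratios and first-order standard errors.

    ratio_j = beta_out_j / beta_exp_j, se_j = se_out_j / |beta_exp_j|.
    SNPs with beta_exp = 0 are excluded; the returned boolean mask (third
    element) marks the retained rows of ``data.kept``.
    """
    bx, by, sy = data.beta_exp, data.beta_out, data.se_out
    mask = bx != 0.0
    ratio = by[mask] / bx[mask]
    ratio_se = sy[mask] / np.abs(bx[mask])
    return ratio, ratio_se, mask


def _scaled_wls(y: np.ndarray, X: np.ndarray, w: np.ndarray):
    """WLS fit with multiplicative random-effects SE (residual scale floored at 1).

    Returns (params, se, sigma) where sigma² is the weighted residual mean
    square and se = fixed-effect se × max(1, sigma).
    """
    res = sm.WLS(y, X, weights=w).fit()
    df_resid = len(y) - X.shape[1]
    sigma2 = float(res.scale) if df_resid > 0 else 1.0  # statsmodels scale = wRSS/df
    # weights are true inverse variances, so the fixed-effect covariance is
    # (X'WX)^-1 with no residual scale
    cov_fixed = np.linalg.inv(X.T @ (w[:, None] * X))
    se_fixed = np.sqrt(np.diag(cov_fixed))
    se = se_fixed * max(1.0, np.sqrt(sigma2))
    return np.atleast_1d(res.params), np.atleast_1d(se), float(np.sqrt(max(sigma2, 0.0)))


def ivw(data: HarmonizedDataset) -> MREstimate:
    """Inverse-variance-weighted estimate.

    Weighted least squares of beta_out on beta_exp through the origin with
    weights 1/se_out² — algebraically Σw·bx·by / Σw·bx².  With a single SNP
    the estimate degenerates to the Wald ratio.
    """
    n = data.n_snp
    if n < 1:
        raise InsufficientInstrumentsError("ivw needs at least 1 SNP")
    bx, by, sy = data.beta_exp, data.beta_out, data.se_out
    if n == 1:
        if bx[0] == 0:
            raise InsufficientInstrumentsError("single SNP with zero exposure beta")
        return finalize(by[0] / bx[0], sy[0] / abs(bx[0]), "wald_ratio", 1)
    w = 1.0 / sy**2
    params, se, _ = _scaled_wls(by, bx[:, None], w)
    return finalize(params[0], se[0], "ivw", n)


def mr_egger(data: HarmonizedDataset) -> MREstimate:
    """MR-Egger regression.

    SNPs are first oriented so every exposure beta is non-negative (joint
    sign flip of the exposure/outcome pair), making the intercept
    interpretable as mean directional pleiotropy.  Weighted least squares of
    beta_out on beta_exp with intercept, weights 1/se_out².
    """
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("mr_egger needs at least 3 SNPs")
    bx, by, sy = data.beta_exp, data.beta_out, data.se_out
    sgn = np.where(bx < 0, -1.0, 1.0)
    bx, by = bx * sgn, by * sgn
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(n), bx])
    params, se, _ = _scaled_wls(by, X, w)
    return finalize(
        params[1],
        se[1],
        "mr_egger",
        n,
        intercept=float(params[0]),
        intercept_se=float(se[0]),
        intercept_p=normal_p(params[0], se[0]),
    )


def _weighted_median(ratio: np.ndarray, weight: np.ndarray) -> float:
    """Interpolated weighted median of ``ratio`` with weights ``weight``."""
    order = np.argsort(ratio, kind="mergesort")
    r = ratio[order]
    w = weight[order] / weight.sum()
    p = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, p, r))


def weighted_median(data: HarmonizedDataset, n_boot: int = 1000, seed: int = 0) -> MREstimate:
    """Weighted-median estimator with parametric-bootstrap standard error.

    Consistent when at least half the instrument weight comes from valid
    instruments.  Weights are 1/ratio_se²; the SE is the standard deviation
    of the estimate over ``n_boot`` parametric resamples
    ratio*_j ~ Normal(ratio_j, ratio_se_j), deterministic given ``seed``.
    """
    if data.n_snp < 3:
        raise InsufficientInstrumentsError("weighted_median needs at least 3 SNPs")
    ratio, ratio_se, _ = wald_ratios(data)
    w = 1.0 / ratio_se**2
    est = _weighted_median(ratio, w)
    se = _bootstrap_se(_weighted_median, ratio, ratio_se, w, n_boot, seed)
    return finalize(est, se, "weighted_median", data.n_snp)


def _mode_point(ratio: np.ndarray, weight: np.ndarray, phi: float) -> float:
    """Kernel-smoothed weighted mode of the Wald ratios.

    Gaussian kernel, bandwidth h = phi × 0.9·min(sd, IQR/1.349)·m^(−1/5);
    the estimate is the argmax of the weighted density on a 512-point grid
    spanning the ratio range padded by 3 bandwidths.  If the bandwidth
    degenerates to zero (all ratios identical) the common ratio is returned.
    """
    m = len(ratio)
    sd = float(np.std(ratio, ddof=1)) if m > 1 else 0.0
    iqr = float(np.subtract(*np.percentile(ratio, [75, 25])))
    candidates = [v for v in (sd, iqr / 1.349) if v > 0]
    h = phi * 0.9 * (min(candidates) if candidates else 0.0) * m ** (-1 / 5)
    if h == 0.0:
        return float(ratio[0])
    grid = np.linspace(ratio.min() - 3 * h, ratio.max() + 3 * h, 512)
    dens = (weight[None, :] * np.exp(-0.5 * ((grid[:, None] - ratio[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def mode_estimate(
    data: HarmonizedDataset,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int = 0,
) -> MREstimate:
    """Mode-based estimator (simple or weighted) with bootstrap SE."""
    if data.n_snp < 3:
        raise InsufficientInstrumentsError("mode_estimate needs at least 3 SNPs")
    if not phi > 0:
        raise ValueError("phi must be positive")
    ratio, ratio_se, _ = wald_ratios(data)
    w = 1.0 / ratio_se**2 if weighted else np.ones_like(ratio)
    w = w / w.sum()
    point = _mode_point(ratio, w, phi)
    se = _bootstrap_se(lambda r, ww: _mode_point(r, ww, phi), ratio, ratio_se, w, n_boot, seed)
    return finalize(point, se, "weighted_mode" if weighted else "simple_mode", data.n_snp)


def _bootstrap_se(stat, ratio, ratio_se, weight, n_boot: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=ratio, scale=ratio_se, size=(n_boot, len(ratio)))
    ests = np.array([stat(draws[b], weight) for b in range(n_boot)])
    se = float(np.std(ests, ddof=1))
    if se == 0.0:  # degenerate data; avoid a zero SE downstream
        se = np.finfo(float).tiny
    return se


#: canonical ordering of the method suite in reports
METHOD_ORDER = ["mr_egger", "weighted_median", "ivw", "simple_mode", "weighted_mode"]

METHOD_LABELS = {
    "mr_egger": "MR Egger",
    "weighted_median": "Weighted median",
    "ivw": "Inverse variance weighted",
    "wald_ratio": "Wald ratio",
    "simple_mode": "Simple mode",
    "weighted_mode": "Weighted mode",
}


def all_estimates(data: HarmonizedDataset, n_boot: int = 1000, seed: int = 0) -> list[MREstimate]:
    """Run the five-method suite in report order."""
    return [
        mr_egger(data),
        weighted_median(data, n_boot=n_boot, seed=seed),
        ivw(data),
        mode_estimate(data, weighted=False, n_boot=n_boot, seed=seed + 1),
        mode_estimate(data, weighted=True, n_boot=n_boot, seed=seed + 2),
    ]
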