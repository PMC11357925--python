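"""Heterogeneity, pleiotropy, outlier and influence diagnostics.

The screening rule these diagnostics feed is: an exposure is *cleared* iff
the MR-Egger intercept p-value exceeds alpha (no evidence of directional
pleiotropy).  Heterogeneity (Cochran's Q) is reported but never used to
drop an exposure — between-instrument heterogeneity is an expected feature
of summary-level MR, not a disqualifier.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .estimators import MREstimate, InsufficientInstrumentsError, finalize, ivw, mr_egger, normal_p
from .instruments import HarmonizedDataset


@dataclass(frozen=True)
class HeterogeneityResult:
    """Cochran's Q for the IVW or Egger fit."""

    method: str
    Q: float
    Q_df: int
    Q_pval: float


@dataclass(frozen=True)
class PleiotropyResult:
    """MR-Egger intercept test for directional pleiotropy."""

    egger_intercept: float
    se: float
    pval: float


@dataclass(frozen=True)
class PressoResult:
    """MR-PRESSO global, outlier and distortion test results."""

    global_rss_obs: float
    global_pval: float
    outlier_pvals: np.ndarray
    outliers: tuple[int, ...]
    distortion_pval: float
    beta_raw: MREstimate
    beta_corrected: MREstimate


@dataclass(frozen=True)
class LeaveOneOutRow:
    left_out_snp: str
    estimate: MREstimate
    flagged: bool


@dataclass(frozen=True)
class GateVerdict:
    """Screening verdict for one exposure."""

    cleared: bool
    significant: bool
    ivw_pval: float
    intercept_pval: float
    heterogeneity: tuple[HeterogeneityResult, ...] = field(default=())


def _fits(data: HarmonizedDataset, method: str):
    """Fitted values of the origin (ivw) or intercept (mr_egger) regression."""
    bx, by, sy = data.beta_exp, data.beta_out, data.se_out
    if method == "ivw":
        est = ivw(data)
        return by, est.beta * bx, sy, data.n_snp - 1
    if method == "mr_egger":
        est = mr_egger(data)
        sgn = np.where(bx < 0, -1.0, 1.0)
        return by * sgn, est.intercept + est.beta * (bx * sgn), sy, data.n_snp - 2
    raise ValueError(f"unknown method {method!r}")


def cochran_q(data: HarmonizedDataset, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q heterogeneity statistic.

    Q = Σ wⱼ (byⱼ − fitⱼ)² with wⱼ = 1/se_outⱼ²; df = n−1 (ivw) or n−2
    (mr_egger); p is the upper chi-square tail.
    """
    need = 2 if method == "ivw" else 3
    if data.n_snp < need:
        raise InsufficientInstrumentsError(f"cochran_q({method}) needs >= {need} SNPs")
    by, fit, sy, df = _fits(data, method)
    Q = float(np.sum(((by - fit) / sy) ** 2))
    return HeterogeneityResult(method=method, Q=Q, Q_df=df, Q_pval=float(sps.chi2.sf(Q, df)))


def egger_intercept_test(data: HarmonizedDataset) -> PleiotropyResult:
    """Two-sided normal test of the MR-Egger intercept (mean directional pleiotropy)."""
    est = mr_egger(data)
    return PleiotropyResult(
        egger_intercept=est.intercept,
        se=est.intercept_se,
        pval=normal_p(est.intercept, est.intercept_se),
    )


def _loo_slopes(bx: np.ndarray, by: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Leave-one-out IVW slopes for every SNP, vectorized."""
    sxy = np.sum(w * bx * by)
    sxx = np.sum(w * bx * bx)
    return (sxy - w * bx * by) / (sxx - w * bx * bx)


def mr_presso(
    data: HarmonizedDataset,
    n_sim: int = 1000,
    seed: int = 0,
    significance: float = 0.05,
) -> PressoResult:
    """MR-PRESSO residual-sum-of-squares outlier detection.

    Global test: the observed RSS is the sum of weighted squared leave-one-out
    residuals; its null distribution comes from ``n_sim`` parametric
    simulations of (bx, by) around the leave-one-out fits (both coordinates
    redrawn with their reported SEs, leave-one-out slopes refitted per
    simulation).  Empirical p-values use the +1 continuity correction.
    Outlier test: each SNP's observed squared residual against its simulated
    distribution, Bonferroni-adjusted across SNPs.  Distortion test: the
    displacement of the outlier-corrected IVW beta is compared with a null of
    random removals of the same count.  Fully deterministic given ``seed``.
    """
    n = data.n_snp
    if n < 4:
        raise InsufficientInstrumentsError(
            "mr_presso needs at least 4 SNPs; skip this diagnostic for smaller sets"
        )
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100")
    rng = np.random.default_rng(seed)
    bx, by = data.beta_exp, data.beta_out
    sx, sy = data.se_exp, data.se_out
    w = 1.0 / sy**2

    slopes_loo = _loo_slopes(bx, by, w)
    resid2_obs = w * (by - slopes_loo * bx) ** 2
    rss_obs = float(resid2_obs.sum())

    # parametric null at the leave-one-out fits
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    by_sim = rng.normal(slopes_loo * bx, sy, size=(n_sim, n))
    w_row = w[None, :]
    sxy = np.sum(w_row * bx_sim * by_sim, axis=1, keepdims=True)
    sxx = np.sum(w_row * bx_sim * bx_sim, axis=1, keepdims=True)
    slopes_sim = (sxy - w_row * bx_sim * by_sim) / (sxx - w_row * bx_sim * bx_sim)
    resid2_sim = w_row * (by_sim - slopes_sim * bx_sim) ** 2
    rss_sim = resid2_sim.sum(axis=1)

    global_pval = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    raw_p = (1 + np.sum(resid2_sim >= resid2_obs[None, :], axis=0)) / (n_sim + 1)
    adj_p = np.minimum(raw_p * n, 1.0)
    outliers = tuple(int(i) for i in np.flatnonzero(adj_p < significance))

    beta_raw = ivw(data)
    if outliers:
        keep = np.ones(n, dtype=bool)
        keep[list(outliers)] = False
        if keep.sum() < 2:
            raise InsufficientInstrumentsError("fewer than 2 SNPs left after outlier removal")
        beta_corrected = ivw(data.subset(keep))
        d_obs = abs(beta_raw.beta - beta_corrected.beta)
        # null: remove the same number of SNPs at random (closed-form IVW slope)
        n_null = 1000
        sxy_full = float(np.sum(w * bx * by))
        sxx_full = float(np.sum(w * bx * bx))
        drops = np.array([rng.choice(n, size=len(outliers), replace=False) for _ in range(n_null)])
        sxy_drop = (w * bx * by)[drops].sum(axis=1)
        sxx_drop = (w * bx * bx)[drops].sum(axis=1)
        d_null = beta_raw.beta - (sxy_full - sxy_drop) / (sxx_full - sxx_drop)
        distortion_pval = float((1 + np.sum(np.abs(d_null) >= d_obs)) / (n_null + 1))
    else:
        beta_corrected = beta_raw
        distortion_pval = float("nan")

    return PressoResult(
        global_rss_obs=rss_obs,
        global_pval=global_pval,
        outlier_pvals=adj_p,
        outliers=outliers,
        distortion_pval=distortion_pval,
        beta_raw=beta_raw,
        beta_corrected=beta_corrected,
    )


def leave_one_out(data: HarmonizedDataset) -> list[LeaveOneOutRow]:
    """IVW re-estimated with each SNP removed in turn.

    A removal is flagged when it changes the sign of the estimate or changes
    whether the 95% CI crosses zero relative to the full-data fit.
    """
    n = data.n_snp
    if n < 3:
        raise InsufficientInstrumentsError("leave_one_out needs at least 3 SNPs")
    full = ivw(data)
    full_crosses = full.lo_ci <= 0.0 <= full.up_ci
    rows = []
    for j in range(n):
        keep = np.ones(n, dtype=bool)
        keep[j] = False
        est = ivw(data.subset(keep))
        crosses = est.lo_ci <= 0.0 <= est.up_ci
        flagged = (np.sign(est.beta) != np.sign(full.beta)) or (crosses != full_crosses)
        rows.append(LeaveOneOutRow(left_out_snp=str(data.snp_ids[j]), estimate=est, flagged=bool(flagged)))
    return rows


def gate(
    estimates: list[MREstimate],
    heterogeneity: list[HeterogeneityResult],
    pleiotropy: PleiotropyResult,
    alpha: float = 0.05,
) -> GateVerdict:
    """Screening verdict: cleared iff intercept p > alpha (strict); significant
    iff IVW p < alpha.  Heterogeneity is recorded but non-blocking."""
    ivw_est = next(e for e in estimates if e.method in ("ivw", "wald_ratio"))
    return GateVerdict(
        cleared=bool(pleiotropy.pval > alpha),
        significant=bool(ivw_est.pval < alpha),
        ivw_pval=ivw_est.pval,
        intercept_pval=pleiotropy.pval,
        heterogeneity=tuple(heterogeneity),
    )
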