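"""Workflow orchestration: many-exposure screening, reverse MR, mediation.

One :class:`RunConfig` drives the whole screen.  Every exposure in the
manifest ends in exactly one of four states — significant, non-significant,
gated-out (pleiotropy) or skipped (too few usable SNPs / failure) — and all
randomness (bootstraps, MR-PRESSO) derives from a single root seed.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import estimators as est
from .estimators import METHOD_LABELS, MREstimate, InsufficientInstrumentsError
from .gwas_io import SummaryStats, read_summary_stats
from .instruments import LDLookup, harmonize, select_instruments
from .mediation import MediationConfig, MediationResult, mediation_screen
from .sensitivity import (
    GateVerdict,
    HeterogeneityResult,
    PleiotropyResult,
    PressoResult,
    cochran_q,
    egger_intercept_test,
    gate,
    leave_one_out,
    mr_presso,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Screen-wide thresholds, manifests and seeding."""

    exposures: dict[str, str] = field(default_factory=dict)  # trait_id -> file
    outcome: str | None = None
    mediators: dict[str, str] = field(default_factory=dict)
    ld_file: str | None = None
    dialect: str = "canonical"
    p_forward: float = 1e-5
    p_reverse: float = 5e-8
    r2_clump: float = 0.001
    f_min: float = 10.0
    alpha: float = 0.05
    n_boot: int = 1000
    presso_nsim: int = 1000
    multiple_testing: str = "none"  # none | bh_fdr
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        for name in ("p_forward", "p_reverse", "r2_clump", "alpha"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name} must lie in (0,1], got {v}")
        if self.multiple_testing not in ("none", "bh_fdr"):
            raise ValueError("multiple_testing must be 'none' or 'bh_fdr'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def derive_seed(self, *labels) -> int:
        """Deterministic per-task child seed from the root seed.

        Hash of (root seed, labels), reduced below 2^31 — documented so runs
        are reproducible task-by-task.
        """
        key = ":".join([str(self.seed), *map(str, labels)]).encode()
        return int(hashlib.sha256(key).hexdigest(), 16) % (2**31)


@dataclass
class ExposureResult:
    """Everything the screen produced for one exposure."""

    exposure_id: str
    status: str  # significant | non_significant | gated_out | skipped
    reason: str = ""
    estimates: list[MREstimate] = field(default_factory=list)
    heterogeneity: list[HeterogeneityResult] = field(default_factory=list)
    pleiotropy: PleiotropyResult | None = None
    presso: PressoResult | None = None
    loo_flags: list[str] = field(default_factory=list)
    verdict: GateVerdict | None = None


@dataclass
class ScreenReport:
    direction: str
    results: list[ExposureResult] = field(default_factory=list)
    seed: int = 0

    @property
    def by_status(self) -> dict[str, list[ExposureResult]]:
        out: dict[str, list[ExposureResult]] = {}
        for r in self.results:
            out.setdefault(r.status, []).append(r)
        return out


def analyze_pair(
    exposure: SummaryStats,
    outcome: SummaryStats,
    config: RunConfig,
    p_threshold: float,
) -> ExposureResult:
    """Full single-pair analysis: select → harmonize → estimate → diagnose → gate."""
    inst = select_instruments(
        exposure,
        p_threshold=p_threshold,
        ld=LDLookup.from_file(config.ld_file) if config.ld_file else LDLookup.independent(),
        f_min=config.f_min,
        r2_clump_threshold=config.r2_clump,
    )
    data = harmonize(inst, outcome)
    if data.n_snp < 2:
        return ExposureResult(exposure.trait_id, "skipped",
                              reason=f"only {data.n_snp} usable SNPs")
    seed = config.derive_seed(exposure.trait_id, outcome.trait_id)
    res = ExposureResult(exposure.trait_id, "skipped")
    if data.n_snp >= 3:
        res.estimates = est.all_estimates(data, n_boot=config.n_boot, seed=seed)
        res.heterogeneity = [cochran_q(data, "ivw"), cochran_q(data, "mr_egger")]
        res.pleiotropy = egger_intercept_test(data)
        res.loo_flags = [r.left_out_snp for r in leave_one_out(data) if r.flagged]
    else:
        res.estimates = [est.ivw(data)]
        res.heterogeneity = [cochran_q(data, "ivw")]
        res.pleiotropy = PleiotropyResult(0.0, float("inf"), 1.0)
    if data.n_snp >= 4:
        res.presso = mr_presso(data, n_sim=config.presso_nsim,
                               seed=config.derive_seed("presso", exposure.trait_id),
                               significance=config.alpha)
    res.verdict = gate(res.estimates, res.heterogeneity, res.pleiotropy, config.alpha)
    if not res.verdict.cleared:
        res.status = "gated_out"
    elif res.verdict.significant:
        res.status = "significant"
    else:
        res.status = "non_significant"
    return res


def run_screen(
    config: RunConfig,
    direction: str = "forward",
    exposures: dict[str, SummaryStats] | None = None,
    outcome: SummaryStats | None = None,
) -> ScreenReport:
    """Screen every manifest exposure against the outcome.

    ``direction='forward'`` tests exposure → outcome at ``p_forward``;
    ``direction='reverse'`` swaps the roles and instruments the outcome trait
    at the stricter ``p_reverse``.  Tables may be passed in-memory (for
    simulation studies) or read from the manifest files.  Per-exposure
    failures are isolated: one bad file never aborts the run.
    """
    if direction not in ("forward", "reverse"):
        raise ValueError("direction must be 'forward' or 'reverse'")
    if outcome is None:
        if not config.outcome:
            raise FileNotFoundError("no outcome file configured")
        outcome = read_summary_stats(config.outcome, config.dialect)
    if exposures is None:
        exposures = {}
        for tid, path in config.exposures.items():
            try:
                exposures[tid] = read_summary_stats(path, config.dialect, trait_id=tid)
            except Exception as exc:
                log.error("exposure %s unreadable (%s); recorded as skipped", tid, exc)
                exposures[tid] = None  # type: ignore[assignment]

    report = ScreenReport(direction=direction, seed=config.seed)
    for tid, stats in exposures.items():
        if stats is None:
            report.results.append(ExposureResult(tid, "skipped", reason="unreadable file"))
            continue
        try:
            if direction == "forward":
                res = analyze_pair(stats, outcome, config, config.p_forward)
            else:
                res = analyze_pair(outcome, stats, config, config.p_reverse)
                res.exposure_id = tid  # keyed by the manifest trait either way
            report.results.append(res)
        except (ValueError, InsufficientInstrumentsError) as exc:
            log.error("exposure %s failed: %s", tid, exc)
            report.results.append(ExposureResult(tid, "skipped", reason=str(exc)))
    if config.multiple_testing == "bh_fdr":
        _annotate_fdr(report)
    return report


def _annotate_fdr(report: ScreenReport) -> None:
    """Attach BH-FDR q-values for the IVW p-values (opt-in, never gating)."""
    from statsmodels.stats.multitest import multipletests

    rows = [r for r in report.results if r.verdict is not None]
    if not rows:
        return
    p = np.array([r.verdict.ivw_pval for r in rows])
    q = multipletests(p, method="fdr_bh")[1]
    for r, qv in zip(rows, q):
        r.reason = (r.reason + f" q_bh={qv:.4g}").strip()


def run_mediation(
    config: RunConfig,
    top_exposure: str,
    exposure: SummaryStats | None = None,
    mediators: dict[str, SummaryStats] | None = None,
    outcome: SummaryStats | None = None,
) -> list[MediationResult]:
    """Mediator screen for one exposure against the configured manifest."""
    if exposure is None:
        if top_exposure not in config.exposures:
            raise KeyError(f"{top_exposure!r} not in exposure manifest")
        exposure = read_summary_stats(config.exposures[top_exposure], config.dialect,
                                      trait_id=top_exposure)
    if outcome is None:
        outcome = read_summary_stats(config.outcome, config.dialect)
    if mediators is None:
        mediators = {
            tid: read_summary_stats(path, config.dialect, trait_id=tid)
            for tid, path in config.mediators.items()
        }
    cfg = MediationConfig(
        p_threshold=config.p_forward,
        f_min=config.f_min,
        r2_clump_threshold=config.r2_clump,
        alpha=config.alpha,
    )
    results = mediation_screen(exposure, list(mediators.values()), outcome, cfg)
    if not results:
        log.warning("no mediators pass the gates for %s", top_exposure)
    return results


# ---------------------------------------------------------------------------
# report tables


def estimates_table(report: ScreenReport, outcome_label: str = "") -> "pd.DataFrame":
    """One row per (exposure, method) in the published column order."""
    import pandas as pd

    rows = []
    for r in report.results:
        for e in r.estimates:
            rows.append(
                {
                    "Exposure": r.exposure_id,
                    "Outcome": outcome_label,
                    "Method": METHOD_LABELS.get(e.method, e.method),
                    "NSNPs": e.n_snp,
                    "Pval": e.pval,
                    "b": e.beta,
                    "lo_ci": e.lo_ci,
                    "up_ci": e.up_ci,
                    "OR": e.or_,
                    "OR_lci95": e.or_lci95,
                    "OR_uci95": e.or_uci95,
                }
            )
    return pd.DataFrame(rows)


def sensitivity_table(report: ScreenReport, outcome_label: str = "") -> "pd.DataFrame":
    """Heterogeneity / pleiotropy rows in the published column order."""
    import pandas as pd

    rows = []
    for r in report.results:
        for h in r.heterogeneity:
            rows.append(
                {
                    "Exposure": r.exposure_id,
                    "Outcome": outcome_label,
                    "method": METHOD_LABELS.get(h.method, h.method),
                    "Q": h.Q,
                    "Q_df": h.Q_df,
                    "Q_pval": h.Q_pval,
                    "egger_intercept": r.pleiotropy.egger_intercept
                    if h.method == "mr_egger" and r.pleiotropy else "",
                    "SE": r.pleiotropy.se
                    if h.method == "mr_egger" and r.pleiotropy else "",
                    "p-value": r.pleiotropy.pval
                    if h.method == "mr_egger" and r.pleiotropy else "",
                }
            )
    return pd.DataFrame(rows)


def mediation_table(results: list[MediationResult]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "exposure": r.exposure_id,
                "mediator": r.mediator_id,
                "outcome": r.outcome_id,
                "a": r.a,
                "se_a": r.se_a,
                "c": r.c,
                "se_c": r.se_c,
                "d": r.d,
                "se_d": r.se_d,
                "indirect": r.indirect,
                "direct": r.direct_b,
                "proportion_pct": r.proportion_pct,
                "proportion_se_pct": r.proportion_se_pct,
                "sign_consistent": r.sign_consistent,
            }
            for r in results
        ]
    )


def write_reports(report: ScreenReport, out_dir: str | Path, outcome_label: str = "") -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    estimates_table(report, outcome_label).to_csv(out / "screen_estimates.tsv", sep="\t", index=False)
    sensitivity_table(report, outcome_label).to_csv(out / "screen_sensitivity.tsv", sep="\t", index=False)
    import pandas as pd

    skipped = pd.DataFrame(
        [
            {"exposure": r.exposure_id, "status": r.status, "reason": r.reason}
            for r in report.results
        ]
    )
    skipped.to_csv(out / "status.tsv", sep="\t", index=False)
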