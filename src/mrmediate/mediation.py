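"""Two-step MR mediation analysis.

The total effect *a* of the exposure on the outcome is decomposed into a
mediator-carried (indirect) part c·d — the product of the exposure→mediator
effect *c* and the mediator→outcome effect *d* — and a direct part
b = a − c·d.  The mediated proportion is c·d/a.  All three step effects come
from the full instrument-selection → harmonization → IVW path; uncertainty
for the product and the ratio uses first-order delta methods treating the
step estimates as independent (the two-sample design motivates, but does
not guarantee, that approximation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .estimators import MREstimate, ivw, InsufficientInstrumentsError
from .gwas_io import SummaryStats
from .instruments import LDLookup, harmonize, select_instruments
from .sensitivity import egger_intercept_test

log = logging.getLogger(__name__)


@dataclass
class MediationConfig:
    """Thresholds for the three step-MR fits.

    ``p_threshold`` is the forward instrument threshold used for both the
    exposure (steps a, c) and the mediator (step d).  ``a_floor`` guards the
    proportion against division by a vanishing total effect.
    """

    p_threshold: float = 1e-5
    f_min: float = 10.0
    r2_clump_threshold: float = 0.001
    alpha: float = 0.05
    a_floor: float = 1e-3
    ld: LDLookup = field(default_factory=LDLookup.independent)


@dataclass(frozen=True)
class MediationResult:
    """Decomposition of the exposure→outcome effect through one mediator."""

    exposure_id: str
    mediator_id: str
    outcome_id: str
    a: float                      # total effect, exposure -> outcome
    se_a: float
    c: float                      # exposure -> mediator
    se_c: float
    d: float                      # mediator -> outcome
    se_d: float
    indirect: float               # c * d
    indirect_se: float
    direct_b: float               # a - c * d
    proportion: float             # (c * d) / a
    proportion_se: float
    sign_consistent: bool
    method_provenance: dict = field(default_factory=dict)
    steps: dict = field(default_factory=dict)

    @property
    def proportion_pct(self) -> float:
        return 100.0 * self.proportion

    @property
    def proportion_se_pct(self) -> float:
        return 100.0 * self.proportion_se


def _step_ivw(
    exposure: SummaryStats, outcome: SummaryStats, cfg: MediationConfig
) -> tuple[MREstimate, object]:
    inst = select_instruments(
        exposure,
        p_threshold=cfg.p_threshold,
        ld=cfg.ld,
        f_min=cfg.f_min,
        r2_clump_threshold=cfg.r2_clump_threshold,
    )
    if inst.n_snp == 0:
        raise InsufficientInstrumentsError(f"no instruments for {exposure.trait_id}")
    data = harmonize(inst, outcome)
    return ivw(data), data


def two_step_mediation(
    exposure_stats: SummaryStats,
    mediator_stats: SummaryStats,
    outcome_stats: SummaryStats,
    config: MediationConfig | None = None,
) -> MediationResult:
    """Run the three step-MR fits and decompose the total effect.

    indirect_se² = c²·se_d² + d²·se_c² (first-order product rule);
    proportion_se by the ratio delta method on (indirect, a).  When |a| is
    below ``config.a_floor`` the proportion is reported as NaN with a
    warning.  ``sign_consistent`` is True iff the indirect effect shares the
    sign of the total effect (equivalently, the proportion is positive);
    sign-inconsistent mediators are reported with negative proportions, never
    suppressed.
    """
    cfg = config or MediationConfig()
    ids = (exposure_stats.trait_id, mediator_stats.trait_id, outcome_stats.trait_id)
    if len(set(ids)) != 3:
        raise ValueError(f"exposure, mediator and outcome traits must be distinct, got {ids}")

    est_a, data_a = _step_ivw(exposure_stats, outcome_stats, cfg)
    est_c, data_c = _step_ivw(exposure_stats, mediator_stats, cfg)
    est_d, data_d = _step_ivw(mediator_stats, outcome_stats, cfg)

    a, c, d = est_a.beta, est_c.beta, est_d.beta
    se_a, se_c, se_d = est_a.se, est_c.se, est_d.se
    indirect = c * d
    indirect_se = float(np.sqrt(c**2 * se_d**2 + d**2 * se_c**2))
    direct_b = a - indirect
    if abs(a) < cfg.a_floor:
        log.warning(
            "total effect |a|=%g below floor %g: mediated proportion undefined",
            abs(a), cfg.a_floor,
        )
        proportion = float("nan")
        proportion_se = float("nan")
    else:
        proportion = indirect / a
        if indirect == 0.0:
            proportion_se = float(indirect_se / abs(a))
        else:
            proportion_se = float(
                abs(proportion)
                * np.sqrt((indirect_se / indirect) ** 2 + (se_a / a) ** 2)
            )
    return MediationResult(
        exposure_id=ids[0],
        mediator_id=ids[1],
        outcome_id=ids[2],
        a=a, se_a=se_a, c=c, se_c=se_c, d=d, se_d=se_d,
        indirect=indirect,
        indirect_se=indirect_se,
        direct_b=direct_b,
        proportion=proportion,
        proportion_se=proportion_se,
        sign_consistent=bool(indirect * a > 0),
        method_provenance={"a": est_a.method, "c": est_c.method, "d": est_d.method},
        steps={"a": (est_a, data_a), "c": (est_c, data_c), "d": (est_d, data_d)},
    )


def mediation_screen(
    exposure_stats: SummaryStats,
    mediator_list: list[SummaryStats],
    outcome_stats: SummaryStats,
    config: MediationConfig | None = None,
) -> list[MediationResult]:
    """Screen candidate mediators.

    Retains candidates whose step effects c and d are both significant at
    ``alpha`` and whose step datasets both clear the Egger intercept
    pleiotropy test (p > alpha); results are sorted by |proportion|
    descending.  Per-candidate failures are isolated and logged.
    """
    cfg = config or MediationConfig()
    kept: list[MediationResult] = []
    for med in mediator_list:
        try:
            res = two_step_mediation(exposure_stats, med, outcome_stats, cfg)
            est_c, data_c = res.steps["c"]
            est_d, data_d = res.steps["d"]
            if est_c.pval >= cfg.alpha or est_d.pval >= cfg.alpha:
                log.info("%s: step effect not significant, excluded", med.trait_id)
                continue
            if (egger_intercept_test(data_c).pval <= cfg.alpha
                    or egger_intercept_test(data_d).pval <= cfg.alpha):
                log.info("%s: failed pleiotropy gate, excluded", med.trait_id)
                continue
            kept.append(res)
        except (ValueError, InsufficientInstrumentsError) as exc:
            log.warning("mediator %s skipped: %s", med.trait_id, exc)
    kept.sort(key=lambda r: -abs(r.proportion) if np.isfinite(r.proportion) else 0.0)
    return kept
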