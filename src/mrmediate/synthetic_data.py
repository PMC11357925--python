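"""Synthetic GWAS summary-statistics generator with known causal structure.

Summary-level simulation only: no individual genotypes are drawn.  For SNP j
with effect-allele frequency p_j and sample size N, the sampling standard
error of a per-allele effect on a unit-variance trait is
se_j = 1/sqrt(2·p_j·(1−p_j)·N), and the observed beta is drawn
Normal(truth, se_j²).  True SNP→exposure effects are half-normal (effects
expressed for the trait-increasing allele, the usual orientation in MR
simulations); a configurable fraction of SNPs carries a direct
(pleiotropic) SNP→outcome effect.  Allele encodings of the outcome table
can be scrambled (swap / strand-complement) and a fraction of SNPs made
palindromic to exercise harmonization; the true orientation is recorded.

The exposure/outcome pair draws no overlapping samples (two-sample design).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .gwas_io import CANONICAL_COLUMNS, SummaryStats

_NONPALINDROMIC_PAIRS = [
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass(frozen=True)
class MediationTruth:
    """True structural coefficients of the exposure→mediator→outcome chain."""

    theta_xm: float = 0.2      # exposure -> mediator
    theta_my: float = 0.0285   # mediator -> outcome
    theta_direct: float = 0.0743  # exposure -> outcome, not through the mediator

    @property
    def total(self) -> float:
        return self.theta_direct + self.theta_xm * self.theta_my

    @property
    def proportion(self) -> float:
        return self.theta_xm * self.theta_my / self.total


@dataclass
class SimConfig:
    """Study conditions for the generator.

    Defaults emulate a strong-instrument screen: 200 instruments for a
    unit-variance exposure measured in a 100k-sample GWAS against a 100k
    outcome GWAS, true causal effect 0.3, no pleiotropy.  The mediator GWAS
    is an order of magnitude smaller (10k, the scale of metabolite panels),
    with a smaller panel of large-effect mediator-specific instruments.
    """

    m_snps: int = 200
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    n_mediator: int = 10_000
    theta: float = 0.3
    gamma_sd: float = 0.1
    pleiotropy_mean: float = 0.0
    pleiotropy_sd: float = 0.0
    invalid_fraction: float = 0.0
    mediation: MediationTruth | None = None
    maf_range: tuple[float, float] = (0.05, 0.5)
    palindromic_fraction: float = 0.1
    scramble_fraction: float = 0.5
    m_mediator_snps: int = 50
    mediator_gamma_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.invalid_fraction <= 1.0:
            raise ValueError("invalid_fraction must lie in [0,1]")
        for n in (self.n_exposure, self.n_outcome, self.n_mediator):
            if n < 100:
                raise ValueError("sample sizes must be >= 100")
        lo, hi = self.maf_range
        if not (0.0 < lo < hi <= 0.5):
            raise ValueError("maf_range must be an interval within (0, 0.5]")
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")


@dataclass
class SimTruth:
    """Ground truth recorded alongside the generated tables."""

    gamma: np.ndarray                   # true SNP -> exposure effects
    alpha: np.ndarray                   # direct SNP -> outcome (pleiotropy)
    theta: float
    eaf: np.ndarray
    beta_outcome_true: np.ndarray
    scrambled: np.ndarray               # outcome encoding: 0 none, 1 swap, 2 comp, 3 both
    palindromic: np.ndarray
    mediation: MediationTruth | None = None
    delta: np.ndarray | None = None     # mediator-specific SNP effects
    beta_mediator_true: np.ndarray | None = None
    snp_ids: np.ndarray | None = None


def _analytic_se(eaf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * sps.norm.sf(np.abs(beta) / se)
    return np.maximum(p, np.finfo(float).tiny)


def _alleles(rng: np.random.Generator, m: int, palindromic_fraction: float):
    pal = rng.random(m) < palindromic_fraction
    pairs = np.empty((m, 2), dtype=object)
    idx_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=m)
    idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=m)
    for j in range(m):
        pairs[j] = _PALINDROMIC_PAIRS[idx_p[j]] if pal[j] else _NONPALINDROMIC_PAIRS[idx_np[j]]
    return pairs, pal

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _table(trait_id, snp_ids, chrom, pos, ea, oa, eaf, beta, se, n) -> SummaryStats:
    df = pd.DataFrame(
        {
            "snp_id": snp_ids,
            "chrom": chrom,
            "pos": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _two_sided_p(beta, se),
            "n": np.full(len(snp_ids), n, dtype="int64"),
        }
    )[CANONICAL_COLUMNS]
    df["pos"] = df["pos"].astype("int64")
    return SummaryStats(trait_id=trait_id, variants=df)


def _scramble_outcome(rng, ea, oa, eaf, beta, pal, scramble_fraction):
    """Re-encode a fraction of outcome rows: swap effect/other and/or strand."""
    m = len(ea)
    mode = np.zeros(m, dtype=int)
    do = rng.random(m) < scramble_fraction
    choice = rng.integers(1, 4, size=m)  # 1 swap, 2 complement, 3 both
    mode[do] = choice[do]
    # complementing a palindromic pair is indistinguishable from a swap and
    # would corrupt the recorded orientation; restrict palindromics to swaps
    mode[pal & (mode == 2)] = 0
    mode[pal & (mode == 3)] = 1
    ea2, oa2 = ea.copy(), oa.copy()
    eaf2, beta2 = eaf.copy(), beta.copy()
    swap = (mode == 1) | (mode == 3)
    comp = (mode == 2) | (mode == 3)
    ea2[swap], oa2[swap] = oa[swap].copy(), ea[swap].copy()
    beta2[swap] = -beta[swap]
    eaf2[swap] = 1.0 - eaf[swap]
    for j in np.flatnonzero(comp):
        ea2[j] = _COMP[ea2[j]]
        oa2[j] = _COMP[oa2[j]]
    return ea2, oa2, eaf2, beta2, mode


def simulate_gwas_pair(config: SimConfig) -> tuple[SummaryStats, SummaryStats, SimTruth]:
    """Generate one exposure/outcome summary-statistics pair.

    Per SNP: eaf ~ Uniform(maf_range); γ ~ |Normal(0, gamma_sd²)|; a fraction
    ``invalid_fraction`` of SNPs receives a direct outcome effect
    α ~ Normal(pleiotropy_mean, pleiotropy_sd²); true outcome effect
    Γ = θ·γ + α.  Observed betas are the truths plus independent sampling
    noise with the frequency/sample-size determined SEs.  Deterministic
    given (config, config.seed).
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    eaf = rng.uniform(*config.maf_range, size=m)
    gamma = np.abs(rng.normal(0.0, config.gamma_sd, size=m))
    alpha = np.zeros(m)
    invalid = rng.random(m) < config.invalid_fraction
    if invalid.any():
        alpha[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=invalid.sum())
    beta_out_true = config.theta * gamma + alpha

    se_x = _analytic_se(eaf, config.n_exposure)
    se_y = _analytic_se(eaf, config.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(beta_out_true, se_y)

    snp_ids = np.array([f"rs{1000000 + j}" for j in range(m)])
    chrom = np.array([str(1 + j % 22) for j in range(m)])
    pos = 1_000_000 + 2_000_000 * np.arange(m, dtype="int64")
    pairs, pal = _alleles(rng, m, config.palindromic_fraction)
    ea = pairs[:, 0].astype(object)
    oa = pairs[:, 1].astype(object)

    exposure = _table("sim_exposure", snp_ids, chrom, pos, ea, oa, eaf, beta_x, se_x,
                      config.n_exposure)
    ea_o, oa_o, eaf_o, beta_y_enc, mode = _scramble_outcome(
        rng, ea, oa, eaf, beta_y, pal, config.scramble_fraction
    )
    outcome = _table("sim_outcome", snp_ids, chrom, pos, ea_o, oa_o, eaf_o, beta_y_enc, se_y,
                     config.n_outcome)
    truth = SimTruth(
        gamma=gamma, alpha=alpha, theta=config.theta, eaf=eaf,
        beta_outcome_true=beta_out_true, scrambled=mode, palindromic=pal,
        snp_ids=snp_ids,
    )
    return exposure, outcome, truth


def simulate_mediation_triple(
    config: SimConfig,
) -> tuple[SummaryStats, SummaryStats, SummaryStats, SimTruth]:
    """Generate an exposure/mediator/outcome triple with a true mediation chain.

    The panel holds ``m_snps`` exposure instruments (effects γ) plus
    ``m_mediator_snps`` mediator-specific instruments (effects δ, larger per
    SNP, reflecting metabolite-QTL architecture).  Truths:
    mediator = θ_xm·γ + δ; outcome = θ_direct·γ + θ_my·mediator (+ α), so the
    total exposure→outcome effect is a = θ_direct + θ_xm·θ_my by
    construction.
    """
    if config.mediation is None:
        raise ValueError("config.mediation must be set for a mediation triple")
    med = config.mediation
    rng = np.random.default_rng(config.seed)
    m_e, m_m = config.m_snps, config.m_mediator_snps
    m = m_e + m_m
    eaf = rng.uniform(*config.maf_range, size=m)

    gamma = np.zeros(m)
    gamma[:m_e] = np.abs(rng.normal(0.0, config.gamma_sd, size=m_e))
    delta = np.zeros(m)
    delta[m_e:] = np.abs(rng.normal(0.0, config.mediator_gamma_sd, size=m_m))
    alpha = np.zeros(m)
    invalid = rng.random(m) < config.invalid_fraction
    if invalid.any():
        alpha[invalid] = rng.normal(config.pleiotropy_mean, config.pleiotropy_sd, size=invalid.sum())

    beta_med_true = med.theta_xm * gamma + delta
    beta_out_true = med.theta_direct * gamma + med.theta_my * beta_med_true + alpha

    se_x = _analytic_se(eaf, config.n_exposure)
    se_m = _analytic_se(eaf, config.n_mediator)
    se_y = _analytic_se(eaf, config.n_outcome)
    beta_x = rng.normal(gamma, se_x)
    beta_m = rng.normal(beta_med_true, se_m)
    beta_y = rng.normal(beta_out_true, se_y)

    snp_ids = np.array([f"rs{2000000 + j}" for j in range(m)])
    chrom = np.array([str(1 + j % 22) for j in range(m)])
    pos = 1_000_000 + 2_000_000 * np.arange(m, dtype="int64")
    pairs, pal = _alleles(rng, m, config.palindromic_fraction)
    ea = pairs[:, 0].astype(object)
    oa = pairs[:, 1].astype(object)

    exposure = _table("sim_exposure", snp_ids, chrom, pos, ea, oa, eaf, beta_x, se_x,
                      config.n_exposure)
    mediator = _table("sim_mediator", snp_ids, chrom, pos, ea, oa, eaf, beta_m, se_m,
                      config.n_mediator)
    ea_o, oa_o, eaf_o, beta_y_enc, mode = _scramble_outcome(
        rng, ea, oa, eaf, beta_y, pal, config.scramble_fraction
    )
    outcome = _table("sim_outcome", snp_ids, chrom, pos, ea_o, oa_o, eaf_o, beta_y_enc, se_y,
                     config.n_outcome)
    truth = SimTruth(
        gamma=gamma, alpha=alpha, theta=med.total, eaf=eaf,
        beta_outcome_true=beta_out_true, scrambled=mode, palindromic=pal,
        mediation=med, delta=delta, beta_mediator_true=beta_med_true,
        snp_ids=snp_ids,
    )
    return exposure, mediator, outcome, truth


#: the seven genome-wide-significant instruments for the disc-degeneration
#: outcome trait (FinnGen finn-b-M13_INTERVERTEB), as published; used for
#: reverse-direction MR and for the R²/F strength checks
_TABLE1_TSV = """\
snp_id\tpval\tchrom\tpos\tn\tbeta\tse\teffect_allele\tother_allele\teaf
rs12308843\t4.36E-08\t12\t23974404\t184683\t0.0689\t0.0126\tC\tG\t0.3103
rs3010043\t4.73E-09\t1\t183942175\t184683\t-0.0836\t0.0143\tG\tA\t0.7913
rs3135840\t9.27E-10\t4\t1796539\t184683\t-0.0816\t0.0133\tT\tA\t0.2631
rs4148946\t3.00E-08\t10\t73770073\t184683\t0.0647\t0.0117\tT\tC\t0.554
rs4473430\t2.42E-08\t2\t69582895\t184683\t-0.0651\t0.0117\tT\tC\t0.5523
rs62099230\t3.27E-11\t18\t50721712\t184683\t0.0785\t0.0118\tA\tG\t0.404
rs6470763\t6.82E-09\t8\t130720646\t184683\t-0.092\t0.0159\tC\tG\t0.1652
"""

#: published per-SNP strength statistics for the same seven instruments
TABLE1_STRENGTH = {
    "rs12308843": (0.002031938, 376.0243903),
    "rs3010043": (0.002308374, 427.2991764),
    "rs3135840": (0.002581902, 478.062514),
    "rs4148946": (0.002068632, 382.8289073),
    "rs4473430": (0.002095821, 387.8711576),
    "rs62099230": (0.002967542, 549.6798979),
    "rs6470763": (0.002334523, 432.1508852),
}


def table1_fixture() -> SummaryStats:
    """The seven published disc-degeneration instrument SNPs as a SummaryStats."""
    df = pd.read_csv(io.StringIO(_TABLE1_TSV), sep="\t")
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype("int64")
    df["n"] = df["n"].astype("int64")
    return SummaryStats(
        trait_id="finn-b-M13_INTERVERTEB",
        variants=df[CANONICAL_COLUMNS],
        trait_label="intervertebral disk degeneration",
    )
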