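"""Instrument selection and exposure/outcome harmonization.

Instruments are SNPs passing a p-value threshold, pruned to approximate
linkage-equilibrium by greedy clumping, and retained only when strong
(F > 10 by convention).  Per-SNP explained variance is computed on the
unit-variance trait scale as R² = 2·eaf·(1−eaf)·β², and instrument strength
as F = R²(N−K−1)/(K(1−R²)) with K = 1 (per-SNP F).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .gwas_io import SummaryStats, empty_frame

log = logging.getLogger(__name__)

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: effect-allele frequency band within which a palindromic SNP's strand
#: cannot be resolved from frequency; such SNPs are dropped
DEFAULT_PALINDROME_WINDOW = (0.42, 0.58)

DEFAULT_CLUMP_WINDOW_BP = 10_000_000


def compute_r2(eaf: float, beta: float) -> float:
    """Variance in a unit-variance trait explained by one SNP.

    R² = 2·eaf·(1−eaf)·β²; symmetric under eaf ↔ 1−eaf and β ↔ −β.
    """
    eaf = np.asarray(eaf, dtype=float)
    if np.any(eaf <= 0.0) or np.any(eaf >= 1.0):
        raise ValueError(f"eaf must lie in (0,1), got {eaf}")
    out = 2.0 * eaf * (1.0 - eaf) * np.asarray(beta, dtype=float) ** 2
    return float(out) if out.ndim == 0 else out


def compute_f(r2: float, n: float, k: int = 1) -> float:
    """Instrument F statistic: F = R²(N−K−1)/(K(1−R²))."""
    r2 = np.asarray(r2, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(r2 < 0.0) or np.any(r2 >= 1.0):
        raise ValueError("r2 must lie in [0,1)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if np.any(n <= k + 1):
        raise ValueError("need n > k + 1")
    out = r2 * (n - k - 1.0) / (k * (1.0 - r2))
    return float(out) if out.ndim == 0 else out


class LDLookup:
    """Pairwise LD r² lookup; unknown pairs are treated as independent (r²=0)."""

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._r2: dict[frozenset, float] = {}
        for (a, b), r2 in (pairs or {}).items():
            self._r2[frozenset((a, b))] = float(r2)

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._r2.get(frozenset((a, b)), 0.0)

    @classmethod
    def independent(cls) -> "LDLookup":
        return cls()

    @classmethod
    def from_file(cls, path: str | Path) -> "LDLookup":
        """Load LD from 3-column TSV (snp_a, snp_b, r2) or a dense labelled matrix."""
        df = pd.read_csv(path, sep="\t")
        cols = [c.lower() for c in df.columns]
        if len(df.columns) == 3 and "r2" in cols:
            df.columns = cols
            a, b = [c for c in cols if c != "r2"]
            return cls({(str(r[a]), str(r[b])): r["r2"] for _, r in df.iterrows()})
        mat = pd.read_csv(path, sep="\t", index_col=0)
        pairs = {}
        for i in mat.index:
            for j in mat.columns:
                if str(i) != str(j):
                    pairs[(str(i), str(j))] = float(mat.loc[i, j])
        return cls(pairs)


@dataclass
class InstrumentSet:
    """Clumped, strength-filtered instruments for one exposure.

    ``records`` carries the canonical variant columns plus per-SNP ``r2``
    and ``f_stat``.
    """

    exposure_id: str
    records: pd.DataFrame
    p_threshold: float
    r2_clump_threshold: float = 0.001
    f_min: float = 10.0
    trait_label: str = ""

    @property
    def n_snp(self) -> int:
        return len(self.records)

    def as_summary_stats(self) -> SummaryStats:
        cols = [c for c in self.records.columns if c not in ("r2", "f_stat")]
        return SummaryStats(self.exposure_id, self.records[cols].copy(), self.trait_label)


@dataclass
class HarmonizedDataset:
    """Exposure and outcome associations joined per SNP on a common effect allele.

    ``rows`` keeps every instrument, including exclusions (``dropped_reason``
    set); estimators consume the retained subset via the array properties.
    """

    exposure_id: str
    outcome_id: str
    rows: pd.DataFrame = field(default_factory=lambda: _empty_harmonized())

    @property
    def kept(self) -> pd.DataFrame:
        return self.rows[self.rows["dropped_reason"].isna()]

    @property
    def n_snp(self) -> int:
        return len(self.kept)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.kept["snp_id"].to_numpy()

    @property
    def beta_exp(self) -> np.ndarray:
        return self.kept["beta_exp"].to_numpy(float)

    @property
    def se_exp(self) -> np.ndarray:
        return self.kept["se_exp"].to_numpy(float)

    @property
    def beta_out(self) -> np.ndarray:
        return self.kept["beta_out"].to_numpy(float)

    @property
    def se_out(self) -> np.ndarray:
        return self.kept["se_out"].to_numpy(float)

    @classmethod
    def from_arrays(
        cls,
        beta_exp,
        se_exp,
        beta_out,
        se_out,
        snp_ids=None,
        exposure_id: str = "exposure",
        outcome_id: str = "outcome",
    ) -> "HarmonizedDataset":
        """Build an already-aligned dataset directly from effect arrays."""
        beta_exp = np.asarray(beta_exp, dtype=float)
        m = len(beta_exp)
        df = pd.DataFrame(
            {
                "snp_id": snp_ids if snp_ids is not None else [f"snp{i}" for i in range(m)],
                "beta_exp": beta_exp,
                "se_exp": np.asarray(se_exp, dtype=float),
                "beta_out": np.asarray(beta_out, dtype=float),
                "se_out": np.asarray(se_out, dtype=float),
                "eaf_exp": np.nan,
                "eaf_out": np.nan,
                "palindromic": False,
                "flipped": False,
                "dropped_reason": None,
            }
        )[HARMONIZED_COLUMNS]
        return cls(exposure_id, outcome_id, df)

    def subset(self, mask: np.ndarray) -> "HarmonizedDataset":
        """Retained-row subset by boolean mask or index array over kept rows."""
        kept = self.kept.iloc[np.asarray(mask)] if np.asarray(mask).dtype != bool else self.kept[mask]
        return HarmonizedDataset(self.exposure_id, self.outcome_id, kept.reset_index(drop=True))


HARMONIZED_COLUMNS = [
    "snp_id",
    "beta_exp",
    "se_exp",
    "beta_out",
    "se_out",
    "eaf_exp",
    "eaf_out",
    "palindromic",
    "flipped",
    "dropped_reason",
]


def _empty_harmonized() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=object) for c in HARMONIZED_COLUMNS})


def clump(
    stats: SummaryStats,
    ld: LDLookup,
    r2_threshold: float = 0.001,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> SummaryStats:
    """Greedy LD clumping.

    SNPs are visited in ascending p-value (ties broken lexicographically by
    rsID) and accepted iff their LD r² with every already-accepted SNP within
    ``window_bp`` on the same chromosome stays below ``r2_threshold``.
    Deterministic and invariant to the input row order.
    """
    if not 0.0 < r2_threshold <= 1.0:
        raise ValueError("r2_threshold must lie in (0,1]")
    df = stats.variants.sort_values(["pval", "snp_id"], kind="mergesort")
    accepted: list[int] = []
    acc_chrom: list[str] = []
    acc_pos: list[int] = []
    acc_id: list[str] = []
    for idx, row in df.iterrows():
        ok = True
        for ch, pos, sid in zip(acc_chrom, acc_pos, acc_id):
            if ch == row["chrom"] and abs(int(row["pos"]) - pos) <= window_bp:
                if ld.r2(row["snp_id"], sid) >= r2_threshold:
                    ok = False
                    break
        if ok:
            accepted.append(idx)
            acc_chrom.append(row["chrom"])
            acc_pos.append(int(row["pos"]))
            acc_id.append(row["snp_id"])
    kept = df.loc[accepted].reset_index(drop=True)
    return SummaryStats(stats.trait_id, kept, stats.trait_label)


def select_instruments(
    stats: SummaryStats,
    p_threshold: float = 1e-5,
    ld: LDLookup | None = None,
    f_min: float = 10.0,
    r2_clump_threshold: float = 0.001,
    window_bp: int = DEFAULT_CLUMP_WINDOW_BP,
) -> InstrumentSet:
    """Select instruments: p-filter, clump, and drop weak SNPs (F ≤ f_min).

    Per-SNP strength uses K = 1 in the F formula.  Returns an empty set (with
    a warning) when nothing survives, so callers can skip the exposure.
    """
    if p_threshold <= 0 or f_min < 0:
        raise ValueError("thresholds must be positive")
    ld = ld or LDLookup.independent()
    sig = stats.variants[stats.variants["pval"] < p_threshold]
    n_sig = len(sig)
    clumped = clump(SummaryStats(stats.trait_id, sig.reset_index(drop=True), stats.trait_label),
                    ld, r2_clump_threshold, window_bp)
    df = clumped.variants.copy()
    if len(df):
        df["r2"] = compute_r2(df["eaf"].to_numpy(float), df["beta"].to_numpy(float))
        df["f_stat"] = compute_f(df["r2"].to_numpy(float), df["n"].to_numpy(float), k=1)
        strong = df[df["f_stat"] > f_min].reset_index(drop=True)
    else:
        strong = df.assign(r2=pd.Series(dtype=float), f_stat=pd.Series(dtype=float))
    log.info(
        "%s: %d variants -> %d at p<%g -> %d after clumping -> %d with F>%g",
        stats.trait_id, stats.n_variants, n_sig, len(df), len(strong), f_min,
    )
    if not len(strong):
        log.warning("%s: no instruments survive selection", stats.trait_id)
    return InstrumentSet(
        exposure_id=stats.trait_id,
        records=strong,
        p_threshold=p_threshold,
        r2_clump_threshold=r2_clump_threshold,
        f_min=f_min,
        trait_label=stats.trait_label,
    )


def _is_palindromic(ea: str, oa: str) -> bool:
    return len(ea) == 1 and len(oa) == 1 and COMPLEMENT.get(ea) == oa


def _comp(allele: str) -> str:
    return "".join(COMPLEMENT.get(c, "N") for c in allele)


def harmonize(
    exposure: InstrumentSet,
    outcome: SummaryStats,
    palindrome_eaf_window: tuple[float, float] = DEFAULT_PALINDROME_WINDOW,
) -> HarmonizedDataset:
    """Align outcome associations to the exposure effect allele per SNP.

    Allele resolution order: direct match; effect/other swap (outcome beta
    sign flipped, eaf reflected); strand complement, then direct/swap again.
    Palindromic pairs (A/T, C/G) are kept only when both effect-allele
    frequencies are known and fall outside ``palindrome_eaf_window`` on the
    same side after orientation; otherwise they are recorded as dropped with
    reason ``palindromic_ambiguous``.  Nothing is silently discarded: every
    instrument appears in the output, exclusions carry a ``dropped_reason``.
    """
    lo, hi = palindrome_eaf_window
    out_idx = outcome.variants.set_index("snp_id")
    rows = []
    for r in exposure.records.itertuples(index=False):
        rec = {
            "snp_id": r.snp_id,
            "beta_exp": float(r.beta),
            "se_exp": float(r.se),
            "beta_out": np.nan,
            "se_out": np.nan,
            "eaf_exp": float(r.eaf),
            "eaf_out": np.nan,
            "palindromic": False,
            "flipped": False,
            "dropped_reason": None,
        }
        if r.snp_id not in out_idx.index:
            rec["dropped_reason"] = "not_in_outcome"
            rows.append(rec)
            continue
        o = out_idx.loc[r.snp_id]
        ea, oa = r.effect_allele, r.other_allele
        o_ea, o_oa = str(o["effect_allele"]), str(o["other_allele"])
        beta_out, se_out, eaf_out = float(o["beta"]), float(o["se"]), float(o["eaf"])
        rec["se_out"] = se_out

        palindromic = _is_palindromic(ea, oa)
        rec["palindromic"] = palindromic

        flipped: bool | None = None
        if (o_ea, o_oa) == (ea, oa):
            flipped = False
        elif (o_ea, o_oa) == (oa, ea):
            flipped = True
        elif not palindromic and (_comp(o_ea), _comp(o_oa)) == (ea, oa):
            flipped = False
        elif not palindromic and (_comp(o_ea), _comp(o_oa)) == (oa, ea):
            flipped = True
        if flipped is None:
            rec["dropped_reason"] = "allele_mismatch"
            rows.append(rec)
            continue
        if flipped:
            beta_out = -beta_out
            if not np.isnan(eaf_out):
                eaf_out = 1.0 - eaf_out
        rec["flipped"] = flipped
        rec["beta_out"] = beta_out
        rec["eaf_out"] = eaf_out
        if palindromic:
            e_exp, e_out = rec["eaf_exp"], eaf_out
            resolvable = (
                not np.isnan(e_exp)
                and not np.isnan(e_out)
                and (e_exp < lo or e_exp > hi)
                and (e_out < lo or e_out > hi)
                and ((e_exp < lo) == (e_out < lo))
            )
            if not resolvable:
                rec["dropped_reason"] = "palindromic_ambiguous"
        rows.append(rec)
    df = pd.DataFrame(rows, columns=HARMONIZED_COLUMNS) if rows else _empty_harmonized()
    n_drop = int(df["dropped_reason"].notna().sum()) if len(df) else 0
    if n_drop:
        log.info("%s vs %s: %d/%d instruments dropped during harmonization",
                 exposure.exposure_id, outcome.trait_id, n_drop, len(df))
    return HarmonizedDataset(exposure.exposure_id, outcome.trait_id, df)
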