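"""Reading and writing GWAS summary-statistic tables.

Summary statistics arrive as tab-separated text with one row per variant.
Different repositories name the columns differently (the GWAS catalog and
FinnGen dialects are built in); everything is mapped onto one canonical
internal representation so the rest of the pipeline never sees source
dialects.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order of the internal representation
CANONICAL_COLUMNS = [
    "snp_id",
    "chrom",
    "pos",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
]

#: columns that must be mappable; the rest may be declared absent
REQUIRED_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se", "pval")

VALID_ALLELE_CHARS = frozenset("ACGT")

#: built-in column dialects (canonical field -> source column name)
DIALECTS: dict[str, dict[str, str]] = {
    "canonical": {c: c for c in CANONICAL_COLUMNS},
    "gwas_catalog": {
        "snp_id": "variant_id",
        "chrom": "chromosome",
        "pos": "base_pair_location",
        "effect_allele": "effect_allele",
        "other_allele": "other_allele",
        "eaf": "effect_allele_frequency",
        "beta": "beta",
        "se": "standard_error",
        "pval": "p_value",
        "n": "n",
    },
    "finngen": {
        "snp_id": "rsids",
        "chrom": "#chrom",
        "pos": "pos",
        "effect_allele": "alt",
        "other_allele": "ref",
        "eaf": "af_alt",
        "beta": "beta",
        "se": "sebeta",
        "pval": "pval",
        "n": "n",
    },
}


class SchemaError(ValueError):
    """A required summary-statistics column could not be mapped."""


@dataclass(frozen=True)
class VariantAssociation:
    """One SNP's summary association with one trait.

    ``beta`` is the per-effect-allele change in the trait (log odds for a
    binary trait), ``se`` its standard error and ``eaf`` the effect-allele
    frequency.  Positions are 1-based.
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    pval: float
    n: int

    def __post_init__(self) -> None:
        if not (np.isnan(self.eaf) or 0.0 < self.eaf < 1.0):
            raise ValueError(f"{self.snp_id}: eaf must lie in (0,1), got {self.eaf}")
        if not self.se > 0:
            raise ValueError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not 0.0 < self.pval <= 1.0:
            raise ValueError(f"{self.snp_id}: pval must lie in (0,1], got {self.pval}")
        if not self.n >= 1:
            raise ValueError(f"{self.snp_id}: n must be >= 1, got {self.n}")
        for name in ("effect_allele", "other_allele"):
            a = getattr(self, name)
            if not a or not set(a) <= VALID_ALLELE_CHARS:
                raise ValueError(f"{self.snp_id}: invalid {name} {a!r}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele identical")


@dataclass
class SummaryStats:
    """A set of variant associations for one trait.

    ``variants`` is a DataFrame in canonical column order with one unique
    ``snp_id`` per row; :meth:`records` exposes the rows as
    :class:`VariantAssociation` objects when object semantics are wanted.
    """

    trait_id: str
    variants: pd.DataFrame = field(default_factory=lambda: empty_frame())
    trait_label: str = ""

    def __post_init__(self) -> None:
        v = self.variants
        if list(v.columns) != CANONICAL_COLUMNS:
            missing = set(CANONICAL_COLUMNS) - set(v.columns)
            if missing:
                raise ValueError(f"variants frame missing columns {sorted(missing)}")
            self.variants = v = v[CANONICAL_COLUMNS]
        if v["snp_id"].duplicated().any():
            dup = v.loc[v["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate snp_id {dup!r} in {self.trait_id}")
        self.variants = v.reset_index(drop=True)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def records(self) -> list[VariantAssociation]:
        return [
            VariantAssociation(
                snp_id=r.snp_id,
                chrom=str(r.chrom),
                pos=int(r.pos),
                effect_allele=r.effect_allele,
                other_allele=r.other_allele,
                eaf=float(r.eaf),
                beta=float(r.beta),
                se=float(r.se),
                pval=float(r.pval),
                n=int(r.n),
            )
            for r in self.variants.itertuples(index=False)
        ]

    def get(self, snp_id: str) -> VariantAssociation | None:
        sub = self.variants[self.variants["snp_id"] == snp_id]
        if sub.empty:
            return None
        return SummaryStats(self.trait_id, sub, self.trait_label).records()[0]


def empty_frame() -> pd.DataFrame:
    """An empty canonical variants frame with correct dtypes."""
    return pd.DataFrame(
        {
            "snp_id": pd.Series(dtype=str),
            "chrom": pd.Series(dtype=str),
            "pos": pd.Series(dtype="int64"),
            "effect_allele": pd.Series(dtype=str),
            "other_allele": pd.Series(dtype=str),
            "eaf": pd.Series(dtype=float),
            "beta": pd.Series(dtype=float),
            "se": pd.Series(dtype=float),
            "pval": pd.Series(dtype=float),
            "n": pd.Series(dtype="int64"),
        }
    )


def _resolve_column_map(column_map: str | Mapping[str, str | None]) -> dict[str, str | None]:
    if isinstance(column_map, str):
        try:
            return dict(DIALECTS[column_map])
        except KeyError:
            raise SchemaError(
                f"unknown dialect {column_map!r}; known: {sorted(DIALECTS)}"
            ) from None
    resolved = dict(DIALECTS["canonical"])
    resolved.update(column_map)
    return resolved


def read_summary_stats(
    path: str | Path,
    column_map: str | Mapping[str, str | None] = "canonical",
    trait_id: str | None = None,
    trait_label: str = "",
    default_n: int | None = None,
) -> SummaryStats:
    """Read a tab-separated summary-statistics table.

    ``column_map`` is a dialect name (``canonical``, ``gwas_catalog``,
    ``finngen``) or a mapping from canonical field names to source column
    names; map a field to ``None`` to declare it absent.  Rows violating the
    :class:`VariantAssociation` invariants are dropped and counted in the
    log.  A missing ``n`` column can be backfilled with ``default_n``.
    Gzip-compressed input is accepted (by file extension).
    """
    path = Path(path)
    cmap = _resolve_column_map(column_map)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str, compression="infer")
    except FileNotFoundError:
        raise
    except OSError as exc:  # pragma: no cover - environment dependent
        raise OSError(f"cannot read {path}: {exc}") from exc

    for fld in REQUIRED_FIELDS:
        col = cmap.get(fld)
        if col is None or col not in raw.columns:
            raise SchemaError(f"required column for field {fld!r} not found (looked for {col!r})")

    out = pd.DataFrame(index=raw.index)
    for fld in CANONICAL_COLUMNS:
        col = cmap.get(fld)
        if col is not None and col in raw.columns:
            out[fld] = raw[col]
        else:
            out[fld] = np.nan

    n_in = len(out)
    for col in ("eaf", "beta", "se", "pval"):
        out[col] = pd.to_numeric(out[col], errors="coerce").astype(float)
    for col in ("n", "pos"):
        out[col] = pd.to_numeric(out[col], errors="coerce")
    if out["n"].isna().all() and default_n is not None:
        out["n"] = float(default_n)
    out["chrom"] = out["chrom"].fillna("").astype(str)
    out["pos"] = out["pos"].fillna(0)
    for col in ("snp_id", "effect_allele", "other_allele"):
        out[col] = out[col].astype(str).str.upper().str.strip()
    out["snp_id"] = raw[cmap["snp_id"]].astype(str).str.strip()

    # p = 0 carries no usable magnitude downstream of a -log transform: clamp
    zero_p = out["pval"] == 0.0
    if zero_p.any():
        log.warning("%s: clamped %d zero p-values to %g", path.name, zero_p.sum(), sys.float_info.min)
        out.loc[zero_p, "pval"] = sys.float_info.min

    allele_ok = out["effect_allele"].map(_valid_allele) & out["other_allele"].map(_valid_allele)
    keep = (
        out["beta"].notna()
        & (out["se"] > 0)
        & (out["pval"] > 0)
        & (out["pval"] <= 1)
        & (out["n"] >= 1)
        & (out["eaf"].isna() | ((out["eaf"] > 0) & (out["eaf"] < 1)))
        & allele_ok
        & (out["effect_allele"] != out["other_allele"])
        & (out["snp_id"] != "")
    )
    dropped = int(n_in - keep.sum())
    if dropped:
        log.info("%s: dropped %d/%d rows violating field invariants", path.name, dropped, n_in)
    out = out[keep].copy()
    out = out.drop_duplicates(subset="snp_id", keep="first")
    out["pos"] = out["pos"].astype("int64")
    out["n"] = out["n"].astype("int64")
    return SummaryStats(
        trait_id=trait_id if trait_id is not None else path.stem,
        variants=out.reset_index(drop=True),
        trait_label=trait_label,
    )


def _valid_allele(a: object) -> bool:
    return isinstance(a, str) and len(a) > 0 and set(a) <= VALID_ALLELE_CHARS


def write_summary_stats(stats: SummaryStats, path: str | Path) -> None:
    """Write ``stats`` as canonical tab-separated text.

    Floats are printed with 17 significant digits, so read ∘ write is the
    identity to full double precision.
    """
    df = stats.variants.copy()
    with open(path, "w") as fh:
        fh.write("\t".join(CANONICAL_COLUMNS) + "\n")
        for row in df.itertuples(index=False):
            fields = [
                row.snp_id,
                str(row.chrom),
                str(int(row.pos)),
                row.effect_allele,
                row.other_allele,
                _fmt(row.eaf),
                _fmt(row.beta),
                _fmt(row.se),
                _fmt(row.pval),
                str(int(row.n)),
            ]
            fh.write("\t".join(fields) + "\n")


def _fmt(x: float) -> str:
    if np.isnan(x):
        return "NA"
    return format(float(x), ".17g")
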