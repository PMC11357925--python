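import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from mrmediate.gwas_io import CANONICAL_COLUMNS, SummaryStats
from mrmediate.instruments import HarmonizedDataset, InstrumentSet, harmonize
from mrmediate.synthetic_data import SimConfig, simulate_gwas_pair, table1_fixture


def make_stats(rows, trait_id="trait"):
    """SummaryStats from a list of dicts; unspecified fields get sane values."""
    defaults = {
        "chrom": "1",
        "pos": 1000,
        "effect_allele": "A",
        "other_allele": "G",
        "eaf": 0.3,
        "beta": 0.1,
        "se": 0.01,
        "pval": 1e-9,
        "n": 10000,
    }
    recs = []
    for i, r in enumerate(rows):
        rec = {"snp_id": f"rs{i}", **defaults, **r}
        recs.append(rec)
    df = pd.DataFrame(recs)[CANONICAL_COLUMNS]
    df["pos"] = df["pos"].astype("int64")
    df["n"] = df["n"].astype("int64")
    return SummaryStats(trait_id, df)


def full_panel_dataset(cfg: SimConfig) -> tuple[HarmonizedDataset, object]:
    """Harmonize every simulated SNP (no p-selection) — estimator-level studies."""
    exp, out, truth = simulate_gwas_pair(cfg)
    df = exp.variants.copy()
    df["r2"] = 0.0
    df["f_stat"] = np.inf
    inst = InstrumentSet(exp.trait_id, df, p_threshold=1.0)
    return harmonize(inst, out), truth


@pytest.fixture(scope="session")
def table1():
    return table1_fixture()


@pytest.fixture
def toy_dataset():
    """5-SNP aligned dataset with hand-pickable numbers."""
    return HarmonizedDataset.from_arrays(
        beta_exp=[0.10, 0.15, 0.20, 0.12, 0.08],
        se_exp=[0.01, 0.01, 0.01, 0.01, 0.01],
        beta_out=[0.030, 0.050, 0.058, 0.041, 0.020],
        se_out=[0.010, 0.012, 0.008, 0.011, 0.015],
    )
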