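import numpy as np
import pandas as pd
import pytest

from mrkit import SimConfig, harmonized_from_arrays, simulate_two_sample
from mrkit.simgen import with_seed
from mrkit.sumstats import CANONICAL_COLUMNS, SumstatsTable


def simulated_hset(seed: int, **cfg_kwargs):
    """Harmonized set built straight from one synthetic two-sample draw.

    Bypasses allele bookkeeping (the generator emits already-aligned
    effects), which keeps replicate loops cheap; returns (hset, truth).
    """
    cfg = with_seed(SimConfig(**cfg_kwargs), seed)
    exposure, outcome, truth = simulate_two_sample(cfg)
    e, o = exposure.frame, outcome.frame
    merged = e.merge(o[["snp_id", "beta", "se"]], on="snp_id", suffixes=("", "_y"))
    h = harmonized_from_arrays(
        merged["beta"], merged["se"], merged["beta_y"], merged["se_y"],
        snp_ids=merged["snp_id"].tolist(), eaf_x=merged["eaf"],
    )
    return h, truth


@pytest.fixture
def make_hset():
    return simulated_hset


@pytest.fixture
def make_table():
    """Build a SumstatsTable from keyword-column overrides of a valid default."""

    def _make(k=5, **overrides):
        base = {
            "snp_id": [f"rs{i+1}" for i in range(k)],
            "chrom": ["1"] * k,
            "pos": [(i + 1) * 1_000_000 for i in range(k)],
            "effect_allele": ["A"] * k,
            "other_allele": ["G"] * k,
            "eaf": [0.3] * k,
            "beta": [0.1] * k,
            "se": [0.01] * k,
            "pvalue": [1e-10] * k,
            "n": [100_000] * k,
        }
        base.update(overrides)
        frame = pd.DataFrame(base)[CANONICAL_COLUMNS]
        return SumstatsTable("test_trait", frame)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
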