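import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import pwmr
from pwmr import LDMatrix, SummaryStats

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_stats(rows, trait_id="trait", trait_type="quantitative"):
    """Build SummaryStats from a list of dicts, filling common defaults."""
    defaults = {"chrom": "1", "eaf": 0.3, "n": 10_000, "pval": 0.5}
    full = []
    for i, r in enumerate(rows):
        d = dict(defaults, pos=1_000_000 + 5_000 * i, variant_id=f"rs{i}")
        d.update(r)
        full.append(d)
    df = pd.DataFrame(full)
    return SummaryStats(trait_id, trait_type, df)


@pytest.fixture
def toy_exposure():
    return make_stats(
        [
            {"variant_id": "rs1", "ea": "A", "oa": "G", "beta": 0.10, "se": 0.01, "pval": 1e-20},
            {"variant_id": "rs2", "ea": "C", "oa": "T", "beta": 0.08, "se": 0.01, "pval": 1e-14},
            {"variant_id": "rs3", "ea": "A", "oa": "T", "beta": 0.12, "se": 0.01, "pval": 1e-25, "eaf": 0.5},
        ],
        trait_id="protein",
    )


@pytest.fixture
def toy_outcome():
    return make_stats(
        [
            {"variant_id": "rs1", "ea": "G", "oa": "A", "beta": -0.05, "se": 0.008, "pval": 1e-8},
            {"variant_id": "rs2", "ea": "C", "oa": "T", "beta": 0.03, "se": 0.008, "pval": 2e-4},
            {"variant_id": "rs3", "ea": "A", "oa": "T", "beta": 0.04, "se": 0.008, "pval": 1e-6},
        ],
        trait_id="disease",
        trait_type="binary",
    )


def ld_from(ids, r, alleles=None):
    if alleles is None:
        alleles = [("A", "G")] * len(ids)
    return LDMatrix(list(ids), alleles, np.asarray(r, dtype=float))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
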