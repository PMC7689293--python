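"""Shared fixtures: small hand-built tables and compact synthetic systems."""

import numpy as np
import pandas as pd
import pytest

from mrmediation.sumstats import HarmonizedSet, SummaryStats


def make_sumstats_frame(rows: list[dict]) -> pd.DataFrame:
    """Raw summary-statistics frame with sensible defaults per row."""
    defaults = {
        "snp_id": None, "chrom": "1", "pos": 0, "effect_allele": "A",
        "other_allele": "G", "eaf": 0.3, "beta": 0.1, "se": 0.02,
        "pvalue": 1e-9, "n": 100_000,
    }
    out = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["snp_id"] = f"rs{i + 1}"
        rec["pos"] = (i + 1) * 10_000
        rec.update(row)
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def toy_exposure() -> SummaryStats:
    frame = make_sumstats_frame(
        [
            {"beta": 0.10, "se": 0.01},
            {"beta": 0.15, "se": 0.012, "effect_allele": "C", "other_allele": "T"},
            {"beta": -0.08, "se": 0.011, "effect_allele": "G", "other_allele": "A"},
        ]
    )
    return SummaryStats.from_frame(frame, trait_name="exposure", trait_type="binary")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_harmonized(
    rng: np.random.Generator, k: int, exposure_type: str = "binary"
) -> HarmonizedSet:
    """Random pre-aligned instrument with positive exposure effects."""
    bx = rng.uniform(0.05, 0.3, size=k)
    sx = rng.uniform(0.005, 0.02, size=k)
    by = 0.2 * bx + rng.normal(0, 0.02, size=k)
    sy = rng.uniform(0.01, 0.05, size=k)
    return HarmonizedSet.from_arrays(bx, sx, by, sy, exposure_type=exposure_type)
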