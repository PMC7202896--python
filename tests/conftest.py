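import numpy as np
import pandas as pd
import pytest

from ryrmod.chem import ChemicalRecord


@pytest.fixture
def small_wells() -> pd.DataFrame:
    """Six-condition duplicate-well screen with known hit structure."""
    rows = [
        # condition, replicate, L1L3, L4, adult, is_control
        ("hitA", 0, 10, 5, 5, False),
        ("hitA", 1, 12, 4, 4, False),
        ("hitB", 0, 18, 1, 1, False),
        ("hitB", 1, 17, 2, 1, False),
        ("half", 0, 19, 1, 0, False),   # escapee in one replicate only
        ("half", 1, 20, 0, 0, False),
        ("clean1", 0, 20, 0, 0, False),
        ("clean1", 1, 21, 0, 0, False),
        ("clean2", 0, 19, 0, 0, False),
        ("clean2", 1, 18, 0, 0, False),
        ("clean3", 0, 20, 0, 0, False),
        ("clean3", 1, 20, 0, 0, False),
        ("DMSO", 0, 20, 0, 0, True),
        ("DMSO", 1, 19, 1, 0, True),
    ]
    return pd.DataFrame(
        rows,
        columns=["condition_id", "replicate", "count_L1L3", "count_L4", "count_adult", "is_control"],
    )


def record(cid: str, bits: list[int], n_bits: int = 8, is_hit: bool = False) -> ChemicalRecord:
    fp = np.zeros(n_bits, dtype=np.uint8)
    fp[bits] = 1
    return ChemicalRecord(compound_id=cid, fingerprint=fp, is_hit=is_hit)


@pytest.fixture
def toy_speed_frame() -> pd.DataFrame:
    """Balanced 2x2 integer speeds, n=3 per cell, for closed-form ANOVA checks."""
    rows = []
    data = {
        ("WT", "vehicle"): [2.0, 3.0, 4.0],
        ("mutant", "vehicle"): [1.0, 2.0, 3.0],
        ("WT", "chem"): [2.0, 2.0, 5.0],
        ("mutant", "chem"): [1.0, 1.0, 2.0],
    }
    i = 0
    for (g, t), speeds in data.items():
        for s in speeds:
            rows.append((f"l{i}", "a1", g, t, s))
            i += 1
    return pd.DataFrame(rows, columns=["larva_id", "assay_id", "genotype", "treatment", "speed_mm_s"])
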