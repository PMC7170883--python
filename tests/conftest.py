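import numpy as np
import pandas as pd
import pytest

from hearvar.pedigree import Individual, Pedigree


@pytest.fixture(scope="session")
def trio_pedigree() -> Pedigree:
    """Affected parent + affected child + married-in unaffected parent."""
    return Pedigree(
        [
            Individual("P1", None, None, "male", "yes"),
            Individual("P2", None, None, "female", "no"),
            Individual("C1", "P1", "P2", "female", "yes"),
        ]
    )


@pytest.fixture(scope="session")
def five_affected_pedigree() -> Pedigree:
    """Five affected across two generations plus two unaffected married-ins."""
    return Pedigree(
        [
            Individual("A1", None, None, "male", "yes"),
            Individual("U1", None, None, "female", "no"),
            Individual("A2", "A1", "U1", "male", "yes"),
            Individual("A3", "A1", "U1", "female", "yes"),
            Individual("U2", None, None, "male", "no"),
            Individual("A4", "U2", "A3", "female", "yes"),
            Individual("A5", "U2", "A3", "male", "yes"),
        ]
    )


def make_traits(**cols) -> pd.DataFrame:
    """Trait-table builder with sane defaults for every recognised column."""
    n = max(len(v) for v in cols.values()) if cols else 1
    base = {
        "id": [f"S{i}" for i in range(n)],
        "vocab": [200.0] * n,
        "nwr": [7.0] * n,
        "wold": [8.0] * n,
        "ccc_fluency": [10.0] * n,
        "ccc_syntax": [10.0] * n,
        "nviq": [100.0] * n,
        "asd_flag": [False] * n,
        "sen_flag": [False] * n,
        "ethnicity": ["british"] * n,
        "gestation_weeks": [40.0] * n,
        "birthweight_g": [3400.0] * n,
        "ac_l_05": [10.0] * n,
        "ac_r_05": [10.0] * n,
        "ac_l_1": [8.0] * n,
        "ac_l_2": [8.0] * n,
        "ac_l_4": [8.0] * n,
        "ac_r_1": [8.0] * n,
        "ac_r_2": [8.0] * n,
        "ac_r_4": [8.0] * n,
        "carrier_flag": [False] * n,
    }
    base.update(cols)
    return pd.DataFrame(base)


def jaccard(a: tuple[int, int], b: tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union else 0.0


def best_region_jaccard(regions, truth_chrom, truth_start, truth_end) -> float:
    best = 0.0
    for r in regions:
        if r.interval.chrom != truth_chrom:
            continue
        best = max(best, jaccard((r.interval.start, r.interval.end), (truth_start, truth_end)))
    return best
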