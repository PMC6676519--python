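import numpy as np
import pandas as pd
import pytest

from sigbench.io import ExpressionCohort


def make_cohort(values, gene_ids=None, sample_ids=None, cohort_id="c1", platform_id="p1"):
    """Build a cohort from a 2-D array (genes x samples)."""
    values = np.asarray(values, dtype=float)
    g, n = values.shape
    gene_ids = gene_ids or [f"G{i}" for i in range(g)]
    sample_ids = sample_ids or [f"S{i}" for i in range(n)]
    return ExpressionCohort(
        cohort_id, pd.DataFrame(values, index=gene_ids, columns=sample_ids), platform_id
    )


@pytest.fixture
def tiny_cohort():
    """4 genes x 3 samples with known per-sample rank structure."""
    # sample S0: A=4 > B=3 > C=2 > D=1 on the rank scale
    values = np.array(
        [
            [9.0, 1.0, 5.0],  # A
            [7.0, 2.0, 5.0],  # B
            [5.0, 3.0, 5.0],  # C
            [3.0, 4.0, 1.0],  # D
        ]
    )
    return make_cohort(values, gene_ids=list("ABCD"), sample_ids=["S0", "S1", "S2"])


@pytest.fixture
def metadata_frame():
    rows = [
        ("s1", "c1", 70.0, "F", "AD", "b1"),
        ("s2", "c1", 71.0, "F", "CTL", "b1"),
        ("s3", "c1", 80.0, "M", "AD", "b2"),
        ("s4", "c1", 79.0, "M", "CTL", "b2"),
        ("s5", "c1", 65.0, "F", "MCI", "b1"),
    ]
    df = pd.DataFrame(
        rows, columns=["sample_id", "cohort_id", "age", "sex", "diagnosis", "batch"]
    )
    return df.set_index("sample_id", drop=False)
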