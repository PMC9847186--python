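import numpy as np
import pandas as pd
import pytest

from triomics import OmicsMatrix, SampleSheet


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_counts():
    """4 genes x 4 samples with easy arithmetic."""
    data = pd.DataFrame(
        {
            "s1": [10, 0, 5, 85],
            "s2": [20, 0, 10, 170],
            "s3": [12, 0, 6, 82],
            "s4": [24, 0, 12, 164],
        },
        index=["g1", "g2", "g3", "g4"],
    )
    return OmicsMatrix(data, "counts")


def make_trio_sheet(reps=3, condition="Dk"):
    rows = []
    for g, role in (("B73", "femaleParent"), ("Mo17", "maleParent"),
                    ("BM", "hybrid"), ("MB", "hybrid")):
        for r in range(1, reps + 1):
            rows.append({"sample_id": f"{g}_{condition}_r{r}", "genotype": g,
                         "role": role, "cross": g if role == "hybrid" else "",
                         "condition": condition, "replicate": r})
    return SampleSheet(pd.DataFrame(rows))


@pytest.fixture
def trio_sheet():
    return make_trio_sheet()
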