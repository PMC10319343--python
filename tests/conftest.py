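import numpy as np
import pandas as pd
import pytest

from seedcycle.io import IntensityTable


def make_table(values: dict[str, list[float]], condition_of: dict[str, str],
               peptides: dict[str, int] | None = None) -> IntensityTable:
    """Build a small IntensityTable from {protein: row} and a design map."""
    samples = list(condition_of)
    mat = pd.DataFrame.from_dict(values, orient="index", columns=samples)
    mat.index.name = "protein_id"
    pep = pd.Series({p: (peptides or {}).get(p, 2) for p in values})
    return IntensityTable(mat, pep, condition_of)


@pytest.fixture
def two_condition_design() -> dict[str, str]:
    return {f"A_{i}": "A" for i in range(1, 6)} | {f"B_{i}": "B" for i in range(1, 6)}


@pytest.fixture
def toy_table(two_condition_design) -> IntensityTable:
    """Six proteins, 5+5 samples; p_absent fully missing in B with graded floors."""
    rng = np.random.default_rng(42)
    values = {}
    for i, base in enumerate([10.0, 20.0, 40.0, 80.0, 160.0]):
        values[f"p{i}"] = list(base * 2 ** (0.1 * rng.standard_normal(10)))
    values["p_absent"] = [40.0] * 5 + [0.0] * 5
    return make_table(values, two_condition_design)
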