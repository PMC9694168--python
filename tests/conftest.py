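import numpy as np
import pandas as pd
import pytest

import aap


@pytest.fixture(scope="session")
def small_dataset():
    """Small synthetic screen shared across read-only tests."""
    spec = aap.SyntheticSpec(n_compounds=120, n_descriptors=30, seed=42)
    desc, act, truth = aap.generate_training(spec)
    return spec, desc, act, truth


@pytest.fixture(scope="session")
def small_model(small_dataset):
    spec, desc, act, truth = small_dataset
    return aap.build_model(desc, act, aap.CLParams(N=30, Z=50.0, G="a"))


@pytest.fixture()
def one_line_activity():
    """Tiny single-cell-line activity matrix builder."""

    def make(values, ids=None, cell_line="CL1", panel="panel-1"):
        ids = ids or [f"C{i + 1}" for i in range(len(values))]
        return aap.ActivityMatrix(
            pd.DataFrame({cell_line: values}, index=ids), {cell_line: panel}
        )

    return make
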