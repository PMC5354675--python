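import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from melafidelity.datamodel_io import ExpressionMatrix, SampleClass, Unit

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


def make_matrix(values, unit=Unit.LOG2_TPM1, sample_class=SampleClass.CELL_LINE,
                genes=None, samples=None) -> ExpressionMatrix:
    """Build an ExpressionMatrix from a 2-D array (genes x samples)."""
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionMatrix(df, unit, pd.Series(sample_class, index=df.columns))


@pytest.fixture
def matrix_factory():
    return make_matrix
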