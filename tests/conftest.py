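import numpy as np
import pytest

from labsieve.records import CohortLabels, LabMatrix


@pytest.fixture
def toy_matrix() -> LabMatrix:
    """5 cases × 3 analytes; troponin observed for 3 cases, b partially, c fully."""
    values = np.array(
        [
            [12.0, np.nan, 1.0],
            [np.nan, 4.2, 2.0],
            [30.0, 4.0, 3.0],
            [np.nan, np.nan, 4.0],
            [55.0, 3.8, 5.0],
        ]
    )
    return LabMatrix(
        values=values,
        observed_mask=np.isfinite(values),
        cases=[f"c{i}" for i in range(5)],
        analytes=["tnt", "k", "crea"],
        units={"tnt": "ng/L", "k": "mmol/L", "crea": "µmol/L"},
    )


@pytest.fixture
def toy_labels(toy_matrix) -> CohortLabels:
    return CohortLabels({c: i % 2 for i, c in enumerate(toy_matrix.cases)})
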