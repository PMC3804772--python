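import numpy as np
import pytest

from noscabind import LIETrainingTable, load_fixture
from noscabind.io import records_to_dataframe


@pytest.fixture(scope="session")
def table1_records():
    return load_fixture("table1")


@pytest.fixture(scope="session")
def table2_records():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table1_training(table1_records):
    df = records_to_dataframe(table1_records)
    return LIETrainingTable.from_dataframe(df, provenance="table1")


def normal_equations_fit(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Independent least-squares oracle: form XᵀX and solve by Cramer's rule.

    Deliberately avoids numpy's lstsq/solve for the 3x3 no-intercept case so
    that it shares no code path with the implementation under test.
    """
    A = X.T @ X
    b = X.T @ y
    if A.shape == (3, 3):
        def det3(m):
            return (m[0, 0] * (m[1, 1] * m[2, 2] - m[1, 2] * m[2, 1])
                    - m[0, 1] * (m[1, 0] * m[2, 2] - m[1, 2] * m[2, 0])
                    + m[0, 2] * (m[1, 0] * m[2, 1] - m[1, 1] * m[2, 0]))
        d = det3(A)
        out = np.empty(3)
        for j in range(3):
            Aj = A.copy()
            Aj[:, j] = b
            out[j] = det3(Aj) / d
        return out
    return np.linalg.solve(A, b)


def coefficient_standard_errors(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Classical OLS standard errors: sqrt(σ̂²·diag((XᵀX)⁻¹))."""
    n, p = X.shape
    beta = normal_equations_fit(X, y)
    resid = y - X @ beta
    sigma2 = float(resid @ resid) / (n - p)
    return np.sqrt(sigma2 * np.diag(np.linalg.inv(X.T @ X)))
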