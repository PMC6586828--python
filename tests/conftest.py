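import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import exclusig as ex

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


def make_cohort(X, groups, proteins=None, ages=None, cohort_label="test"):
    """Assemble a CohortData from a raw array and group labels."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    proteins = list(proteins) if proteins is not None else [f"P{j:03d}" for j in range(p)]
    samples = [f"S{i:04d}" for i in range(n)]
    matrix = pd.DataFrame(X, index=samples, columns=proteins)
    meta = pd.DataFrame(
        {
            "group": list(groups),
            "age": ages if ages is not None else np.full(n, 60.0),
            "cohort": cohort_label,
        },
        index=samples,
    )
    return ex.CohortData(matrix, meta)


def two_group_cohort(X_benign, X_case, case_group="stageIII_IV", **kw):
    X = np.vstack([X_benign, X_case])
    groups = ["benign"] * len(X_benign) + [case_group] * len(X_case)
    return make_cohort(X, groups, **kw)


@pytest.fixture
def separable_cohort():
    """60+60 samples, one perfectly separating protein plus two nulls."""
    rng = np.random.default_rng(42)
    n = 60
    sep = np.r_[rng.uniform(0, 1, n), rng.uniform(2, 3, n)]
    noise = rng.standard_normal((2 * n, 2))
    X = np.column_stack([sep, noise])
    groups = ["benign"] * n + ["stageIII_IV"] * n
    return make_cohort(X, groups, proteins=["SEP", "N1", "N2"])


@pytest.fixture
def small_manifest():
    table = pd.DataFrame(
        {
            "panel": ["a", "a", "b"],
            "lod": [2.5, 0.0, -1.0],
            "dilution_factor": [1.0, 1.0, 45.0],
            "hemolysate_tolerance": [20.0, 50.0, 20.0],
        },
        index=pd.Index(["P000", "P001", "P002"], name="protein_id"),
    )
    return ex.AssayManifest(table)
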