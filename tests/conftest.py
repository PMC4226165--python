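import numpy as np
import pandas as pd
import pytest

from entrobeat import cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full synthetic cohort at study-scale defaults."""
    return cohort.sample_cohort(cohort.CohortConfig(master_seed=2024))


@pytest.fixture(scope="session")
def anova_fixture():
    """Deterministic 8-subject x 2-condition x 3-block within design."""
    rng = np.random.default_rng(42)
    rows = []
    for s in range(8):
        subj_effect = rng.normal(0, 1)
        for ci, c in enumerate(["a", "b"]):
            for b in range(3):
                rows.append({"subj": s, "cond": c, "block": b,
                             "y": subj_effect + 0.5 * ci + 0.2 * b
                                  + rng.normal(0, 1)})
    return pd.DataFrame(rows)
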