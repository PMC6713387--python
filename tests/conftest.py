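import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def make_cohort():
    """Build a long-format cohort table from wide per-subject arrays."""

    def _make(G, Y, D=None, U=None):
        G = np.asarray(G)
        Y = np.atleast_2d(np.asarray(Y, dtype=float))
        n, n_per = Y.shape
        D = np.zeros((n, n_per)) if D is None else np.atleast_2d(np.asarray(D))
        rows = {
            "subject_id": np.repeat(np.arange(n), n_per),
            "genotype": np.repeat(G, n_per),
            "period": np.tile(np.arange(n_per), n),
            "treatment": D.ravel().astype(int),
            "phenotype": Y.ravel(),
        }
        if U is not None:
            rows["confounder"] = np.atleast_2d(np.asarray(U)).ravel()
        return pd.DataFrame(rows)

    return _make
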