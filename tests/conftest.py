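import numpy as np
import pandas as pd
import pytest

import secretoscope as sc


@pytest.fixture
def small_secretome():
    """3 cytokines × 4 samples, one missing entry."""
    df = pd.DataFrame(
        [[10.0, 20.0, 30.0, 40.0],
         [1.0, 2.0, np.nan, 4.0],
         [100.0, 90.0, 80.0, 70.0]],
        index=["IFNg", "IL6", "TNFa"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return sc.SecretomeMatrix(df, detection_floor=0.1)


@pytest.fixture
def paper_like():
    """Default 30×48 four-process scenario with its planted truth."""
    truth = sc.make_truth(seed=7)
    secretome, truth = sc.gen_secretome(truth)
    return secretome, truth


@pytest.fixture
def replicated_study():
    """Study with 4 replicate fragments per animal × arm (192 samples)."""
    return sc.simulate_study(seed=11, replicates=4)


def brute_force_svd(x: np.ndarray):
    """Independent SVD oracle via eigendecomposition of the Gram matrix.

    Returns (singular_values, U, Vt) with components ordered by
    non-increasing singular value; signs arbitrary.
    """
    gram = x.T @ x
    w, v = np.linalg.eigh(gram)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    s = np.sqrt(np.clip(w, 0.0, None))
    keep = min(x.shape)
    s, v = s[:keep], v[:, :keep]
    u = np.zeros((x.shape[0], keep))
    for j in range(keep):
        if s[j] > 1e-12:
            u[:, j] = x @ v[:, j] / s[j]
    return s, u, v.T
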