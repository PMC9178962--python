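import numpy as np
import pandas as pd
import pytest

import msageing as msa


@pytest.fixture(scope="session")
def small_parcellation():
    return msa.Parcellation.of_size(20)


@pytest.fixture(scope="session")
def small_truth(small_parcellation):
    return msa.default_trajectories(small_parcellation, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_parcellation, small_truth):
    """80-subject normative cohort with MS-level data (deterministic)."""
    demo = msa.sample_cohort(msa.CohortSpec(80, (20, 80), seed=11))
    ms = msa.generate_regional_ms(demo, small_truth, seed=12)
    return demo, ms


@pytest.fixture(scope="session")
def feature_cohort(small_parcellation, small_truth):
    """8-subject feature-level cohort (generation is the slow part)."""
    demo = msa.sample_cohort(msa.CohortSpec(8, (20, 80), seed=21))
    table = msa.generate_feature_table(demo, small_truth, seed=22)
    return demo, table


def brute_force_ms(z):
    """Direct per-pair Pearson over feature profiles (independent oracle)."""
    n = z.shape[0]
    out = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            a = z[i] - z[i].mean()
            b = z[j] - z[j].mean()
            out[i, j] = out[j, i] = (a @ b) / np.sqrt((a @ a) * (b @ b))
    return out


def bh_qvalues(p):
    """Hand-rolled Benjamini–Hochberg (oracle for the packaged FDR)."""
    p = np.asarray(p, float)
    m = p.size
    order = np.argsort(p)
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(q, 1.0)
    return out
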