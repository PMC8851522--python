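import numpy as np
import pandas as pd
import pytest

from ifncyto import serology, synth


@pytest.fixture(scope="session")
def toy_sam_data():
    """10-antigen, 6-vs-6 array with one strongly reactive antigen."""
    mfim, truth = synth.generate_array_data(
        6, [f"Ag{i}" for i in range(10)], reactive={"Ag0": 2.0},
        noise_sd=0.4, seed=5)
    clean, flags = serology.preprocess_mfi(mfim)
    return clean, flags, truth


@pytest.fixture(scope="session")
def small_qpcr_cohort():
    ctm, truth = synth.generate_qpcr_cohort(40, 12, n_genes=10, seed=17)
    return ctm, truth


def bh_oracle(p):
    """Literal BH step-up: q_i = min over {j: p_(j) >= p_(i)} of p_(j)*m/rank(j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    q = np.empty(m)
    for i in range(m):
        cands = [p[j] * m / ranks[j] for j in range(m) if p[j] >= p[i]]
        q[i] = min(1.0, min(cands))
    return q
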