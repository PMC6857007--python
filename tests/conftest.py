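import numpy as np
import pandas as pd
import pytest

import aphimeth as am


@pytest.fixture(scope="session")
def small_cfg():
    return am.SimulationConfig(n_autosomal_scaffolds=9, n_x_scaffolds=3,
                               seed=11)


@pytest.fixture(scope="session")
def small_data(small_cfg):
    """One small simulated dataset shared by read-only tests."""
    return am.simulate_dataset(small_cfg)


@pytest.fixture(scope="session")
def bs_groups():
    return {"F": ["F1", "F2", "F3"], "M": ["M1", "M2", "M3"]}


@pytest.fixture(scope="session")
def expr_groups():
    return {am.ASEXUAL_FEMALE: [f"FE{i + 1}" for i in range(6)],
            am.MALE: [f"ME{i + 1}" for i in range(6)]}


def make_site_counts(rows, samples):
    """Build a SiteCounts from (scaffold, pos, strand, context, {sample: (m,u)})
    tuples."""
    recs = []
    for scaffold, pos, strand, context, counts in rows:
        rec = {"scaffold": scaffold, "pos": pos, "strand": strand,
               "context": context}
        for s in samples:
            m, u = counts.get(s, (0, 0))
            rec["m_" + s] = m
            rec["u_" + s] = u
        recs.append(rec)
    return am.SiteCounts(pd.DataFrame(recs), samples)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
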