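import numpy as np
import pytest

from luxomics.pipeline import RunConfig, run_pipeline
from luxomics.simulate import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default truth-labelled cohort (2000 genes, 3 replicates, seed 42)."""
    return generate_cohort(GeneratorConfig())


@pytest.fixture(scope="session")
def default_result(tmp_path_factory):
    """End-to-end pipeline result on the default simulated cohort."""
    out = tmp_path_factory.mktemp("run")
    return run_pipeline(RunConfig(out_dir=out, simulate=GeneratorConfig(), write_artifacts=True))


@pytest.fixture(scope="session")
def null_result(tmp_path_factory):
    """Pipeline result on a cohort with every effect multiplier set to 1."""
    out = tmp_path_factory.mktemp("null")
    cfg = GeneratorConfig(seed=7).null()
    return run_pipeline(RunConfig(out_dir=out, simulate=cfg, write_artifacts=False))


# ---------------------------------------------------------------------------
# independent oracles, shared by unit and acceptance tests

def welch_oracle(a, b):
    """Unequal-variance t-test from first principles (statistic, Satterthwaite
    df, two-tailed p via the t distribution)."""
    from scipy.stats import t as tdist

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t_stat = (a.mean() - b.mean()) / np.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2.0 * tdist.sf(abs(t_stat), df)


def bh_oracle(p):
    """Step-up FDR adjustment by exhaustive tail minimum (O(n^2))."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_i, i in enumerate(order):
        tail = [p[order[j]] / ((j + 1) / m) for j in range(rank_i, m)]
        q[i] = min(1.0, min(tail))
    return q
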