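import numpy as np
import pytest

from cairs.bayesnet import CategoricalBn, Cpt
from cairs.domains import DomainRegistry, ProfileState
from cairs.graphs import Dag
from cairs.panel import PanelDataset, PanelRecord
from cairs.synthetic import GeneratorConfig, sample_scm, simulate_panel


@pytest.fixture(scope="session")
def reg3():
    return DomainRegistry(("a", "b", "c"))


@pytest.fixture(scope="session")
def reg7():
    return DomainRegistry()


@pytest.fixture(scope="session")
def chain_data():
    """n=500 draws from the linear chain X -> Y -> Z (continuous)."""
    rng = np.random.default_rng(5)
    n = 500
    X = np.empty((n, 3))
    X[:, 0] = rng.normal(size=n)
    X[:, 1] = 0.7 * X[:, 0] + 0.8 * rng.normal(size=n)
    X[:, 2] = 0.6 * X[:, 1] + 0.9 * rng.normal(size=n)
    return X


@pytest.fixture(scope="session")
def truth3(reg3):
    cfg = GeneratorConfig(
        registry=reg3, n_lagged_edges=1, n_within_edges=1, seed=3
    )
    return sample_scm(cfg)


@pytest.fixture(scope="session")
def panel3(truth3):
    return simulate_panel(truth3, 400, seed=4)


def make_panel(registry, rows, ids=None):
    """Panel from rows of 2k level codes (baseline then follow-up)."""
    k = len(registry)
    records = []
    for i, row in enumerate(rows):
        records.append(
            PanelRecord(
                str(ids[i] if ids else i),
                ProfileState(registry, tuple(row[:k])),
                ProfileState(registry, tuple(row[k:])),
            )
        )
    return PanelDataset(registry, tuple(records))


@pytest.fixture(scope="session")
def confounded_bn(reg3):
    """Hand-built network where do(b) and conditioning on b differ for c.

    Domains (a, b, c); a's follow-up node is a confounder driving both b
    and c at follow-up.  Conditioning on b=healthy changes belief about the
    confounder and hence about c; do(b=healthy) does not.
    """
    k = 3
    # nodes: a_t0,b_t0,c_t0, a_t1(=3), b_t1(=4), c_t1(=5); edges 3->4, 3->5
    dag = Dag.from_edges(6, [(3, 4), (3, 5)])
    uniform = np.full(3, 1 / 3)
    conf_prior = np.array([0.4, 0.2, 0.4])
    effect = np.array(
        [[0.7, 0.2, 0.1], [0.3, 0.4, 0.3], [0.1, 0.2, 0.7]]
    )  # child level dist per confounder level
    cpts = (
        Cpt(0, (), uniform),
        Cpt(1, (), uniform),
        Cpt(2, (), uniform),
        Cpt(3, (), conf_prior),
        Cpt(4, (3,), effect),
        Cpt(5, (3,), effect),
    )
    return CategoricalBn(reg3, dag, cpts)
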