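import numpy as np
import pytest

from connectrol.core import Connectome, ParcelInfo, Parcellation
from connectrol.synthetic import GeneratorConfig, make_parcellation, \
    simulate_cohort, simulate_connectome


def toy_parcellation(n: int) -> Parcellation:
    """Minimal all-cortical single-hemisphere layout for algebraic tests."""
    return Parcellation([ParcelInfo(i, f"p{i}", "left", "cortical")
                         for i in range(n)])


def toy_connectome(W, subject_id="t") -> Connectome:
    W = np.asarray(W, dtype=float)
    return Connectome(W, toy_parcellation(W.shape[0]), subject_id)


@pytest.fixture(scope="session")
def parc253():
    return make_parcellation()


@pytest.fixture(scope="session")
def control_connectome(parc253):
    cfg = GeneratorConfig()
    rng = np.random.default_rng(12345)
    C, _ = simulate_connectome(cfg, "control", rng, parc253, "ctl")
    return C


# reduced cohort reused across cohort / resection / acceptance tests
REDUCED_COHORT_CONFIG = GeneratorConfig(
    n_controls=10, n_resective=14, n_vns=8,
    n_seizure_free=8, n_vns_responders=4)


@pytest.fixture(scope="session")
def reduced_cohort():
    return simulate_cohort(REDUCED_COHORT_CONFIG, seed=42)


@pytest.fixture(scope="session")
def reduced_cohort_metrics(reduced_cohort):
    from connectrol.controllability import node_metrics
    records, conns, truth = reduced_cohort
    tables = {r.subject_id: node_metrics(conns[r.subject_id])
              for r in records}
    return records, conns, truth, tables
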