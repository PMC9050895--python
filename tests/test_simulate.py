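import numpy as np
import pytest

from connectrol.core import Connectome, ParcelInfo, Parcellation
from connectrol.graph_metrics import density
from connectrol.simulate import (PerturbationConfig, add_random_edges,
                                 boost_edges, edge_pool,
                                 network_fingerprint,
                                 run_fingerprint_experiment)


@pytest.fixture
def mini_brain():
    """4 parcels: left thalamus, left cortex, right cortex x2; edges:
    thalamocortical (left) and one cross-hemisphere edge."""
    parc = Parcellation([
        ParcelInfo(0, "thal-l", "left", "thalamic"),
        ParcelInfo(1, "ctx-l", "left", "cortical"),
        ParcelInfo(2, "ctx-r1", "right", "cortical"),
        ParcelInfo(3, "ctx-r2", "right", "cortical"),
    ])
    W = np.zeros((4, 4))
    W[0, 1] = W[1, 0] = 5.0   # left thalamocortical
    W[1, 2] = W[2, 1] = 2.0   # cross-hemisphere
    W[2, 3] = W[3, 2] = 1.0   # right intra-hemisphere
    return Connectome(W, parc, "mini")


class TestEdgePools:
    def test_thalamocortical_pool(self, mini_brain):
        i, j = edge_pool(mini_brain, "thalamocortical_ipsilateral")
        assert list(zip(i, j)) == [(0, 1)]

    def test_ipsilateral_excludes_cross_hemisphere(self, mini_brain):
        i, j = edge_pool(mini_brain, "ipsilateral_any")
        assert set(zip(i, j)) == {(0, 1), (2, 3)}

    def test_absent_pool(self, mini_brain):
        i, j = edge_pool(mini_brain, "absent_any")
        assert set(zip(i, j)) == {(0, 2), (0, 3), (1, 3)}

    def test_generator_guarantees_boost_pool(self, control_connectome):
        i, _ = edge_pool(control_connectome, "thalamocortical_ipsilateral")
        assert i.size >= 1440


class TestBoostEdges:
    def test_zero_edges_is_identity(self, control_connectome):
        rng = np.random.default_rng(0)
        pool = edge_pool(control_connectome, "thalamocortical_ipsilateral")
        out = boost_edges(control_connectome, pool, 0, rng)
        np.testing.assert_array_equal(out.weights,
                                      control_connectome.weights)

    def test_total_weight_increase_matches_expectation(self,
                                                       control_connectome):
        rng = np.random.default_rng(1)
        pool = edge_pool(control_connectome, "thalamocortical_ipsilateral")
        out = boost_edges(control_connectome, pool, 1440, rng, mu=50, sd=15)
        iu = control_connectome.upper_triangle()
        delta = (out.weights - control_connectome.weights)[iu].sum()
        # E = 1440*50, sd = sqrt(1440)*15
        assert abs(delta - 72_000) < 4 * np.sqrt(1440) * 15

    def test_exactly_n_entries_change(self, control_connectome):
        rng = np.random.default_rng(2)
        pool = edge_pool(control_connectome, "thalamocortical_ipsilateral")
        out = boost_edges(control_connectome, pool, 137, rng)
        iu = control_connectome.upper_triangle()
        changed = (out.weights != control_connectome.weights)[iu].sum()
        assert changed == 137

    def test_seeded_determinism(self, control_connectome):
        pool = edge_pool(control_connectome, "thalamocortical_ipsilateral")
        a = boost_edges(control_connectome, pool, 100,
                        np.random.default_rng(3))
        b = boost_edges(control_connectome, pool, 100,
                        np.random.default_rng(3))
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_pool_too_small(self, mini_brain):
        pool = edge_pool(mini_brain, "thalamocortical_ipsilateral")
        with pytest.raises(ValueError, match="pool too small"):
            boost_edges(mini_brain, pool, 5, np.random.default_rng(0))

    def test_boosts_are_positive_and_symmetric(self, mini_brain):
        pool = edge_pool(mini_brain, "ipsilateral_any")
        out = boost_edges(mini_brain, pool, 2, np.random.default_rng(4))
        assert (out.weights >= mini_brain.weights).all()
        np.testing.assert_array_equal(out.weights, out.weights.T)


class TestAddRandomEdges:
    def test_same_density_is_identity(self, mini_brain):
        out = add_random_edges(mini_brain, density(mini_brain),
                               np.random.default_rng(0))
        np.testing.assert_array_equal(out.weights, mini_brain.weights)

    def test_fill_to_complete(self, mini_brain):
        out = add_random_edges(mini_brain, 1.0, np.random.default_rng(1))
        iu = np.triu_indices(4, 1)
        assert (out.weights[iu] > 0).all()

    def test_existing_edges_untouched(self, control_connectome):
        rng = np.random.default_rng(2)
        out = add_random_edges(control_connectome, 0.71, rng)
        mask = control_connectome.weights > 0
        np.testing.assert_array_equal(out.weights[mask],
                                      control_connectome.weights[mask])

    def test_density_target_reached(self, control_connectome):
        rng = np.random.default_rng(3)
        out = add_random_edges(control_connectome, 0.71, rng)
        assert density(out) == pytest.approx(0.71, abs=0.001)

    def test_target_above_one_rejected(self, mini_brain):
        with pytest.raises(ValueError, match="exceed 1"):
            add_random_edges(mini_brain, 1.2, np.random.default_rng(0))


class TestFingerprint:
    def test_isomorphic_graphs_same_fingerprint(self, control_connectome):
        fp1 = network_fingerprint(control_connectome, seed=1)
        fp2 = network_fingerprint(control_connectome.copy(), seed=1)
        assert fp1 == fp2

    def test_correlations_scale_invariant(self, control_connectome):
        # WD and MC ranks are exactly scale-invariant; AC ranks under the
        # spectral normalisation are invariant only up to the (tiny) change
        # in relative eigenvalue weighting, hence the looser tolerance
        scaled = control_connectome.copy()
        scaled.weights *= 10.0
        fp1 = network_fingerprint(control_connectome, seed=1)
        fp2 = network_fingerprint(scaled, seed=1)
        assert fp1.wd_mc_corr == pytest.approx(fp2.wd_mc_corr, abs=1e-12)
        assert fp1.wd_ac_corr == pytest.approx(fp2.wd_ac_corr, abs=1e-3)
        assert fp1.ac_mc_corr == pytest.approx(fp2.ac_mc_corr, abs=1e-3)

    def test_composition_matches_individual_modules(self, control_connectome):
        from connectrol.controllability import node_metrics
        fp = network_fingerprint(control_connectome, seed=1)
        t = node_metrics(control_connectome)
        assert fp.mean_wd == pytest.approx(t["weighted_degree"].mean())
        assert fp.mean_mc == pytest.approx(
            t["modal_controllability"].mean())
        assert fp.density == pytest.approx(density(control_connectome))


@pytest.fixture(scope="module")
def small_result(parc253):
    from connectrol.synthetic import GeneratorConfig, simulate_connectome
    cfg = GeneratorConfig()
    ss = np.random.SeedSequence(5)
    controls = [simulate_connectome(cfg, "control",
                                    np.random.default_rng(c),
                                    parc253, f"c{k}")[0]
                for k, c in enumerate(ss.spawn(3))]
    pc = PerturbationConfig(n_constrained_models=2, n_null_models=8,
                            louvain_repeats=2)
    return run_fingerprint_experiment(controls, pc, seed=9), controls, pc


class TestExperiment:

    def test_null_zscores_self_normalise(self, small_result):
        res, _, _ = small_result
        nulls = res.zscores[res.zscores.kind == "null"]
        for _, sub in nulls.groupby("control_id"):
            assert abs(sub["mean_ac"].mean()) < 1e-10
            assert sub["mean_ac"].std(ddof=1) == pytest.approx(1.0)

    def test_deterministic_rerun(self, small_result):
        res, controls, pc = small_result
        res2 = run_fingerprint_experiment(controls, pc, seed=9)
        import pandas as pd
        pd.testing.assert_frame_equal(res.fingerprints, res2.fingerprints)
        pd.testing.assert_frame_equal(res.tests, res2.tests)

    def test_one_row_per_metric_per_contrast(self, small_result):
        res, _, _ = small_result
        counts = res.tests.groupby("contrast").size()
        assert (counts == 9).all()
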