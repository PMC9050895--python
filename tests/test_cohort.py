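import numpy as np
import pandas as pd
import pytest

from connectrol.cohort import (build_cohort_table, edge_class_masks,
                               glm_group_compare, mean_matrix_difference,
                               metric_correlations, node_level_flags,
                               subset_sensitivity, zscore_vs_controls)
from connectrol.core import Connectome
from connectrol.synthetic import GeneratorConfig, make_parcellation, \
    simulate_cohort


def rank_table(wd_ranks, ac_ranks, mc_ranks):
    return pd.DataFrame({"wd_rank": wd_ranks, "ac_rank": ac_ranks,
                         "mc_rank": mc_ranks})


class TestMetricCorrelations:
    def test_identical_ranks_give_plus_one(self):
        t = rank_table([1, 2, 3], [1, 2, 3], [1, 2, 3])
        c = metric_correlations(t)
        assert c.wd_ac == pytest.approx(1.0)

    def test_reversed_ranks_give_minus_one(self):
        t = rank_table([1, 2, 3], [3, 2, 1], [1, 2, 3])
        assert metric_correlations(t).wd_ac == pytest.approx(-1.0)

    def test_constant_column_rejected(self):
        t = rank_table([2, 2, 2], [1, 2, 3], [1, 2, 3])
        with pytest.raises(ValueError, match="undefined correlation"):
            metric_correlations(t)

    def test_control_ac_mc_strongly_negative(self, reduced_cohort_metrics):
        records, _, _, tables = reduced_cohort_metrics
        controls = [r.subject_id for r in records if r.group == "control"]
        corrs = [metric_correlations(tables[c]).ac_mc for c in controls]
        assert np.mean(corrs) < -0.5

    def test_invariant_to_monotone_transform(self, reduced_cohort_metrics):
        _, _, _, tables = reduced_cohort_metrics
        t = next(iter(tables.values())).copy()
        c1 = metric_correlations(t)
        from scipy.stats import rankdata
        t2 = t.copy()
        t2["wd_rank"] = rankdata(np.log(t["weighted_degree"]))
        c2 = metric_correlations(t2)
        assert c1.wd_ac == pytest.approx(c2.wd_ac, abs=1e-12)


class TestZScores:
    def test_controls_self_normalise(self, reduced_cohort_metrics):
        records, _, _, tables = reduced_cohort_metrics
        controls = [r.subject_id for r in records if r.group == "control"]
        Z = zscore_vs_controls(tables, controls)
        sub = Z.data[Z.data.subject_id.isin(controls)]
        grouped = sub.groupby("parcel_id")[["wd_z", "ac_z", "mc_z"]]
        assert grouped.mean().abs().to_numpy().max() < 1e-12
        assert np.abs(grouped.std(ddof=1).to_numpy() - 1).max() < 1e-12

    def test_hand_computed_z(self):
        def table(ranks):
            return pd.DataFrame({"wd_rank": ranks, "ac_rank": ranks,
                                 "mc_rank": ranks})
        tables = {"c1": table([1, 9]), "c2": table([2, 9]),
                  "c3": table([3, 8]), "p": table([4, 7])}
        Z = zscore_vs_controls(tables, ["c1", "c2", "c3"])
        p = Z.subject("p")
        # parcel 0: control ranks 1,2,3 -> mean 2, sd 1; patient 4 -> z = 2
        assert p.loc[0, "wd_z"] == pytest.approx(2.0)

    def test_needs_two_controls(self, reduced_cohort_metrics):
        _, _, _, tables = reduced_cohort_metrics
        with pytest.raises(ValueError, match="2 controls"):
            zscore_vs_controls(tables, list(tables)[:1])

    def test_zero_control_sd_names_parcel(self):
        def table(ranks):
            return pd.DataFrame({"wd_rank": ranks, "ac_rank": ranks,
                                 "mc_rank": ranks})
        tables = {"c1": table([1, 2]), "c2": table([1, 2])}
        with pytest.raises(ValueError, match="parcel 0"):
            zscore_vs_controls(tables, ["c1", "c2"])


class TestGLM:
    @staticmethod
    def simulate_table(rng, delta=0.0, n=30):
        group = np.repeat(["control", "patient"], n)
        age = rng.uniform(5, 18, 2 * n)
        sex = rng.choice(["M", "F"], 2 * n)
        y = 10 + 0.2 * age + (group == "patient") * delta \
            + rng.normal(0, 1.0, 2 * n)
        return pd.DataFrame({"group": group, "age": age, "sex": sex,
                             "y": y})

    def test_identical_groups_give_null_result(self):
        rng = np.random.default_rng(0)
        t = self.simulate_table(rng, delta=0.0)
        t["y"] = np.tile(t["y"][:30], 2)
        t["age"] = np.tile(t["age"][:30], 2)
        t["sex"] = np.tile(t["sex"][:30], 2)
        res = glm_group_compare(t, "y", ["age", "sex"], "gaussian")[0]
        assert res.mean_difference == pytest.approx(0.0, abs=1e-10)
        assert res.p_unadjusted > 0.99

    def test_gaussian_recovers_planted_shift(self):
        rng = np.random.default_rng(1)
        t = self.simulate_table(rng, delta=2.0, n=60)
        res = glm_group_compare(t, "y", ["age", "sex"], "gaussian")[0]
        se = abs(res.mean_difference) / max(abs(res.cohen_d), 1e-9) \
            / np.sqrt(60 / 2)
        assert abs(abs(res.mean_difference) - 2.0) < 3 * max(se, 0.3)
        assert res.p_unadjusted < 1e-4

    def test_gamma_rejects_nonpositive_response(self):
        rng = np.random.default_rng(2)
        t = self.simulate_table(rng)
        t.loc[0, "y"] = 0.0
        with pytest.raises(ValueError, match="strictly positive"):
            glm_group_compare(t, "y", ["age", "sex"], "gamma")

    def test_gamma_log_link_runs(self):
        rng = np.random.default_rng(3)
        t = self.simulate_table(rng, delta=3.0)
        res = glm_group_compare(t, "y", ["age", "sex"], "gamma")[0]
        assert res.p_unadjusted < 0.01
        assert res.cohen_d > 0

    def test_emm_confidence_coverage(self):
        """Planted group effects are recovered by the covariate-adjusted
        contrasts in most replicates (interval coverage check)."""
        rng = np.random.default_rng(4)
        hits = 0
        n_rep = 100
        for _ in range(n_rep):
            t = self.simulate_table(rng, delta=1.5, n=25)
            res = glm_group_compare(t, "y", ["age", "sex"], "gaussian")[0]
            # Wald 95% CI on the contrast, from d and the residual sd
            resid_sd = abs(res.mean_difference) / max(res.cohen_d, 1e-12)
            se = resid_sd * np.sqrt(2 / 25)
            lo = abs(res.mean_difference) - 1.96 * se
            hi = abs(res.mean_difference) + 1.96 * se
            hits += lo <= 1.5 <= hi
        assert hits / n_rep >= 0.90


class TestFlagsAndDifferences:
    def test_no_flags_when_z_zero(self, reduced_cohort_metrics):
        records, _, _, tables = reduced_cohort_metrics
        controls = [r.subject_id for r in records if r.group == "control"]
        Z = zscore_vs_controls(tables, controls)
        flags = node_level_flags(Z, controls, threshold=3.1)
        for dirs in flags.values():
            assert not dirs["above"] and not dirs["below"]

    def test_planted_extreme_parcel_flagged(self, reduced_cohort_metrics):
        records, _, _, tables = reduced_cohort_metrics
        controls = [r.subject_id for r in records if r.group == "control"]
        Z = zscore_vs_controls(tables, controls)
        data = Z.data.copy()
        data.loc[(data.subject_id == controls[0]) & (data.parcel_id == 5),
                 "mc_z"] = -400.0  # forces the group mean below -3.1
        Z2 = type(Z)(data, Z.control_ids, Z.control_mean, Z.control_sd)
        flags = node_level_flags(Z2, controls, threshold=3.1)
        assert 5 in flags["modal_controllability"]["below"]

    def test_thalamic_parcels_flagged_in_patients(self,
                                                  reduced_cohort_metrics):
        records, conns, _, tables = reduced_cohort_metrics
        controls = [r.subject_id for r in records if r.group == "control"]
        patients = [r.subject_id for r in records if r.group != "control"]
        Z = zscore_vs_controls(tables, controls)
        flags = node_level_flags(Z, patients, threshold=3.1)
        parc = conns[controls[0]].parcellation
        thal = set(np.nonzero(parc.thalamic)[0])
        assert flags["weighted_degree"]["above"] & thal
        assert flags["modal_controllability"]["below"] & thal

    def test_identical_groups_no_difference_counts(self, parc253,
                                                   control_connectome):
        summ = mean_matrix_difference([control_connectome],
                                      [control_connectome])
        assert all(v == 0 for v in summ.counts.values())

    def test_planted_thalamocortical_increase_counted(self, parc253,
                                                      control_connectome):
        masks = edge_class_masks(parc253)
        i, j = np.nonzero(masks["thalamocortical_ipsilateral"]
                          & (control_connectome.weights > 0))
        other = control_connectome.copy()
        other.weights[i[:10], j[:10]] += 50.0
        other.weights[j[:10], i[:10]] += 50.0
        summ = mean_matrix_difference([control_connectome], [other],
                                      low_weight_cutoff=100.0)
        assert summ.counts["thalamocortical_ipsilateral"] == 10
        assert summ.counts["other_ipsilateral"] == 0

    def test_majority_increase_is_thalamocortical_with_boost_only(self):
        """With the thalamocortical boost as the only planted group
        difference, most low-weight mean increases are thalamocortical."""
        cfg = GeneratorConfig(
            n_controls=6, n_resective=8, n_vns=0, n_seizure_free=0,
            n_vns_responders=0,
            target_density_patients=GeneratorConfig.target_density_controls)
        records, conns, _ = simulate_cohort(cfg, seed=7)
        controls = [conns[r.subject_id] for r in records
                    if r.group == "control"]
        patients = [conns[r.subject_id] for r in records
                    if r.group == "resective"]
        summ = mean_matrix_difference(controls, patients)
        assert summ.majority_class == "thalamocortical_ipsilateral"


class TestSubset:
    def test_min_age_zero_is_identity(self):
        t = pd.DataFrame({"age": [5.0, 13.0, 20.0], "x": [1, 2, 3]})
        pd.testing.assert_frame_equal(subset_sensitivity(t, 0), t)

    def test_threshold_filters(self):
        t = pd.DataFrame({"age": [5.0, 13.0, 20.0]})
        assert len(subset_sensitivity(t, 12)) == 2

    def test_empty_subset_rejected(self):
        t = pd.DataFrame({"age": [5.0]})
        with pytest.raises(ValueError, match="empty subset"):
            subset_sensitivity(t, 12)
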