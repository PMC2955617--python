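"""Ground-truth generators: determinism, planted structure, noise model."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import kinoscope as ks
from kinoscope.errors import ParameterError


class TestGenerateAnnotation:
    def test_study_scale_annotation_structure(self):
        ann, kinases, pathways, _ = ks.generate_annotation(
            1024, 120, 8, multi_map_rate=0.2, cell_cycle_fraction=0.27, seed=1
        )
        assert len(kinases) == 120
        n_cc = sum("cell_cycle" in k.categories for k in kinases)
        assert n_cc == round(0.27 * 120)
        per_kinase = {}
        for ks_set in ann.mapping.values():
            for k in ks_set:
                per_kinase[k] = per_kinase.get(k, 0) + 1
        assert all(per_kinase[k.kinase_id] >= 1 for k in kinases)

    def test_zero_multi_map_gives_single_memberships(self):
        ann, _, _, _ = ks.generate_annotation(50, 10, 4, 0.0, 0.0, seed=3)
        assert all(len(v) == 1 for v in ann.mapping.values())

    def test_same_seed_reproduces_tables(self):
        a1 = ks.generate_annotation(100, 10, 5, 0.3, 0.2, seed=9)
        a2 = ks.generate_annotation(100, 10, 5, 0.3, 0.2, seed=9)
        assert a1[0].mapping == a2[0].mapping
        assert a1[1] == a2[1]
        assert a1[2].members == a2[2].members

    def test_infeasible_assignment_rejected(self):
        with pytest.raises(ParameterError, match="exceed"):
            ks.generate_annotation(20, 10, 8, 0.0, 0.0, seed=0)

    def test_planted_pathway_covers_requested_kinases(self):
        planted = frozenset({"KIN001", "KIN005"})
        _, _, pathways, pw_id = ks.generate_annotation(
            50, 10, 4, 0.0, 0.0, seed=1, planted_pathway_kinases=planted
        )
        assert pathways.members[pw_id] == planted


class TestSimulateArrays:
    def test_fixed_seed_is_bit_identical(self, small_cohort):
        truth = small_cohort["truth"]
        s1 = ks.simulate_arrays(small_cohort["layout"], small_cohort["annotation"], truth, 2)
        s2 = ks.simulate_arrays(small_cohort["layout"], small_cohort["annotation"], truth, 2)
        for a, b in zip(s1, s2):
            pd.testing.assert_frame_equal(a.spots, b.spots)
            assert a.total_hits == b.total_hits

    def test_intensities_nonnegative_and_hits_sum(self, small_cohort):
        for scan in small_cohort["scans"]:
            assert (scan.spots["intensity"] >= 0).all()
            assert scan.total_hits == pytest.approx(scan.spots["intensity"].sum())

    def test_boosted_substrates_outshine_background_every_sample(self, small_cohort):
        truth = ks.SyntheticTruth(
            active_kinases=small_cohort["truth"].active_kinases,
            boost=3.0, replicate_cv=0.1, dropout_rate=0.0, seed=5,
        )
        ann = small_cohort["annotation"]
        scans = ks.simulate_arrays(small_cohort["layout"], ann, truth, 4)
        active = {s for s, kset in ann.mapping.items()
                  if kset & truth.active_kinases}
        for scan in scans:
            sub = scan.substrate_spots()
            is_active = sub["substrate_id"].isin(active)
            assert sub.loc[is_active, "intensity"].mean() > sub.loc[~is_active, "intensity"].mean()

    def test_null_boost_makes_groups_exchangeable(self, small_cohort):
        """boost=1: active/inactive mean comparison should be significant at
        roughly the nominal rate over seeds, not systematically."""
        ann = small_cohort["annotation"]
        active_kin = small_cohort["truth"].active_kinases
        active = {s for s, kset in ann.mapping.items() if kset & active_kin}
        n_sig = 0
        n_seeds = 100
        for seed in range(n_seeds):
            truth = ks.SyntheticTruth(active_kinases=active_kin, boost=1.0,
                                      dropout_rate=0.0, seed=seed)
            (scan,) = ks.simulate_arrays(small_cohort["layout"], ann, truth, 1)
            sub = scan.substrate_spots()
            # compare per-substrate means: replicates of one substrate share a
            # base draw, so spot-level tests would not be independent
            per_sub = sub.groupby("substrate_id")["intensity"].mean()
            mask = per_sub.index.isin(active)
            _, p = stats.ttest_ind(per_sub[mask], per_sub[~mask])
            n_sig += p < 0.05
        # Binomial(100, 0.05): beyond 13 rejections is a ~3.5-sigma excursion
        assert n_sig <= 13

    def test_increasing_boost_never_worsens_planted_rank(self, small_cohort):
        """Monotonicity of planted recovery in the boost factor (over seeds)."""
        ann = small_cohort["annotation"]
        layout = small_cohort["layout"]
        planted = small_cohort["truth"].active_kinases

        def mean_worst_rank(boost):
            worst = []
            for seed in range(8):
                truth = ks.SyntheticTruth(active_kinases=planted, boost=boost,
                                          background_log_mean=7.5, seed=seed)
                scans = ks.simulate_arrays(layout, ann, truth, 3)
                profiles, _ = ks.preprocess_cohort(scans, layout)
                acts = ks.infer_kinase_activity(profiles, ann, top_n=60)
                ranks = {a.kinase_id: a.rank for a in acts}
                worst.append(max(ranks.get(k, len(ann.kinase_ids) + 1) for k in planted))
            return np.mean(worst)

        assert mean_worst_rank(3.0) <= mean_worst_rank(1.5)

    def test_parameter_validation(self, small_cohort):
        with pytest.raises(ParameterError):
            ks.simulate_arrays(small_cohort["layout"], small_cohort["annotation"],
                               small_cohort["truth"], 0)
        bad = ks.SyntheticTruth(active_kinases=frozenset({"NOPE"}), seed=0)
        with pytest.raises(ParameterError, match="NOPE"):
            ks.simulate_arrays(small_cohort["layout"], small_cohort["annotation"], bad, 1)
        with pytest.raises(ParameterError):
            ks.SyntheticTruth(active_kinases=frozenset(), boost=0.5)


class TestSimulateViability:
    def test_noiseless_midpoint_is_exact(self):
        truth = ks.ViabilityTruth(lower=0.0, upper=1.0, ec50=100.0, hill=1.0,
                                  noise_sd=0.0, seed=0)
        plate = ks.simulate_viability([50.0, 100.0, 200.0, 400.0], truth, n_replicates=2)
        dr = ks.normalize_plate(plate)
        assert dr.mean_viability()[100.0] == pytest.approx(0.5, abs=1e-12)

    def test_viability_floor_matches_lower_asymptote(self):
        truth = ks.ViabilityTruth(lower=0.60, upper=1.0, ec50=100.0, hill=1.5,
                                  noise_sd=0.0, seed=0)
        plate = ks.simulate_viability(ks.DASATINIB_DOSES_NM, truth, n_replicates=4)
        dr = ks.normalize_plate(plate)
        assert dr.mean_viability().min() == pytest.approx(0.60, abs=0.02)

    def test_quadruplicate_grid_shape(self):
        truth = ks.ViabilityTruth(lower=0.2, upper=1.0, ec50=100.0, hill=1.0, seed=1)
        plate = ks.simulate_viability(ks.DASATINIB_DOSES_NM, truth, n_replicates=4)
        treated = plate[plate["role"] == "treated"]
        assert (treated.groupby("dose").size() == 4).all()
        assert set(treated["dose"]) == set(ks.DASATINIB_DOSES_NM)

    def test_nonpositive_dose_rejected(self):
        truth = ks.ViabilityTruth(lower=0.0, upper=1.0, ec50=1.0, hill=1.0, seed=0)
        with pytest.raises(ParameterError):
            ks.simulate_viability([0.0, 1.0, 2.0, 4.0], truth)


class TestPaperCohort:
    def test_cohort_mirrors_study_design(self):
        c = ks.paper_cohort(seed=3)
        assert len(c.tumor_scans) == 6
        assert len(c.control_scans) == 2
        assert len(c.truth_tumor.active_kinases) == 6
        assert c.truth_tumor.active_kinases.isdisjoint(c.truth_control.active_kinases)
        assert c.pathways.members[c.planted_pathway_id] == c.truth_tumor.active_kinases
        assert set(c.viability_plates) == {"drug_a", "drug_b", "combo"}

    def test_cohort_is_deterministic(self):
        c1, c2 = ks.paper_cohort(seed=5), ks.paper_cohort(seed=5)
        assert c1.truth_tumor == c2.truth_tumor
        pd.testing.assert_frame_equal(c1.tumor_scans[0].spots, c2.tumor_scans[0].spots)
        pd.testing.assert_frame_equal(c1.viability_plates["drug_a"],
                                      c2.viability_plates["drug_a"])
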