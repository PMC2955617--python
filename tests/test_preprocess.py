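"""QC stages, background correction, summarization, quantile normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kinoscope as ks
from kinoscope.errors import ParameterError, ValidationError
from kinoscope.preprocess import quantile_normalize

from conftest import make_scan


class TestAcquisitionQC:
    @pytest.mark.parametrize(
        "hits,expected",
        [(1_200_000, True), (1_000_000, True), (999_999, False)],
    )
    def test_inclusive_million_hit_threshold(self, hits, expected):
        scan = make_scan({"S0001": [hits]})
        scan.total_hits = float(hits)
        assert ks.acquisition_qc(scan).passed is expected

    def test_failure_reports_reason(self):
        scan = make_scan({"S0001": [1.0]})
        scan.total_hits = 10.0
        res = ks.acquisition_qc(scan)
        assert not res.passed and "below minimum" in res.reason


class TestReplicateQC:
    def test_tight_triplicate_untouched(self):
        scan = ks.replicate_qc(make_scan({"A": [100, 102, 98]}))
        assert not scan.spots["flagged"].any()
        assert not scan.qc.loc["A", "dropout"]
        assert scan.qc.loc["A", "cv"] == pytest.approx(0.01633, abs=1e-4)

    def test_gross_outlier_ejected_substrate_retained(self):
        scan = ks.replicate_qc(make_scan({"A": [100, 100, 10000]}))
        flagged = scan.spots[scan.spots["flagged"]]
        assert len(flagged) == 1
        assert flagged["intensity"].iloc[0] == 10000
        assert scan.qc.loc["A", "n_surviving"] == 2
        assert not scan.qc.loc["A", "dropout"]

    def test_single_replicate_is_dropout_not_error(self):
        scan = ks.replicate_qc(make_scan({"A": [50.0]}), min_replicates=2)
        assert scan.qc.loc["A", "dropout"]

    def test_only_one_ejection_per_substrate(self):
        # still discordant after one ejection: no second pass
        scan = ks.replicate_qc(make_scan({"A": [1, 1000, 100000]}))
        assert scan.spots["flagged"].sum() == 1


class TestBackgroundCorrect:
    def test_subtracts_negative_control_mean(self):
        scan = make_scan({"A": [120.0]}, negatives=[40.0, 60.0])
        out = ks.background_correct(scan)
        assert out.substrate_spots()["intensity"].iloc[0] == pytest.approx(70.0)

    def test_clips_at_zero(self):
        scan = make_scan({"A": [30.0]}, negatives=[50.0])
        out = ks.background_correct(scan)
        assert out.substrate_spots()["intensity"].iloc[0] == 0.0

    def test_zero_background_is_identity(self):
        scan = make_scan({"A": [30.0]}, negatives=[0.0])
        out = ks.background_correct(scan)
        assert out.substrate_spots()["intensity"].iloc[0] == 30.0

    def test_missing_negatives_instructs_to_disable(self):
        with pytest.raises(ValidationError, match="disable background"):
            ks.background_correct(make_scan({"A": [30.0]}))


class TestSummarizeTriplicates:
    @pytest.mark.parametrize(
        "reps,expected",
        [([3, 5, 100], 5.0), ([7, 7, 7], 7.0), ([4, 6], 5.0)],
    )
    def test_median_of_unflagged(self, reps, expected):
        prof = ks.summarize_triplicates(make_scan({"A": reps}), min_replicates=2)
        assert prof.values["A"] == pytest.approx(expected)

    def test_dropout_substrates_omitted_with_flag(self):
        scan = ks.replicate_qc(make_scan({"A": [1.0], "B": [5, 6, 7]}))
        prof = ks.summarize_triplicates(scan)
        assert "A" not in prof.values.index
        assert "A" in prof.qc["dropout"]
        assert prof.values["B"] == 6.0


def qn_oracle(x):
    """Independent brute force: sort columns, row-mean, map back by rank,
    tied entries averaged."""
    s = np.sort(x, axis=0)
    ref = s.mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        order = np.argsort(x[:, j], kind="mergesort")
        col = np.empty(x.shape[0])
        col[order] = ref
        for val in np.unique(x[:, j]):
            m = x[:, j] == val
            if m.sum() > 1:
                col[m] = col[m].mean()
        out[:, j] = col
    return out


class TestQuantileNormalize:
    def test_two_array_example(self):
        out = quantile_normalize([[1, 2, 3], [2, 4, 6]])
        np.testing.assert_allclose(out.to_numpy().T, [[1.5, 3, 4.5], [1.5, 3, 4.5]])

    def test_identical_arrays_fixed_point(self):
        out = quantile_normalize([[5, 1, 9], [5, 1, 9]])
        np.testing.assert_allclose(out.to_numpy().T, [[5, 1, 9], [5, 1, 9]])

    def test_tied_entries_share_normalized_value(self):
        out = quantile_normalize([[1, 1, 2], [3, 5, 7]]).to_numpy().T
        assert out[0][0] == out[0][1]
        np.testing.assert_allclose(out[0], qn_oracle(np.array([[1, 3], [1, 5], [2, 7]], float))[:, 0])

    def test_matches_bruteforce_oracle_on_random_matrices(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            x = rng.lognormal(0, 1, (int(rng.integers(2, 51)), int(rng.integers(2, 9))))
            got = quantile_normalize(pd.DataFrame(x)).to_numpy()
            np.testing.assert_allclose(got, qn_oracle(x), atol=1e-12, rtol=0)

    def test_sorted_vectors_identical_across_arrays(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(0, 1, (40, 5))
        out = quantile_normalize(pd.DataFrame(x)).to_numpy()
        for j in range(1, 5):
            np.testing.assert_allclose(np.sort(out[:, j]), np.sort(out[:, 0]), atol=1e-9)

    def test_preserves_within_array_rank_order(self):
        rng = np.random.default_rng(3)
        x = rng.normal(10, 2, (30, 4))
        out = quantile_normalize(pd.DataFrame(x)).to_numpy()
        for j in range(4):
            assert (np.argsort(out[:, j]) == np.argsort(x[:, j])).all()

    def test_single_array_rejected(self):
        with pytest.raises(ParameterError):
            quantile_normalize([[1, 2, 3]])

    def test_missing_values_imputed_and_flagged(self):
        x = pd.DataFrame(
            [[1.0, 2.0], [2.0, np.nan], [3.0, 6.0], [4.0, 8.0]],
            columns=["a", "b"],
        )
        out, imputed = quantile_normalize(x, return_imputed=True)
        assert imputed.loc[1, "b"]
        assert imputed.to_numpy().sum() == 1
        assert np.isfinite(out.to_numpy()).all()
        # imputed value interior to the reference distribution
        assert out.loc[1, "b"] > out.loc[0, "b"]
        assert out.loc[1, "b"] < out.loc[3, "b"]

    @settings(max_examples=25, deadline=None)
    @given(st.integers(3, 25), st.integers(2, 6), st.integers(0, 10_000))
    def test_property_sorted_vectors_agree(self, n, m, seed):
        rng = np.random.default_rng(seed)
        x = rng.lognormal(0, 1, (n, m))
        out = quantile_normalize(pd.DataFrame(x)).to_numpy()
        ref = np.sort(out[:, 0])
        for j in range(1, m):
            np.testing.assert_allclose(np.sort(out[:, j]), ref, atol=1e-9)


class TestCohortDriver:
    def test_failing_array_excluded_with_reason(self, small_cohort):
        scans = list(small_cohort["scans"])
        starved = make_scan({f"S{i + 1:04d}": [1.0, 1.0, 1.0] for i in range(200)},
                            sample_id="dud", negatives=[0.5])
        profiles, report = ks.preprocess_cohort(scans + [starved])
        assert "dud" in report["excluded"]
        assert report["n_passing"] == len(scans)
        assert {p.sample_id for p in profiles} == {s.sample_id for s in scans}

    def test_spotlevel_normalization_order_supported(self, small_cohort):
        profiles, _ = ks.preprocess_cohort(
            small_cohort["scans"], small_cohort["layout"],
            normalize_before_summarize=True,
        )
        assert len(profiles) == len(small_cohort["scans"])
        assert all((p.values >= 0).all() for p in profiles)
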