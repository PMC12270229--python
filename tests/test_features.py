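"""Epoch aggregation, imputation, windowing and scaling."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from iwsrisk import features as feat
from iwsrisk.schema import DEFAULT_SCHEMA, DRUGS, FEATURE_INDEX, N_FEATURES, VITALS
from iwsrisk.timelines import PatientTimeline


class TestVitalAggregation:
    @pytest.mark.parametrize(
        "measurements,expected",
        [
            ([(1.0, 120), (2.5, 140), (3.9, 130)], (120, 140, 20, 130, 3)),
            ([(0.2, 98.6)], (98.6, 98.6, 0.0, 98.6, 1)),
        ],
    )
    def test_summary_statistics(self, measurements, expected):
        s = feat.aggregate_vital_epoch(measurements)
        assert (s.vmin, s.vmax, s.max_delta, s.mean, s.count) == pytest.approx(expected)

    def test_empty_epoch_is_missing_sentinel(self):
        s = feat.aggregate_vital_epoch([])
        assert s.count == 0 and s.is_missing
        assert all(math.isnan(v) for v in (s.vmin, s.vmax, s.max_delta, s.mean))


class TestMedicationAggregation:
    def test_no_admins_gives_zero_rate(self):
        m = feat.aggregate_medication_epoch([], weight_kg=10, epoch_index=1)
        assert m.current_avg_dose_per_kg == 0.0
        assert m.cumulative_dose_per_kg == 0.0

    def test_epoch_rate_is_dose_over_weight_hours(self):
        admins = [(0.5, 2.0), (3.0, 2.0)]
        m = feat.aggregate_medication_epoch(admins, weight_kg=10, epoch_index=1)
        assert m.current_avg_dose_per_kg == pytest.approx(4 / (10 * 4))

    def test_cumulative_dose_includes_prior_epochs(self):
        # 8 mg across epochs 1-2, then 4 mg in epoch 3, weight 10 kg
        admins = [(1.0, 5.0), (6.0, 3.0), (9.0, 4.0)]
        m = feat.aggregate_medication_epoch(admins, weight_kg=10, epoch_index=3)
        assert m.cumulative_dose_per_kg == pytest.approx(1.2)
        assert m.previous_epoch_dose_per_kg == pytest.approx(0.3)

    def test_duration_counts_exposed_epochs(self):
        admins = [(1.0, 1.0), (2.0, 1.0), (13.0, 1.0)]  # epochs 1 and 4
        m = feat.aggregate_medication_epoch(admins, weight_kg=5, epoch_index=5)
        assert m.cumulative_duration_h == pytest.approx(8.0)

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            feat.aggregate_medication_epoch([(1.0, -2.0)], weight_kg=10, epoch_index=1)

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 5)), max_size=30))
    def test_cumulative_fields_nondecreasing(self, admins):
        admins = sorted(admins)
        prev_cum, prev_dur = 0.0, 0.0
        for e in range(1, 27):
            m = feat.aggregate_medication_epoch(admins, weight_kg=7.5, epoch_index=e)
            assert m.cumulative_dose_per_kg >= prev_cum - 1e-12
            assert m.cumulative_duration_h >= prev_dur
            prev_cum, prev_dur = m.cumulative_dose_per_kg, m.cumulative_duration_h


class TestImputation:
    def _summary(self, value):
        return feat.VitalSummary(value, value, 0.0, value, 1)

    def test_carry_forward_from_previous_epoch(self):
        series = [self._summary(110), feat.VitalSummary()]
        out = feat.impute_vitals(series, patient_mean=100.0)
        assert out[1].mean == 110 and out[1].max_delta == 0.0

    def test_patient_mean_when_carry_forward_unavailable(self):
        series = [feat.VitalSummary(), feat.VitalSummary(), self._summary(120)]
        out = feat.impute_vitals(series, patient_mean=100.0)
        assert out[0].mean == 100.0
        # second epoch: previous epoch was itself missing -> patient mean
        assert out[1].mean == 100.0

    def test_no_missing_is_identity(self):
        series = [self._summary(v) for v in (1.0, 2.0, 3.0)]
        out = feat.impute_vitals(series, patient_mean=9.9)
        assert [s.mean for s in out] == [1.0, 2.0, 3.0]

    def test_cohort_fallback_for_patient_without_measurements(self):
        series = [feat.VitalSummary(), feat.VitalSummary()]
        out = feat.impute_vitals(series, patient_mean=None, cohort_mean=37.0)
        assert all(s.mean == 37.0 for s in out)

    @given(st.lists(st.booleans(), min_size=1, max_size=40))
    def test_no_sentinels_remain(self, missing_mask):
        series = [
            feat.VitalSummary() if m else self._summary(50.0 + i)
            for i, m in enumerate(missing_mask)
        ]
        out = feat.impute_vitals(series, patient_mean=55.0)
        assert not any(s.is_missing for s in out)


class TestWindows:
    def _vectors(self, k):
        return np.arange(k * N_FEATURES, dtype=float).reshape(k, N_FEATURES)

    @pytest.mark.parametrize("k,expected", [(7, 1), (6, 0), (10, 4), (0, 0)])
    def test_window_count_formula(self, k, expected):
        ws = feat.build_windows("p", self._vectors(k), np.zeros(k, int))
        assert len(ws) == expected
        assert [w.window_start_epoch_index for w in ws] == list(range(1, expected + 1))

    def test_window_count_exhaustive(self):
        for k in range(21):
            ws = feat.build_windows("p", self._vectors(k), np.zeros(k, int))
            assert len(ws) == max(0, k - 6)

    def test_label_comes_from_epoch_after_window(self):
        labels = np.zeros(10, int)
        labels[6] = 1  # epoch 7 positive
        ws = feat.build_windows("p", self._vectors(10), labels)
        assert [w.label for w in ws] == [1, 0, 0, 0]

    def test_exclude_mode_drops_unassessed_prediction_epochs(self):
        labels = np.zeros(8, int)
        assessed = np.ones(8, bool)
        assessed[7] = False
        ws = feat.build_windows(
            "p", self._vectors(8), labels, assessed, label_missing_wat1="exclude"
        )
        assert len(ws) == 1  # only the window predicting epoch 7 survives

    def test_label_against_brute_force_wat1_scan(self):
        """Window label = 1 iff a WAT-1 >= 3 falls in the prediction epoch."""
        rng = np.random.default_rng(42)
        tl = PatientTimeline("p", weight_kg=10, age_months=12, mech_vent_duration_h=100)
        k = 12
        tl.wat1_scores = [
            (float(rng.uniform(0, k * 4)), int(rng.integers(0, 13))) for _ in range(60)
        ]
        labels, _ = feat.epoch_labels(tl, k)
        for e in range(1, k + 1):  # brute-force scan oracle
            expected = any(
                (e - 1) * 4.0 <= t < e * 4.0 and s >= 3 for t, s in tl.wat1_scores
            )
            assert labels[e - 1] == int(expected)


class TestScaling:
    def test_midpoint_and_clipping(self):
        stats = feat.fit_minmax(np.array([[2.0], [4.0], [6.0]]))
        assert feat.apply_minmax(np.array([4.0]), stats) == pytest.approx([0.5])
        assert feat.apply_minmax(np.array([8.0]), stats) == pytest.approx([1.0])
        assert feat.apply_minmax(np.array([0.0]), stats) == pytest.approx([0.0])

    def test_constant_feature_maps_to_zero(self):
        stats = feat.fit_minmax(np.full((5, 1), 3.3))
        assert feat.apply_minmax(np.array([3.3]), stats) == pytest.approx([0.0])
        assert feat.apply_minmax(np.array([99.0]), stats) == pytest.approx([0.0])

    def test_unfitted_stats_rejected(self):
        stats = feat.ScalingStats(np.zeros(1), np.ones(1), fitted=False)
        with pytest.raises(ValueError):
            feat.apply_minmax(np.array([0.5]), stats)

    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_recovers_training_values(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 5)) * rng.uniform(0.5, 10, size=5)
        stats = feat.fit_minmax(X)
        back = feat.inverse_minmax(feat.apply_minmax(X, stats), stats)
        assert np.allclose(back, X, atol=1e-12)

    def test_json_round_trip(self, tmp_path):
        stats = feat.fit_minmax(np.random.default_rng(0).random((10, 4)))
        stats.to_json(tmp_path / "s.json")
        loaded = feat.ScalingStats.from_json(tmp_path / "s.json")
        assert np.allclose(loaded.train_min, stats.train_min)
        assert np.allclose(loaded.train_max, stats.train_max)


class TestFeatureVector:
    def _inputs(self):
        vit = {v: feat.VitalSummary(1, 2, 1, 1.5, 3) for v in VITALS}
        med = {d: feat.MedSummary() for d in DRUGS}
        return vit, med

    def test_vector_has_66_features_in_schema_order(self):
        vit, med = self._inputs()
        vec = feat.assemble_feature_vector(vit, med, 24.0, 2, 6, 120.0)
        assert vec.shape == (66,)
        assert vec[FEATURE_INDEX["previous_epochs"]] == 6
        assert vec[FEATURE_INDEX["prior_withdrawal_epochs"]] == 2
        assert vec[FEATURE_INDEX["age_months"]] == 24.0

    def test_no_medication_gives_zero_dose_block(self):
        vit, med = self._inputs()
        vec = feat.assemble_feature_vector(vit, med, 12.0, 0, 1, 50.0)
        drug_slice = vec[30:62]
        assert np.all(drug_slice == 0.0)

    def test_missing_vital_raises_with_names(self):
        vit, med = self._inputs()
        del vit["heart_rate"]
        with pytest.raises(ValueError, match="heart_rate"):
            feat.assemble_feature_vector(vit, med, 12.0, 0, 1, 50.0)


class TestPipeline:
    def test_prepared_windows_are_scaled_and_complete(self, small_prepared):
        for part in (small_prepared.train, small_prepared.val, small_prepared.test):
            assert part.X.shape[1:] == (6, 66)
            assert not np.isnan(part.X).any()
            assert part.X.min() >= 0.0 and part.X.max() <= 1.0

    def test_patient_splits_are_disjoint(self, small_prepared):
        s = small_prepared.split
        assert not (set(s["train"]) & set(s["test"]))
        assert not (set(s["train"]) & set(s["val"]))
        assert not (set(s["val"]) & set(s["test"]))

    def test_window_csv_round_trip(self, small_prepared, tmp_path):
        ds = small_prepared.test
        ds.to_csv(tmp_path / "w.csv")
        back = feat.WindowDataset.from_csv(tmp_path / "w.csv")
        assert np.allclose(back.X, ds.X)
        assert np.array_equal(back.y, ds.y)
        assert list(back.patient_ids) == list(ds.patient_ids)
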