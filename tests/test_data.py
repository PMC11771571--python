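"""Domain types, IO round-trips, covariate preprocessing, splitting."""

import numpy as np
import pandas as pd
import pytest

import jmbiexp as jm
from jmbiexp.data import (IntegrityError, SchemaError, build_block,
                          preprocess_covariates, read_block, split_train_test,
                          write_block)

from conftest import make_tiny_block


class TestBlockConstruction:
    def test_build_and_invariants(self):
        longitudinal, survival, covariates = make_tiny_block(n=6, seed=1)
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        assert ds.n_patients == 6
        assert ds.n_events == 2
        assert set(ds.biomarker_ids) <= {1, 2}

    def test_patient_without_measurements_is_legal(self):
        survival = pd.DataFrame([("P0", 100.0, 1), ("P1", 50.0, 0)],
                                columns=["patient_id", "time", "event"])
        longitudinal = pd.DataFrame(
            [("P0", 1, 0.0, 12.0)],
            columns=["patient_id", "biomarker_id", "time", "value"])
        covariates = pd.DataFrame({"patient_id": ["P0", "P1"], "age": [60.0, 70.0]})
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        assert len(ds.get_series("P1", 1)) == 0

    def test_measurement_after_outcome_rejected(self):
        survival = pd.DataFrame([("P0", 300.0, 1)],
                                columns=["patient_id", "time", "event"])
        longitudinal = pd.DataFrame(
            [("P0", 1, 400.0, 5.0)],
            columns=["patient_id", "biomarker_id", "time", "value"])
        covariates = pd.DataFrame({"patient_id": ["P0"], "age": [60.0]})
        with pytest.raises(IntegrityError):
            build_block(longitudinal, survival, covariates, n_events=2)

    def test_event2_in_single_event_block_rejected(self):
        survival = pd.DataFrame([("P0", 100.0, 2)],
                                columns=["patient_id", "time", "event"])
        longitudinal = pd.DataFrame(
            columns=["patient_id", "biomarker_id", "time", "value"])
        covariates = pd.DataFrame({"patient_id": ["P0"], "age": [60.0]})
        with pytest.raises(IntegrityError):
            build_block(longitudinal, survival, covariates, n_events=1)

    def test_duplicate_measurement_rejected(self):
        survival = pd.DataFrame([("P0", 100.0, 0)],
                                columns=["patient_id", "time", "event"])
        longitudinal = pd.DataFrame(
            [("P0", 1, 5.0, 2.0), ("P0", 1, 5.0, 3.0)],
            columns=["patient_id", "biomarker_id", "time", "value"])
        covariates = pd.DataFrame({"patient_id": ["P0"], "age": [60.0]})
        with pytest.raises(IntegrityError):
            build_block(longitudinal, survival, covariates, n_events=2)

    def test_missing_column_names_offender(self):
        longitudinal, survival, covariates = make_tiny_block(n=3)
        with pytest.raises(SchemaError, match="event"):
            build_block(longitudinal, survival.drop(columns=["event"]),
                        covariates, n_events=2)


class TestRoundTrip:
    def test_write_read_round_trip(self, tmp_path):
        longitudinal, survival, covariates = make_tiny_block(n=6, seed=2)
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        paths = write_block(ds, tmp_path)
        ds2 = read_block(paths["longitudinal"], paths["survival"],
                         paths["covariates"], n_events=2)
        pd.testing.assert_frame_equal(
            ds.survival_frame().sort_values("patient_id").reset_index(drop=True),
            ds2.survival_frame().sort_values("patient_id").reset_index(drop=True))
        pd.testing.assert_frame_equal(
            ds.longitudinal_frame().sort_values(
                ["patient_id", "biomarker_id", "time"]).reset_index(drop=True),
            ds2.longitudinal_frame().sort_values(
                ["patient_id", "biomarker_id", "time"]).reset_index(drop=True))


class TestPreprocessing:
    def test_log_standardize_hand_computed(self):
        frame = pd.DataFrame({"x": np.exp([0.0, 2.0, 4.0])},
                             index=pd.Index(list("abc"), name="patient_id"))
        raw = jm.CovariateTable(frame, continuous=("x",))
        out, spec = preprocess_covariates(raw, log_columns=("x",))
        expected = np.array([-1.0, 0.0, 1.0]) * np.sqrt(1.5)
        np.testing.assert_allclose(out.frame["x"].to_numpy(), expected,
                                   atol=1e-12)
        use_log, mean, sd = spec.continuous["x"]
        assert use_log and mean == pytest.approx(2.0)

    def test_missing_test_entry_imputed_to_standardized_mean(self):
        train = jm.CovariateTable(
            pd.DataFrame({"x": [1.0, 2.0, 3.0]},
                         index=pd.Index(list("abc"), name="patient_id")),
            continuous=("x",))
        _, spec = preprocess_covariates(train)
        test = jm.CovariateTable(
            pd.DataFrame({"x": [np.nan, 2.0]},
                         index=pd.Index(list("de"), name="patient_id")),
            continuous=("x",))
        out, _ = preprocess_covariates(test, spec=spec)
        assert out.frame["x"].iloc[0] == 0.0
        assert out.frame["x"].iloc[1] == pytest.approx(0.0)  # train mean is 2

    def test_spec_reuse_is_deterministic(self):
        longitudinal, survival, covariates = make_tiny_block(n=8, seed=3)
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        _, spec = preprocess_covariates(ds.covariates)
        once, _ = preprocess_covariates(ds.covariates, spec=spec)
        twice, _ = preprocess_covariates(ds.covariates, spec=spec)
        pd.testing.assert_frame_equal(once.frame, twice.frame)

    def test_nonpositive_log_column_rejected(self):
        raw = jm.CovariateTable(
            pd.DataFrame({"x": [1.0, -2.0]},
                         index=pd.Index(list("ab"), name="patient_id")),
            continuous=("x",))
        with pytest.raises(ValueError, match="log"):
            preprocess_covariates(raw, log_columns=("x",))

    def test_zero_variance_column_rejected(self):
        raw = jm.CovariateTable(
            pd.DataFrame({"x": [2.0, 2.0, 2.0]},
                         index=pd.Index(list("abc"), name="patient_id")),
            continuous=("x",))
        with pytest.raises(ValueError, match="SD"):
            preprocess_covariates(raw)

    def test_one_hot_reference_coding(self):
        raw = jm.CovariateTable(
            pd.DataFrame({"g": ["A", "B", "C", "A"]},
                         index=pd.Index(list("abcd"), name="patient_id")),
            categorical=("g",))
        out, spec = preprocess_covariates(raw)
        assert tuple(out.design_columns) == ("g_B", "g_C")
        np.testing.assert_array_equal(out.frame["g_B"], [0, 1, 0, 0])


class TestSplit:
    @pytest.mark.parametrize("n,fraction,n_train", [
        (10, 0.8, 8),
        (5490, 0.8, 4392),   # ceil(0.8 * 5490)
        (7, 0.5, 4),
    ])
    def test_split_sizes(self, n, fraction, n_train):
        survival = pd.DataFrame({"patient_id": [f"P{i}" for i in range(n)],
                                 "time": 100.0, "event": 0})
        longitudinal = pd.DataFrame(
            columns=["patient_id", "biomarker_id", "time", "value"])
        covariates = pd.DataFrame({"patient_id": survival.patient_id,
                                   "age": 60.0})
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        train, test = split_train_test(ds, fraction, seed=7)
        assert train.n_patients == n_train
        assert test.n_patients == n - n_train
        assert set(train.patient_ids).isdisjoint(test.patient_ids)
        assert set(train.patient_ids) | set(test.patient_ids) == set(ds.patient_ids)

    def test_split_reproducible(self):
        longitudinal, survival, covariates = make_tiny_block(n=10, seed=4)
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        a1, b1 = split_train_test(ds, 0.8, seed=7)
        a2, b2 = split_train_test(ds, 0.8, seed=7)
        assert a1.patient_ids == a2.patient_ids
        assert b1.patient_ids == b2.patient_ids

    def test_bad_fraction_rejected(self):
        longitudinal, survival, covariates = make_tiny_block(n=4)
        ds = build_block(longitudinal, survival, covariates, n_events=2)
        with pytest.raises(ValueError):
            split_train_test(ds, 1.2, seed=0)
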