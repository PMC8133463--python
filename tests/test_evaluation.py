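"""Radial folds, AUC, max-kappa thresholding and delta-AUC importance."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from climenv.errors import (
    ConfigurationError,
    DegenerateFoldError,
    UndefinedMetricError,
)
from climenv.evaluation import (
    auc_roc,
    delta_auc_importance,
    loocv_predict,
    max_kappa_threshold,
    radial_segments,
    select_algorithms,
)
from climenv.models import AlgorithmSpec
from climenv.occurrence import GeoPoint

from conftest import auc_brute_force, max_kappa_brute_force


class TestRadialSegments:
    CENTER = GeoPoint(38.0, 0.0)

    def _frame(self, bearings_deg, radius=0.5):
        ang = np.radians(np.asarray(bearings_deg, dtype=float))
        return pd.DataFrame(
            {
                "lon": self.CENTER.lon + radius * np.cos(ang),
                "lat": self.CENTER.lat + radius * np.sin(ang),
            }
        )

    def test_k_below_two_rejected(self):
        with pytest.raises(ConfigurationError):
            radial_segments(self._frame([0]), k=1, center=self.CENTER)

    def test_east_west_points_split_with_k2(self):
        seg = radial_segments(self._frame([0, 180]), k=2, center=self.CENTER)
        assert seg.indices[0] != seg.indices[1]

    def test_five_sectors_one_bearing_each(self):
        seg = radial_segments(self._frame([10, 80, 150, 220, 290]), k=5,
                              center=self.CENTER)
        assert sorted(seg.indices) == [0, 1, 2, 3, 4]

    def test_uniform_ring_fills_sectors_evenly(self):
        bearings = 0.1 + 0.36 * np.arange(1000)
        seg = radial_segments(self._frame(bearings), k=5, center=self.CENTER)
        assert np.bincount(seg.indices, minlength=5).tolist() == [200] * 5

    def test_center_point_goes_to_sector_zero(self):
        frame = pd.DataFrame({"lon": [self.CENTER.lon], "lat": [self.CENTER.lat]})
        seg = radial_segments(frame, k=4, center=self.CENTER, offset_deg=33.0)
        assert seg.indices[0] == 0

    def test_default_center_is_presence_centroid(self):
        frame = pd.DataFrame(
            {
                "lon": [38.0, 39.0, 0.0],
                "lat": [4.0, 5.0, 0.0],
                "label": ["presence", "presence", "pseudo_absence"],
            }
        )
        seg = radial_segments(frame, k=3)
        assert seg.center == GeoPoint(38.5, 4.5)


class TestAucRoc:
    def test_trivial_cases(self):
        assert auc_roc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1]) == 1.0
        assert auc_roc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5]) == 0.5
        with pytest.raises(UndefinedMetricError):
            auc_roc([1, 1], [0.4, 0.5])

    def test_worked_example_matches_pair_enumeration(self):
        obs = np.array([1, 1, 0, 0, 0])
        pred = np.array([0.9, 0.4, 0.5, 0.3, 0.3])
        oracle = auc_brute_force(obs, pred)
        assert oracle == pytest.approx(5.0 / 6.0)
        assert auc_roc(obs, pred) == pytest.approx(oracle)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_instances(self, data):
        n1 = data.draw(st.integers(1, 40))
        n0 = data.draw(st.integers(1, 40))
        # coarse probabilities force plenty of ties
        pred = data.draw(
            st.lists(st.integers(0, 10), min_size=n1 + n0, max_size=n1 + n0)
        )
        obs = np.array([1] * n1 + [0] * n0)
        pred = np.array(pred) / 10.0
        assert auc_roc(obs, pred) == pytest.approx(auc_brute_force(obs, pred))

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        obs = rng.integers(0, 2, 200)
        obs[:3] = [0, 1, 1]
        pred = rng.random(200)
        a = auc_roc(obs, pred)
        assert auc_roc(obs, np.exp(3 * pred)) == pytest.approx(a)
        assert auc_roc(obs, pred**3) == pytest.approx(a)


class TestMaxKappa:
    def test_perfect_separation_gives_kappa_one_at_smallest_threshold(self):
        res = max_kappa_threshold([1, 1, 0, 0], [0.9, 0.7, 0.3, 0.1])
        assert res.kappa == pytest.approx(1.0)
        # smallest candidate achieving kappa=1 is the lowest positive score
        assert res.threshold == pytest.approx(0.7)
        assert (res.tp, res.fp, res.fn, res.tn) == (2, 0, 0, 2)

    def test_worked_example_matches_exhaustive_search(self):
        obs = [1, 1, 0, 0]
        pred = [0.8, 0.6, 0.7, 0.2]
        t_oracle, k_oracle = max_kappa_brute_force(obs, pred)
        res = max_kappa_threshold(obs, pred)
        assert res.threshold == pytest.approx(t_oracle)
        assert res.kappa == pytest.approx(k_oracle)

    @given(st.data())
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_brute_force_on_random_instances(self, data):
        n1 = data.draw(st.integers(1, 30))
        n0 = data.draw(st.integers(1, 30))
        pred = data.draw(
            st.lists(st.integers(0, 10), min_size=n1 + n0, max_size=n1 + n0)
        )
        obs = np.array([1] * n1 + [0] * n0)
        pred = np.array(pred) / 10.0
        t_oracle, k_oracle = max_kappa_brute_force(obs, pred)
        res = max_kappa_threshold(obs, pred)
        assert res.kappa == pytest.approx(k_oracle)
        assert res.threshold == pytest.approx(t_oracle)

    def test_null_predictions_have_low_max_kappa(self):
        rng = np.random.default_rng(2)
        obs = rng.integers(0, 2, 5000)
        pred = rng.random(5000)
        assert max_kappa_threshold(obs, pred).kappa <= 0.1

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            max_kappa_threshold([1, 1], [0.2, 0.4])


class TestLoocv:
    def test_every_record_predicted_once_by_out_of_segment_model(self, small_table):
        seg = radial_segments(small_table, k=5)
        ev = loocv_predict(AlgorithmSpec("GLM"), small_table, seg)
        assert np.isfinite(ev.predicted).all()
        assert len(ev.predicted) == len(small_table)
        np.testing.assert_array_equal(ev.fold_index, seg.indices)

    def test_strong_signal_recovery_on_synthetic_world(self, small_table):
        seg = radial_segments(small_table, k=5)
        ev = loocv_predict(AlgorithmSpec("GLM"), small_table, seg)
        assert ev.auc > 0.8

    def test_null_covariates_give_chance_auc(self):
        rng = np.random.default_rng(3)
        n = 5000
        table = pd.DataFrame(
            {
                "lon": rng.uniform(33, 43, n),
                "lat": rng.uniform(2, 7, n),
                "response": rng.integers(0, 2, n),
                "c1": rng.normal(size=n),
                "c2": rng.normal(size=n),
            }
        )
        seg = radial_segments(table, k=5)
        ev = loocv_predict(AlgorithmSpec("GLM"), table, seg)
        assert 0.45 <= ev.auc <= 0.55

    def test_degenerate_fold_is_named(self):
        # all presences sit in sector 0, so the fold-0 training set is one-class
        table = pd.DataFrame(
            {
                "lon": [39.0, 39.1, 37.0, 37.1],
                "lat": [4.0, 4.0, 4.0, 4.0],
                "response": [1, 1, 0, 0],
                "c1": [1.0, 2.0, 3.0, 4.0],
            }
        )
        seg = radial_segments(table, k=2, center=GeoPoint(38.0, 4.0))
        with pytest.raises(DegenerateFoldError, match="fold"):
            loocv_predict(AlgorithmSpec("GLM"), table, seg)

    def test_loocv_auc_not_above_in_sample_auc_on_average(self):
        """Across replicates, held-out AUC does not beat training AUC for a
        flexible fitter."""
        from climenv.models import fit, predict

        rng = np.random.default_rng(9)
        spec = AlgorithmSpec("RF", {"n_estimators": 60}, seed=1)
        diffs = []
        for _ in range(20):
            n = 300
            x = rng.normal(size=n)
            prob = 1 / (1 + np.exp(-(0.8 * x)))
            table = pd.DataFrame(
                {
                    "lon": rng.uniform(-1, 1, n),
                    "lat": rng.uniform(-1, 1, n),
                    "response": (rng.random(n) < prob).astype(int),
                    "x": x,
                    "z": rng.normal(size=n),
                }
            )
            seg = radial_segments(table, k=4, center=GeoPoint(0, 0))
            cv_auc = loocv_predict(spec, table, seg).auc
            model = fit(spec, table)
            ins_auc = auc_roc(table["response"], predict(model, table))
            diffs.append(ins_auc - cv_auc)
        assert np.mean(diffs) >= 0


class TestImportance:
    def test_governing_variable_dominates_and_shares_normalise(self, small_table):
        seg = radial_segments(small_table, k=5)
        imp = delta_auc_importance(AlgorithmSpec("GLM"), small_table, seg)
        assert imp.shares is not None
        assert sum(imp.shares.values()) == pytest.approx(1.0, abs=1e-9)
        # at this compact scale the thermal constraint carries the signal;
        # no nuisance variable outranks it
        top = max(imp.delta_auc, key=imp.delta_auc.get)
        assert top == "bio_maxtemp"
        for v in ("bio_tseason", "bio_trange", "bio_pwet"):
            assert imp.delta_auc[v] < imp.delta_auc["bio_maxtemp"]

    def test_pure_noise_covariate_has_near_zero_delta(self, small_table):
        rng = np.random.default_rng(8)
        table = small_table.copy()
        table["pure_noise"] = rng.normal(size=len(table))
        seg = radial_segments(table, k=5)
        imp = delta_auc_importance(AlgorithmSpec("GLM"), table, seg)
        assert abs(imp.delta_auc["pure_noise"]) <= 0.02


def test_select_algorithms_cutoff():
    aucs = {"GLM": 0.62, "GAM": 0.59, "RF": 0.60}
    assert select_algorithms(aucs, cutoff=0.6) == ["GLM"]
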