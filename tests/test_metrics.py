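"""Reconstruction metrics, anomaly masks, LOESS density curves, bulk report."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dotrecon as dr
from dotrecon import metrics as M


def _two_level_volume(delta, shape=(4, 4, 2), block=slice(0, 2)):
    """Flat background 1.0 with an elevated block at 1 + delta."""
    v = np.ones(shape)
    v[block, block, :] = 1.0 + delta
    return v


class TestRmse:
    def test_identity_is_zero(self, rng):
        y = rng.random((5, 5, 3))
        assert M.rmse(y, y) == 0.0

    def test_hand_computed_example(self):
        assert M.rmse(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 5])) == 0.5

    def test_constant_offset_closed_form(self, rng):
        y = rng.random((4, 4, 2))
        assert M.rmse(y + 0.37, y) == pytest.approx(0.37, rel=1e-12)

    def test_unit_conversion_coherence(self, rng):
        """RMSE in mm^-1 scales exactly into m^-1 (x1000) and cm^-1 (x10)."""
        a, b = rng.random(20), rng.random(20)
        base = M.rmse(a, b)
        assert M.rmse(1000 * a, 1000 * b) == pytest.approx(1000 * base, rel=1e-12)
        assert M.rmse(10 * a, 10 * b) == pytest.approx(10 * base, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            M.rmse(np.zeros(3), np.zeros(4))


class TestAnomalyMask:
    def test_binary_volume(self):
        v = np.zeros((3, 3, 2)); v[1, 1, :] = 1.0
        np.testing.assert_array_equal(M.anomaly_mask(v), v == 1.0)

    def test_positive_affine_invariance(self, rng):
        v = rng.random((3, 3, 2))
        np.testing.assert_array_equal(M.anomaly_mask(v), M.anomaly_mask(2.5 * v + 7))

    def test_matches_exhaustive_threshold_enumeration(self, rng):
        v = rng.random((3, 3, 2))
        mask = M.anomaly_mask(v)
        lo, hi = v.min(), v.max()
        for idx in np.ndindex(*v.shape):
            assert mask[idx] == ((v[idx] - lo) / (hi - lo) > 0.5)

    def test_exact_half_goes_to_background(self):
        v = np.array([0.0, 0.5, 1.0])
        np.testing.assert_array_equal(M.anomaly_mask(v), [False, False, True])

    def test_constant_channel_undefined(self):
        assert M.anomaly_mask(np.full((2, 2), 3.0)) is None


class TestSdc:
    def test_identity_is_one(self, rng):
        v = _two_level_volume(0.5)
        assert M.sdc(v, v) == 1.0

    def test_disjoint_masks_zero(self):
        a = np.zeros((4, 1, 1)); a[0] = 1
        b = np.zeros((4, 1, 1)); b[3] = 1
        assert M.sdc(a, b) == 0.0

    def test_hand_counted_overlap(self):
        # masks of sizes 3 and 3 sharing 2 voxels -> 2*2/6
        a = np.zeros(10); a[[0, 1, 2]] = 1
        b = np.zeros(10); b[[1, 2, 5]] = 1
        assert M.sdc(a, b) == pytest.approx(2 * 2 / 6)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_symmetry(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.random((3, 3, 2)), r.random((3, 3, 2))
        assert M.sdc(a, b) == M.sdc(b, a)

    def test_undefined_propagates(self):
        assert np.isnan(M.sdc(np.full((2, 2), 1.0), np.ones((2, 2))))


class TestContrastRatio:
    def test_identity_is_one(self):
        v = _two_level_volume(0.8)
        assert M.contrast_ratio(v, v) == pytest.approx(1.0)

    def test_halved_elevation_formula(self):
        delta = 0.8
        y = _two_level_volume(delta)
        y_hat = _two_level_volume(delta / 2)
        expected = (1 + delta / 2) / (1 + delta)
        assert M.contrast_ratio(y_hat, y) == pytest.approx(expected, rel=1e-12)

    def test_positive_scaling_invariance(self, rng):
        y = _two_level_volume(0.5)
        y_hat = _two_level_volume(0.3) + 0.01 * rng.random(y.shape)
        assert M.contrast_ratio(3.7 * y_hat, y) == pytest.approx(
            M.contrast_ratio(y_hat, y), rel=1e-12)

    def test_undefined_on_constant_channel(self):
        assert np.isnan(M.contrast_ratio(np.ones((2, 2)), _two_level_volume(0.5)))


class TestDensityCurve:
    def _report(self, n, y):
        return pd.DataFrame({"n_measurements": n, "metric": y})

    def test_constant_input_gives_constant_curve(self):
        rep = self._report([1, 5, 9, 20, 40], [0.7] * 5)
        curve = M.density_curve(rep, "metric")
        np.testing.assert_allclose(curve["metric"], 0.7)

    def test_linear_input_reproduced_exactly(self):
        n = np.arange(1, 60)
        rep = self._report(n, 0.3 + 0.01 * n)
        curve = M.density_curve(rep, "metric")
        np.testing.assert_allclose(curve["metric"], 0.3 + 0.01 * curve["n_measurements"],
                                   atol=1e-6)

    def test_matches_brute_force_weighted_least_squares(self, rng):
        """50 noisy points vs an independent tricube-WLS implementation."""
        n = rng.integers(1, 80, size=50)
        y = np.sin(n / 20) + 0.1 * rng.normal(size=50)
        rep = self._report(n, y)
        curve = M.density_curve(rep, "metric")
        for x0 in (1, 10, 37, int(n.max())):
            d = np.abs(n - x0)
            w = np.where(d < 20, (1 - (d / 20.0) ** 3) ** 3, 0.0)
            sel = w > 0
            X = np.column_stack([np.ones(sel.sum()), n[sel] - x0])
            W = np.diag(w[sel])
            beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y[sel])
            got = curve.loc[curve["n_measurements"] == x0, "metric"].iloc[0]
            assert got == pytest.approx(beta[0], rel=1e-8)

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            M.density_curve(self._report([5, 5, 5], [1, 2, 3]), "metric")


class TestEvaluatePairAndReport:
    def test_schema_and_identity_scores(self, rng, tiny_cfg):
        vol, _ = dr.sample_phantom(rng, tiny_cfg.replace(n_anomalies_range=(1, 1)))
        df = M.evaluate_pair(vol, vol, n_measurements=9, example_id="a")
        assert list(df["parameter"]) == ["mua", "musp"]
        assert np.all(df["rmse_mm_inv"] == 0)
        assert np.all(df["sdc"] == 1.0)
        np.testing.assert_allclose(df["cr"], 1.0)

    def test_homogeneous_examples_have_undefined_spatial_metrics(self, rng, tiny_cfg):
        vol, _ = dr.sample_phantom(rng, tiny_cfg.replace(n_anomalies_range=(0, 0)))
        df = M.evaluate_pair(vol, vol)
        assert df["sdc"].isna().all() and df["cr"].isna().all()


class TestBulkRecoveryReport:
    class _PerfectModel:
        def __init__(self, records):
            self._by_id = {id(r): r for r in records}

        def predict_tensor(self, records):
            return np.stack([r.target.as_tensor() for r in records])

    class _MeanModel:
        def __init__(self, mean):
            self.mean = mean

        def predict_tensor(self, records):
            return np.stack([self.mean] * len(records))

    def _records(self, cfg, rng, n=12):
        return dr.simulate_dataset(cfg, n, rng, n_positions=3, homogeneous_only=True)

    def test_perfect_predictor_scores_zero(self, rng, tiny_cfg):
        recs = self._records(tiny_cfg, rng)
        report = dr.bulk_recovery_report(self._PerfectModel(recs), recs)
        assert len(report) == 2
        assert np.all(report["rmse_percent_mean"] == 0)

    def test_mean_predictor_matches_direct_computation(self, rng, tiny_cfg):
        """Baseline oracle: predicting the dataset mean gives an error
        computable directly from the sampled truths."""
        recs = self._records(tiny_cfg, rng, n=20)
        mean_vol = np.stack([r.target.as_tensor() for r in recs]).mean(axis=0)
        report = dr.bulk_recovery_report(self._MeanModel(mean_vol), recs)
        for c, name in enumerate(("mua", "musp")):
            expected = np.mean([
                100.0 * M.rmse(mean_vol[..., c], r.target.as_tensor()[..., c])
                / r.target.as_tensor()[..., c].mean()
                for r in recs
            ])
            row = report[report["parameter"] == name].iloc[0]
            assert row["rmse_percent_mean"] == pytest.approx(expected, rel=1e-12)

    def test_no_qualifying_examples_rejected(self, rng, tiny_cfg):
        recs = dr.simulate_dataset(tiny_cfg, 2, rng, n_positions=8,
                                   homogeneous_only=True)
        with pytest.raises(ValueError):
            dr.bulk_recovery_report(object(), recs, max_measurements=5)
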