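"""Accuracy/precision metrics against brute-force oracles and the
generator's analytic expectations."""

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import norm

from gazelab import pipeline, quality, synthetic
from gazelab.model import TargetSet


class TestMae:
    def test_exact_series_is_zero(self):
        assert quality.mae(np.full(50, 3.0), 3.0) == 0.0

    def test_constant_offset(self):
        assert quality.mae(np.full(50, 3.1), 3.0) == pytest.approx(0.1)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(1)
        x = rng.normal(2.0, 0.3, 100)
        x[rng.choice(100, 10, replace=False)] = np.nan
        expected = np.mean([abs(v - 2.0) for v in x if np.isfinite(v)])
        assert quality.mae(x, 2.0) == pytest.approx(expected)

    def test_empty_is_nan(self):
        assert np.isnan(quality.mae(np.full(5, np.nan), 1.0))


class TestRmsS2s:
    def test_constant_is_zero(self):
        assert quality.rms_s2s(np.full(20, 1.0)) == 0.0

    def test_alternating_step(self):
        x = np.tile([1.0, 1.3], 25)
        assert quality.rms_s2s(x) == pytest.approx(0.3)

    def test_matches_brute_force_and_skips_gap_pairs(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=60)
        x[10] = np.nan
        pairs = [(x[i + 1] - x[i]) ** 2 for i in range(59)
                 if np.isfinite(x[i]) and np.isfinite(x[i + 1])]
        assert quality.rms_s2s(x) == pytest.approx(np.sqrt(np.mean(pairs)))
        assert len(pairs) == 57  # both pairs through the gap dropped


class TestStdPrecision:
    def test_constant_is_zero(self):
        assert quality.std_precision(np.full(10, 4.0)) == 0.0

    def test_translation_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        assert quality.std_precision(x + 7.5) == pytest.approx(quality.std_precision(x))

    def test_matches_two_pass_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30)
        mean = sum(x) / 30
        var = sum((v - mean) ** 2 for v in x) / 29  # n-1 denominator
        assert quality.std_precision(x) == pytest.approx(np.sqrt(var))


class TestCombineEyes:
    @pytest.mark.parametrize("vals, expected", [
        ((0.10, 0.14), 0.12),
        ((float("nan"), 0.2), 0.2),
        ((0.3, 0.3), 0.3),
    ])
    def test_rules(self, vals, expected):
        assert quality.combine_eyes(*vals) == pytest.approx(expected)

    def test_all_undefined(self):
        assert np.isnan(quality.combine_eyes(float("nan"), float("nan")))


class TestBuildReport:
    def test_noise_free_report_is_exact(self, clean_recording, targets):
        rec, _ = clean_recording
        rep = pipeline.run_pipeline(rec, targets)
        t = rep.table
        assert np.allclose(t.mae_m, 0.0, atol=1e-9)
        assert np.allclose(t.visual_angle_deg, 0.0, atol=1e-6)
        assert np.allclose(t.rms_s2s_m, 0.0, atol=1e-9)
        assert np.allclose(t.std_m, 0.0, atol=1e-9)

    def test_identical_eyes_combine_to_same_metrics(self, clean_recording, targets):
        rec, _ = clean_recording
        rep = pipeline.run_pipeline(rec, targets)
        t = rep.table.set_index(["eye", "target_id"])
        for tid in range(6):
            for col in ("mae_m", "rms_s2s_m", "std_m"):
                le, ri = t.loc[("left", tid), col], t.loc[("right", tid), col]
                assert t.loc[("mean", tid), col] == pytest.approx((le + ri) / 2)

    def test_noise_increases_every_metric(self, targets):
        """Fixed seed, growing angular jitter: every per-target MAE, RMS-S2S
        and STD strictly increases."""
        tables = []
        for sd in (0.1, 0.3):
            p = synthetic.SimulationParams(seed=11, angular_noise_sd=sd,
                                           dropout_rate=0.0)
            rec, _ = synthetic.synthesize_recording(p)
            rep = pipeline.run_pipeline(rec, targets)
            tables.append(rep.table.query("eye == 'mean'").sort_values("target_id"))
        lo, hi = tables
        for col in ("mae_m", "rms_s2s_m", "std_m"):
            assert np.all(hi[col].to_numpy() > lo[col].to_numpy())

    def test_mae_matches_halfnormal_quadrature_oracle(self, targets):
        """Per-target MAE under pure angular jitter equals the expectation of
        |h tan(a + e) - h tan(a)|, e ~ N(0, sigma), by numerical quadrature
        (within 3 Monte-Carlo standard errors)."""
        sd_deg = 0.2
        p = synthetic.SimulationParams(seed=21, angular_noise_sd=sd_deg,
                                       dropout_rate=0.0, sway_amplitude=0.0,
                                       inter_eye_offset=0.0, drift_deg_per_s=0.0)
        rec, gt = synthetic.synthesize_recording(p)
        rep = pipeline.run_pipeline(rec, targets)
        h = p.eye_height
        sd = np.radians(sd_deg)
        for tid, tx in enumerate(targets.xs):
            a = np.arctan(tx / h)
            f = lambda e: abs(h * np.tan(a + e) - tx) * norm.pdf(e, scale=sd)
            expect, _ = quad(f, -6 * sd, 6 * sd)
            row = rep.table.query("eye == 'mean' and target_id == @tid").iloc[0]
            # MC standard error of a mean of ~400 half-normal-ish samples/eye
            se = expect * 0.76 / np.sqrt(2 * row.n_samples / 2)
            assert row.mae_m == pytest.approx(expect, abs=3 * se + 5e-4)

    def test_distance_trend_and_flat_angular_rms(self, targets):
        """Constant angular noise: world-space MAE and STD grow with target
        distance while RMS-S2S of the viewing-angle series stays flat."""
        from gazelab import geometry, segmentation
        p = synthetic.SimulationParams(seed=13, dropout_rate=0.0)
        rec, _ = synthetic.synthesize_recording(p)
        rep = pipeline.run_pipeline(rec, targets)
        m = rep.table.query("eye == 'mean'").sort_values("target_id")
        assert np.all(np.diff(m.mae_m) > 0)
        assert np.all(np.diff(m.std_m) > 0)
        track = rec.left
        ang = np.where(track.valid, geometry.viewing_angle(track.gaze), np.nan)
        x = pipeline.intercept_x_series(track)
        segs = segmentation.segment_viewing_periods(x, rec.fs, 6)
        ang_rms = [quality.rms_s2s(ang[s.start:s.end + 1]) for s in segs]
        assert max(ang_rms) / min(ang_rms) < 1.3  # flat in angular units

    def test_one_eye_absent_average_is_that_eye(self, clean_params, targets):
        from gazelab.model import Recording
        rec, _ = synthetic.synthesize_recording(clean_params)
        mono = Recording(left=rec.left, right=None, fs=rec.fs)
        rep = pipeline.run_pipeline(mono, targets)
        t = rep.table
        assert set(t.eye) == {"left", "mean"}
        left = t.query("eye == 'left'").sort_values("target_id")
        mean = t.query("eye == 'mean'").sort_values("target_id")
        assert np.allclose(left.mae_m.to_numpy(), mean.mae_m.to_numpy(), equal_nan=True)

    def test_visual_angle_of_mae_flat_under_constant_jitter(self, targets):
        """Under constant angular jitter the visual angle of the MAE is
        first-order independent of target distance: the world-space growth
        of MAE is exactly undone by mapping back through the geometry."""
        p = synthetic.SimulationParams(seed=13, dropout_rate=0.0)
        rec, _ = synthetic.synthesize_recording(p)
        rep = pipeline.run_pipeline(rec, targets)
        ang = rep.table.query("eye == 'mean'").sort_values("target_id").visual_angle_deg
        assert max(ang) / min(ang) < 1.4
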