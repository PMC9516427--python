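"""Filtering, cutoff selection, gap filling and the gap-size study."""

import numpy as np
import pytest

from gazelab import signal_processing as sp
from gazelab import synthetic

FS = 50.0


def _sine(freq, fs=FS, n=2000, amp=1.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t)


class TestButterworth:
    def test_constant_is_identity(self):
        x = np.full(500, 3.7)
        for mode in ("dual", "single"):
            y = sp.butterworth_lowpass(x, FS, sp.FilterSpec(5.0, mode=mode))
            assert np.allclose(y, 3.7, atol=1e-9)

    def test_stopband_attenuation(self):
        # 20 Hz signal through a 5 Hz low-pass at fs 100: essentially removed
        x = _sine(20.0, fs=100.0, n=3000)
        y = sp.butterworth_lowpass(x, 100.0, sp.FilterSpec(5.0))
        core = slice(500, 2500)
        assert np.max(np.abs(y[core])) <= 0.03 * np.max(np.abs(x[core]))

    @pytest.mark.parametrize("mode, expected_gain", [
        ("single", 10 ** (-3 / 20)),   # -3 dB at the designed cutoff
        ("dual", 10 ** (-6 / 20)),     # squared response: -6 dB
    ])
    def test_gain_at_cutoff_matches_design(self, mode, expected_gain):
        fc = 5.0
        x = _sine(fc, n=4000)
        y = sp.butterworth_lowpass(x, FS, sp.FilterSpec(fc, mode=mode))
        core = slice(1000, 3000)
        gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
        assert gain == pytest.approx(expected_gain, rel=0.02)

    def test_analytic_magnitude_response_oracle(self):
        """Dual-pass gain equals the squared Butterworth magnitude at the
        bilinear-prewarped frequency ratio."""
        fc, order = 6.0, 4
        warp = lambda f: np.tan(np.pi * f / FS)
        for f in (1.0, 3.0, 8.0, 12.0):
            x = _sine(f, n=4000)
            y = sp.butterworth_lowpass(x, FS, sp.FilterSpec(fc, order=order))
            core = slice(1000, 3000)
            gain = np.sqrt(np.mean(y[core] ** 2) / np.mean(x[core] ** 2))
            analytic = 1.0 / (1.0 + (warp(f) / warp(fc)) ** (2 * order))
            assert gain == pytest.approx(analytic, rel=0.02, abs=1e-4)

    def test_dual_pass_phase_symmetry(self):
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(size=800))
        spec = sp.FilterSpec(4.0)
        fwd = sp.butterworth_lowpass(x, FS, spec)
        rev = sp.butterworth_lowpass(x[::-1], FS, spec)
        core = slice(100, 700)  # edge transients depend on the extension
        assert np.allclose(fwd[core], rev[::-1][core], atol=1e-6)

    def test_cutoff_at_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sp.butterworth_lowpass(np.zeros(100), FS, sp.FilterSpec(25.0))

    def test_nonfinite_rejected(self):
        x = np.zeros(100)
        x[3] = np.nan
        with pytest.raises(ValueError):
            sp.butterworth_lowpass(x, FS, sp.FilterSpec(5.0))


class TestAutocorrelationCutoff:
    def test_white_noise_selects_grid_minimum(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=1500)
        grid = np.arange(1.0, 15.5, 0.5)
        assert sp.autocorrelation_cutoff(x, FS, grid) == grid[0]

    def test_signal_band_respected(self):
        rng = np.random.default_rng(2)
        x = _sine(2.0, n=1500) + 0.3 * rng.normal(size=1500)
        grid = np.arange(1.0, 15.5, 0.5)
        fc = sp.autocorrelation_cutoff(x, FS, grid)
        assert 2.0 <= fc < grid[-1]

    def test_selection_is_member_of_grid_and_minimizes_criterion(self):
        rng = np.random.default_rng(3)
        x = _sine(1.5, n=1200) + 0.2 * rng.normal(size=1200)
        grid = np.arange(2.0, 12.5, 0.5)
        fc = sp.autocorrelation_cutoff(x, FS, grid)
        assert fc in grid
        # brute-force evaluation of the criterion over the grid
        r1 = [abs(sp.residual_lag1_autocorrelation(x, FS, f)) for f in grid]
        assert abs(sp.residual_lag1_autocorrelation(x, FS, fc)) == min(r1)

    def test_degenerate_series_warns_and_returns_minimum(self):
        with pytest.warns(UserWarning):
            fc = sp.autocorrelation_cutoff(np.full(1000, 2.0), FS)
        assert fc == 1.0


class TestQuinticFill:
    def test_no_gaps_identity(self):
        x = np.sin(np.arange(100) / 7.0)
        filled, still = sp.quintic_fill(x)
        assert np.array_equal(filled, x)
        assert not still.any()

    def test_linear_gap_recovered_exactly(self):
        x = 0.3 * np.arange(100.0) - 2.0
        g = x.copy()
        g[40:45] = np.nan
        filled, still = sp.quintic_fill(g)
        assert np.max(np.abs(filled - x)) < 1e-9
        assert not still.any()

    def test_quadratic_gap_recovered_exactly(self):
        # within the boundary-fit support span the bridge is pure Hermite
        # and reproduces polynomial trends exactly
        t = np.arange(120.0)
        x = 0.01 * t ** 2 - 0.3 * t + 1.0
        g = x.copy()
        g[60:67] = np.nan
        filled, _ = sp.quintic_fill(g)
        assert np.max(np.abs(filled - x)) < 1e-6

    def test_sine_gap_error_below_noise_floor(self):
        t = np.arange(500) / FS
        x = np.sin(2 * np.pi * 1.0 * t)
        g = x.copy()
        g[200:205] = np.nan
        filled, _ = sp.quintic_fill(g)
        err = np.max(np.abs(filled[200:205] - x[200:205]))
        assert err < 5e-3  # well under any realistic jitter amplitude
        # independent piecewise-polynomial oracle: a quintic Hermite bridge
        # built by scipy from the sine's true boundary derivatives
        from scipy.interpolate import BPoly
        w = 2 * np.pi
        t0, t1 = 199 / FS, 205 / FS
        ders = lambda tt: [np.sin(w * tt), w * np.cos(w * tt),
                           -w ** 2 * np.sin(w * tt)]
        bridge = BPoly.from_derivatives([t0, t1], [ders(t0), ders(t1)])
        tq = np.arange(200, 205) / FS
        assert np.max(np.abs(filled[200:205] - bridge(tq))) < 5e-3

    def test_never_alters_valid_samples(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=300)
        g = x.copy()
        g[50:70] = np.nan
        g[100:103] = np.nan
        filled, _ = sp.quintic_fill(g)
        ok = np.isfinite(g)
        assert np.array_equal(filled[ok], x[ok])

    def test_max_gap_and_edge_gaps_left_missing(self):
        x = np.sin(np.arange(200) / 9.0)
        g = x.copy()
        g[:4] = np.nan          # edge gap
        g[50:56] = np.nan       # 6 samples > max_gap
        g[120:123] = np.nan     # fillable
        filled, still = sp.quintic_fill(g, max_gap=5)
        assert still[:4].all() and still[50:56].all()
        assert not still[120:123].any()
        assert np.isfinite(filled[120:123]).all()

    def test_too_few_support_points(self):
        x = np.full(10, np.nan)
        x[:5] = 1.0
        with pytest.raises(ValueError):
            sp.quintic_fill(x)


class TestCreateGaps:
    def test_size_zero_copies_identical(self):
        x = np.arange(300.0)
        cfg = sp.GapStudyConfig(gaps_per_eye=5, edge_buffer=50, rng_seed=0)
        for g, (a, b) in sp.create_gaps(x, cfg, 0):
            assert np.array_equal(g, x) and a == b

    def test_edge_buffer_respected(self):
        x = np.zeros(400)
        cfg = sp.GapStudyConfig(gaps_per_eye=200, edge_buffer=50, rng_seed=1)
        for g, (a, b) in sp.create_gaps(x, cfg, 30):
            assert a >= 50 and b <= 350
            assert np.isnan(g[a:b]).all() and np.isfinite(g[:a]).all()

    def test_deterministic_from_seed(self):
        x = np.zeros(500)
        cfg = sp.GapStudyConfig(gaps_per_eye=20, rng_seed=42)
        w1 = [w for _, w in sp.create_gaps(x, cfg, 10)]
        w2 = [w for _, w in sp.create_gaps(x, cfg, 10)]
        assert w1 == w2

    def test_series_too_short(self):
        with pytest.raises(ValueError):
            sp.create_gaps(np.zeros(120), sp.GapStudyConfig(edge_buffer=50), 30)


class TestGapFillMae:
    def test_identical_series_zero(self):
        x = np.arange(100.0)
        assert sp.gap_fill_mae(x, x.copy(), (20, 30)) == 0.0

    def test_constant_offset_on_window(self):
        x = np.zeros(100)
        y = x.copy()
        y[40:50] += 0.05
        assert sp.gap_fill_mae(x, y, (40, 50)) == pytest.approx(0.05)

    def test_matches_brute_force_and_skips_missing(self):
        rng = np.random.default_rng(5)
        a = rng.normal(size=200)
        b = a + rng.normal(0, 0.1, 200)
        a[60] = np.nan  # originally-missing sample inside the window
        window = (55, 70)
        vals = [abs(a[i] - b[i]) for i in range(55, 70) if np.isfinite(a[i])]
        assert sp.gap_fill_mae(a, b, window) == pytest.approx(np.mean(vals))


class TestGapStudy:
    @pytest.fixture(scope="class")
    def smooth_recordings(self):
        """Saccade-free single-fixation trials: the smooth-data regime in
        which interpolation error grows cleanly with gap size."""
        recs = []
        for seed, tx in ((0, 2.0), (1, 3.0), (2, 4.0)):
            p = synthetic.SimulationParams(seed=seed, target_xs=(tx,),
                                           dropout_rate=0.0)
            recs.append(synthetic.synthesize_recording(p)[0])
        return recs

    def test_bookkeeping_counts(self, smooth_recordings):
        cfg = sp.GapStudyConfig(gap_sizes=(0, 5), gaps_per_eye=4, rng_seed=0)
        res = sp.run_gap_study(smooth_recordings[:2], cfg)
        assert (res.table.n == 2 * 2 * 4).all()
        # the full study design: 11 participants x 2 eyes x 50 gaps
        full = sp.GapStudyConfig()
        assert sp.planned_comparisons(11, 2, full) == 1100
        assert len(full.gap_sizes) == 11 and full.gap_sizes[-1] == 50

    def test_mae_non_decreasing_and_size0_is_processing_deviation(
            self, smooth_recordings):
        cfg = sp.GapStudyConfig(gap_sizes=(0, 5, 10, 20, 30), gaps_per_eye=10,
                                rng_seed=11)
        res = sp.run_gap_study(smooth_recordings, cfg, keep_comparisons=True)
        m = res.table.set_index("gap_size_samples").mean_mae_m
        assert np.all(np.diff(m.loc[m.index > 0]) >= 0)
        # size 0 compares treated vs untreated over the whole trial, so all
        # its comparisons within one eye are identical
        per0 = res.per_comparison.query("gap_size_samples == 0")
        assert (per0.groupby(["recording", "eye"]).mae_m.nunique() == 1).all()
        assert (per0.mae_m > 0).all()

    def test_deterministic_given_seed(self, smooth_recordings):
        cfg = sp.GapStudyConfig(gap_sizes=(0, 10), gaps_per_eye=5, rng_seed=3)
        r1 = sp.run_gap_study(smooth_recordings[:1], cfg)
        r2 = sp.run_gap_study(smooth_recordings[:1], cfg)
        assert r1.table.equals(r2.table)

    def test_no_artificial_sample_enters_mae(self):
        """Originally-missing samples are re-masked after treatment, so a gap
        window overlapping them scores only the surviving samples."""
        p = synthetic.SimulationParams(seed=5, target_xs=(3.0,),
                                       dropout_rate=1.0 / 40.0)
        rec, _ = synthetic.synthesize_recording(p)
        cfg = sp.GapStudyConfig(gap_sizes=(0, 20), gaps_per_eye=10, rng_seed=1,
                                edge_buffer=50)
        res = sp.run_gap_study([rec], cfg, keep_comparisons=True)
        assert np.isfinite(res.table.mean_mae_m).all()
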