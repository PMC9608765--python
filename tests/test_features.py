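"""Time-domain features vs naive-loop oracles; thresholds; the R sweep."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import semgkit as sk
from semgkit.features import HUDGINS, MAV_ONLY, R_GRID, FeatureConfig
from semgkit.signal_io import REST_CALIBRATION, ValidationError

from conftest import make_config, mav_oracle, ssc_oracle, wl_oracle, zc_oracle

window_strategy = st.lists(
    st.floats(-10, 10, allow_nan=False, width=32), min_size=3, max_size=64
)


class TestScalarFeatures:
    def test_hand_enumerated_examples(self):
        assert sk.mav([-1, 2, -3]) == pytest.approx(2.0)
        assert sk.wl([1, 3, 2]) == pytest.approx(3.0)
        assert sk.zc([1, -1, 1, -1], 0.0) == 3
        assert sk.zc([1, -1, 1, -1], 3.0) == 0  # each |delta| = 2 < 3
        assert sk.ssc([0, 1, 0, 1, 0], 0.0) == 3

    def test_degenerate_cases(self):
        assert sk.mav(np.zeros(5)) == 0.0
        assert sk.mav(np.full(4, -2.5)) == 2.5
        assert sk.wl(np.full(7, 3.0)) == 0.0
        assert sk.zc(np.abs(np.random.default_rng(0).standard_normal(50)) + 0.1, 1.0) == 0
        assert sk.ssc(np.arange(10.0), 0.5) == 0  # monotone: products <= 0 < threshold

    def test_minimum_length_contracts(self):
        with pytest.raises(ValidationError):
            sk.mav([])
        with pytest.raises(ValidationError):
            sk.wl([1.0])
        with pytest.raises(ValidationError):
            sk.zc([1.0], 0.0)
        with pytest.raises(ValidationError):
            sk.ssc([1.0, 2.0], 0.0)

    def test_wl_is_reversal_invariant(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40)
        assert sk.wl(x) == pytest.approx(sk.wl(x[::-1]))

    @settings(max_examples=150, deadline=None)
    @given(window=window_strategy, r_idx=st.integers(0, 20))
    def test_features_match_naive_oracles(self, window, r_idx):
        t = R_GRID[r_idx] * 0.1
        assert sk.mav(window) == pytest.approx(mav_oracle(window), rel=1e-12, abs=1e-15)
        assert sk.wl(window) == pytest.approx(wl_oracle(window), rel=1e-12, abs=1e-15)
        assert sk.zc(window, t) == zc_oracle(window, t)
        assert sk.ssc(window, t) == ssc_oracle(window, t)

    @settings(max_examples=100, deadline=None)
    @given(window=window_strategy, k=st.floats(0.1, 50))
    def test_amplitude_equivariance(self, window, k):
        x = np.asarray(window)
        t = 0.3
        assert sk.mav(k * x) == pytest.approx(k * sk.mav(x), rel=1e-9, abs=1e-12)
        assert sk.wl(k * x) == pytest.approx(k * sk.wl(x), rel=1e-9, abs=1e-12)
        assert sk.zc(k * x, k * t) == sk.zc(x, t)

    def test_zc_ssc_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            x = rng.standard_normal(int(rng.integers(3, 200)))
            zc_seq = [sk.zc(x, 0.1 * r) for r in R_GRID]
            ssc_seq = [sk.ssc(x, 0.1 * r) for r in R_GRID]
            assert all(a >= b for a, b in zip(zc_seq, zc_seq[1:]))
            assert all(a >= b for a, b in zip(ssc_seq, ssc_seq[1:]))


class TestThresholdCalibration:
    def _rest(self, samples):
        return sk.SEMGRecording(samples, 1926.0, REST_CALIBRATION, 1, 1, "t")

    def test_grid_has_21_values(self):
        assert len(R_GRID) == 21
        assert R_GRID[0] == 0.0 and R_GRID[-1] == 10.0
        assert np.allclose(np.diff(R_GRID), 0.5)

    def test_zero_R_gives_zero_thresholds(self):
        thr = sk.calibrate_threshold(self._rest(np.ones((3, 100))), 0.0)
        assert np.all(thr == 0)

    def test_constant_rest_channel(self):
        thr = sk.calibrate_threshold(self._rest(np.full((1, 50), 2.0)), 1.5)
        assert thr[0] == pytest.approx(3.0)

    def test_wrong_label_rejected(self):
        rec = sk.SEMGRecording(np.ones((1, 10)), 1926.0, "rest", 1, 1, "t")
        with pytest.raises(ValidationError):
            sk.calibrate_threshold(rec, 1.0)

    def test_missing_rest_trial_rejected(self):
        with pytest.raises(ValidationError, match="no calibration trial"):
            sk.calibrate_threshold([], 1.0)


class TestExtraction:
    def test_matrix_shapes_and_mav_consistency(self, tiny_windows):
        n_ch = tiny_windows[0].samples.shape[0]
        hud = sk.extract_features(tiny_windows, FeatureConfig(HUDGINS, 0.0))
        mav_only = sk.extract_features(tiny_windows, FeatureConfig(MAV_ONLY, 0.0))
        assert hud.X.shape == (len(tiny_windows), 4 * n_ch)
        assert mav_only.X.shape == (len(tiny_windows), n_ch)
        assert np.array_equal(mav_only.X, hud.X[:, 0::4])
        assert np.all(hud.X[:, 0::4] >= 0) and np.all(hud.X[:, 1::4] >= 0)
        zc_cols = hud.X[:, 2::4]
        assert np.array_equal(zc_cols, np.round(zc_cols)) and np.all(zc_cols >= 0)

    def test_every_cell_matches_scalar_loop(self, tiny_windows):
        windows = tiny_windows[:40]
        thr = np.array([0.02, 0.05, 0.01])
        fm = sk.extract_features(windows, FeatureConfig(HUDGINS, 1.0), thr)
        for i, w in enumerate(windows):
            for c in range(w.samples.shape[0]):
                x = w.samples[c]
                assert fm.X[i, 4 * c + 0] == pytest.approx(mav_oracle(x), rel=1e-12)
                assert fm.X[i, 4 * c + 1] == pytest.approx(wl_oracle(x), rel=1e-12)
                assert fm.X[i, 4 * c + 2] == zc_oracle(x, thr[c])
                assert fm.X[i, 4 * c + 3] == ssc_oracle(x, thr[c])

    def test_concatenation_equals_rowwise_union(self, tiny_windows):
        a = sk.extract_features(tiny_windows[:20], FeatureConfig(HUDGINS, 0.0))
        b = sk.extract_features(tiny_windows[20:50], FeatureConfig(HUDGINS, 0.0))
        both = sk.extract_features(tiny_windows[:50], FeatureConfig(HUDGINS, 0.0))
        assert np.array_equal(both.X, np.vstack([a.X, b.X]))

    def test_threshold_length_mismatch_rejected(self, tiny_windows):
        with pytest.raises(ValidationError):
            sk.extract_features(tiny_windows[:5], FeatureConfig(HUDGINS, 1.0), np.zeros(7))

    def test_column_order_documented(self, tiny_windows):
        fm = sk.extract_features(tiny_windows[:5], FeatureConfig(HUDGINS, 0.0))
        assert fm.columns[:4] == ("ch1:MAV", "ch1:WL", "ch1:ZC", "ch1:SSC")


class TestOptimizeR:
    def test_single_session_rejected(self, tiny_dataset):
        _, recs, _ = tiny_dataset
        one = [r for r in recs if r.session_id == 1]
        with pytest.raises(ValidationError, match="fixed R"):
            sk.optimize_R(one)

    def test_singleton_grid_returned(self, tiny_dataset):
        _, recs, _ = tiny_dataset
        subset = [r for r in recs if r.session_id <= 3]
        best, table = sk.optimize_R(subset, grid=[0.0])
        assert best == 0.0
        assert len(table) == 1 and 0 <= table[0][1] <= 100

    def test_tie_breaks_toward_smaller_R(self, tiny_dataset):
        """On an easy subset every R classifies perfectly, so the sweep must
        return the smallest grid value."""
        _, recs, _ = tiny_dataset
        subset = [r for r in recs if r.session_id <= 3]
        best, table = sk.optimize_R(subset, grid=[0.0, 0.5, 1.0])
        accs = [acc for _, acc in table]
        if accs.count(max(accs)) > 1:
            assert best == min(r for r, acc in table if acc == max(accs))
        assert best in (0.0, 0.5, 1.0)

    def test_sweep_rejects_zero_threshold_when_only_crossing_magnitude_informs(self):
        """The sweep must select R > 0 on a dataset whose two classes agree
        on MAV, WL, ZC(0) and SSC(0) per period but differ in the magnitude
        of their zero-crossing steps.

        Class A is a square-ish wave with hard +/-c transitions (step 2c)
        plus slanted double-dips (steps ~c); class B redistributes the same
        total variation into soft transitions and single dips so that every
        crossing step is ~c.  Only a threshold between c and 2c separates
        them; unthresholded features are class-blind by construction."""
        c, d1, d2 = 0.2, 0.01, 0.02

        def period_a():
            x = np.concatenate([np.full(32, c), np.full(32, -c)])
            x[14], x[15] = -d1, -d2
            x[46], x[47] = +d1, +d2
            return x

        def period_b():
            x = np.concatenate([np.full(32, c), np.full(32, -c)])
            x[15] = -d2
            x[47] = +d2
            x[32] = +d1
            x[0] = -d1
            return x

        base_a, base_b = np.tile(period_a(), 70), np.tile(period_b(), 70)
        # per-period feature parity: only the crossing-step histogram differs
        assert sk.mav(base_a) == pytest.approx(sk.mav(base_b))
        assert sk.zc(base_a, 0.28) > 0 == sk.zc(base_b, 0.28)

        rng = np.random.default_rng(21)
        fs, n = 1926.0, int(2 * 1926)

        def trial(base):
            a = np.exp(rng.normal(0, 0.15))  # amplitude hides MAV/WL info
            x = np.roll(np.tile(base, n // len(base) + 1)[:n], rng.integers(64))
            return a * x + 0.02 * rng.standard_normal(n)

        recs = []
        for session in range(1, 5):
            recs.append(sk.SEMGRecording(trial(base_a)[None, :], fs, "spread", session, 1, "t"))
            recs.append(sk.SEMGRecording(trial(base_b)[None, :], fs, "V sign", session, 1, "t"))
            recs.append(sk.SEMGRecording(
                (0.04 * rng.standard_normal(n))[None, :], fs, REST_CALIBRATION, session, 1, "t"))
        best, table = sk.optimize_R(recs, grid=[0.0, 3.5, 7.0], seed=3)
        table = dict(table)
        assert best > 0.0
        assert table[best] > table[0.0]
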