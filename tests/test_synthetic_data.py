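"""Simulator: crosstalk mixing, seed determinism, amplitude statistics."""

import numpy as np
import pytest

import semgkit as sk
from semgkit.signal_io import REST_CALIBRATION, ValidationError
from semgkit.synthetic_data import SynthConfig, crosstalk_matrix

from conftest import make_config


class TestCrosstalk:
    def test_zero_lambda_is_identity(self):
        x = np.random.default_rng(0).standard_normal((4, 100))
        assert np.array_equal(sk.apply_crosstalk(x, 0.0), x)

    def test_two_channel_worked_example(self):
        x = np.vstack([np.full(10, 3.0), np.zeros(10)])
        out = sk.apply_crosstalk(x, 0.2)
        assert np.allclose(out[0], 0.8 * 3.0)
        assert np.allclose(out[1], 0.2 * 3.0)

    def test_constant_across_channels_is_eigenvector(self):
        x = np.ones((5, 50)) * 2.5
        assert np.allclose(sk.apply_crosstalk(x, 0.3), x)

    def test_rows_sum_to_one(self):
        m = crosstalk_matrix(7, 0.25)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert np.allclose(np.diag(m), 0.75)

    def test_lambda_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            sk.apply_crosstalk(np.zeros((2, 5)), 0.5)


class TestConfigValidation:
    def test_empty_posture_set_rejected(self):
        with pytest.raises(ValidationError):
            make_config(postures=())

    def test_amplitude_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            make_config(amplitude=np.ones((2, 3)), postures=("rest", "spread", "V sign"))

    def test_requesting_day_beyond_schedule_rejected(self):
        cfg = make_config(sigma=(0.2,))
        with pytest.raises(ValidationError):
            sk.generate_dataset(cfg, days=[2])

    def test_config_json_round_trip(self, tmp_path):
        cfg = make_config()
        cfg.to_json(tmp_path / "c.json")
        back = SynthConfig.from_json(tmp_path / "c.json")
        assert back.postures == cfg.postures
        assert np.array_equal(back.amplitude_matrix, cfg.amplitude_matrix)
        assert back.sigma_trial == cfg.sigma_trial

    def test_shipped_fixtures_load(self):
        healthy = sk.load_fixture_config("healthy_9ch")
        amputee = sk.load_fixture_config("amputee_8ch")
        assert healthy.n_channels == 9 and len(healthy.postures) == 12
        assert amputee.n_channels == 8
        assert healthy.sigma_trial == (0.5, 0.25, 0.1)


class TestGeneration:
    def test_protocol_layout(self, tiny_dataset):
        cfg, recs, truth = tiny_dataset
        per_session = len(cfg.postures) + 1  # + rest-calibration
        assert len(recs) == cfg.sessions_per_day * per_session
        rest = [r for r in recs if r.posture == REST_CALIBRATION]
        assert len(rest) == cfg.sessions_per_day
        assert len(truth) == len(recs)

    def test_posture_order_is_shuffled_per_session(self, tiny_dataset):
        cfg, recs, _ = tiny_dataset
        orders = {}
        for r in recs:
            if r.posture != REST_CALIBRATION:
                orders.setdefault(r.session_id, []).append(r.posture)
        assert len(set(tuple(o) for o in orders.values())) > 1

    def test_seed_determinism_bit_identical(self):
        cfg = make_config(sessions=2, trial_s=1.0)
        a, _ = sk.generate_dataset(cfg)
        b, _ = sk.generate_dataset(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.samples, y.samples)
            assert x.posture == y.posture

    def test_different_seeds_differ(self):
        a, _ = sk.generate_dataset(make_config(sessions=1, trial_s=1.0, seed=1))
        b, _ = sk.generate_dataset(make_config(sessions=1, trial_s=1.0, seed=2))
        assert not np.array_equal(a[0].samples, b[0].samples)

    def test_zero_dispersion_zero_crosstalk_repeats_amplitudes(self):
        cfg = make_config(sigma=(0.0,), sessions=3, trial_s=1.0, crosstalk_lambda=0.0)
        _, truth = sk.generate_dataset(cfg)
        by_posture = {}
        for t in truth:
            by_posture.setdefault(t.posture, []).append(t.realized_amplitudes)
        for amps in by_posture.values():
            for a in amps[1:]:
                assert np.array_equal(a, amps[0])

    def test_zero_amplitude_row_yields_silent_channels(self):
        cfg = make_config(
            postures=("rest", "spread"),
            amplitude=np.array([[0.0, 0.0, 0.0], [0.5, 0.5, 0.5]]),
            rest_amplitude=0.0,
            sessions=1,
            trial_s=1.0,
        )
        recs, _ = sk.generate_dataset(cfg)
        silent = [r for r in recs if r.posture in ("rest", REST_CALIBRATION)]
        for r in silent:
            assert np.sqrt(np.mean(r.samples**2)) < 1e-12

    def test_long_trial_rms_converges_to_target(self):
        """Law of large numbers: a 60 s unit-amplitude single-channel trial
        has sample RMS within 2 % of 1.0."""
        cfg = make_config(
            postures=("spread",),
            n_channels=1,
            amplitude=np.array([[1.0]]),
            centroids=np.array([[120.0]]),
            sessions=1,
            trial_s=60.0,
            sigma=(0.0,),
            crosstalk_lambda=0.0,
        )
        recs, _ = sk.generate_dataset(cfg)
        trial = next(r for r in recs if r.posture == "spread")
        assert np.sqrt(np.mean(trial.samples**2)) == pytest.approx(1.0, rel=0.02)

    def test_realized_rms_unbiased_without_crosstalk(self):
        """Mean relative bias of trial RMS vs realized target < 1 % over 200
        trials (lambda = 0; crosstalk is a separate, documented distortion)."""
        cfg = make_config(
            postures=("spread", "V sign"), n_channels=2, sessions=100,
            trial_s=0.5, sigma=(0.3,), crosstalk_lambda=0.0,
        )
        recs, truth = sk.generate_dataset(cfg)
        ratios = []
        for r, t in zip(recs, truth):
            if r.posture == REST_CALIBRATION:
                continue
            rms = np.sqrt(np.mean(r.samples**2, axis=1))
            ratios.extend(rms / t.realized_amplitudes)
        assert abs(np.mean(ratios) - 1.0) < 0.01

    def test_sigma_recovery_from_log_amplitudes(self):
        """SD of log realized amplitudes recovers sigma_trial within 15 %."""
        sigma = 0.4
        cfg = make_config(
            postures=("spread",), n_channels=1, amplitude=np.array([[1.0]]),
            centroids=np.array([[120.0]]), sessions=100, trial_s=0.5,
            sigma=(sigma,), crosstalk_lambda=0.0,
        )
        _, truth = sk.generate_dataset(cfg)
        logs = [np.log(t.realized_amplitudes[0]) for t in truth if t.posture == "spread"]
        assert np.std(logs, ddof=1) == pytest.approx(sigma, rel=0.15)


class TestAmputeeMode:
    def test_channel_removal_arity(self):
        cfg = sk.load_fixture_config("healthy_9ch")
        out = sk.amputee_mode(cfg, [2])
        assert out.n_channels == 8
        assert out.amplitude_matrix.shape == (12, 8)
        assert "EDM" not in out.channel_names

    def test_empty_loss_is_identity(self):
        cfg = make_config()
        assert sk.amputee_mode(cfg, []) is cfg

    def test_removing_all_channels_rejected(self):
        with pytest.raises(ValidationError):
            sk.amputee_mode(make_config(n_channels=2), [0, 1])

    def test_renormalization_preserves_peak_amplitude(self):
        cfg = sk.load_fixture_config("healthy_9ch")
        out = sk.amputee_mode(cfg, [0, 1])  # drop the two largest-activation columns
        assert out.amplitude_matrix.max() == pytest.approx(cfg.amplitude_matrix.max())
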