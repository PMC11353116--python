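"""The ten expert features: spectra, ratios, EM events, masking."""

import numpy as np
import pytest

from mlsnet import (
    BandSpec,
    EMThresholds,
    EpochedRecording,
    FeatureScaler,
    Hypnogram,
    SynthConfig,
    em_event_frequency,
    extract_features,
    fit_em_thresholds,
    mask_em_features,
    mean_amplitude,
    rms,
    spectral_power,
    synthesize_epoch,
    theta_delta_ratio,
)
from mlsnet.features import CANONICAL_BANDS, RATIO_CAP, ThresholdFitError
from mlsnet.io_poly import ConfigurationError

FS = 500.0
EPOCH_S = 4.0
N = int(FS * EPOCH_S)


def brute_force_band_power(x, fs, f_lo, f_hi):
    """O(n^2) DFT band power: the independent oracle for spectral_power."""
    n = len(x)
    total = 0.0
    for k in range(n // 2 + 1):
        f = k * fs / n
        if f_lo <= f <= f_hi:
            re = sum(x[t] * np.cos(-2 * np.pi * k * t / n) for t in range(n))
            im = sum(x[t] * np.sin(-2 * np.pi * k * t / n) for t in range(n))
            total += re**2 + im**2
    return total


class TestSpectralPower:
    def test_matches_brute_force_dft(self, rng):
        # short epoch keeps the O(n^2) oracle affordable
        x = rng.normal(size=128)
        band = BandSpec("theta", 6.0, 9.0)
        ours = spectral_power(x, FS, band)
        oracle = brute_force_band_power(x, FS, 6.0, 9.0)
        assert ours == pytest.approx(oracle, rel=1e-9)

    def test_sinusoid_power_lands_in_its_band(self, rng):
        t = np.arange(N) / FS
        x = np.sin(2 * np.pi * 7.0 * t)
        theta = spectral_power(x, FS, CANONICAL_BANDS["theta"])
        delta = spectral_power(x, FS, CANONICAL_BANDS["delta"])
        total = spectral_power(x, FS, BandSpec("all", 0.25, FS / 2))
        assert theta >= 0.99 * total
        assert delta < 0.01 * total

    def test_zero_signal(self):
        assert spectral_power(np.zeros(100), FS, CANONICAL_BANDS["delta"]) == 0.0

    def test_band_beyond_nyquist(self):
        with pytest.raises(ConfigurationError):
            spectral_power(np.zeros(100), FS, BandSpec("bad", 200.0, 300.0))

    def test_additive_over_disjoint_bands(self, rng):
        x = rng.normal(size=N)
        a = spectral_power(x, FS, BandSpec("lo", 10.0, 20.0))
        b = spectral_power(x, FS, BandSpec("hi", 20.25, 30.0))
        both = spectral_power(x, FS, BandSpec("ab", 10.0, 30.0))
        assert a + b == pytest.approx(both, rel=1e-9)

    def test_band_power_bounded_by_full_band(self, rng):
        x = rng.normal(size=N)
        part = spectral_power(x, FS, CANONICAL_BANDS["delta"])
        full = spectral_power(x, FS, BandSpec("full", 0.0, FS / 2))
        assert part <= full * (1 + 1e-12)


class TestThetaDeltaRatio:
    @pytest.mark.parametrize(
        "theta,delta,expected", [(4.0, 2.0, 2.0), (0.0, 5.0, 0.0), (0.0, 0.0, 0.0)]
    )
    def test_values(self, theta, delta, expected):
        assert theta_delta_ratio(theta, delta) == expected

    def test_zero_delta_sentinel(self):
        assert theta_delta_ratio(1.0, 0.0) == RATIO_CAP

    def test_rem_like_exceeds_nrem_like(self, rng):
        cfg = SynthConfig(seed=0)
        ratios = {}
        for state in ("REM", "NREM"):
            vals = []
            for _ in range(30):
                eeg, _, _ = synthesize_epoch(state, cfg, rng)
                th = spectral_power(eeg, FS, CANONICAL_BANDS["theta"])
                de = spectral_power(eeg, FS, CANONICAL_BANDS["delta"])
                vals.append(theta_delta_ratio(th, de))
            ratios[state] = np.mean(vals)
        assert ratios["REM"] > ratios["NREM"]


class TestTimeDomain:
    def test_rms_hand_value(self):
        assert rms(np.array([3.0, 4.0])) == pytest.approx(np.sqrt(12.5))

    def test_rms_constant(self):
        assert rms(np.full(10, -2.0)) == pytest.approx(2.0)

    def test_rms_matches_loop_oracle(self, rng):
        x = rng.normal(size=1000)
        oracle = np.sqrt(sum(v * v for v in x) / len(x))
        assert rms(x) == pytest.approx(oracle, abs=1e-12)

    def test_mean_amplitude_alternating(self):
        assert mean_amplitude(np.array([-1.0, 1.0, -1.0, 1.0])) == 1.0

    def test_mean_amplitude_zeros(self):
        assert mean_amplitude(np.zeros(5)) == 0.0

    def test_mean_amplitude_matches_loop_oracle(self, rng):
        x = rng.normal(size=777)
        oracle = sum(abs(v) for v in x) / len(x)
        assert mean_amplitude(x) == pytest.approx(oracle, abs=1e-12)

    @pytest.mark.parametrize("fn", [rms, mean_amplitude])
    def test_empty_rejected(self, fn):
        with pytest.raises(ValueError):
            fn(np.array([]))


class TestEMThresholds:
    def test_zero_variance_wake(self):
        labels = np.array(["WAKE", "REM"], dtype=object)
        em = np.concatenate([np.zeros(N), np.ones(N)])
        thr = fit_em_thresholds(em, Hypnogram(labels), FS, EPOCH_S)
        assert thr.a_wake == 0.0
        assert thr.a_rem == pytest.approx(1.0)

    def test_standard_normal_converges_to_quantile(self, rng):
        """mean + 1.96*std of standard-normal EM samples -> 1.96."""
        n_epochs = 200
        labels = np.array(["WAKE", "REM"] * (n_epochs // 2), dtype=object)
        em = rng.standard_normal(n_epochs * N)
        thr = fit_em_thresholds(em, Hypnogram(labels), FS, EPOCH_S)
        assert thr.a_wake == pytest.approx(1.96, abs=0.05)
        assert thr.a_rem == pytest.approx(1.96, abs=0.05)

    def test_missing_rem_class(self, rng):
        labels = np.array(["WAKE", "NREM"], dtype=object)
        with pytest.raises(ThresholdFitError, match="REM"):
            fit_em_thresholds(rng.normal(size=2 * N), Hypnogram(labels), FS, EPOCH_S)


class TestEMEventFrequency:
    def test_pulse_train(self):
        x = np.zeros(N)
        for k in range(4):
            x[200 + 500 * k : 260 + 500 * k] = 5.0
        assert em_event_frequency(x, 1.0, EPOCH_S) == pytest.approx(1.0)

    def test_all_below_threshold(self, rng):
        x = rng.uniform(-0.5, 0.5, size=N)
        assert em_event_frequency(x, 1.0, EPOCH_S) == 0.0

    def test_wake_rate_recovered_from_generator(self, rng):
        """Generated wake-state EM traces carry ~0.90 events/s."""
        cfg = SynthConfig(seed=0, amplitude_jitter=0.0)
        rates = []
        # threshold between noise (std 1) and events (amp 8)
        for _ in range(80):
            _, _, em = synthesize_epoch("WAKE", cfg, rng)
            rates.append(em_event_frequency(em, 4.0, EPOCH_S))
        assert np.mean(rates) == pytest.approx(0.90, rel=0.20)


class TestFeatureMatrix:
    def _epoched(self, rng, with_em=True, n_epochs=4):
        sig = lambda: rng.normal(size=(n_epochs, N))
        return EpochedRecording(
            "m", FS, EPOCH_S, sig(), sig(), sig() if with_em else None
        )

    def test_shape_and_order(self, rng):
        ep = self._epoched(rng)
        F = extract_features(ep, EMThresholds(1.0, 1.0))
        assert F.shape == (4, 10)

    def test_em_absent_gives_null_mask_columns(self, rng):
        ep = self._epoched(rng, with_em=False)
        F = extract_features(ep)
        assert np.all(F[:, 7:10] == 0.0)
        assert np.any(F[:, :7] != 0.0)

    def test_delta_dominant_epoch_argmax(self, rng):
        cfg = SynthConfig(seed=0)
        eeg, emg, em = synthesize_epoch("NREM", cfg, rng)
        ep = EpochedRecording("m", FS, EPOCH_S, eeg[None], emg[None], em[None])
        F = extract_features(ep, EMThresholds(3.0, 3.0))
        assert int(np.argmax(F[0, :4])) == 0  # delta column

    def test_epoch_order_invariance(self, rng):
        ep = self._epoched(rng, n_epochs=6)
        thr = EMThresholds(1.0, 1.5)
        F = extract_features(ep, thr)
        perm = np.array([3, 1, 5, 0, 2, 4])
        ep2 = EpochedRecording(
            "m", FS, EPOCH_S, ep.eeg[perm], ep.emg[perm], ep.em[perm]
        )
        np.testing.assert_allclose(extract_features(ep2, thr), F[perm], rtol=1e-12)

    def test_missing_thresholds_with_em_channel(self, rng):
        with pytest.raises(ConfigurationError):
            extract_features(self._epoched(rng))


class TestMasking:
    def test_masks_em_columns_only(self, rng):
        F = rng.normal(size=(20, 10))
        M = mask_em_features(F)
        assert np.all(M[:, 7:10] == 0.0)
        np.testing.assert_array_equal(M[:, :7], F[:, :7])

    def test_idempotent(self, rng):
        F = rng.normal(size=(5, 10))
        np.testing.assert_array_equal(mask_em_features(mask_em_features(F)),
                                      mask_em_features(F))

    def test_wrong_width(self, rng):
        with pytest.raises(ValueError):
            mask_em_features(rng.normal(size=(5, 8)))


class TestStateRanking:
    def test_feature_means_rank_states_as_expected(self, rng):
        """theta/delta: REM > WAKE > NREM; EMG RMS: WAKE highest;
        wake-threshold EM rate: WAKE highest."""
        cfg = SynthConfig(seed=0)
        per_state = {}
        thr = EMThresholds(4.0, 4.0)
        for state in ("WAKE", "NREM", "REM"):
            epochs = [synthesize_epoch(state, cfg, rng) for _ in range(40)]
            ep = EpochedRecording(
                "m", FS, EPOCH_S,
                np.stack([e[0] for e in epochs]),
                np.stack([e[1] for e in epochs]),
                np.stack([e[2] for e in epochs]),
            )
            per_state[state] = extract_features(ep, thr).mean(axis=0)
        f5 = {s: v[4] for s, v in per_state.items()}
        assert f5["REM"] > f5["WAKE"] > f5["NREM"]
        f6 = {s: v[5] for s, v in per_state.items()}
        assert f6["WAKE"] > max(f6["NREM"], f6["REM"])
        f9 = {s: v[8] for s, v in per_state.items()}
        assert f9["WAKE"] == max(f9.values())


class TestFeatureScaler:
    def test_null_mask_sits_at_column_mean(self, rng):
        F = rng.normal(loc=5.0, size=(200, 10))
        scaler = FeatureScaler().fit(F)
        Z = scaler.transform(F)
        np.testing.assert_allclose(Z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(Z.std(axis=0), 1.0, atol=1e-9)
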