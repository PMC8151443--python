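"""Synthetic-cohort generator: hypnogram law, spectra, corruption, determinism."""

import numpy as np
import pytest

import sleepband as sb
from sleepband.cleaning import CleaningThresholds, detect_corrupted
from sleepband.constants import STAGES
from sleepband.synthetic import CLINICAL_STAGE_DISTRIBUTION, transition_matrix


def _profiles_with_matrix(P):
    profs = sb.default_profiles()
    return [
        sb.StageProfile(
            stage=p.stage,
            band_powers=p.band_powers,
            amplitude_scale=p.amplitude_scale,
            transition_row=P[i],
        )
        for i, p in enumerate(profs)
    ]


class TestHypnogram:
    def test_absorbing_chain_stays_in_start_stage(self):
        profs = _profiles_with_matrix(np.eye(5))
        hyp = sb.generate_hypnogram(profs, 10, seed=0)
        assert list(hyp.stages) == ["W"] * 10

    def test_uniform_chain_visits_stages_equally(self):
        profs = _profiles_with_matrix(np.full((5, 5), 0.2))
        hyp = sb.generate_hypnogram(profs, 50_000, seed=1)
        for s in STAGES:
            assert np.mean(hyp.stages == s) == pytest.approx(0.2, abs=0.01)

    def test_stationary_law_matches_clinical_distribution(self):
        hyp = sb.generate_hypnogram(sb.default_profiles(), 100_000, seed=2)
        for s, target in CLINICAL_STAGE_DISTRIBUTION.items():
            assert np.mean(hyp.stages == s) == pytest.approx(target, abs=0.01)

    def test_transition_matrix_has_requested_stationary_law(self):
        P = transition_matrix()
        pi = np.array([CLINICAL_STAGE_DISTRIBUTION[s] for s in STAGES])
        assert np.allclose(pi @ P, pi)
        assert np.all(np.diag(P) >= 0.85)

    def test_invalid_transition_matrix_rejected(self):
        bad = np.full((5, 5), 0.3)
        with pytest.raises(ValueError):
            _profiles_with_matrix(bad)


class TestStageSignal:
    def test_delta_dominant_profile_concentrates_power_below_4hz(self, profiles):
        n3 = profiles[STAGES.index("N3")]
        sig = sb.generate_stage_signal(n3, 30, 500, seed=3)
        freqs = np.fft.rfftfreq(sig.shape[1], 1 / 500)
        power = np.abs(np.fft.rfft(sig[0])) ** 2
        assert power[freqs < 4.0].sum() / power.sum() >= 0.80

    def test_zero_channel_noise_gives_identical_channels(self, profiles):
        sig = sb.generate_stage_signal(profiles[0], 30, 500, seed=4, channel_noise_ratio=0.0)
        assert np.array_equal(sig[0], sig[1])

    def test_rms_matches_amplitude_scale(self, profiles):
        for p in profiles:
            sig = sb.generate_stage_signal(p, 60, 500, seed=5)
            rms = np.sqrt(np.mean(sig**2))
            assert rms == pytest.approx(p.amplitude_scale, rel=0.05)

    def test_clean_epoch_correlation_high(self, profiles):
        sig = sb.generate_stage_signal(profiles[2], 300, 500, seed=6)
        for i in range(10):
            seg = sig[:, i * 15000 : (i + 1) * 15000]
            assert np.corrcoef(seg)[0, 1] >= 0.9

    def test_spectral_fidelity_of_band_fractions(self, profiles):
        """100-epoch-average relative band power within 10% of the profile."""
        for p in profiles:
            sig = sb.generate_stage_signal(p, 100 * 30, 500, seed=7)
            freqs = np.fft.rfftfreq(sig.shape[1], 1 / 500)
            power = np.abs(np.fft.rfft(sig[0])) ** 2
            total = power[(freqs >= 0.5) & (freqs < 12)].sum()
            for (lo, hi), frac in p.band_powers.items():
                got = power[(freqs >= lo) & (freqs < hi)].sum() / total
                assert got == pytest.approx(frac, abs=0.1 * max(frac, 0.1))

    def test_duration_must_be_epoch_multiple(self, profiles):
        with pytest.raises(ValueError):
            sb.generate_stage_signal(profiles[0], 45, 500, seed=0)


class TestInjectCorruption:
    def _recording(self, n_epochs=100, fs=100.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(n_epochs * 30 * fs)
        return sb.Recording(
            subject_id="X",
            device="HB",
            channel_names=("F3-A1", "F4-A2"),
            sample_rate=fs,
            signal=10.0 * rng.standard_normal((2, n)),
        )

    def test_zero_fraction_is_identity(self):
        rec = self._recording()
        out, idx = sb.inject_corruption(rec, sb.CorruptionSpec(fraction_of_epochs=0.0), seed=1)
        assert idx.size == 0
        assert np.array_equal(out.signal, rec.signal)

    def test_fixed_fraction_gives_exact_deterministic_count(self):
        rec = self._recording(n_epochs=1000)
        spec = sb.CorruptionSpec(fraction_of_epochs=0.1)
        _, idx1 = sb.inject_corruption(rec, spec, seed=7)
        _, idx2 = sb.inject_corruption(rec, spec, seed=7)
        assert idx1.size == 100
        assert np.array_equal(idx1, idx2)

    def test_artifact_amplitude_exceeds_physiological_range(self):
        """150 µV RMS artifact pushes mean |amplitude| above the ~100 µV
        ceiling of ordinary EEG."""
        rec = self._recording(n_epochs=50)
        spec = sb.CorruptionSpec(fraction_of_epochs=0.2, artifact_rms=150.0, affected_channel="2")
        out, idx = sb.inject_corruption(rec, spec, seed=3)
        fs = int(rec.sample_rate)
        for i in idx:
            seg = out.signal[1, i * 30 * fs : (i + 1) * 30 * fs]
            assert np.mean(np.abs(seg)) > 100.0

    def test_rail_drift_artifact_hits_target_rms(self):
        rec = self._recording(n_epochs=20)
        spec = sb.CorruptionSpec(
            fraction_of_epochs=0.5, artifact_rms=200.0, artifact_kind="rail_drift"
        )
        out, idx = sb.inject_corruption(rec, spec, seed=4)
        fs = int(rec.sample_rate)
        i = idx[0]
        ch = 0 if not np.array_equal(
            out.signal[0, i * 30 * fs : (i + 1) * 30 * fs],
            rec.signal[0, i * 30 * fs : (i + 1) * 30 * fs],
        ) else 1
        seg = out.signal[ch, i * 30 * fs : (i + 1) * 30 * fs]
        assert np.sqrt(np.mean(seg**2)) == pytest.approx(200.0, rel=0.01)

    def test_full_fraction_warns(self):
        rec = self._recording(n_epochs=10)
        with pytest.warns(UserWarning):
            sb.inject_corruption(rec, sb.CorruptionSpec(fraction_of_epochs=1.0), seed=0)


class TestCohort:
    def test_shapes_one_hour(self):
        cfg = sb.SyntheticCohortConfig(n_subjects=2, record_hours=1.0, seed=0)
        cohort = sb.generate_cohort(cfg)
        assert len(cohort) == 2
        for s in cohort:
            assert len(s.hypnogram) == 120
            assert s.recording.n_samples == int(3600 * cfg.sample_rate)

    def test_same_seed_bit_identical_different_subjects_differ(self):
        cfg = sb.SyntheticCohortConfig(n_subjects=2, record_hours=0.5, seed=11)
        a = sb.generate_cohort(cfg)
        b = sb.generate_cohort(cfg)
        for x, y in zip(a, b):
            assert np.array_equal(x.recording.signal, y.recording.signal)
            assert list(x.hypnogram.stages) == list(y.hypnogram.stages)
        assert not np.array_equal(a[0].recording.signal, a[1].recording.signal)

    def test_rejects_single_subject(self):
        with pytest.raises(ValueError):
            sb.SyntheticCohortConfig(n_subjects=1)

    def test_clean_epochs_pass_validity_rule(self, small_cohort):
        """Uncorrupted generated epochs pass the (0.9, 40 µV) rule >= 99%."""
        thr = CleaningThresholds()
        total = flagged = 0
        for epochs in small_cohort:
            rep = detect_corrupted(epochs, thr)
            total += epochs.n_epochs
            flagged += len(rep.flagged)
        assert flagged / total <= 0.01

    def test_device_shift_produces_psg_rendering(self):
        cfg = sb.SyntheticCohortConfig(
            n_subjects=2, record_hours=0.5, seed=5, device_shift=sb.DeviceShift()
        )
        cohort = sb.generate_cohort(cfg)
        s = cohort[0]
        assert s.psg_recording is not None
        assert s.psg_recording.device == "PSG"
        assert s.recording.device == "HB"
        # HB rendering is gain-scaled + noise, so strictly larger RMS
        assert np.std(s.recording.signal) > np.std(s.psg_recording.signal)

    def test_nearest_centroid_on_band_powers_separates_stages(self, small_cohort):
        """The default profiles are separable: a trivial nearest-centroid
        classifier on relative band powers exceeds 90% stage accuracy."""
        from scipy import signal as sps

        def band_powers(data):
            freqs, psd = sps.welch(data, fs=25.0, nperseg=100, axis=1)
            edges = np.linspace(0.5, 12.0, 12)
            cols = []
            for i in range(11):
                mask = (freqs >= edges[i]) & (freqs < edges[i + 1] + (1e-9 if i == 10 else 0))
                cols.append(psd[:, mask, :].sum(axis=1))
            bp = np.stack(cols, axis=1)  # (n, 11, 2)
            rel = bp / bp.sum(axis=1, keepdims=True)
            return rel.reshape(len(data), -1)

        train = sb.EpochArray.concatenate(small_cohort[:2])
        test = small_cohort[2]
        ftr, fte = band_powers(train.data), band_powers(test.data)
        centroids = {s: ftr[train.labels == s].mean(axis=0) for s in set(train.labels)}
        names = list(centroids)
        C = np.stack([centroids[s] for s in names])
        pred = np.array(names)[np.linalg.norm(fte[:, None] - C[None], axis=2).argmin(axis=1)]
        assert np.mean(pred == test.labels) > 0.90
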