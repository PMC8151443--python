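"""Correlation/amplitude cleaning rule, repair policy, threshold grid search."""

import numpy as np
import pytest

import sleepband as sb
from sleepband.cleaning import CleaningThresholds, detect_corrupted, repair

from conftest import make_epoch, sine


def _epochs(list_of_epochs, labels=None, device="HB"):
    data = np.stack(list_of_epochs)
    return sb.EpochArray(
        data=data,
        labels=np.array(labels or ["N2"] * len(data)),
        subject_id="T",
        device=device,
    )


def _noisy(rng, amp):
    return amp * rng.standard_normal(750)


class TestEpochStats:
    def test_identical_channels_correlate_perfectly(self, rng):
        x = _noisy(rng, 10)
        corr, a1, a2 = sb.epoch_stats(make_epoch(x, x))
        assert corr == pytest.approx(1.0)
        assert a1 == a2

    def test_mirrored_channel_gives_minus_one(self, rng):
        x = _noisy(rng, 10)
        corr, _, _ = sb.epoch_stats(make_epoch(x, -x))
        assert corr == pytest.approx(-1.0)

    def test_mean_amplitude_of_unit_sine_is_two_over_pi(self):
        x = sine(2.0)  # integer cycles over 30 s
        _, a1, _ = sb.epoch_stats(make_epoch(x, x))
        # 25 Hz sampling discretizes the rectified sine slightly
        assert a1 == pytest.approx(2 / np.pi, rel=5e-3)

    def test_zero_variance_channel_reports_zero_correlation(self):
        corr, _, _ = sb.epoch_stats(make_epoch(np.zeros(750), sine(2.0)))
        assert corr == 0.0

    def test_nonfinite_epoch_rejected(self):
        bad = np.full((750, 2), np.nan)
        with pytest.raises(ValueError):
            sb.epoch_stats(bad)


class TestDetectRule:
    """Truth table of the conjunction: flag iff low correlation AND at
    least one loud channel."""

    def _cases(self, rng):
        quiet = _noisy(rng, 10)  # mean |x| ~ 8 µV
        loud = _noisy(rng, 150)  # mean |x| ~ 120 µV
        return {
            "corr_hi_amp_lo": make_epoch(quiet, quiet),
            "corr_hi_amp_hi": make_epoch(loud, loud),
            "corr_lo_amp_lo": make_epoch(quiet, _noisy(rng, 10)),
            "corr_lo_amp_hi": make_epoch(quiet, _noisy(rng, 150)),
        }

    def test_only_low_corr_and_high_amp_is_flagged(self, rng):
        cases = self._cases(rng)
        ep = _epochs(list(cases.values()))
        rep = detect_corrupted(ep, CleaningThresholds())
        assert rep.flagged.tolist() == [3]

    def test_high_amplitude_alone_is_not_flagged(self, rng):
        loud = _noisy(rng, 150)
        rep = detect_corrupted(_epochs([make_epoch(loud, loud)]), CleaningThresholds())
        assert rep.flagged.size == 0

    def test_low_correlation_alone_is_not_flagged(self, rng):
        rep = detect_corrupted(
            _epochs([make_epoch(_noisy(rng, 10), _noisy(rng, 10))]), CleaningThresholds()
        )
        assert rep.flagged.size == 0

    @pytest.mark.parametrize("corr_pair", [(0.6, 0.9), (0.7, 0.8)])
    @pytest.mark.parametrize("amp_pair", [(30.0, 60.0), (40.0, 50.0)])
    def test_monotonicity_in_both_thresholds(self, rng, corr_pair, amp_pair):
        """Raising min_correlation can only grow the flagged set; raising
        max_amplitude can only shrink it."""
        eps = [make_epoch(_noisy(rng, a), _noisy(rng, b))
               for a, b in [(10, 10), (10, 60), (40, 45), (10, 150), (80, 90), (20, 35)]]
        ep = _epochs(eps)
        lo_c, hi_c = corr_pair
        lo_a, hi_a = amp_pair
        f = lambda c, a: set(
            detect_corrupted(ep, CleaningThresholds(c, a)).flagged.tolist()
        )
        assert f(lo_c, lo_a) <= f(hi_c, lo_a)
        assert f(lo_c, hi_a) <= f(lo_c, lo_a)


class TestRepair:
    def test_corrupted_channel_replaced_by_valid_one(self, rng):
        quiet = _noisy(rng, 10)
        ep = _epochs([make_epoch(quiet, _noisy(rng, 150))])
        rep = detect_corrupted(ep, CleaningThresholds())
        out, rep = repair(ep, rep)
        assert rep.actions == ["repaired_ch2"]
        assert np.array_equal(out.data[0, :, 0], out.data[0, :, 1])
        corr, _, _ = sb.epoch_stats(out.data[0])
        assert corr == pytest.approx(1.0)

    def test_empty_flagged_set_is_identity(self, rng):
        ep = _epochs([make_epoch(_noisy(rng, 10), _noisy(rng, 10))])
        rep = detect_corrupted(ep, CleaningThresholds())
        out, _ = repair(ep, rep)
        assert np.array_equal(out.data, ep.data)

    def test_double_corruption_drops_the_epoch(self, rng):
        quiet = _noisy(rng, 10)
        ep = _epochs(
            [make_epoch(quiet, quiet), make_epoch(_noisy(rng, 200), _noisy(rng, 200))],
            labels=["W", "N2"],
        )
        rep = detect_corrupted(ep, CleaningThresholds())
        out, rep = repair(ep, rep)
        assert out.n_epochs == 1
        assert list(out.labels) == ["W"]
        assert rep.actions[1] == "dropped"

    def test_repair_is_idempotent(self, rng):
        eps = [
            make_epoch(_noisy(rng, 10), _noisy(rng, 150)),
            make_epoch(_noisy(rng, 120), _noisy(rng, 130)),
            make_epoch(_noisy(rng, 10), _noisy(rng, 10)),
        ]
        ep = _epochs(eps)
        out, _ = sb.clean_epochs(ep, CleaningThresholds())
        rep2 = detect_corrupted(out, CleaningThresholds())
        assert rep2.flagged.size == 0

    def test_psg_data_requires_override(self, rng):
        ep = _epochs([make_epoch(_noisy(rng, 10), _noisy(rng, 10))], device="PSG")
        with pytest.raises(ValueError):
            sb.clean_epochs(ep)
        out, _ = sb.clean_epochs(ep, force=True)
        assert out.n_epochs == 1


class TestGridSearch:
    def test_default_grid_enumerates_sixteen_combinations(self):
        calls = []

        def eval_fn(cohort, thr):
            calls.append((thr.min_correlation, thr.max_amplitude))
            return 50.0, 1.0

        res = sb.threshold_grid_search(None, eval_fn)
        assert len(res.grid) == 16
        assert len(set(calls)) == 16

    def test_single_point_grid(self):
        res = sb.threshold_grid_search(
            None, lambda c, t: (80.0, 0.0), corr_values=(0.9,), amp_values=(40.0,)
        )
        assert len(res.grid) == 1
        assert res.best == CleaningThresholds(0.9, 40.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            sb.threshold_grid_search(None, lambda c, t: (0, 0), corr_values=())

    def test_tie_break_prefers_strict_correlation_then_low_amplitude(self):
        res = sb.threshold_grid_search(None, lambda c, t: (50.0, 0.0))
        assert res.best == CleaningThresholds(0.9, 30.0)

    def test_best_thresholds_separate_injected_corruption(self):
        """Grid search scored against ground truth recovers thresholds that
        flag >= 95% of injected corrupt epochs and < 2% of clean ones."""
        cfg = sb.SyntheticCohortConfig(
            n_subjects=2,
            record_hours=0.5,
            seed=13,
            corruption=sb.CorruptionSpec(fraction_of_epochs=0.15, artifact_rms=150.0),
        )
        cohort = sb.generate_cohort(cfg)
        prepped = [
            (sb.preprocess_recording(s.recording, s.hypnogram), set(s.corrupt_epochs.tolist()))
            for s in cohort
        ]

        def flag_accuracy(cohort_, thr):
            accs = []
            for epochs, truth in cohort_:
                rep = detect_corrupted(epochs, thr)
                flagged = set(epochs.epoch_index[rep.flagged].tolist())
                correct = sum(
                    (i in flagged) == (i in truth) for i in epochs.epoch_index.tolist()
                )
                accs.append(100.0 * correct / epochs.n_epochs)
            return float(np.mean(accs)), float(np.std(accs))

        res = sb.threshold_grid_search(prepped, flag_accuracy)
        hits = misses = clean_flagged = clean_total = 0
        for epochs, truth in prepped:
            rep = detect_corrupted(epochs, res.best)
            flagged = set(epochs.epoch_index[rep.flagged].tolist())
            hits += len(flagged & truth)
            misses += len(truth - flagged)
            clean = set(epochs.epoch_index.tolist()) - truth
            clean_flagged += len(flagged & clean)
            clean_total += len(clean)
        assert hits / (hits + misses) >= 0.95
        assert clean_flagged / clean_total < 0.02
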