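"""Generator contracts: schedules, kernels, determinism, noise scaling."""

import numpy as np
import pytest

from dcpot import (
    AEPKernelParams,
    ShiftEntry,
    SimConfig,
    ValidationError,
    aep_kernel,
    build_effect_schedule,
    inject_artifacts,
    simulate_session,
    slow_shift_kernel,
)
from dcpot.io import SESSION_DAYS
from dcpot.simulate import pink_noise

FS = 500.0


class TestEffectSchedule:
    def test_covers_all_22_pairs_and_peaks_day4(self):
        sched = build_effect_schedule(SimConfig())
        assert len(sched.entries) == 22
        amps = {
            d: abs(sched[(f"conditioning{d}", "rewarded")].amp_uv) for d in range(1, 6)
        }
        assert max(amps.values()) == amps[4]

    def test_independent_day_tone_identical(self):
        sched = build_effect_schedule(SimConfig())
        assert sched[("independent", "rewarded")] == sched[("independent", "unrewarded")]

    def test_extinction_day2_within_no_difference_tolerance(self):
        sched = build_effect_schedule(SimConfig())
        diff = abs(
            sched[("extinction2", "rewarded")].amp_uv
            - sched[("extinction2", "unrewarded")].amp_uv
        )
        assert diff <= sched.no_difference_tol_uv

    def test_rewarded_dominates_after_divergence(self):
        sched = build_effect_schedule(SimConfig())
        for d in (3, 4, 5):
            assert abs(sched[(f"conditioning{d}", "rewarded")].amp_uv) >= abs(
                sched[(f"conditioning{d}", "unrewarded")].amp_uv
            )


class TestAEPKernel:
    def test_p1_peak_location_and_zero_onset(self):
        k = aep_kernel(AEPKernelParams(), FS)
        t_ms = np.arange(len(k)) * 1000.0 / FS
        win = (t_ms >= 20) & (t_ms < 80)
        assert abs(t_ms[win][np.argmax(k[win])] - 47.0) <= 2.0
        assert k[0] == 0.0

    def test_zero_amplitudes_give_zero_waveform(self):
        params = AEPKernelParams(p1_amp_uv=0.0, n1_amp_uv=0.0, p2_amp_uv=0.0)
        assert np.all(aep_kernel(params, FS) == 0.0)

    def test_doubling_p1_doubles_early_peak_exactly(self):
        base = AEPKernelParams()
        doubled = AEPKernelParams(p1_amp_uv=2 * base.p1_amp_uv)
        t_ms = np.arange(int(FS)) * 1000.0 / FS
        win = (t_ms >= 20) & (t_ms < 80)
        assert aep_kernel(doubled, FS)[win].max() == pytest.approx(
            2 * aep_kernel(base, FS)[win].max(), rel=1e-12
        )

    def test_unordered_latencies_rejected(self):
        with pytest.raises(ValidationError, match="ordered"):
            AEPKernelParams(p1_latency_ms=100.0, n1_latency_ms=90.0)


class TestSlowShiftKernel:
    def test_sustained_holds_plateau(self):
        k = slow_shift_kernel(ShiftEntry(-60.0, "sustained"), FS)
        assert k[-1] == -60.0
        t_ms = np.arange(len(k)) * 1000.0 / FS
        assert np.all(k[t_ms < 300.0] == 0.0)

    def test_reduced_matches_closed_form_exponential(self):
        entry = ShiftEntry(-60.0, "reduced", decay_tau_ms=400.0)
        k = slow_shift_kernel(entry, FS)
        t_ms = np.arange(len(k)) * 1000.0 / FS
        late = t_ms >= 600.0
        np.testing.assert_allclose(
            k[late], -60.0 * np.exp(-(t_ms[late] - 600.0) / 400.0), rtol=1e-12
        )
        # extrapolating the closed form to 1000 ms gives -60/e
        assert -60.0 * np.exp(-400.0 / 400.0) == pytest.approx(-22.0728, abs=1e-3)

    def test_zero_amplitude_is_all_zero(self):
        assert np.all(slow_shift_kernel(ShiftEntry(0.0, "reduced"), FS) == 0.0)

    def test_invalid_timing_rejected(self):
        with pytest.raises(ValidationError):
            ShiftEntry(-60.0, "sustained", onset_ms=700.0, plateau_ms=600.0)


class TestSimulateSession:
    def test_conditioning_schedule_contract(self, tiny_config):
        cfg = tiny_config.replace(n_trials_per_tone=20)
        rec, events, _ = simulate_session(cfg, "conditioning1", "S01")
        assert len(events) == 40
        gaps = np.diff(events.onsets)
        assert gaps.min() >= 10.0 - 1e-6 and gaps.max() <= 14.0 + 1e-6
        assert events.df["stim_followed"].sum() == 20
        assert set(events.df.loc[events.df.stim_followed, "tone"]) == {"rewarded"}
        events.check_within(rec)

    def test_same_seed_bit_identical(self, tiny_config):
        a_rec, a_ev, a_log = simulate_session(tiny_config, "conditioning3", "S02")
        b_rec, b_ev, b_log = simulate_session(tiny_config, "conditioning3", "S02")
        assert np.array_equal(a_rec.data, b_rec.data)
        assert a_ev.df.equals(b_ev.df)
        assert a_log.equals(b_log)

    def test_unknown_session_is_key_error(self, tiny_config):
        with pytest.raises(KeyError):
            simulate_session(tiny_config, "conditioning7", "S01")

    def test_noise_free_signal_is_pure_kernel_superposition(self):
        """With all noise sources off, the signal equals the summed kernels."""
        cfg = SimConfig(
            n_subjects=1,
            include_noisy_subject=False,
            n_trials_per_tone=5,
            channels=("frontal",),
            noise_sd=0.0,
            drift_amp_uv=0.0,
            artifact_rate_per_min=0.0,
            subject_scale_sd=0.0,
            rng_seed=5,
        )
        rec, events, log = simulate_session(cfg, "extinction3", "S01")
        assert len(log) == 0
        from dcpot.simulate import build_effect_schedule

        sched = build_effect_schedule(cfg)
        expected = np.zeros(rec.n_samples)
        for onset, tone in zip(events.onsets, events.df["tone"]):
            s0 = int(np.ceil(onset * FS - 1e-9))
            kern = aep_kernel(cfg.aep_params["frontal"], FS) + slow_shift_kernel(
                sched[("extinction3", tone)], FS
            )
            expected[s0 : s0 + len(kern)] += kern
        np.testing.assert_allclose(rec.data[0], expected, atol=1e-12)

    def test_averaged_noise_shrinks_with_sqrt_n(self):
        """SD of N-trial averages of the generator's noise scales as
        1/sqrt(N) within 20% for N in {10, 50, 150}.

        Trial values are baseline-corrected window means (how trials enter
        every DC metric); the per-epoch baseline subtraction is what removes
        the long-range 1/f component that would otherwise couple trials.
        Group SDs are estimated over random disjoint partitions.
        """
        from dcpot import extract_epochs

        silent = {day: ((0.0, "sustained"), (0.0, "sustained")) for day in SESSION_DAYS}
        cfg = SimConfig(
            n_subjects=1,
            include_noisy_subject=False,
            n_trials_per_tone=1500,
            channels=("frontal",),
            noise_sd=5.0,
            artifact_rate_per_min=0.0,
            subject_scale_sd=0.0,
            shift_overrides=silent,
            rng_seed=9,
        )
        rec, events, _ = simulate_session(cfg, "extinction3", "S01")
        epochs = extract_epochs(rec, events)
        t = epochs.times_ms
        base, win = (t >= -500) & (t < 0), (t >= 300) & (t < 1000)
        x = epochs.data[:, 0, :]
        trial_means = x[:, win].mean(axis=1) - x[:, base].mean(axis=1)
        sd1 = trial_means.std()
        rng = np.random.default_rng(0)
        for n_avg in (10, 50, 150):
            collected = []
            for _ in range(40):
                perm = rng.permutation(len(trial_means))
                usable = (len(trial_means) // n_avg) * n_avg
                collected.append(
                    trial_means[perm][:usable].reshape(-1, n_avg).mean(axis=1)
                )
            measured = np.concatenate(collected).std()
            assert measured == pytest.approx(sd1 / np.sqrt(n_avg), rel=0.20)


class TestInjectArtifacts:
    def test_rate_zero_is_identity(self, flat_recording):
        rec, _ = flat_recording
        out, log = inject_artifacts(rec, 0.0, 500.0, np.random.default_rng(0))
        assert len(log) == 0
        assert np.array_equal(out.data, rec.data)

    def test_seeded_poisson_count_and_sorted_log(self, flat_recording):
        rec, _ = flat_recording
        rng = np.random.default_rng(42)
        expected_count = np.random.default_rng(42).poisson(
            2.0 * rec.duration_s / 60.0
        )
        out, log = inject_artifacts(rec, 2.0, 500.0, rng)
        assert len(log) == expected_count
        assert np.all(np.diff(log["onset"]) >= 0)

    def test_artifacts_exceed_p2p_criterion(self):
        """500-uV artifacts on 5-uV noise always break a 300-uV threshold."""
        rng = np.random.default_rng(3)
        rec_data = pink_noise(30000, 5.0, 1.0, rng)[None, :]
        from dcpot import Recording

        rec = Recording(channels=["frontal"], fs=FS, data=rec_data)
        out, log = inject_artifacts(rec, 30.0, 500.0, rng)
        assert len(log) > 0
        for onset, dur in zip(log["onset"], log["duration_s"]):
            a = int(onset * FS)
            b = a + int(round(dur * FS))
            seg = out.data[0, a:b]
            assert seg.max() - out.data[0].min() > 300.0 or out.data[0].max() - seg.min() > 300.0
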