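"""Statistical structure and determinism of the night simulator."""

import numpy as np
import pytest

from somnoloop import (
    SimConfig, VirtualSleeper,
    inject_artifacts, simulate_closed_loop_step, simulate_hypnogram,
    simulate_night, stationary_distribution, synthesize_exg, synthesize_vitals,
)
from somnoloop.features import band_powers
from somnoloop.signal_io import EXG_CHANNELS, Hypnogram, stage_indices
from somnoloop.synthetic_psg import _apply_event


class TestHypnogram:
    def test_absorbing_chain_stays_in_first_sleep_stage(self):
        tm = np.eye(4)
        tm[0] = [0.0, 1.0, 0.0, 0.0]  # W exits to LS, LS absorbing
        cfg = SimConfig(seed=3, duration_min=60, transition_matrix=tm)
        h = simulate_hypnogram(cfg)
        idx = stage_indices(h.stages)
        first_sleep = np.argmax(idx != 0)
        assert first_sleep > 0
        assert all(s == "LS" for s in h.stages[first_sleep:])

    def test_proportions_match_stationary_distribution(self):
        cfg = SimConfig(seed=7, duration_min=480)
        h = simulate_hypnogram(cfg)
        pi = stationary_distribution(cfg.transition_matrix)
        idx = stage_indices(h.stages)
        emp = np.bincount(idx, minlength=4) / len(idx)
        assert np.all(np.abs(emp - pi) < 0.05 + 0.0)  # within 5 points

    def test_deterministic_under_seed(self):
        cfg = SimConfig(seed=11, duration_min=120)
        assert simulate_hypnogram(cfg) == simulate_hypnogram(cfg)

    def test_initial_wake_run_present(self):
        cfg = SimConfig(seed=5, duration_min=120)
        h = simulate_hypnogram(cfg)
        assert h.stages[0] == "W"

    def test_absorbing_wake_warns_but_generates(self):
        tm = np.eye(4)
        cfg = SimConfig(seed=1, duration_min=60, transition_matrix=tm)
        with pytest.warns(UserWarning, match="absorbing"):
            h = simulate_hypnogram(cfg)
        assert len(h) == 120


class TestExG:
    def _dominant_relative(self, cfg, stage):
        h = Hypnogram([stage] * 4)
        rec = synthesize_exg(h, cfg)
        _, rel = band_powers(rec.exg["FH_L"][:6000], rec.exg_rate)
        return rel

    def test_deep_sleep_is_delta_dominant(self):
        cfg = SimConfig(seed=2, noise_uv=1.0)
        rel = self._dominant_relative(cfg, "DS")
        assert max(rel, key=rel.get) == "Delta"
        assert rel["Delta"] > 0.8

    def test_wake_without_alpha_or_sources_is_flat(self):
        from somnoloop.features import BANDS
        amps = dict(SimConfig().amplitudes)
        amps.update(alpha_uv=0.0, blink_uv=0.0, emg_uv=1.0)
        cfg = SimConfig(seed=2, amplitudes=amps, noise_uv=0.0)
        h = Hypnogram(["W"] * 4)
        rec = synthesize_exg(h, cfg)
        absolute, _ = band_powers(rec.exg["FH_L"][:6000], rec.exg_rate)
        # white muscle noise only: power *density* near-equal across bands
        density = {b: absolute[b] / (hi - lo)
                   for b, (lo, hi) in BANDS.items()}
        vals = sorted(density.values())
        assert vals[-1] < 2 * vals[0]

    def test_sample_for_sample_reproducible(self):
        cfg = SimConfig(seed=9, duration_min=30)
        h = simulate_hypnogram(cfg)
        a = synthesize_exg(h, cfg)
        b = synthesize_exg(h, cfg)
        for ch in EXG_CHANNELS:
            assert np.array_equal(a.exg[ch], b.exg[ch])


class TestVitals:
    def test_ppg_fundamental_at_heart_rate(self):
        cfg = SimConfig(seed=4, duration_min=10,
                        hr_by_stage={s: (60.0, 0.0) for s in "W LS DS R".split()})
        h = Hypnogram(["LS"] * 20)
        ppg, _, _ = synthesize_vitals(h, cfg)
        f = np.fft.rfftfreq(len(ppg), 1 / cfg.ppg_rate)
        spec = np.abs(np.fft.rfft(ppg - ppg.mean()))
        sel = (f > 0.3) & (f < 3.0)
        assert f[sel][np.argmax(spec[sel])] == pytest.approx(1.0, abs=0.02)

    def test_respiration_peak_at_rr(self):
        cfg = SimConfig(seed=4, duration_min=10,
                        rr_by_stage={s: (12.0, 0.0) for s in "W LS DS R".split()},
                        posture_change_prob=0.0, movement_burst_prob=0.0)
        h = Hypnogram(["LS"] * 20)
        _, acc, _ = synthesize_vitals(h, cfg)
        dyn = acc - acc.mean(axis=0)
        pc = dyn[:, np.argmax(dyn.std(axis=0))]
        f = np.fft.rfftfreq(len(pc), 1 / cfg.acc_rate)
        spec = np.abs(np.fft.rfft(pc))
        sel = (f > 0.05) & (f < 1.0)
        assert f[sel][np.argmax(spec[sel])] == pytest.approx(0.20, abs=0.02)

    def test_supine_gravity_orientation(self):
        cfg = SimConfig(seed=4, duration_min=5, posture_change_prob=0.0,
                        movement_burst_prob=0.0)
        h = Hypnogram(["LS"] * 10)
        _, acc, truth = synthesize_vitals(h, cfg)
        assert all(p == "supine" for p in truth.posture)
        g = acc.mean(axis=0)
        angle = np.degrees(np.arccos(g[2] / np.linalg.norm(g)))
        assert angle < 10.0


class TestArtifacts:
    def test_zero_rate_is_identity(self, night2h):
        cfg = SimConfig(seed=8, duration_min=30, artifact_rate=0.0)
        h = simulate_hypnogram(cfg)
        rec = synthesize_exg(h, cfg)
        out, mask = inject_artifacts(rec, cfg)
        assert not mask.mask.any()
        for ch in EXG_CHANNELS:
            assert np.array_equal(out.exg[ch], rec.exg[ch])

    def test_unmasked_samples_conserved(self, night2h):
        clean, corrupted = night2h.clean_recording, night2h.recording
        epoch_n = int(corrupted.exg_rate * 30)
        for ci, ch in enumerate(EXG_CHANNELS):
            # epochs that no event touches at all must be bit-identical
            touched = np.zeros(corrupted.n_epochs, dtype=bool)
            for ech, _k, t0, dur in night2h.mask.kinds:
                if ech == ch:
                    lo = int(t0 // 30)
                    hi = min(int(np.ceil((t0 + dur) / 30)), len(touched))
                    touched[lo:hi] = True
            for ep in np.flatnonzero(~touched):
                sl = slice(ep * epoch_n, (ep + 1) * epoch_n)
                assert np.array_equal(corrupted.exg[ch][sl], clean.exg[ch][sl])

    def test_forced_flatline_masks_expected_epochs(self):
        cfg = SimConfig(seed=8, duration_min=60, artifact_rate=0.0)
        h = simulate_hypnogram(cfg)
        rec = synthesize_exg(h, cfg)
        rng = np.random.default_rng(0)
        _apply_event(rec.exg["FH_L"], rec.exg_rate, 300.0, 300.0, "flatline", rng)
        seg = rec.exg["FH_L"][int(300 * 200):int(600 * 200)]
        assert np.all(seg == seg[0])

    def test_reproducible_under_seed(self):
        cfg = SimConfig(seed=13, duration_min=60, artifact_rate=4.0)
        h = simulate_hypnogram(cfg)
        rec = synthesize_exg(h, cfg)
        _, m1 = inject_artifacts(rec, cfg)
        _, m2 = inject_artifacts(rec, cfg)
        assert np.array_equal(m1.mask, m2.mask)
        assert m1.kinds == m2.kinds


class TestVirtualSleeper:
    def test_driftless_walk_stays_near_start(self):
        sleeper = VirtualSleeper(content_effect={"c": -0.05}, relax_rate=0.05,
                                 effect_sd=0.05)
        # relax_rate + effect = 0: pure diffusion
        finals = []
        for i in range(1000):
            rng = np.random.default_rng(i)
            x = 0.0
            for _ in range(20):
                x, _ = simulate_closed_loop_step(sleeper, "c", x, rng)
            finals.append(x)
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(np.mean(finals)) < 2 * se + 1e-9

    def test_large_drift_reaches_onset_within_50min(self):
        sleeper = VirtualSleeper(content_effect={"c": 0.10}, relax_rate=0.05,
                                 effect_sd=0.02, baseline_sol_min=40.0)
        for i in range(100):
            rng = np.random.default_rng(1000 + i)
            x = 0.0
            asleep_run = 0
            onset = None
            for ep in range(100):  # 50 min
                x, dist = simulate_closed_loop_step(sleeper, "c", x, rng)
                if np.argmax(dist) != 0:
                    asleep_run += 1
                    if asleep_run >= 3:
                        onset = ep
                        break
                else:
                    asleep_run = 0
            assert onset is not None

    def test_identical_seeds_identical_trajectories(self):
        sleeper = VirtualSleeper(content_effect={"c": 0.03})
        out = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            x, xs = 0.0, []
            for _ in range(30):
                x, _ = simulate_closed_loop_step(sleeper, "c", x, rng)
                xs.append(x)
            out.append(xs)
        assert out[0] == out[1]

    def test_unknown_content_rejected(self):
        sleeper = VirtualSleeper(content_effect={"c": 0.0})
        with pytest.raises(KeyError):
            simulate_closed_loop_step(sleeper, "zzz", 0.0,
                                      np.random.default_rng(0))


def test_whole_night_is_deterministic():
    a = simulate_night(SimConfig(seed=21, duration_min=30))
    b = simulate_night(SimConfig(seed=21, duration_min=30))
    assert a.hypnogram == b.hypnogram
    assert np.array_equal(a.recording.exg["OTE_L"], b.recording.exg["OTE_L"])
    assert np.array_equal(a.recording.ppg, b.recording.ppg)
    assert np.array_equal(a.mask.mask, b.mask.mask)
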