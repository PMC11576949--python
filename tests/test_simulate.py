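"""Synthetic-EEG generator: trial structure, determinism, spectral
shape, ground-truth recovery."""

import numpy as np
import pytest
from scipy import signal

from lithic_eeg import (
    EffectMap,
    SimulationConfig,
    align_markers,
    band_mean_table,
    baseline_correct,
    extract_step_epochs,
    reject_epochs,
    segment_trials,
    simulate_cohort,
    simulate_recording,
)
from lithic_eeg.simulate import simulate_beta_table


class TestEffectMap:
    def test_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="unknown channel"):
            EffectMap({("XX", "cut.hold"): 1.5})

    def test_unknown_condition_rejected(self):
        with pytest.raises(ValueError, match="unknown condition"):
            EffectMap({("Cz", "cut.fly"): 1.5})

    def test_default_multiplier_is_one(self):
        eff = EffectMap({("Cz", "cut.hold"): 1.5})
        assert eff.multiplier("Cz", "cut.hold") == 1.5
        assert eff.multiplier("Cz", "cut.aim") == 1.0
        assert eff.multiplier("Pz", "cut.hold") == 1.0


class TestRecordingStructure:
    def test_exact_length(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=3, seed=0)
        rec = simulate_recording(cfg, EffectMap(), "S", "cut")
        assert rec.n_samples == 3 * 20 * 250  # trials x 20 s x rate

    def test_marker_count_steps_plus_rest(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=3, seed=0)
        rec = simulate_recording(cfg, EffectMap(), "S", "nutcrack")
        assert len(rec.markers) == 3 * 4
        rec = simulate_recording(cfg, EffectMap(), "S", "control")
        assert len(rec.markers) == 3 * 2  # movement + rest

    def test_cue_pulses_coincide_with_true_onsets(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=3,
                               marker_jitter_ms=0.0, seed=0)
        rec = simulate_recording(cfg, EffectMap(), "S", "cut")
        cue = rec.audio_cue
        onsets = np.flatnonzero((cue > 0.5) & ~(np.roll(cue, 1) > 0.5))
        marker_samples = sorted(m.sample for m in rec.markers)
        assert sorted(onsets.tolist()) == marker_samples

    def test_unknown_task_rejected(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=1, seed=0)
        with pytest.raises(ValueError, match="unknown task"):
            simulate_recording(cfg, EffectMap(), "S", "juggling")


class TestDeterminismAndCohort:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=2, seed=9)
        r1 = simulate_recording(cfg, EffectMap(), "S", "cut")
        r2 = simulate_recording(cfg, EffectMap(), "S", "cut")
        assert np.array_equal(r1.data, r2.data)
        assert [m.sample for m in r1.markers] == [m.sample for m in r2.markers]

    def test_cohort_counts_and_manifest(self, tmp_path):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=1, n_subjects=3,
                               seed=1)
        recs, manifest = simulate_cohort(cfg, EffectMap(),
                                         tasks=("cut", "control"),
                                         out_dir=tmp_path)
        assert len(recs) == 3 * 2
        factors = manifest[manifest.kind == "subject_factor"]
        assert len(factors) == 3
        assert (tmp_path / "manifest.tsv").exists()
        assert (tmp_path / "S01_cut.dat").exists()

    def test_cohort_byte_identical_across_runs(self, tmp_path):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=1, n_subjects=2,
                               seed=5)
        a, _ = simulate_cohort(cfg, EffectMap(), tasks=("cut",),
                               out_dir=tmp_path / "a")
        b, _ = simulate_cohort(cfg, EffectMap(), tasks=("cut",),
                               out_dir=tmp_path / "b")
        assert (tmp_path / "a/S01_cut.dat").read_bytes() == \
            (tmp_path / "b/S01_cut.dat").read_bytes()

    def test_zero_subject_sd_gives_unit_factors(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=1, n_subjects=3,
                               inter_subject_sd=0.0, seed=1)
        _, manifest = simulate_cohort(cfg, EffectMap(), tasks=("control",))
        factors = manifest[manifest.kind == "subject_factor"].value
        assert np.allclose(factors, 1.0)

    def test_cohort_needs_two_subjects(self):
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=1, n_subjects=1,
                               seed=1)
        with pytest.raises(ValueError, match="2 subjects"):
            simulate_cohort(cfg, EffectMap(), tasks=("control",))


class TestSpectralShape:
    def test_background_follows_configured_slope(self):
        """Log-log PSD regression over 2-40 Hz recovers the 1/f exponent
        within 0.2."""
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=6,
                               alpha_uv=0.0, beta_uv=0.0, line_noise_uv=0.0,
                               blink_rate_per_min=0.0, impact_amplitude_uv=0.0,
                               seed=0)
        rec = simulate_recording(cfg, EffectMap(), "S", "cut",
                                 rng=np.random.default_rng(2),
                                 subject_factor=1.0)
        f, pxx = signal.welch(rec.data, fs=250.0, nperseg=2048, axis=1)
        sel = (f >= 2) & (f <= 40)
        slope = np.polyfit(np.log(f[sel]), np.log(pxx[:, sel].mean(axis=0)), 1)[0]
        assert abs(-slope - cfg.one_over_f_exponent) < 0.2

    def test_null_model_equal_beta_across_conditions(self):
        """Background only: downstream beta means agree across steps
        within sampling error."""
        cfg = SimulationConfig(rate=250.0, n_trials_per_task=12,
                               beta_uv=0.0, line_noise_uv=0.0,
                               blink_rate_per_min=0.0, impact_amplitude_uv=0.0,
                               seed=0)
        rec = simulate_recording(cfg, EffectMap(), "S", "cut",
                                 rng=np.random.default_rng(4),
                                 subject_factor=1.0)
        eps = reject_epochs(extract_step_epochs(
            baseline_correct(segment_trials(align_markers(rec))),
            exclusions=set()))
        bt = band_mean_table(eps, "S")
        means = bt.groupby("condition").beta_uv.mean()
        assert means.max() / means.min() < 1.10


class TestGroundTruthRecovery:
    def test_multiplier_recovered_from_band_ratio(self):
        """(FC1, cut.hold, 1.5): the FC1 hold-step band-mean ratio between
        the two tasks converges to the injected multiplier (Monte-Carlo at
        120 trials, +-10%)."""
        eff = EffectMap({("FC1", "cut.hold"): 1.5})
        cfg = SimulationConfig(rate=125.0, n_trials_per_task=120,
                               blink_rate_per_min=0.0, line_noise_uv=0.0,
                               impact_amplitude_uv=0.0, seed=0)
        vals = {}
        for task in ("cut", "nutcrack"):
            rec = simulate_recording(cfg, eff, "S", task,
                                     rng=np.random.default_rng(8),
                                     subject_factor=1.0)
            eps = reject_epochs(extract_step_epochs(
                baseline_correct(segment_trials(align_markers(rec)))))
            bt = band_mean_table(eps, "S")
            vals[task] = bt[(bt.condition == f"{task}.hold") &
                            (bt.channel == "FC1")].beta_uv.iloc[0]
        assert vals["cut"] / vals["nutcrack"] == pytest.approx(1.5, rel=0.10)

    def test_injected_channel_dominates_difference_topography(self):
        """The max |difference| channel of the grand-average beta map is
        the injected channel."""
        eff = EffectMap({("C3", "cut.aim"): 1.6})
        cfg = SimulationConfig(rate=125.0, n_trials_per_task=20,
                               blink_rate_per_min=0.0, line_noise_uv=0.0,
                               impact_amplitude_uv=0.0, seed=0)
        diffs = []
        for task in ("cut", "nutcrack"):
            rec = simulate_recording(cfg, eff, "S", task,
                                     rng=np.random.default_rng(3),
                                     subject_factor=1.0)
            eps = reject_epochs(extract_step_epochs(
                baseline_correct(segment_trials(align_markers(rec)))))
            bt = band_mean_table(eps, "S")
            diffs.append(bt[bt.condition == f"{task}.aim"]
                         .set_index("channel").beta_uv)
        delta = (diffs[0] - diffs[1]).abs()
        assert delta.idxmax() == "C3"


class TestBetaTableSurrogate:
    def test_shape_and_reproducibility(self):
        a = simulate_beta_table(5, seed=3)
        b = simulate_beta_table(5, seed=3)
        assert a.equals(b)
        assert set(a.columns) == {"subject", "condition", "channel", "beta_uv"}
        assert a.subject.nunique() == 5

    def test_multipliers_enter_means(self):
        eff = EffectMap({("Cz", "cut.hold"): 2.0})
        df = simulate_beta_table(40, eff, conditions=["cut.hold", "cut.aim"],
                                 measurement_sd=0.01, seed=0)
        wide = df.pivot_table(index="subject", columns=["condition", "channel"],
                              values="beta_uv")
        ratio = (wide[("cut.hold", "Cz")] / wide[("cut.aim", "Cz")]).mean()
        assert ratio == pytest.approx(2.0, rel=0.05)
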