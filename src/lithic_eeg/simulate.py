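"""Synthetic event-structured EEG with known ground truth.

The generator emulates the recording and trial structure of a staged
tool-use experiment: 32 channels in the 10-20 montage referenced to FCz,
2500 Hz acquisition, trials of consecutive 5-s steps (Hold / Aim /
Execute for the two tool tasks, a single Movement step for the control)
followed by a 5-s rest, a 30-ms auditory cue at every step onset, and
manually placed (jittered) markers that downstream alignment snaps to the
cue.  The signal model is:

* pink (1/f) background noise, per channel, exact spectral shaping;
* alpha-band (8-12 Hz) and beta-band (12.5-30 Hz) band-limited noise,
  independent across channels;
* the beta amplitude of a channel during a step is
  ``beta_uv x subject_factor x effect_multiplier`` — the effect map is
  the ground truth that recovery tests chase;
* common-phase 50 Hz line noise;
* eye blinks: 300-ms raised-cosine transients mixed through a fixed
  frontal spatial vector (a genuinely rank-1 artifact for ICA);
* a broadband impact artifact 400 ms into the hammerstone Execute step,
  large enough that those epochs fail the downstream amplitude criterion;
* a lognormal per-subject baseline factor producing strong
  inter-individual variability.

Everything is reproducible from the configuration seed; cohort members
get independent child seeds derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sp_signal

from .montage import Montage, load_montage
from .recording import Marker, Recording, TASK_STEPS

__all__ = [
    "EffectMap",
    "SimulationConfig",
    "simulate_recording",
    "simulate_cohort",
    "simulate_beta_table",
    "condition_ids",
]


def condition_ids(include_rest: bool = False) -> list[str]:
    out = []
    for task, steps in TASK_STEPS.items():
        out.extend(f"{task}.{s}" for s in steps)
        if include_rest:
            out.append(f"{task}.rest")
    return out


class EffectMap:
    """Ground-truth beta-amplitude multipliers per (channel, condition).

    Unlisted pairs default to 1.0.  Channels must belong to the montage
    and conditions to the declared ``task.step`` set.
    """

    def __init__(self, entries: dict[tuple[str, str], float] | None = None,
                 montage: Montage | None = None):
        self.montage = montage or load_montage("builtin-32")
        valid_conditions = set(condition_ids(include_rest=True))
        self._entries: dict[tuple[str, str], float] = {}
        for (ch, cond), mult in (entries or {}).items():
            if ch not in self.montage.channel_names:
                raise ValueError(f"unknown channel in effect map: {ch!r}")
            if cond not in valid_conditions:
                raise ValueError(f"unknown condition in effect map: {cond!r}")
            if mult < 0:
                raise ValueError("multipliers must be >= 0")
            self._entries[(ch, cond)] = float(mult)

    def multiplier(self, channel: str, condition: str) -> float:
        return self._entries.get((channel, condition), 1.0)

    @property
    def entries(self) -> dict[tuple[str, str], float]:
        return dict(self._entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"channel": c, "condition": k, "multiplier": m}
             for (c, k), m in sorted(self._entries.items())]
        )


@dataclass(frozen=True)
class SimulationConfig:
    """Study-scale defaults: 23 subjects, 50 trials/task, 2500 Hz."""

    n_subjects: int = 23
    n_trials_per_task: int = 50
    rate: float = 2500.0
    step_s: float = 5.0
    rest_s: float = 5.0
    cue_ms: float = 30.0
    one_over_f_exponent: float = 1.5
    background_uv: float = 4.0       # rms of the pink background (1-40 Hz)
    alpha_uv: float = 2.0            # rms of 8-12 Hz noise
    beta_uv: float = 3.0             # baseline rms of 12.5-30 Hz noise
    line_noise_uv: float = 2.0       # 50 Hz amplitude
    blink_rate_per_min: float = 15.0
    blink_amplitude_uv: float = 250.0
    impact_condition: str = "nutcrack.execute"
    impact_latency_ms: float = 400.0
    impact_amplitude_uv: float = 400.0
    impact_duration_ms: float = 80.0
    inter_subject_sd: float = 0.4    # lognormal sd of subject baseline
    marker_jitter_ms: float = 40.0   # sd of manual-marker placement error
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_task < 1:
            raise ValueError("n_trials_per_task must be >= 1")
        if min(self.step_s, self.rest_s, self.rate) <= 0 or self.cue_ms <= 0:
            raise ValueError("durations and rate must be positive")
        for a in ("background_uv", "alpha_uv", "beta_uv", "line_noise_uv",
                  "blink_amplitude_uv", "impact_amplitude_uv"):
            if getattr(self, a) < 0:
                raise ValueError(f"{a} must be >= 0")


def _pink_noise(rng, n_ch: int, n: int, rate: float, exponent: float,
                rms: float) -> np.ndarray:
    """Per-channel 1/f^exponent noise via exact spectral shaping."""
    white = rng.standard_normal((n_ch, n))
    X = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n, d=1.0 / rate)
    shape = np.ones_like(f)
    floor = 1.0
    nz = f > 0
    shape[nz] = np.maximum(f[nz], floor) ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(X * shape[None, :], n=n, axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return x / cur * rms


def _band_noise(rng, n_ch: int, n: int, rate: float, lo: float, hi: float
                ) -> np.ndarray:
    """Unit-rms band-limited noise per channel."""
    hi = min(hi, 0.499 * rate)
    sos = sp_signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    x = sp_signal.sosfilt(sos, rng.standard_normal((n_ch, n)), axis=1)
    cur = x.std(axis=1, keepdims=True)
    cur[cur == 0] = 1.0
    return x / cur


def _blink_weights(montage: Montage) -> np.ndarray:
    p = montage.positions3d
    try:
        mid = p[montage.index("Fp1")] + p[montage.index("Fp2")]
    except KeyError:
        mid = p[np.argmax(p[:, 1])].copy()
    mid /= np.linalg.norm(mid)
    ang = np.arccos(np.clip(p @ mid, -1.0, 1.0))
    return np.exp(-((ang / 0.9) ** 2))


def simulate_recording(
    cfg: SimulationConfig,
    effects: EffectMap,
    subject_id: str,
    task: str,
    rng: np.random.Generator | None = None,
    subject_factor: float | None = None,
) -> Recording:
    """One subject x one task continuous recording.

    The recording starts with a short lead-in (1 s, taken out of the final
    rest period) so the first trial's baseline window exists; total length
    is exactly ``n_trials x trial duration`` samples.
    """
    if task not in TASK_STEPS:
        raise ValueError(f"unknown task {task!r}")
    steps = TASK_STEPS[task]
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    montage = effects.montage
    n_ch = montage.n_channels
    rate = cfg.rate
    trial_s = cfg.step_s * len(steps) + cfg.rest_s
    n = int(round(cfg.n_trials_per_task * trial_s * rate))
    lead = int(round(min(1.0, cfg.rest_s / 2.0) * rate))
    step_n = int(round(cfg.step_s * rate))
    trial_n = int(round(trial_s * rate))

    if subject_factor is None:
        subject_factor = float(np.exp(rng.normal(0.0, cfg.inter_subject_sd))) \
            if cfg.inter_subject_sd > 0 else 1.0

    data = _pink_noise(rng, n_ch, n, rate, cfg.one_over_f_exponent,
                       cfg.background_uv * subject_factor)
    if cfg.alpha_uv > 0:
        data += cfg.alpha_uv * subject_factor * _band_noise(rng, n_ch, n, rate,
                                                            8.0, 12.0)

    # beta with per-step, per-channel amplitude envelope
    beta = _band_noise(rng, n_ch, n, rate, 12.5, 30.0)
    env = np.ones((n_ch, n))
    onsets: list[tuple[str, int]] = []       # true (condition, sample) pairs
    for t in range(cfg.n_trials_per_task):
        t0 = lead + t * trial_n
        for k, stp in enumerate(steps):
            s0 = t0 + k * step_n
            onsets.append((f"{task}.{stp}", s0))
        onsets.append((f"{task}.rest", t0 + len(steps) * step_n))
    onsets = [(c, s) for c, s in onsets if s < n]
    if cfg.beta_uv > 0:
        for ci, ch in enumerate(montage.channel_names):
            for cond, s0 in onsets:
                m = effects.multiplier(ch, cond)
                if m != 1.0:
                    env[ci, s0:min(s0 + step_n, n)] = m
        data += cfg.beta_uv * subject_factor * beta * env

    if cfg.line_noise_uv > 0:
        tvec = np.arange(n) / rate
        phase = rng.uniform(0, 2 * np.pi)
        gains = rng.uniform(0.8, 1.2, size=n_ch)
        data += cfg.line_noise_uv * gains[:, None] * np.sin(
            2 * np.pi * 50.0 * tvec + phase)[None, :]

    if cfg.blink_rate_per_min > 0 and cfg.blink_amplitude_uv > 0:
        dur_min = n / rate / 60.0
        n_blinks = rng.poisson(cfg.blink_rate_per_min * dur_min)
        blink_n = int(round(0.3 * rate))
        wave = 0.5 * (1 - np.cos(2 * np.pi * np.arange(blink_n) / blink_n))
        w = _blink_weights(montage)
        starts = rng.integers(0, max(1, n - blink_n), size=n_blinks)
        for s0 in starts:
            amp = cfg.blink_amplitude_uv * rng.uniform(0.7, 1.3)
            data[:, s0:s0 + blink_n] += amp * w[:, None] * wave[None, :]

    if cfg.impact_amplitude_uv > 0:
        imp_n = int(round(cfg.impact_duration_ms / 1000.0 * rate))
        lat_n = int(round(cfg.impact_latency_ms / 1000.0 * rate))
        w = rng.uniform(0.6, 1.0, size=n_ch)
        for cond, s0 in onsets:
            if cond != cfg.impact_condition:
                continue
            a = s0 + lat_n
            b = min(a + imp_n, n)
            if a >= n:
                continue
            burst = rng.standard_normal((n_ch, b - a))
            ramp = np.sin(np.pi * np.arange(b - a) / max(1, imp_n))
            data[:, a:b] += cfg.impact_amplitude_uv * w[:, None] * burst * ramp

    # auditory cue: square pulses at every (step and rest) onset
    cue = np.zeros(n)
    cue_n = max(1, int(round(cfg.cue_ms / 1000.0 * rate)))
    for _, s0 in onsets:
        cue[s0:s0 + cue_n] = 1.0

    # manually placed markers: jittered versions of the true onsets
    markers = []
    jit_sd = cfg.marker_jitter_ms / 1000.0 * rate
    for cond, s0 in onsets:
        jitter = int(round(np.clip(rng.normal(0, jit_sd), -3 * jit_sd, 3 * jit_sd)))
        markers.append(Marker(cond, int(np.clip(s0 + jitter, 0, n - 1)), "manual"))

    return Recording(
        data=data,
        rate=rate,
        montage=montage,
        markers=markers,
        audio_cue=cue,
    )


def simulate_cohort(
    cfg: SimulationConfig,
    effects: EffectMap,
    tasks: tuple[str, ...] = ("nutcrack", "cut", "control"),
    out_dir: str | Path | None = None,
):
    """One recording per subject per task, plus a ground-truth manifest.

    Returns ``(recordings, manifest)`` where ``recordings`` maps
    ``(subject_id, task)`` to :class:`Recording` (or to the written
    portable base path when ``out_dir`` is given) and ``manifest`` is a
    tidy TSV-ready frame of subject factors and effect multipliers.
    """
    if cfg.n_subjects < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    root = np.random.SeedSequence(cfg.seed)
    subject_seqs = root.spawn(cfg.n_subjects)
    recordings: dict[tuple[str, str], object] = {}
    rows = []
    for si, sseq in enumerate(subject_seqs):
        subject = f"S{si + 1:02d}"
        factor_rng = np.random.default_rng(sseq)
        factor = float(np.exp(factor_rng.normal(0.0, cfg.inter_subject_sd))) \
            if cfg.inter_subject_sd > 0 else 1.0
        rows.append({"kind": "subject_factor", "subject": subject,
                     "channel": "", "condition": "", "value": factor})
        for ti, task in enumerate(tasks):
            rng = np.random.default_rng(sseq.spawn(len(tasks))[ti])
            rec = simulate_recording(cfg, effects, subject, task,
                                     rng=rng, subject_factor=factor)
            if out_dir is not None:
                from .io import write_recording

                base = Path(out_dir) / f"{subject}_{task}"
                write_recording(rec, base, dialect="portable")
                recordings[(subject, task)] = base
            else:
                recordings[(subject, task)] = rec
    for (ch, cond), m in sorted(effects.entries.items()):
        rows.append({"kind": "effect", "subject": "", "channel": ch,
                     "condition": cond, "value": m})
    manifest = pd.DataFrame(rows, columns=["kind", "subject", "channel",
                                           "condition", "value"])
    if out_dir is not None:
        manifest.to_csv(Path(out_dir) / "manifest.tsv", sep="\t", index=False)
    return recordings, manifest


def simulate_beta_table(
    n_subjects: int = 23,
    effects: EffectMap | None = None,
    conditions: list[str] | None = None,
    base_uv: float = 1.2,
    inter_subject_sd: float = 0.4,
    measurement_sd: float = 0.05,
    seed: int = 0,
    montage: Montage | None = None,
) -> pd.DataFrame:
    """Subject-level beta-power table drawn from the generator's
    statistical model, bypassing the signal chain.

    Emulates what the full pipeline delivers after trial averaging: each
    entry is ``base x subject_factor x multiplier x exp(eps)`` with
    ``eps ~ N(0, measurement_sd)`` representing residual trial-sampling
    noise.  Used for large replication studies (type-I error) where
    thousands of continuous simulations would be pointlessly slow; the
    paired tests see exchangeable pairs under the null regardless of the
    noise law.
    """
    montage = montage or (effects.montage if effects else load_montage("builtin-32"))
    effects = effects or EffectMap(montage=montage)
    conditions = conditions or condition_ids()
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        subject = f"S{si + 1:02d}"
        factor = float(np.exp(rng.normal(0.0, inter_subject_sd))) \
            if inter_subject_sd > 0 else 1.0
        for cond in conditions:
            eps = rng.normal(0.0, measurement_sd, size=montage.n_channels)
            for ci, ch in enumerate(montage.channel_names):
                val = base_uv * factor * effects.multiplier(ch, cond) * \
                    float(np.exp(eps[ci]))
                rows.append({"subject": subject, "condition": cond,
                             "channel": ch, "beta_uv": val})
    return pd.DataFrame(rows)
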