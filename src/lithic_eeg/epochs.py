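"""Cue alignment, trial segmentation, baseline correction, conditional
step epoching, and artifact-based epoch rejection.

Time windows are half-open ``[start, end)`` in milliseconds relative to
the event; sample indices are 0-based.  A trial segment runs from -200 ms
before the first-step onset to the end of the last 5-s step (so 15,200 ms
for the three-step tool tasks at the study timing), excluding the rest
period; step epochs are the first 1000 ms of each step.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage
from .recording import Marker, Recording, TASK_STEPS

__all__ = [
    "EpochSet",
    "align_markers",
    "segment_trials",
    "baseline_correct",
    "extract_step_epochs",
    "reject_epochs",
]

BASELINE_MS = 200.0
STEP_MS = 5000.0
EPOCH_MS = 1000.0
DEFAULT_EXCLUDED_CONDITIONS = frozenset({"nutcrack.execute"})


@dataclass
class EpochSet:
    """Fixed-length, event-locked segments.

    ``epochs`` is ``(n, channels, samples)`` in uV; ``window_ms`` is the
    half-open window relative to the locking event.  For trial segments
    ``step_offsets`` maps step name -> offset in samples from the segment
    start for each trial (only steps whose markers aligned cleanly).
    """

    epochs: np.ndarray
    window_ms: tuple[float, float]
    rate: float
    labels: list[str]
    montage: Montage
    subject: str = ""
    rejected: np.ndarray | None = None
    reject_reason: list[str] = field(default_factory=list)
    step_offsets: list[dict[str, int]] = field(default_factory=list)
    baseline_corrected: bool = False

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=np.float64)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be (n, channels, samples)")
        if self.window_ms[0] >= self.window_ms[1]:
            raise ValueError("window start must precede end")
        if len(self.labels) != self.n_epochs:
            raise ValueError("one label per epoch required")
        if self.rejected is None:
            self.rejected = np.zeros(self.n_epochs, dtype=bool)
            self.reject_reason = [""] * self.n_epochs

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def n_retained(self) -> int:
        return int((~self.rejected).sum())

    def retained(self) -> "EpochSet":
        keep = ~self.rejected
        return EpochSet(
            self.epochs[keep],
            self.window_ms,
            self.rate,
            [l for l, k in zip(self.labels, keep) if k],
            self.montage,
            self.subject,
            step_offsets=[s for s, k in zip(self.step_offsets, keep) if k]
            if self.step_offsets else [],
            baseline_corrected=self.baseline_corrected,
        )

    def save(self, path) -> list[Path]:
        """Portable storage: JSON header + float32 binary + TSV label sheet."""
        base = Path(path)
        base.parent.mkdir(parents=True, exist_ok=True)
        hdr = base.with_suffix(".json")
        dat = base.with_suffix(".dat")
        tsv = base.with_suffix(".labels.tsv")
        hdr.write_text(json.dumps({
            "format": "lithic-eeg-epochs",
            "shape": list(self.epochs.shape),
            "window_ms": list(self.window_ms),
            "rate_hz": self.rate,
            "subject": self.subject,
            "channel_names": list(self.montage.channel_names),
            "positions3d": self.montage.positions3d.tolist(),
            "positions2d": self.montage.positions2d.tolist(),
            "reference_label": self.montage.reference_label,
            "baseline_corrected": self.baseline_corrected,
        }, indent=1))
        self.epochs.astype("<f4").tofile(dat)
        pd.DataFrame({
            "label": self.labels,
            "rejected": self.rejected.astype(int),
            "reason": self.reject_reason,
        }).to_csv(tsv, sep="\t", index=False)
        return [hdr, dat, tsv]

    @classmethod
    def load(cls, path) -> "EpochSet":
        base = Path(path)
        hdr = json.loads(base.with_suffix(".json").read_text())
        if hdr.get("format") != "lithic-eeg-epochs":
            raise ValueError("not an epoch-set header")
        shape = tuple(hdr["shape"])
        epochs = np.fromfile(base.with_suffix(".dat"), dtype="<f4").reshape(shape)
        sheet = pd.read_csv(base.with_suffix(".labels.tsv"), sep="\t",
                            keep_default_na=False)
        montage = Montage(
            tuple(hdr["channel_names"]),
            np.array(hdr["positions3d"]),
            np.array(hdr["positions2d"]),
            hdr["reference_label"],
        )
        es = cls(
            epochs.astype(np.float64),
            tuple(hdr["window_ms"]),
            hdr["rate_hz"],
            [str(x) for x in sheet["label"]],
            montage,
            hdr.get("subject", ""),
            baseline_corrected=hdr.get("baseline_corrected", False),
        )
        es.rejected = sheet["rejected"].to_numpy().astype(bool)
        es.reject_reason = [str(x) for x in sheet["reason"]]
        return es


def _detect_cue_onsets(cue: np.ndarray) -> np.ndarray:
    peak = np.abs(cue).max()
    if peak <= 0:
        raise ValueError("no cue pulses detected (flat cue channel)")
    above = np.abs(cue) > 0.5 * peak
    onsets = np.flatnonzero(above & ~np.roll(above, 1))
    if above[0]:
        onsets = np.unique(np.concatenate([[0], onsets]))
    if onsets.size == 0:
        raise ValueError("no cue pulses detected")
    return onsets


def align_markers(rec: Recording, tolerance_ms: float = 250.0) -> Recording:
    """Snap manually placed markers to the nearest auditory-cue onset.

    Markers with no cue onset within ``tolerance_ms`` are flagged (their
    steps are excluded downstream), mirroring the manual removal of
    mis-executed trials.
    """
    if rec.audio_cue is None:
        raise ValueError("recording has no audio cue channel")
    onsets = _detect_cue_onsets(rec.audio_cue)
    tol = int(round(tolerance_ms * rec.rate / 1000.0))
    new: list[Marker] = []
    for m in rec.markers:
        j = int(np.argmin(np.abs(onsets - m.sample)))
        if abs(int(onsets[j]) - m.sample) <= tol:
            new.append(Marker(m.label, int(onsets[j]), "beep-aligned", False))
        else:
            new.append(Marker(m.label, m.sample, m.source, True))
    return rec.copy_with(markers=new, history=rec.history + ["align"])


def segment_trials(
    rec: Recording,
    baseline_ms: float = BASELINE_MS,
    step_ms: float = STEP_MS,
) -> EpochSet:
    """One segment per trial: ``[-baseline, n_steps * step_ms)`` around the
    first-step onset (rest excluded).  Trials whose first-step marker is
    flagged, or that fall too close to the recording edge, are dropped.

    Step onsets inside each segment come from that trial's aligned
    markers, so cue jitter is tolerated rather than assumed away.
    """
    rate = rec.rate
    pre = int(round(baseline_ms * rate / 1000.0))
    step_n = int(round(step_ms * rate / 1000.0))
    first_steps = {t: f"{t}.{steps[0]}" for t, steps in TASK_STEPS.items()}
    task_of_first = {v: k for k, v in first_steps.items()}

    segments, labels, offsets = [], [], []
    for m in rec.markers:
        task = task_of_first.get(m.label)
        if task is None or m.flagged:
            continue
        steps = TASK_STEPS[task]
        start = m.sample - pre
        end = m.sample + step_n * len(steps)
        if start < 0 or end > rec.n_samples:
            continue
        # collect this trial's aligned step markers
        offs: dict[str, int] = {steps[0]: pre}
        for k, stp in enumerate(steps[1:], 1):
            lbl = f"{task}.{stp}"
            expected = m.sample + k * step_n
            cands = [
                mm for mm in rec.markers
                if mm.label == lbl and not mm.flagged
                and abs(mm.sample - expected) < step_n // 2
            ]
            if cands:
                mm = min(cands, key=lambda x: abs(x.sample - expected))
                offs[stp] = pre + (mm.sample - m.sample)
        segments.append(rec.data[:, start:end])
        labels.append(task)
        offsets.append(offs)
    epochs = (
        np.stack(segments)
        if segments
        else np.empty((0, rec.n_channels, pre + step_n))
    )
    n_steps = len(TASK_STEPS[labels[0]]) if labels else 1
    return EpochSet(
        epochs,
        (-baseline_ms, step_ms * n_steps),
        rate,
        labels,
        rec.montage,
        step_offsets=offsets,
    )


def baseline_correct(ep: EpochSet) -> EpochSet:
    """Subtract the per-epoch, per-channel mean over ``[-baseline, 0) ms``."""
    if ep.window_ms[0] >= 0:
        raise ValueError("epoch window has no pre-event baseline span")
    n_base = int(round(-ep.window_ms[0] * ep.rate / 1000.0))
    base = ep.epochs[:, :, :n_base].mean(axis=2, keepdims=True)
    out = EpochSet(
        ep.epochs - base,
        ep.window_ms,
        ep.rate,
        list(ep.labels),
        ep.montage,
        ep.subject,
        step_offsets=list(ep.step_offsets),
        baseline_corrected=True,
    )
    out.rejected = ep.rejected.copy()
    out.reject_reason = list(ep.reject_reason)
    return out


def extract_step_epochs(
    ep: EpochSet,
    exclusions: frozenset[str] | set[str] = DEFAULT_EXCLUDED_CONDITIONS,
    epoch_ms: float = EPOCH_MS,
) -> EpochSet:
    """Cut one ``[0, epoch_ms)`` epoch per retained step per trial.

    ``exclusions`` are ``task.step`` condition labels dropped from the
    output; the default removes the impact-contaminated hammerstone
    Execute step, leaving the five analysed conditions.
    """
    valid = {f"{t}.{s}" for t, steps in TASK_STEPS.items() for s in steps}
    unknown = set(exclusions) - valid
    if unknown:
        raise ValueError(f"unknown exclusion label(s): {sorted(unknown)}")
    if not ep.baseline_corrected:
        raise ValueError("trial segments must be baseline-corrected first")
    n = int(round(epoch_ms * ep.rate / 1000.0))
    out, labels = [], []
    for i in range(ep.n_epochs):
        task = ep.labels[i]
        offs = ep.step_offsets[i] if ep.step_offsets else {}
        for stp, off in offs.items():
            cond = f"{task}.{stp}"
            if cond in exclusions:
                continue
            if off + n > ep.epochs.shape[2]:
                continue
            out.append(ep.epochs[i, :, off:off + n])
            labels.append(cond)
    epochs = np.stack(out) if out else np.empty((0, ep.epochs.shape[1], n))
    return EpochSet(epochs, (0.0, epoch_ms), ep.rate, labels, ep.montage,
                    ep.subject, baseline_corrected=True)


def reject_epochs(
    ep: EpochSet,
    amp_uv: float = 100.0,
    grad_uv: float = 50.0,
) -> EpochSet:
    """Flag epochs exceeding amplitude or per-sample gradient criteria.

    An epoch is rejected when any channel exceeds ``|x| > amp_uv`` or any
    successive-sample step exceeds ``grad_uv``; the reason code records
    which criterion fired first (amplitude checked first).
    """
    if amp_uv <= 0 or grad_uv <= 0:
        raise ValueError("rejection thresholds must be positive")
    out = EpochSet(
        ep.epochs,
        ep.window_ms,
        ep.rate,
        list(ep.labels),
        ep.montage,
        ep.subject,
        step_offsets=list(ep.step_offsets),
        baseline_corrected=ep.baseline_corrected,
    )
    rejected = np.zeros(ep.n_epochs, dtype=bool)
    reasons = [""] * ep.n_epochs
    amp_bad = np.abs(ep.epochs).max(axis=(1, 2)) > amp_uv
    grad_bad = np.abs(np.diff(ep.epochs, axis=2)).max(axis=(1, 2)) > grad_uv
    for i in range(ep.n_epochs):
        if amp_bad[i]:
            rejected[i], reasons[i] = True, "amplitude"
        elif grad_bad[i]:
            rejected[i], reasons[i] = True, "gradient"
    out.rejected = rejected
    out.reject_reason = reasons
    return out
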