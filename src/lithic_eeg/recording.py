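"""Continuous-recording container and event markers."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .montage import Montage

__all__ = ["Marker", "Recording", "PipelineStateError"]

# Condition labels are "task.step" compound keys, e.g. "cut.hold",
# "nutcrack.execute", "control.movement"; the trial-final rest period is
# "task.rest".
TASK_STEPS: dict[str, tuple[str, ...]] = {
    "nutcrack": ("hold", "aim", "execute"),
    "cut": ("hold", "aim", "execute"),
    "control": ("movement",),
}


class PipelineStateError(RuntimeError):
    """Raised when preprocessing stages are applied out of order."""


@dataclass(frozen=True)
class Marker:
    """Event marker: a labelled 0-based sample index.

    ``source`` distinguishes manually placed markers from markers snapped
    to the auditory cue; ``flagged`` marks markers with no cue within the
    alignment tolerance (their trials are excluded downstream).
    """

    label: str
    sample: int
    source: str = "manual"  # {"manual", "beep-aligned"}
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.sample < 0:
            raise ValueError("marker sample must be non-negative")
        if self.source not in ("manual", "beep-aligned"):
            raise ValueError(f"unknown marker source {self.source!r}")


@dataclass
class Recording:
    """Continuous multichannel EEG in microvolts.

    Attributes
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in uV; row order follows ``montage.channel_names``.
    rate : float
        Sampling rate in Hz.
    montage : Montage
    markers : list of Marker, sorted by sample.
    audio_cue : ndarray or None, shape (n_samples,)
        Simultaneously recorded cue channel (beep pulses), if present.
    bad_channels : set of str
    history : list of str
        Names of processing steps applied, in order; used to enforce the
        downsample -> filter -> reference stage ordering.
    """

    data: np.ndarray
    rate: float
    montage: Montage
    markers: list[Marker] = field(default_factory=list)
    audio_cue: np.ndarray | None = None
    bad_channels: set[str] = field(default_factory=set)
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be a 2-D (channels x samples) array")
        if self.data.shape[0] != self.montage.n_channels:
            raise ValueError(
                f"data has {self.data.shape[0]} rows but montage has "
                f"{self.montage.n_channels} channels"
            )
        if not self.rate > 0:
            raise ValueError("sampling rate must be positive")
        self.markers = sorted(self.markers, key=lambda m: m.sample)
        for m in self.markers:
            if m.sample >= self.n_samples:
                raise ValueError(
                    f"marker {m.label!r} at sample {m.sample} beyond recording "
                    f"length {self.n_samples}"
                )
        if self.audio_cue is not None:
            self.audio_cue = np.asarray(self.audio_cue, dtype=np.float64).ravel()
            if self.audio_cue.shape[0] != self.n_samples:
                raise ValueError("audio_cue length must match data")
        good = self.good_indices
        if good.size and not np.all(np.isfinite(self.data[good])):
            raise ValueError("non-finite samples on non-bad channels")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.rate

    @property
    def good_indices(self) -> np.ndarray:
        return np.array(
            [i for i, n in enumerate(self.montage.channel_names)
             if n not in self.bad_channels],
            dtype=int,
        )

    def copy_with(self, **changes) -> "Recording":
        base = dict(
            data=self.data,
            rate=self.rate,
            montage=self.montage,
            markers=list(self.markers),
            audio_cue=None if self.audio_cue is None else self.audio_cue.copy(),
            bad_channels=set(self.bad_channels),
            history=list(self.history),
        )
        base.update(changes)
        return Recording(**base)

    def require_stage_before(self, step: str, forbidden: tuple[str, ...]) -> None:
        done = set(self.history)
        bad = [f for f in forbidden if f in done]
        if bad:
            raise PipelineStateError(
                f"cannot apply {step!r} after {bad}: pipeline order is "
                "downsample -> filter -> bad-channel handling -> reference"
            )
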