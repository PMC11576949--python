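"""Per-epoch amplitude spectra and beta-band means.

The estimator follows the convention of classic ERP/spectral packages: a
10% Hanning (Tukey) taper on each 1000-ms epoch, a single-trial FFT
calibrated in amplitude (uV) so a unit sinusoid at a bin frequency under
the rectangular window reads 1.0 uV at its bin, averaging across trials
per subject and condition, and finally the mean over the 12.5-30 Hz beta
band.  On the 1-Hz grid of a 1000-ms epoch the band covers the 13...30 Hz
bins inclusive (18 bins; no bin exists at 12.5 Hz).

Amplitude — not power — is averaged across trials; ``amp_to_power`` is
provided for readers who want uV^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import windows

from .epochs import EpochSet

__all__ = [
    "SpectralConfig",
    "Spectrum",
    "taper",
    "amplitude_spectrum",
    "mean_spectrum",
    "band_mean",
    "band_mean_table",
    "amp_to_power",
]


@dataclass(frozen=True)
class SpectralConfig:
    taper_fraction: float = 0.10
    band_lo_hz: float = 12.5
    band_hi_hz: float = 30.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.taper_fraction <= 1.0:
            raise ValueError("taper_fraction must be in [0, 1]")
        if not 0 < self.band_lo_hz < self.band_hi_hz:
            raise ValueError("band edges must satisfy 0 < lo < hi")


@dataclass
class Spectrum:
    """One-sided amplitude spectrum, channels x frequency bins, in uV."""

    freqs: np.ndarray
    amp: np.ndarray
    n_epochs_averaged: int = 1

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.amp = np.asarray(self.amp, dtype=float)
        if self.amp.shape[-1] != self.freqs.shape[0]:
            raise ValueError("amp and freqs length mismatch")
        if (self.amp < 0).any():
            raise ValueError("amplitude spectrum must be non-negative")


def taper(epoch: np.ndarray, fraction: float = 0.10) -> np.ndarray:
    """Tukey taper: raised-cosine ramps covering ``fraction/2`` of the
    epoch at each end; ``fraction=0`` is rectangular, ``fraction=1`` full
    Hann."""
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("taper fraction must be in [0, 1]")
    epoch = np.asarray(epoch, dtype=float)
    w = windows.tukey(epoch.shape[-1], alpha=fraction, sym=False)
    return epoch * w


def amplitude_spectrum(epoch: np.ndarray, rate: float) -> Spectrum:
    """Single-epoch one-sided amplitude spectrum.

    Scaling: ``2 |X_k| / N`` for interior bins (``|X_0| / N`` at DC and
    the Nyquist bin), so a unit sinusoid at a bin frequency gives 1.0 at
    that bin under the rectangular window.
    """
    epoch = np.atleast_2d(np.asarray(epoch, dtype=float))
    n = epoch.shape[-1]
    if n < 2:
        raise ValueError("epoch too short for a spectrum")
    X = np.fft.rfft(epoch, axis=-1)
    amp = np.abs(X) * (2.0 / n)
    amp[..., 0] /= 2.0
    if n % 2 == 0:
        amp[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / rate)
    return Spectrum(freqs, amp, 1)


def mean_spectrum(spectra: list[Spectrum]) -> Spectrum:
    """Element-wise mean across retained epochs of one subject x condition."""
    if not spectra:
        raise ValueError("no retained epochs to average")
    f0 = spectra[0].freqs
    for s in spectra[1:]:
        if s.freqs.shape != f0.shape or not np.allclose(s.freqs, f0):
            raise ValueError("spectra are not on a common frequency grid")
    amp = np.mean([s.amp for s in spectra], axis=0)
    return Spectrum(f0, amp, len(spectra))


def band_mean(spec: Spectrum, cfg: SpectralConfig = SpectralConfig()) -> np.ndarray:
    """Per-channel mean amplitude over bins with ``lo <= f <= hi``."""
    sel = (spec.freqs >= cfg.band_lo_hz) & (spec.freqs <= cfg.band_hi_hz)
    if not sel.any():
        raise ValueError("frequency grid does not cover the requested band")
    return spec.amp[..., sel].mean(axis=-1)


def amp_to_power(amp: np.ndarray) -> np.ndarray:
    """Convert amplitude (uV) to power (uV^2)."""
    return np.asarray(amp) ** 2


def band_mean_table(
    step_epochs: EpochSet,
    subject: str,
    cfg: SpectralConfig = SpectralConfig(),
) -> pd.DataFrame:
    """Beta-band means for every condition in a rejected/retained epoch set.

    Returns long-format rows ``(subject, condition, channel, beta_uv,
    n_epochs)`` — the entries of the beta-power table the inference stage
    consumes.  Conditions with zero retained epochs are flagged by raising.
    """
    kept = step_epochs.retained()
    rows = []
    names = kept.montage.channel_names
    for cond in sorted(set(kept.labels)):
        idx = [i for i, l in enumerate(kept.labels) if l == cond]
        spectra = [
            amplitude_spectrum(taper(kept.epochs[i], cfg.taper_fraction), kept.rate)
            for i in idx
        ]
        ms = mean_spectrum(spectra)
        bm = band_mean(ms, cfg)
        for ch, v in zip(names, bm):
            rows.append(
                {"subject": subject, "condition": cond, "channel": ch,
                 "beta_uv": float(v), "n_epochs": len(idx)}
            )
    return pd.DataFrame(rows)
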