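"""Continuous-signal conditioning.

Stage order is downsample -> filter -> bad-channel handling -> reference;
applying a stage after a later one raises :class:`PipelineStateError`.
All filters are zero-phase (forward-backward) IIR designs: Butterworth
band-pass (order 4 by default) and a 50 Hz notch (quality 35), matching
the corner frequencies of the study protocol this package reimplements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .leadfield import leadfield_for_positions
from .recording import PipelineStateError, Recording

__all__ = [
    "FilterSpec",
    "downsample",
    "apply_filter",
    "detect_bad_channels",
    "interpolate_channels",
    "rereference_average",
    "rereference_rest",
]


@dataclass(frozen=True)
class FilterSpec:
    """IIR filter specification (zero-phase application).

    ``kind`` is ``"bandpass"`` (Butterworth, ``low_hz``-``high_hz``) or
    ``"notch"`` (IIR notch at ``notch_hz`` with quality factor ``q``).
    """

    kind: str = "bandpass"
    low_hz: float = 1.0
    high_hz: float = 40.0
    notch_hz: float = 50.0
    order: int = 4
    q: float = 35.0

    def validate(self, rate: float) -> None:
        nyq = rate / 2.0
        if self.kind == "bandpass":
            if not (0 < self.low_hz < self.high_hz < nyq):
                raise ValueError(
                    f"bandpass corners must satisfy 0 < low < high < rate/2 "
                    f"(got {self.low_hz}-{self.high_hz} Hz at {rate} Hz)"
                )
        elif self.kind == "notch":
            if not (0 < self.notch_hz < nyq):
                raise ValueError(f"notch frequency {self.notch_hz} outside (0, {nyq})")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")


def downsample(rec: Recording, target_hz: float) -> Recording:
    """Anti-aliased integer-factor decimation.

    Marker and cue indices are rescaled by floor division; the output
    length is ``floor(n / factor)``.
    """
    rec.require_stage_before("downsample", ("filter", "reference"))
    if target_hz > rec.rate:
        raise ValueError("target rate above current rate")
    factor_f = rec.rate / target_hz
    factor = int(round(factor_f))
    if abs(factor_f - factor) > 1e-9:
        raise ValueError(
            f"downsampling factor {factor_f} is not an integer "
            f"({rec.rate} -> {target_hz} Hz)"
        )
    if factor == 1:
        return rec.copy_with(history=rec.history + ["downsample"])
    n_out = rec.n_samples // factor
    data = signal.decimate(rec.data, factor, ftype="iir", zero_phase=True, axis=1)
    data = data[:, :n_out]
    cue = None
    if rec.audio_cue is not None:
        # preserve pulse edges: max-pool rather than low-pass the cue
        cue = rec.audio_cue[: n_out * factor].reshape(n_out, factor).max(axis=1)
    markers = [
        m.__class__(m.label, m.sample // factor, m.source, m.flagged)
        for m in rec.markers
        if m.sample // factor < n_out
    ]
    return rec.copy_with(
        data=data,
        rate=target_hz,
        markers=markers,
        audio_cue=cue,
        history=rec.history + ["downsample"],
    )


def apply_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Zero-phase filtering; preserves length and marker alignment."""
    rec.require_stage_before("filter", ("reference",))
    spec.validate(rec.rate)
    if spec.kind == "bandpass":
        sos = signal.butter(
            spec.order, [spec.low_hz, spec.high_hz], btype="bandpass",
            fs=rec.rate, output="sos",
        )
        _, poles, _ = signal.sos2zpk(sos)
        if np.any(np.abs(poles) >= 1.0 - 1e-12):
            raise ValueError(
                f"unstable band-pass design at order {spec.order}; try a lower order"
            )
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        b, a = signal.iirnotch(spec.notch_hz, spec.q, fs=rec.rate)
        data = signal.filtfilt(b, a, rec.data, axis=1)
    return rec.copy_with(data=data, history=rec.history + ["filter"])


def detect_bad_channels(
    rec: Recording,
    z_threshold: float = 5.0,
    corr_z_threshold: float = 5.0,
) -> set[str]:
    """Automatic bad-channel screening (deterministic).

    Flags channels that are (a) near-constant, (b) log-variance outliers
    under a robust (median/MAD) z-score, or (c) decoupled from every other
    channel — their best absolute correlation is a robust low outlier
    relative to the other channels' best correlations.  Criterion (c) is
    relative rather than absolute so it stays silent on data whose sources
    are genuinely channel-independent.
    """
    if rec.n_channels < 8:
        raise ValueError("need at least 8 channels for robust screening")
    x = rec.data
    names = rec.montage.channel_names
    bad: set[str] = set()
    var = x.var(axis=1)
    tiny = var < max(1e-12, 1e-10 * np.median(var))
    bad.update(n for n, t in zip(names, tiny) if t)

    ok = ~tiny
    logv = np.log(np.maximum(var, 1e-300))
    med = np.median(logv[ok])
    mad = np.median(np.abs(logv[ok] - med)) * 1.4826
    if mad > 0:
        rz = np.abs(logv - med) / mad
        bad.update(n for n, z, t in zip(names, rz, ~tiny) if t and z > z_threshold)

    with np.errstate(invalid="ignore"):
        cm = np.abs(np.corrcoef(x))
    np.fill_diagonal(cm, 0.0)
    cm[~np.isfinite(cm)] = 0.0  # zero-variance rows
    best = cm.max(axis=1)
    fz = np.arctanh(np.clip(best, 0.0, 1 - 1e-12))
    med = np.median(fz[ok])
    mad = np.median(np.abs(fz[ok] - med)) * 1.4826
    if mad > 0:
        low = (med - fz) / mad
        bad.update(n for n, z, t in zip(names, low, ~tiny) if t and z > corr_z_threshold)
    return bad


def interpolate_channels(rec: Recording, bad: set[str] | None = None) -> Recording:
    """Replace bad channels by spherical inverse-distance interpolation.

    Weights are ``1 / angle**2`` (great-circle angle on the unit sphere)
    over the good channels, normalised to sum to one, so a spatially
    constant field is reproduced exactly.
    """
    bad = set(rec.bad_channels if bad is None else bad)
    if not bad:
        return rec.copy_with(history=rec.history + ["interpolate"])
    unknown = bad - set(rec.montage.channel_names)
    if unknown:
        raise ValueError(f"bad channels not in montage: {sorted(unknown)}")
    good_idx = [i for i, n in enumerate(rec.montage.channel_names) if n not in bad]
    if len(good_idx) < 3:
        raise ValueError("fewer than 3 good channels; cannot interpolate")
    data = rec.data.copy()
    p = rec.montage.positions3d
    for name in sorted(bad):
        i = rec.montage.index(name)
        cosang = np.clip(p[good_idx] @ p[i], -1.0, 1.0)
        ang = np.arccos(cosang)
        w = 1.0 / np.maximum(ang, 1e-6) ** 2
        w /= w.sum()
        data[i] = w @ rec.data[good_idx]
    return rec.copy_with(data=data, bad_channels=set(),
                         history=rec.history + ["interpolate"])


def rereference_average(rec: Recording) -> Recording:
    """Common-average reference over non-bad channels (idempotent)."""
    good = rec.good_indices
    data = rec.data - rec.data[good].mean(axis=0, keepdims=True)
    return rec.copy_with(
        data=data,
        montage=rec.montage.with_reference("AVG"),
        history=rec.history + ["reference"],
    )


def rest_transform(positions3d: np.ndarray, rcond: float = 1e-4) -> np.ndarray:
    """Channels x channels REST operator for average-referenced data.

    ``T = G @ pinv(G_avg)`` with ``G`` the infinity-referenced spherical
    lead field and ``G_avg`` its average-referenced version; the
    pseudoinverse truncates singular values below ``rcond`` times the
    largest (deterministic, no data-dependent tuning).
    """
    G = leadfield_for_positions(positions3d)
    G_avg = G - G.mean(axis=0, keepdims=True)
    return G @ np.linalg.pinv(G_avg, rcond=rcond)


def rereference_rest(
    rec: Recording,
    leadfield: np.ndarray | None = None,
    rcond: float = 1e-4,
) -> Recording:
    """Re-reference toward an infinity (REST) reference.

    The recording must already be average-referenced.  A custom gain
    matrix ``leadfield`` (channels x sources, infinity-referenced) may be
    supplied; by default the built-in three-shell spherical model is used
    and the resulting channels x channels operator is cached per montage.
    """
    if rec.montage.reference_label != "AVG":
        raise PipelineStateError(
            "REST expects average-referenced input; call rereference_average first"
        )
    if leadfield is None:
        T = rest_transform(rec.montage.positions3d, rcond=rcond)
    else:
        G = np.asarray(leadfield, dtype=float)
        if G.shape[0] != rec.n_channels:
            raise ValueError(
                f"leadfield has {G.shape[0]} rows for {rec.n_channels} channels"
            )
        G_avg = G - G.mean(axis=0, keepdims=True)
        T = G @ np.linalg.pinv(G_avg, rcond=rcond)
    return rec.copy_with(
        data=T @ rec.data,
        montage=rec.montage.with_reference("REST"),
        history=rec.history + ["reference"],
    )
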