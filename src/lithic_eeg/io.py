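"""Reading and writing continuous recordings and result tables.

Two on-disk dialects are supported:

``portable``
    The package's canonical format: a JSON header (``<base>.json``), a raw
    little-endian float32 channel-major matrix (``<base>.dat``) and a TSV
    marker sheet (``<base>.markers.tsv``).  Round trips are bit-exact at
    float32 precision.

``brainvision``
    Best-effort support for the BrainVision header/marker/binary triplet
    (.vhdr/.vmrk/.eeg) in its common variant: IEEE float32, multiplexed,
    microvolt units.  Reading goes through :func:`mne.io.read_raw_brainvision`;
    writing is implemented here.

Result tables (channel statistics, PC scores, ...) are plain TSV files read
and written with pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import Montage, _ANGLES_DEG, _montage_from_angles, load_montage
from .recording import Marker, Recording

__all__ = ["read_recording", "write_recording", "write_result_table", "read_result_table"]

_CUE_CHANNEL = "AUX_CUE"
_PORTABLE_VERSION = 1


def _portable_paths(path: Path) -> tuple[Path, Path, Path]:
    base = path.with_suffix("") if path.suffix == ".json" else path
    return (
        base.with_suffix(".json"),
        base.with_suffix(".dat"),
        base.with_suffix(".markers.tsv"),
    )


# ---------------------------------------------------------------------------
# portable dialect


def _write_portable(rec: Recording, path: Path) -> list[Path]:
    hdr_p, dat_p, mrk_p = _portable_paths(path)
    n_rows = rec.n_channels + (1 if rec.audio_cue is not None else 0)
    header = {
        "format": "lithic-eeg-portable",
        "version": _PORTABLE_VERSION,
        "rate_hz": rec.rate,
        "unit": "uV",
        "dtype": "<f4",
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "n_rows": n_rows,
        "has_audio_cue": rec.audio_cue is not None,
        "channel_names": list(rec.montage.channel_names),
        "reference_label": rec.montage.reference_label,
        "positions3d": rec.montage.positions3d.tolist(),
        "positions2d": rec.montage.positions2d.tolist(),
        "bad_channels": sorted(rec.bad_channels),
        "history": list(rec.history),
    }
    hdr_p.write_text(json.dumps(header, indent=1))
    mat = rec.data
    if rec.audio_cue is not None:
        mat = np.vstack([mat, rec.audio_cue[None, :]])
    mat.astype("<f4").tofile(dat_p)
    rows = [
        {"label": m.label, "sample": m.sample, "source": m.source,
         "flagged": int(m.flagged)}
        for m in rec.markers
    ]
    pd.DataFrame(rows, columns=["label", "sample", "source", "flagged"]).to_csv(
        mrk_p, sep="\t", index=False
    )
    return [hdr_p, dat_p, mrk_p]


def _read_portable(path: Path) -> Recording:
    hdr_p, dat_p, mrk_p = _portable_paths(path)
    for p in (hdr_p, dat_p, mrk_p):
        if not p.exists():
            raise FileNotFoundError(f"portable recording file missing: {p}")
    header = json.loads(hdr_p.read_text())
    if header.get("format") != "lithic-eeg-portable":
        raise ValueError(f"{hdr_p} is not a portable recording header")
    n_rows, n_samples = header["n_rows"], header["n_samples"]
    raw = np.fromfile(dat_p, dtype=header["dtype"])
    if raw.size != n_rows * n_samples:
        raise ValueError(
            f"{dat_p}: expected {n_rows * n_samples} values, found {raw.size} "
            "(truncated or corrupt data file)"
        )
    mat = raw.reshape(n_rows, n_samples).astype(np.float64)
    montage = Montage(
        tuple(header["channel_names"]),
        np.array(header["positions3d"], dtype=float),
        np.array(header["positions2d"], dtype=float),
        header["reference_label"],
    )
    cue = mat[-1] if header["has_audio_cue"] else None
    data = mat[: header["n_channels"]]
    mdf = pd.read_csv(mrk_p, sep="\t")
    markers = [
        Marker(str(r.label), int(r.sample), str(r.source), bool(r.flagged))
        for r in mdf.itertuples()
    ]
    return Recording(
        data=data,
        rate=float(header["rate_hz"]),
        montage=montage,
        markers=markers,
        audio_cue=cue,
        bad_channels=set(header.get("bad_channels", [])),
        history=list(header.get("history", [])),
    )


# ---------------------------------------------------------------------------
# brainvision dialect


def _write_brainvision(rec: Recording, path: Path) -> list[Path]:
    base = path.with_suffix("")
    vhdr, vmrk, eeg = (base.with_suffix(s) for s in (".vhdr", ".vmrk", ".eeg"))
    names = list(rec.montage.channel_names)
    cue = rec.audio_cue is not None
    if cue:
        names = names + [_CUE_CHANNEL]
    n_ch = len(names)
    lines = [
        "Brain Vision Data Exchange Header File Version 1.0",
        "; written by lithic-eeg",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        f"MarkerFile={vmrk.name}",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={1e6 / rec.rate:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    for i, name in enumerate(names, 1):
        lines.append(f"Ch{i}={name},,1,µV")
    vhdr.write_text("\n".join(lines) + "\n", encoding="utf-8")

    mlines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={eeg.name}",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,00000000000000000000",
    ]
    for i, m in enumerate(rec.markers, 2):
        # BrainVision marker positions are 1-based
        mlines.append(f"Mk{i}=Stimulus,{m.label},{m.sample + 1},1,0")
    vmrk.write_text("\n".join(mlines) + "\n", encoding="utf-8")

    mat = rec.data
    if cue:
        mat = np.vstack([mat, rec.audio_cue[None, :]])
    # multiplexed: sample-major interleave
    mat.T.astype("<f4").tofile(eeg)
    return [vhdr, vmrk, eeg]


def _read_brainvision(path: Path) -> Recording:
    import mne

    vhdr = path if path.suffix == ".vhdr" else path.with_suffix(".vhdr")
    if not vhdr.exists():
        raise FileNotFoundError(f"missing BrainVision header: {vhdr}")
    raw = mne.io.read_raw_brainvision(vhdr, preload=True, verbose="error")
    rate = float(raw.info["sfreq"])
    names = list(raw.ch_names)
    data_v = raw.get_data()  # volts
    data = data_v * 1e6
    cue = None
    if _CUE_CHANNEL in names:
        i = names.index(_CUE_CHANNEL)
        cue = data[i]
        data = np.delete(data, i, axis=0)
        names.remove(_CUE_CHANNEL)
    unknown = [n for n in names if n not in _ANGLES_DEG]
    if unknown:
        raise ValueError(f"no built-in montage position for channel(s) {unknown}")
    montage = _montage_from_angles(names, _ANGLES_DEG)
    markers = []
    for ann in raw.annotations:
        desc = ann["description"]
        if desc.startswith("New Segment"):
            continue
        label = desc.split("/", 1)[-1].strip()
        sample = int(round(ann["onset"] * rate))
        markers.append(Marker(label, sample, "manual"))
    return Recording(data=data, rate=rate, montage=montage, markers=markers,
                     audio_cue=cue)


# ---------------------------------------------------------------------------
# public API


def write_recording(rec: Recording, path, dialect: str = "portable") -> list[Path]:
    """Write a recording; returns the list of files produced.

    The header records the sampling rate, channel names and the unit (uV).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "portable":
        return _write_portable(rec, path)
    if dialect == "brainvision":
        return _write_brainvision(rec, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path, dialect: str = "portable") -> Recording:
    """Read a recording written by :func:`write_recording` (or, for the
    brainvision dialect, by BrainVision-compatible software)."""
    path = Path(path)
    if dialect == "portable":
        return _read_portable(path)
    if dialect == "brainvision":
        return _read_brainvision(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_result_table(df: pd.DataFrame, path) -> Path:
    """Write a result table as TSV; validates any p-value column."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if "p" in df.columns:
        p = pd.to_numeric(df["p"])
        if ((p < 0) | (p > 1)).any():
            raise ValueError("p values outside [0, 1]")
    df.to_csv(path, sep="\t", index=False)
    return path


def read_result_table(path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t")
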