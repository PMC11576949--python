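"""Electrode montage geometry for the 32-channel 10-20 cap.

The montage used throughout the package is the standard 32-electrode
10-20/10-10 layout with FCz as the online reference.  Electrode positions
are the ideal spherical 10-20 angles (inclination measured from the vertex
Cz, azimuth measured from the nasion meridian, positive toward the right
ear), i.e. the textbook BESA/EasyCap angle table re-expressed in a single
convention; see ``docs/methods.md`` for the source table and conversion.

Coordinates live on the unit sphere; the 2D layout used for topographic
maps and neighbour weighting is the azimuthal-equidistant projection about
Cz, so Cz maps to the origin and great-circle distance from Cz is preserved
along every meridian.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["Montage", "load_montage", "CHANNELS_32", "DEFAULT_REFERENCE"]

DEFAULT_REFERENCE = "FCz"

# Circular (left-front -> left-back -> right-back -> right-front) channel
# ordering of the standard 32-channel cap.  This ordering is the canonical
# channel order of the package: files are written in it and deterministic
# tie-breaks refer to it.
CHANNELS_32: tuple[str, ...] = (
    "Fp1", "Fz", "F3", "F7", "FT9", "FC5", "FC1", "C3", "T7", "TP9",
    "CP5", "CP1", "Pz", "P3", "P7", "O1", "Oz", "O2", "P4", "P8",
    "TP10", "CP6", "CP2", "Cz", "C4", "T8", "FT10", "FC6", "FC2", "F4",
    "F8", "Fp2",
)

# Ideal spherical 10-20 angles: (inclination from vertex, azimuth from the
# nasion, degrees; azimuth positive clockwise toward the right ear).
_ANGLES_DEG: dict[str, tuple[float, float]] = {
    "Cz":   (0.0,    0.0),
    "FCz":  (23.0,   0.0),
    "Fz":   (46.0,   0.0),
    "Pz":   (46.0, 180.0),
    "Oz":   (92.0, 180.0),
    "Fp1":  (92.0,  -18.0), "Fp2":  (92.0,  18.0),
    "F7":   (92.0,  -54.0), "F8":   (92.0,  54.0),
    "T7":   (92.0,  -90.0), "T8":   (92.0,  90.0),
    "P7":   (92.0, -126.0), "P8":   (92.0, 126.0),
    "O1":   (92.0, -162.0), "O2":   (92.0, 162.0),
    "F3":   (60.0,  -39.0), "F4":   (60.0,  39.0),
    "P3":   (60.0, -141.0), "P4":   (60.0, 141.0),
    "C3":   (46.0,  -90.0), "C4":   (46.0,  90.0),
    "FC1":  (32.0,  -45.0), "FC2":  (32.0,  45.0),
    "CP1":  (32.0, -135.0), "CP2":  (32.0, 135.0),
    "FC5":  (71.0,  -69.0), "FC6":  (71.0,  69.0),
    "CP5":  (71.0, -111.0), "CP6":  (71.0, 111.0),
    "FT9":  (113.0, -72.0), "FT10": (113.0, 72.0),
    "TP9":  (113.0, -108.0), "TP10": (113.0, 108.0),
}


def _sphere_xyz(theta_deg: float, phi_deg: float) -> np.ndarray:
    """Unit-sphere position: x right, y anterior, z superior."""
    th = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    return np.array(
        [math.sin(th) * math.sin(ph), math.sin(th) * math.cos(ph), math.cos(th)]
    )


def _azimuthal_equidistant(theta_deg: float, phi_deg: float) -> np.ndarray:
    r = math.radians(theta_deg)
    ph = math.radians(phi_deg)
    return np.array([r * math.sin(ph), r * math.cos(ph)])


@dataclass(frozen=True)
class Montage:
    """Electrode names and geometry.

    Parameters
    ----------
    channel_names
        Ordered channel labels; the ordering is meaningful (files and
        tie-breaks use it).
    positions3d
        ``(n, 3)`` unit-sphere coordinates (x right, y anterior, z up).
    positions2d
        ``(n, 2)`` azimuthal-equidistant projection about the vertex.
    reference_label
        Name of the online reference electrode (not part of the channel
        set), ``"FCz"`` by default, or ``"AVG"`` / ``"REST"`` after
        re-referencing.
    """

    channel_names: tuple[str, ...]
    positions3d: np.ndarray
    positions2d: np.ndarray
    reference_label: str = DEFAULT_REFERENCE

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate channel label(s): {dupes}")
        p3 = np.asarray(self.positions3d, dtype=float)
        p2 = np.asarray(self.positions2d, dtype=float)
        if p3.shape != (len(names), 3) or p2.shape != (len(names), 2):
            raise ValueError("position array shapes do not match channel count")
        norms = np.linalg.norm(p3, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions3d must lie on the unit sphere")
        object.__setattr__(self, "positions3d", p3)
        object.__setattr__(self, "positions2d", p2)

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"unknown channel label: {name!r}") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def subset(self, names) -> "Montage":
        idx = self.indices(names)
        return Montage(
            tuple(names),
            self.positions3d[idx],
            self.positions2d[idx],
            self.reference_label,
        )

    def with_reference(self, label: str) -> "Montage":
        return Montage(self.channel_names, self.positions3d, self.positions2d, label)


def _montage_from_angles(labels, angles, reference=DEFAULT_REFERENCE) -> Montage:
    p3 = np.array([_sphere_xyz(*angles[c]) for c in labels])
    p2 = np.array([_azimuthal_equidistant(*angles[c]) for c in labels])
    return Montage(tuple(labels), p3, p2, reference)


def load_montage(name: str | Path = "builtin-32") -> Montage:
    """Load the built-in 32-channel montage or a user angle table.

    A user file is a whitespace/tab-separated table of
    ``label  inclination_deg  azimuth_deg`` rows (``#`` comments allowed),
    using the same angle convention as the built-in table.

    Raises
    ------
    ValueError
        On duplicate or unknown labels, or malformed rows.
    """
    if str(name) == "builtin-32":
        return _montage_from_angles(CHANNELS_32, _ANGLES_DEG)

    path = Path(name)
    if not path.exists():
        raise ValueError(f"unknown montage identifier or missing file: {name!r}")
    labels: list[str] = []
    angles: dict[str, tuple[float, float]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 3:
            raise ValueError(f"{path}:{lineno}: expected 'label theta phi', got {line!r}")
        label = parts[0]
        try:
            theta, phi = float(parts[1]), float(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: malformed position row {line!r}") from None
        if label in angles:
            raise ValueError(f"{path}:{lineno}: duplicate channel label {label!r}")
        labels.append(label)
        angles[label] = (theta, phi)
    return _montage_from_angles(labels, angles)


def reference_position(montage: Montage) -> np.ndarray | None:
    """3D position of the named reference electrode, if it is a known label."""
    if montage.reference_label in _ANGLES_DEG:
        return _sphere_xyz(*_ANGLES_DEG[montage.reference_label])
    return None
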