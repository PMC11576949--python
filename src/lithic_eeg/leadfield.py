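"""Three-shell concentric-sphere EEG forward model.

Used to build the gain (lead-field) matrix behind the REST re-reference.
The head is modelled as three concentric spherical shells — brain, skull,
scalp — with relative radii (0.87, 0.92, 1.0) and conductivities
(1.0, 0.0125, 1.0).  For each spherical-harmonic degree ``n`` the radial
potential profile in every layer is ``A r^n + B r^-(n+1)``; matching
potential and radial current at each interface and zero current at the
scalp surface gives a small linear system per degree, solved numerically.

The scalp potential of a dipole with moment ``q`` at position ``r0``
(inside the brain compartment) is then

    V(e) = 1/(4 pi s1) * sum_n  s_n r0^(n-1)
           [ n (q . rhat) P_n(c)  +  (q . e - c (q . rhat)) P_n'(c) ]

with ``c`` the cosine of the angle between electrode direction ``e`` and
dipole direction ``rhat``, and ``s_n`` the solved surface coefficient for
a unit primary coefficient.  Sources form an equivalent-dipole shell on a
Fibonacci spiral at 65% of the scalp radius, restricted to the cranial
vault (z > -0.15, roughly where cortex sits under an upper-head electrode
cap; ~2600 dipoles), three orthogonal moments each.  The restriction
matters for REST: with sources extending to the base of the sphere the
common-mode (reference offset) component of the potential is poorly
constrained by a 32-channel cap and the infinity-reference reconstruction
degrades.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["shell_coefficients", "fibonacci_sphere", "leadfield_matrix"]

DEFAULT_RADII = (0.87, 0.92, 1.0)
DEFAULT_SIGMAS = (1.0, 0.0125, 1.0)
DEFAULT_DIPOLE_RADIUS = 0.65
DEFAULT_N_DIPOLES = 4600          # spiral points before the vault cut
DEFAULT_Z_MIN = -0.15
DEFAULT_N_TERMS = 60


def shell_coefficients(
    n_max: int = DEFAULT_N_TERMS,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
) -> np.ndarray:
    """Surface potential coefficients ``s_n`` (index 0 -> degree 1).

    ``s_n`` is the coefficient of ``P_n`` on the outer surface when the
    primary (source) field contributes a unit ``r^-(n+1)`` term in the
    innermost compartment.
    """
    r1, r2, R = radii
    s1, s2, s3 = sigmas
    out = np.empty(n_max)
    for n in range(1, n_max + 1):
        # unknowns: A1, A2, B2, A3, B3 ; primary coefficient p = 1
        A = np.zeros((5, 5))
        b = np.zeros(5)
        # potential continuity at r1
        A[0] = [r1**n, -(r1**n), -(r1 ** -(n + 1)), 0, 0]
        b[0] = -(r1 ** -(n + 1))
        # radial current continuity at r1
        A[1] = [
            s1 * n * r1 ** (n - 1),
            -s2 * n * r1 ** (n - 1),
            s2 * (n + 1) * r1 ** -(n + 2),
            0,
            0,
        ]
        b[1] = s1 * (n + 1) * r1 ** -(n + 2)
        # potential continuity at r2
        A[2] = [0, r2**n, r2 ** -(n + 1), -(r2**n), -(r2 ** -(n + 1))]
        # radial current continuity at r2
        A[3] = [
            0,
            s2 * n * r2 ** (n - 1),
            -s2 * (n + 1) * r2 ** -(n + 2),
            -s3 * n * r2 ** (n - 1),
            s3 * (n + 1) * r2 ** -(n + 2),
        ]
        # no current through the scalp surface
        A[4] = [0, 0, 0, n * R ** (n - 1), -(n + 1) * R ** -(n + 2)]
        x = np.linalg.solve(A, b)
        out[n - 1] = x[3] * R**n + x[4] * R ** -(n + 1)
    return out


def fibonacci_sphere(n: int) -> np.ndarray:
    """``n`` near-uniform unit vectors on the sphere (golden-spiral)."""
    i = np.arange(n)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def _legendre_sums(c: np.ndarray, weights: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Accumulate ``sum_n w_n n P_n(c)`` and ``sum_n w_n P_n'(c)``.

    Upward recurrences for P_n and its derivative, vectorised over ``c``.
    """
    n_max = weights.shape[0]
    p_prev = np.ones_like(c)          # P_0
    p_cur = c.copy()                  # P_1
    dp_prev = np.zeros_like(c)        # P_0'
    dp_cur = np.ones_like(c)          # P_1'
    s_npn = weights[0] * 1 * p_cur
    s_dp = weights[0] * dp_cur
    for n in range(2, n_max + 1):
        p_next = ((2 * n - 1) * c * p_cur - (n - 1) * p_prev) / n
        dp_next = dp_prev + (2 * n - 1) * p_cur
        p_prev, p_cur = p_cur, p_next
        dp_prev, dp_cur = dp_cur, dp_next
        s_npn += weights[n - 1] * n * p_cur
        s_dp += weights[n - 1] * dp_cur
    return s_npn, s_dp


def leadfield_matrix(
    electrodes: np.ndarray,
    n_dipoles: int = DEFAULT_N_DIPOLES,
    dipole_radius: float = DEFAULT_DIPOLE_RADIUS,
    n_terms: int = DEFAULT_N_TERMS,
    radii: tuple[float, float, float] = DEFAULT_RADII,
    sigmas: tuple[float, float, float] = DEFAULT_SIGMAS,
    z_min: float = DEFAULT_Z_MIN,
) -> np.ndarray:
    """Infinity-referenced gain matrix, shape ``(n_channels, 3 * n_kept)``.

    ``n_dipoles`` spiral points are generated and those below ``z_min``
    discarded (the cranial-vault restriction).  Columns are grouped per
    dipole: unit moments along x, y, z.  Electrode positions must be unit
    vectors (scalp radius 1).
    """
    E = np.asarray(electrodes, dtype=float)
    if E.ndim != 2 or E.shape[1] != 3:
        raise ValueError("electrodes must be an (n, 3) array of unit vectors")
    D = fibonacci_sphere(n_dipoles)
    D = D[D[:, 2] > z_min]
    r0 = dipole_radius
    s_n = shell_coefficients(n_terms, radii, sigmas)
    n_arr = np.arange(1, n_terms + 1)
    weights = s_n * r0 ** (n_arr - 1) / (4.0 * np.pi * sigmas[0])
    C = np.clip(E @ D.T, -1.0, 1.0)  # (n_ch, n_dip)
    K1, K2 = _legendre_sums(C, weights)  # radial-term and derivative sums
    n_ch = E.shape[0]
    G = np.empty((n_ch, 3 * D.shape[0]))
    for k in range(3):
        qr = D[:, k][None, :]          # q . rhat per dipole
        qe = E[:, k][:, None]          # q . e per electrode
        G[:, k::3] = K1 * qr + K2 * (qe - C * qr)
    return G


@lru_cache(maxsize=8)
def _cached_leadfield(key: tuple) -> np.ndarray:
    positions = np.array(key, dtype=float).reshape(-1, 3)
    return leadfield_matrix(positions)


def leadfield_for_positions(positions3d: np.ndarray) -> np.ndarray:
    """Cached default leadfield for a set of unit-sphere electrode positions."""
    key = tuple(np.asarray(positions3d, dtype=float).ravel().tolist())
    return _cached_leadfield(key)
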