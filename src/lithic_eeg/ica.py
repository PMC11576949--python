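"""Infomax ICA decomposition and artifact-component removal.

The decomposition is natural-gradient Infomax with a logistic
nonlinearity (no extended sub/super-Gaussian switching — the artifact
classes this pipeline targets, blinks and focal muscle, are
super-Gaussian).  Data are PCA-whitened first; the Infomax weight update
itself is :func:`mne.preprocessing.infomax`.  Component identification is
an automatic operationalisation of the usual visual criteria: an ocular
score combining frontal topography with low-frequency activation power,
and a muscle score combining high-frequency power with topographic
focality.  Cleaning subtracts the back-projection of removed components,
so removing nothing is exactly lossless.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .montage import Montage
from .recording import Recording

__all__ = ["ICADecomposition", "fit_infomax", "score_components", "remove_components"]


@dataclass
class ICADecomposition:
    unmixing: np.ndarray            # components x channels
    mixing: np.ndarray              # channels x components
    activations: np.ndarray         # components x samples
    rate: float
    channel_mean: np.ndarray        # per-channel mean removed before fitting
    converged: bool
    n_iter: int
    eye_scores: np.ndarray | None = None
    muscle_scores: np.ndarray | None = None
    removed: set[int] = field(default_factory=set)

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]


def fit_infomax(
    rec: Recording,
    n_components: int | None = None,
    seed: int = 0,
    max_iter: int = 500,
) -> ICADecomposition:
    """Fit Infomax ICA on a (high-pass filtered) continuous recording.

    Reproducible for a given ``seed``.  Non-convergence at ``max_iter``
    is returned with ``converged=False`` rather than raised.
    """
    X = rec.data
    n_ch, n_samp = X.shape
    if n_components is None:
        n_components = n_ch
    if n_components > n_ch:
        raise ValueError("more components than channels")
    mean = X.mean(axis=1, keepdims=True)
    Xc = X - mean
    # PCA whitening
    U, s, _ = np.linalg.svd(Xc @ Xc.T / n_samp)
    rank = int(np.sum(s > s[0] * 1e-10))
    if rank < n_components:
        raise ValueError(
            f"data rank {rank} below requested {n_components} components"
        )
    W_white = (U[:, :n_components] / np.sqrt(s[:n_components])).T
    Xw = W_white @ Xc
    from mne.preprocessing import infomax

    W, n_iter = infomax(
        Xw.T,
        extended=False,
        max_iter=max_iter,
        rng=seed,
        return_n_iter=True,
        verbose="error",
    )
    unmixing = W @ W_white
    mixing = np.linalg.pinv(unmixing)
    return ICADecomposition(
        unmixing=unmixing,
        mixing=mixing,
        activations=unmixing @ Xc,
        rate=rec.rate,
        channel_mean=mean,
        converged=n_iter < max_iter,
        n_iter=n_iter,
    )


def _frontal_template(montage: Montage) -> np.ndarray:
    """Spatial blink template: Gaussian in great-circle distance from the
    midpoint between Fp1 and Fp2 (falls back to the most anterior site)."""
    p = montage.positions3d
    try:
        mid = p[montage.index("Fp1")] + p[montage.index("Fp2")]
    except KeyError:
        mid = p[np.argmax(p[:, 1])].copy()
    mid /= np.linalg.norm(mid)
    ang = np.arccos(np.clip(p @ mid, -1.0, 1.0))
    return np.exp(-((ang / 0.9) ** 2))


def score_components(dec: ICADecomposition, montage: Montage) -> ICADecomposition:
    """Populate per-component eye and muscle scores (both in [0, 1]).

    eye score    = |corr(topography, frontal template)| x fraction of
                   activation power below 4 Hz
    muscle score = fraction of activation power above 20 Hz x sqrt of
                   topographic focality (max^2 / sum of squares)
    """
    n_comp = dec.n_components
    eye = np.zeros(n_comp)
    muscle = np.zeros(n_comp)
    template = _frontal_template(montage)
    nper = int(min(dec.activations.shape[1], 4 * dec.rate))
    for k in range(n_comp):
        topo = dec.mixing[:, k]
        denom = np.std(topo) * np.std(template)
        corr = 0.0
        if denom > 0:
            corr = abs(np.corrcoef(topo, template)[0, 1])
        f, pxx = sp_signal.welch(dec.activations[k], fs=dec.rate, nperseg=nper)
        total = pxx.sum()
        if total <= 0:
            continue
        lf = pxx[f < 4.0].sum() / total
        hf = pxx[f > 20.0].sum() / total
        focality = (topo**2).max() / (topo**2).sum() if (topo**2).sum() > 0 else 0.0
        eye[k] = min(1.0, corr * lf)
        muscle[k] = min(1.0, hf * np.sqrt(focality))
    dec.eye_scores = eye
    dec.muscle_scores = muscle
    return dec


def remove_components(
    rec: Recording,
    dec: ICADecomposition,
    eye_threshold: float = 0.6,
    muscle_threshold: float = 0.6,
) -> Recording:
    """Back-project retained components; subtract the flagged ones.

    Components with ``eye_score >= eye_threshold`` or ``muscle_score >=
    muscle_threshold`` are removed.  Refuses to remove every component.
    """
    if dec.eye_scores is None or dec.muscle_scores is None:
        raise ValueError("scores not computed; call score_components first")
    removed = {
        k
        for k in range(dec.n_components)
        if dec.eye_scores[k] >= eye_threshold
        or dec.muscle_scores[k] >= muscle_threshold
    }
    if len(removed) == dec.n_components:
        raise ValueError("thresholds would remove every component; refusing")
    dec.removed = removed
    if not removed:
        cleaned = rec.data
    else:
        idx = sorted(removed)
        cleaned = rec.data - dec.mixing[:, idx] @ dec.activations[idx]
    return rec.copy_with(data=cleaned, history=rec.history + ["ica"])
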