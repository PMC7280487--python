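"""Empirical Mode Decomposition by standard Huang sifting.

A small, dependency-free sifter sufficient for short event segments:
cubic-spline upper/lower envelopes through the local extrema
(mirror-extended at the segment edges) and the classic
standard-deviation stopping criterion.  The decomposition is complete by
construction: the IMFs plus the residue sum exactly to the input.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.signal import argrelextrema

__all__ = ["emd", "instantaneous_frequency"]


def _envelope(x: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Cubic-spline envelope through extrema, mirror-extended at the edges.

    Mirroring up to two extrema about each boundary is the standard cure
    for spline divergence outside the outermost extrema, which otherwise
    injects large spurious low-frequency modes.
    """
    n = x.size
    k = min(2, idx.size)
    left = -idx[:k][::-1]
    right = 2 * (n - 1) - idx[-k:][::-1]
    pts = np.concatenate([left, idx, right])
    vals = np.concatenate([x[idx[:k][::-1]], x[idx], x[idx[-k:][::-1]]])
    pts, keep = np.unique(pts, return_index=True)
    return CubicSpline(pts, vals[keep])(np.arange(n))


def emd(
    x: np.ndarray,
    max_imfs: int = 8,
    max_siftings: int = 60,
    sd_threshold: float = 0.2,
) -> tuple[list[np.ndarray], np.ndarray, bool]:
    """Decompose ``x`` into intrinsic mode functions.

    Returns ``(imfs, residue, converged)``.  Sifting of a mode stops when
    the normalized squared change between iterations falls below
    ``sd_threshold`` (Huang's SD criterion) or ``max_siftings`` is hit, in
    which case ``converged`` is False for the decomposition.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValueError("segment too short for sifting (need >= 4 samples)")
    residue = x.copy()
    total = np.sum(x**2)
    imfs: list[np.ndarray] = []
    converged = True
    for _ in range(max_imfs):
        if total > 0 and np.sum(residue**2) < 1e-12 * total:
            break  # residue is numerically zero
        maxima = argrelextrema(residue, np.greater)[0]
        minima = argrelextrema(residue, np.less)[0]
        if maxima.size < 2 or minima.size < 2:
            break  # monotone-ish residue: done
        h = residue.copy()
        mode_converged = False
        for _ in range(max_siftings):
            mx = argrelextrema(h, np.greater)[0]
            mn = argrelextrema(h, np.less)[0]
            if mx.size < 2 or mn.size < 2:
                mode_converged = True
                break
            mean_env = 0.5 * (_envelope(h, mx) + _envelope(h, mn))
            h_new = h - mean_env
            denom = np.sum(h**2)
            sd = np.sum(mean_env**2) / denom if denom > 0 else 0.0
            h = h_new
            if sd < sd_threshold:
                mode_converged = True
                break
        if not mode_converged:
            converged = False
        imfs.append(h)
        residue = residue - h
    return imfs, residue, converged


def instantaneous_frequency(imf: np.ndarray, fs: float) -> float:
    """Mean instantaneous frequency of a mode via the analytic signal."""
    from scipy.signal import hilbert

    if imf.size < 4 or not np.any(imf):
        return 0.0
    phase = np.unwrap(np.angle(hilbert(imf)))
    # trim 10% at each edge where the Hilbert estimate is unreliable
    k = max(imf.size // 10, 1)
    dphi = np.diff(phase[k : imf.size - k])
    if dphi.size == 0:
        return 0.0
    return float(np.abs(np.mean(dphi)) * fs / (2 * np.pi))
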