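"""Rotation-invariant uniform local binary patterns (riu2).

For each non-border pixel, the N circular neighbors at radius R are
sampled (bilinear interpolation off the grid), thresholded against
the center (ties count as 1, so flat regions code as the all-ones
pattern), and mapped riu2-style: uniform patterns (at most two
circular 0/1 transitions) are binned by their number of ones
(0..N), all non-uniform patterns share one catch-all bin — N+2 bins
in total, ten for the default N=8.

Two single-number features summarize the histogram: the mean of the
N+1 uniform-bin frequencies and the non-uniform bin frequency; by
normalization ``(N+1)*uniform + nonuniform = 1``.

Conventions (documented for oracle reproducibility): neighbor 0 lies
east of the center, subsequent neighbors proceed counter-clockwise;
border pixels within R of the edge are excluded rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspaces import ChannelImage

#: the paper-scale radius sweep
RADIUS_SWEEP = (1, 5, 10, 15, 25, 50, 100, 150, 250)


@dataclass(frozen=True)
class LBPHistogram:
    """riu2 pattern-class frequencies: bins 0..N uniform-by-ones, bin N+1 non-uniform."""

    bins: np.ndarray
    R: float
    N: int

    def __post_init__(self) -> None:
        b = np.asarray(self.bins, dtype=float)
        if b.shape != (self.N + 2,):
            raise ValueError("riu2 histogram must have N+2 bins")
        if np.any(b < 0) or abs(b.sum() - 1.0) > 1e-12:
            raise ValueError("histogram must be normalized")


@dataclass(frozen=True)
class LBPFeatures:
    uniform: float
    nonuniform: float


def neighbor_offsets(R: float, N: int) -> np.ndarray:
    """(row, col) offsets of the N circular neighbors, east first, CCW.

    Offsets within 1e-9 of an integer are snapped so that axial
    samples land exactly on pixel centers.
    """
    k = np.arange(N)
    ang = 2.0 * np.pi * k / N
    off = np.stack([-R * np.sin(ang), R * np.cos(ang)], axis=1)
    snapped = np.round(off)
    off[np.abs(off - snapped) < 1e-9] = snapped[np.abs(off - snapped) < 1e-9]
    return off


def sample_neighbors(ch: ChannelImage, center: tuple[int, int], R: float, N: int = 8) -> np.ndarray:
    """Bilinear samples of the N neighbors around one pixel."""
    r, c = center
    out = np.empty(N)
    v = ch.values
    for k, (dr, dc) in enumerate(neighbor_offsets(R, N)):
        out[k] = _bilinear(v, r + dr, c + dc)
    return out


def _bilinear(v: np.ndarray, r: float, c: float) -> float:
    r0, c0 = int(np.floor(r)), int(np.floor(c))
    fr, fc = r - r0, c - c0
    r1, c1 = min(r0 + 1, v.shape[0] - 1), min(c0 + 1, v.shape[1] - 1)
    return float(
        v[r0, c0] * (1 - fr) * (1 - fc)
        + v[r0, c1] * (1 - fr) * fc
        + v[r1, c0] * fr * (1 - fc)
        + v[r1, c1] * fr * fc
    )


def _ge(values: np.ndarray, center) -> np.ndarray:
    """Threshold with ties -> 1, robust to bilinear rounding error.

    Interpolated samples of a flat region can undershoot the center by
    ~1 ulp; a small relative guard keeps exact ties coding as 1.
    """
    tol = 1e-9 * (1.0 + np.abs(center))
    return np.asarray(values) - center >= -tol


def lbp_code(neighbor_values: np.ndarray, center_value: float) -> int:
    """Binary pattern: bit k set iff neighbor_k >= center (ties -> 1)."""
    bits = _ge(neighbor_values, center_value)
    return int(sum(int(b) << k for k, b in enumerate(bits)))


def uniformity(pattern: int, N: int = 8) -> int:
    """Number of circular 0<->1 transitions of an N-bit pattern."""
    bits = [(pattern >> k) & 1 for k in range(N)]
    return sum(bits[k] != bits[(k + 1) % N] for k in range(N))


def is_uniform(pattern: int, N: int = 8) -> bool:
    return uniformity(pattern, N) <= 2


def riu2_class(pattern: int, N: int = 8) -> int:
    """riu2 bin of a pattern: popcount if uniform, else N+1."""
    if is_uniform(pattern, N):
        return bin(pattern).count("1")
    return N + 1


def lbp_histogram(ch: ChannelImage, R: float, N: int = 8) -> LBPHistogram:
    """riu2 histogram over all pixels farther than R from the border."""
    v = ch.values
    H, W = v.shape
    m = int(np.ceil(R))
    if H < 2 * m + 1 or W < 2 * m + 1:
        raise ValueError(f"image smaller than 2R+1 = {2 * m + 1} pixels")
    rows = np.arange(m, H - m)
    cols = np.arange(m, W - m)
    center = v[m : H - m, m : W - m]
    # accumulate, per neighbor, the riu2 ingredients over the whole valid block
    bits = np.empty((N,) + center.shape, dtype=bool)
    for k, (dr, dc) in enumerate(neighbor_offsets(R, N)):
        rr = rows[:, None] + dr
        cc = cols[None, :] + dc
        r0 = np.floor(rr).astype(int)
        c0 = np.floor(cc).astype(int)
        fr, fc = rr - r0, cc - c0
        r1 = np.minimum(r0 + 1, H - 1)
        c1 = np.minimum(c0 + 1, W - 1)
        sample = (
            v[r0, c0] * (1 - fr) * (1 - fc)
            + v[r0, c1] * (1 - fr) * fc
            + v[r1, c0] * fr * (1 - fc)
            + v[r1, c1] * fr * fc
        )
        bits[k] = _ge(sample, center)
    ones = bits.sum(axis=0)
    transitions = np.zeros(center.shape, dtype=np.int32)
    for k in range(N):
        transitions += bits[k] != bits[(k + 1) % N]
    classes = np.where(transitions <= 2, ones, N + 1)
    counts = np.bincount(classes.ravel(), minlength=N + 2).astype(float)
    return LBPHistogram(counts / counts.sum(), R=R, N=N)


def lbp_features(hist: LBPHistogram) -> LBPFeatures:
    """Mean uniform-bin frequency and the non-uniform bin frequency."""
    b = np.asarray(hist.bins)
    return LBPFeatures(uniform=float(b[: hist.N + 1].mean()), nonuniform=float(b[hist.N + 1]))
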