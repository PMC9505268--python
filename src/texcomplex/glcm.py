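"""Co-occurrence matrices and the five second-order texture features.

A co-occurrence matrix (CoM) holds the joint probabilities of ordered
pixel-value pairs at displacement (distance ``d``, angle ``theta``).
From it the five classic Haralick-style features are computed: energy
(angular second moment), contrast, correlation, entropy (bits), and
homogeneity (inverse difference moment).  Rotation-invariant features
average the per-angle feature values over the eight 45-degree-spaced
angles; diagonal displacements use the (+-d, +-d) chessboard offsets.

The counting here deliberately does not delegate to
``skimage.feature.graycomatrix``: for 45-degree-family angles that
routine rounds ``d*cos`` / ``d*sin`` offsets (d=5 at 45 degrees gives
offset 4), whereas the chessboard convention keeps the full distance
on both axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspaces import ChannelImage

ANGLES_8 = (0, 45, 90, 135, 180, 225, 270, 315)
#: the paper-scale distance sweep
DISTANCE_SWEEP = (1, 5, 10, 15, 25, 50, 100, 150, 250)

# (row, col) displacement per angle, angles CCW from east, rows increasing
# downward; diagonals use the full (+-d, +-d) offsets.
_OFFSETS = {
    0: (0, 1),
    45: (-1, 1),
    90: (-1, 0),
    135: (-1, -1),
    180: (0, -1),
    225: (1, -1),
    270: (1, 0),
    315: (1, 1),
}

FEATURE_NAMES = ("enrg_com", "cont_com", "corr_com", "entp_com", "homg_com")


@dataclass(frozen=True)
class CoMatrix:
    """L x L joint probability matrix of pixel pairs at (d, theta)."""

    P: np.ndarray
    d: int
    theta: int
    levels: int

    def __post_init__(self) -> None:
        P = np.asarray(self.P, dtype=float)
        if P.shape != (self.levels, self.levels):
            raise ValueError("CoMatrix shape must be levels x levels")
        if np.any(P < 0) or abs(P.sum() - 1.0) > 1e-12:
            raise ValueError("CoMatrix must be a probability matrix")


@dataclass(frozen=True)
class CoMFeatures:
    enrg_com: float
    cont_com: float
    corr_com: float
    entp_com: float
    homg_com: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in FEATURE_NAMES}


def quantize(ch: ChannelImage, levels: int = 256) -> np.ndarray:
    """Uniformly quantize the channel's nominal range into integer bins.

    Returns an int array with values in [0, levels).  Idempotent on an
    already-quantized channel (the bin centers map back to their own
    bins).
    """
    if levels < 2:
        raise ValueError("levels must be >= 2")
    lo, hi = ch.value_range
    if not hi > lo:
        hi = lo + 1.0
    x = (np.clip(ch.values, lo, hi) - lo) / (hi - lo)
    return np.minimum((x * levels).astype(np.int64), levels - 1)


def compute_com(indexed: np.ndarray, d: int, theta: int, levels: int) -> CoMatrix:
    """Co-occurrence matrix of ordered pairs at displacement (d, theta).

    Pairs whose second pixel falls outside the image are dropped (no
    wrap-around).
    """
    indexed = np.asarray(indexed)
    if d < 1:
        raise ValueError("d must be >= 1")
    if theta not in _OFFSETS:
        raise ValueError(f"theta must be one of {ANGLES_8}")
    dr, dc = (o * d for o in _OFFSETS[theta])
    H, W = indexed.shape
    r0, r1 = max(0, -dr), min(H, H - dr)
    c0, c1 = max(0, -dc), min(W, W - dc)
    if r1 <= r0 or c1 <= c0:
        raise ValueError("displacement exceeds image extent: no valid pairs")
    a = indexed[r0:r1, c0:c1].ravel()
    b = indexed[r0 + dr : r1 + dr, c0 + dc : c1 + dc].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(levels, levels)
    return CoMatrix(counts / counts.sum(), d=d, theta=theta, levels=levels)


def com_energy(C: CoMatrix) -> float:
    """Angular second moment sum(P^2)."""
    return float(np.sum(np.asarray(C.P) ** 2))


def com_contrast(C: CoMatrix) -> float:
    """sum((i-j)^2 P): local intensity variation."""
    i, j = np.indices(C.P.shape)
    return float(np.sum((i - j) ** 2 * C.P))


def com_correlation(C: CoMatrix) -> float:
    """Linear dependency of paired values; NaN when either margin is constant."""
    P = np.asarray(C.P)
    i = np.arange(C.levels, dtype=float)
    pi, pj = P.sum(axis=1), P.sum(axis=0)
    mi, mj = float(i @ pi), float(i @ pj)
    si = float(np.sqrt(((i - mi) ** 2) @ pi))
    sj = float(np.sqrt(((i - mj) ** 2) @ pj))
    if si * sj == 0.0:
        return float("nan")
    ii, jj = np.indices(P.shape)
    return float(np.sum((ii - mi) * (jj - mj) * P) / (si * sj))


def com_entropy(C: CoMatrix) -> float:
    """-sum(P log2 P) in bits."""
    p = np.asarray(C.P).ravel()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def com_homogeneity(C: CoMatrix, abs_variant: bool = False) -> float:
    """Inverse difference moment sum(P / (1 + (i-j)^2)).

    ``abs_variant`` switches the denominator to ``1 + |i-j|``.
    """
    i, j = np.indices(C.P.shape)
    den = 1 + (np.abs(i - j) if abs_variant else (i - j) ** 2)
    return float(np.sum(C.P / den))


def com_features(C: CoMatrix) -> CoMFeatures:
    """All five features of one co-occurrence matrix."""
    return CoMFeatures(
        enrg_com=com_energy(C),
        cont_com=com_contrast(C),
        corr_com=com_correlation(C),
        entp_com=com_entropy(C),
        homg_com=com_homogeneity(C),
    )


def rotation_invariant_com_features(
    ch: ChannelImage, d: int, levels: int = 256, angles: tuple[int, ...] = ANGLES_8
) -> CoMFeatures:
    """Per-angle features averaged over the angle set.

    Features are computed per angle and then averaged (not the
    matrices), so each angle's matrix is normalized independently.
    A NaN correlation at any angle propagates to the average.
    """
    indexed = quantize(ch, levels)
    per_angle = [com_features(compute_com(indexed, d, t, levels)) for t in angles]
    return CoMFeatures(
        **{k: float(np.mean([getattr(f, k) for f in per_angle])) for k in FEATURE_NAMES}
    )
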