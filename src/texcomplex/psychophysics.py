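"""Rank-order psychophysics: visual rank scores, STRESS, viewing geometry.

A panel of S observers sorts T samples from weakest to strongest
expression of an attribute; ties are allowed and consume a single
position value.  The visual rank score of a sample is

    VRS = (1 / (S (T - 1))) * sum_t t * Q_t,

where Q_t counts the observers that placed the sample at position t
— i.e. the sample's mean assigned position divided by (T - 1).  The
raw score lies in [1/(T-1), T/(T-1)] and is linearly rescaled per
attribute so the analyzed set spans 0..10.

Observer consistency is quantified with STRESS (standardized
residual sum of squares), a 0..100 scale-invariant disagreement
index between two score vectors: 0 means one is a positive multiple
of the other.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class RankMatrix:
    """S x T matrix of assigned positions (1..T, ties allowed).

    ``observers`` and ``replicates`` optionally tag each row; rows of
    the same observer with different replicate indices are repeat
    sessions, used by the intra-observer STRESS analysis.
    """

    ranks: np.ndarray
    attribute: str = ""
    observers: list | None = None
    replicates: list | None = None
    sample_ids: list | None = None

    def __post_init__(self) -> None:
        r = np.asarray(self.ranks, dtype=int)
        if r.ndim != 2 or r.shape[1] == 0 or r.shape[0] == 0:
            raise ValueError("ranks must be a non-empty S x T matrix")
        T = r.shape[1]
        if r.min() < 1 or r.max() > T:
            raise ValueError(f"rank positions must lie in 1..{T}")
        self.ranks = r
        if self.observers is None:
            self.observers = list(range(r.shape[0]))
        if self.replicates is None:
            self.replicates = [0] * r.shape[0]
        if self.sample_ids is None:
            self.sample_ids = [f"s{j:03d}" for j in range(T)]

    @property
    def n_observers(self) -> int:
        return len(set(self.observers))

    @property
    def n_samples(self) -> int:
        return self.ranks.shape[1]


@dataclass(frozen=True)
class VRSVector:
    """Per-sample visual rank scores, raw and rescaled to 0..10."""

    raw: np.ndarray
    rescaled: np.ndarray
    attribute: str = ""
    sample_ids: list | None = None


@dataclass(frozen=True)
class StressReport:
    intra_per_observer: dict = field(default_factory=dict)
    inter_per_observer: dict = field(default_factory=dict)

    @property
    def intra(self) -> float:
        v = list(self.intra_per_observer.values())
        return float(np.mean(v)) if v else float("nan")

    @property
    def inter(self) -> float:
        v = list(self.inter_per_observer.values())
        return float(np.mean(v)) if v else float("nan")


def rescale_0_10(x: np.ndarray) -> np.ndarray:
    """Min-max rescale so the minimum maps to 0 and the maximum to 10."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn("all scores equal; rescaled values set to 5.0", stacklevel=2)
        return np.full_like(x, 5.0)
    return 10.0 * (x - lo) / (hi - lo)


def vrs(rm: RankMatrix) -> VRSVector:
    """Visual rank scores of all samples from one rank matrix."""
    S, T = rm.ranks.shape
    if T < 2:
        raise ValueError("need at least two samples to rank")
    raw = rm.ranks.mean(axis=0) / (T - 1)
    return VRSVector(raw=raw, rescaled=rescale_0_10(raw), attribute=rm.attribute, sample_ids=rm.sample_ids)


def stress(a: np.ndarray, b: np.ndarray) -> float:
    """STRESS between score vectors, in 0..100 percent units.

    ``b`` is scaled by the least-squares factor F = sum(a b)/sum(b^2)
    before residuals are taken:

        STRESS = 100 * sqrt( sum((a - F b)^2) / sum((F b)^2) ).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("score vectors must have equal length")
    bb = float(b @ b)
    if bb == 0.0:
        raise ValueError("reference vector is identically zero")
    F = float(a @ b) / bb
    scaled = F * b
    denom = float(scaled @ scaled)
    if denom == 0.0:
        return 100.0
    return float(100.0 * np.sqrt(float((a - scaled) @ (a - scaled)) / denom))


def intra_observer_stress(rm: RankMatrix) -> StressReport:
    """Per-observer STRESS between replicate rank vectors.

    All replicate pairs of an observer are compared and averaged;
    observers with fewer than two replicates are omitted.
    """
    per: dict = {}
    for obs in dict.fromkeys(rm.observers):
        rows = [i for i, o in enumerate(rm.observers) if o == obs]
        if len(rows) < 2:
            continue
        vals = [
            stress(rm.ranks[i], rm.ranks[j])
            for ai, i in enumerate(rows)
            for j in rows[ai + 1 :]
        ]
        per[obs] = float(np.mean(vals))
    return StressReport(intra_per_observer=per)


def inter_observer_stress(rm: RankMatrix) -> StressReport:
    """Each observer's mean ranks against the leave-one-out panel mean.

    The leave-one-out reference avoids inflating agreement by
    correlating an observer with a mean that contains them.
    """
    obs_ids = list(dict.fromkeys(rm.observers))
    if len(obs_ids) < 2:
        raise ValueError("inter-observer STRESS needs at least two observers")
    means = {
        o: rm.ranks[[i for i, oo in enumerate(rm.observers) if oo == o]].mean(axis=0)
        for o in obs_ids
    }
    per: dict = {}
    for o in obs_ids:
        others = np.mean([means[q] for q in obs_ids if q != o], axis=0)
        per[o] = stress(means[o], others)
    return StressReport(inter_per_observer=per)


def visual_angle(extent_cm: float, distance_cm: float) -> float:
    """Visual angle in degrees subtended by ``extent_cm`` at ``distance_cm``."""
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    return float(np.rad2deg(2.0 * np.arctan2(extent_cm / 2.0, distance_cm)))


def pixels_to_extent(pixels: float, image_px: int, sample_cm: float) -> float:
    """Physical extent (cm) of ``pixels`` image pixels on the sample."""
    if image_px <= 0:
        raise ValueError("image_px must be positive")
    return float(pixels) * sample_cm / image_px
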