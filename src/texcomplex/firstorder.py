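"""First-order image descriptors: global statistics and histogram measures.

Six descriptors per channel: global mean (brightness) and population
standard deviation (contrast as value spread), plus four measures of
the value histogram — skewness, kurtosis (non-excess), energy
sum(p_i^2) and Shannon entropy in bits.  Histogram energy and entropy
vary inversely over concentration/dispersion of the value
distribution, which is why entropy has a history as a crude
complexity proxy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .colorspaces import ChannelImage

DESCRIPTOR_NAMES = ("mu", "sigma", "m3", "m4", "enrg_h", "entp_h")


@dataclass(frozen=True)
class Histogram:
    """Normalized equal-width histogram of a channel's values."""

    bin_edges: np.ndarray
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("histogram probabilities must be nonnegative and sum to 1")

    @property
    def bin_centers(self) -> np.ndarray:
        e = np.asarray(self.bin_edges, dtype=float)
        return 0.5 * (e[:-1] + e[1:])


@dataclass(frozen=True)
class DescriptorSet:
    mu: float
    sigma: float
    m3: float
    m4: float
    enrg_h: float
    entp_h: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


def global_mean(ch: ChannelImage) -> float:
    """Arithmetic mean of all pixel values (general brightness)."""
    return float(np.mean(ch.values))


def global_std(ch: ChannelImage) -> float:
    """Population standard deviation of pixel values (value spread)."""
    return float(np.std(ch.values))


def histogram(ch: ChannelImage, n_bins: int = 256) -> Histogram:
    """Equal-width histogram over the channel's nominal range.

    Values outside the nominal range (possible for a* / b*) are
    clipped into the edge bins.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    lo, hi = ch.value_range
    if not hi > lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    counts, _ = np.histogram(np.clip(ch.values, lo, hi), bins=edges)
    return Histogram(edges, counts / counts.sum())


def _standardized_moment(h: Histogram, order: int) -> float:
    c = h.bin_centers
    p = np.asarray(h.probabilities, dtype=float)
    mu = float(np.sum(p * c))
    var = float(np.sum(p * (c - mu) ** 2))
    if var <= 0.0:
        return 0.0 if order % 2 == 1 else float("nan")
    return float(np.sum(p * (c - mu) ** order) / var ** (order / 2.0))


def hist_skewness(h: Histogram) -> float:
    """Standardized third central moment; 0 for a degenerate histogram."""
    return _standardized_moment(h, 3)


def hist_kurtosis(h: Histogram) -> float:
    """Standardized fourth central moment (non-excess); NaN when degenerate."""
    return _standardized_moment(h, 4)


def hist_energy(h: Histogram) -> float:
    """sum(p_i^2): high when mass concentrates in few values."""
    return float(np.sum(np.asarray(h.probabilities) ** 2))


def hist_entropy(h: Histogram) -> float:
    """Shannon entropy -sum(p log2 p) in bits, with 0 log 0 := 0."""
    p = np.asarray(h.probabilities, dtype=float)
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def descriptors(ch: ChannelImage, n_bins: int = 256) -> DescriptorSet:
    """All six first-order descriptors of a channel."""
    h = histogram(ch, n_bins)
    return DescriptorSet(
        mu=global_mean(ch),
        sigma=global_std(ch),
        m3=hist_skewness(h),
        m4=hist_kurtosis(h),
        enrg_h=hist_energy(h),
        entp_h=hist_entropy(h),
    )
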