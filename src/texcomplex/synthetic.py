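"""Synthetic textures with known latent attributes, and simulated panels.

The visual study this package analyzes used physical textiles whose
per-sample scores were never deposited, so every pipeline stage is
exercised on a controllable stand-in:

* textures: a periodic grating blended with band-limited noise drives
  the luminance plane; smooth opponent-plane noise around a base
  color drives chromatic variation.  The generator knobs map onto the
  perceptual attributes — noise amplitude = randomness, contrast
  amplitude = strongness, chroma amplitude = color variation,
  1 - noise = regularity, grating cycle count = repetitiveness;
* the latent complexity of a texture is the weighted sum
  0.50 randomness + 0.34 color variation + 0.41 strongness
  - 0.19 regularity - 0.14 repetitiveness (the attribute-model
  weights, reused as generating truth so recovery of the model form
  is testable);
* observer panels: each observer draws a persistent bias
  (sd = sigma_inter) and each replicate adds fresh perceptual noise
  (sd = sigma_intra, same units as the latent score) before ranking
  samples by perceived score.

Construction is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi
from scipy.stats import rankdata

from .psychophysics import RankMatrix

#: generating weights of latent complexity over
#: (randomness, color variation, strongness, regularity, repetitiveness)
COMPLEXITY_WEIGHTS = {
    "randomness": 0.50,
    "color_variation": 0.34,
    "strongness": 0.41,
    "regularity": -0.19,
    "repetitiveness": -0.14,
}

ATTRIBUTE_NAMES = tuple(COMPLEXITY_WEIGHTS)

# inverse of the Ohta I1I2I3 forward matrix: the luminance plane below
# is I1 of the output exactly, so intensity-channel statistics follow
# the generator's closed forms regardless of chroma perturbation
_OHTA = np.array([[1 / 3, 1 / 3, 1 / 3], [0.5, 0.0, -0.5], [-0.25, 0.5, -0.25]])
_OHTA_INV = np.linalg.inv(_OHTA)


@dataclass(frozen=True)
class TextureParams:
    """Knobs of one synthetic texture.

    Amplitudes live in [0, 1]; ``grating_period`` is in pixels
    (>= 2).  ``noise_smoothness`` is the Gaussian low-pass sigma (px)
    of the band-limited noise.
    """

    size_px: int = 256
    grating_period: int = 32
    noise_amplitude: float = 0.0
    contrast_amplitude: float = 0.5
    chroma_amplitude: float = 0.0
    base_color: tuple[float, float, float] = (0.5, 0.5, 0.5)
    noise_smoothness: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("noise_amplitude", "contrast_amplitude", "chroma_amplitude"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.grating_period < 2:
            raise ValueError("grating_period must be >= 2 px")
        if self.size_px < 4:
            raise ValueError("size_px must be >= 4")


@dataclass(frozen=True)
class ObserverPanel:
    """A simulated panel: S observers with intra/inter noise levels."""

    n_observers: int = 10
    sigma_intra: float = 0.10
    sigma_inter: float = 0.22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_observers < 1:
            raise ValueError("need at least one observer")
        if self.sigma_intra < 0 or self.sigma_inter < 0:
            raise ValueError("noise levels must be nonnegative")


def _grating(size: int, period: int) -> np.ndarray:
    """Diagonal sine grating in [-1, 1]; RMS = 1/sqrt(2) over full periods."""
    idx = np.arange(size)
    phase = 2.0 * np.pi * (idx[:, None] + idx[None, :]) / period
    return np.sin(phase)


def _bandlimited_noise(size: int, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Low-pass-filtered white Gaussian noise, zero mean, unit RMS."""
    n = _ndi.gaussian_filter(rng.standard_normal((size, size)), sigma, mode="wrap")
    n -= n.mean()
    rms = np.sqrt(np.mean(n**2))
    return n / rms if rms > 0 else n


def generate_texture(p: TextureParams) -> np.ndarray:
    """Render the texture as an H x W x 3 sRGB array in [0, 1].

    The luminance plane is
    ``0.5 + contrast_amplitude * blend / 2`` with
    ``blend = sqrt(1 - a) * grating + sqrt(2 a) * noise_field`` for
    noise amplitude ``a``, where both components have RMS 1/sqrt(2).
    The square-root mixing makes the blend's power linear in ``a``,
    so the luminance spread grows strictly monotonically with the
    randomness driver — disordered textures carry more luminance
    variation, not just differently arranged variation — while a
    noise-free texture stays a pure grating whose intensity-channel
    standard deviation is exactly ``contrast_amplitude / (2 sqrt 2)``
    (and inside [0, 1] at any contrast).  Chromatic variation adds
    smooth noise to the two opponent planes around the base color.
    """
    rng = np.random.default_rng(p.seed)
    g = _grating(p.size_px, p.grating_period)
    noise = _bandlimited_noise(p.size_px, p.noise_smoothness, rng) / np.sqrt(2.0)
    a = p.noise_amplitude
    blend = np.sqrt(1.0 - a) * g + np.sqrt(2.0 * a) * noise
    lum = np.clip(0.5 + 0.5 * p.contrast_amplitude * blend, 0.0, 1.0)

    base = np.asarray(p.base_color, dtype=float)
    base_opp = _OHTA @ base  # (I1, I2, I3) of the base color
    chroma_gain = 0.15  # opponent-plane excursion at full chroma amplitude
    c2 = base_opp[1] + p.chroma_amplitude * chroma_gain * _bandlimited_noise(
        p.size_px, p.noise_smoothness, rng
    )
    c3 = base_opp[2] + p.chroma_amplitude * chroma_gain * _bandlimited_noise(
        p.size_px, p.noise_smoothness, rng
    )
    # per-pixel gamut compression of the chroma vector: rgb = lum + B q, so
    # shrinking q toward neutral keeps rgb in [0, 1] without touching the
    # intensity plane (Int = I1 = lum exactly)
    B = _OHTA_INV[:, 1:3]
    q = np.stack([c2, c3], axis=-1)
    delta = q @ B.T  # per-channel excursion around lum
    with np.errstate(divide="ignore", invalid="ignore"):
        room_hi = np.where(delta > 0, (1.0 - lum[..., None]) / delta, np.inf)
        room_lo = np.where(delta < 0, -lum[..., None] / delta, np.inf)
    scale = np.minimum(1.0, np.minimum(room_hi, room_lo).min(axis=-1))
    rgb = lum[..., None] + scale[..., None] * delta
    return np.clip(rgb, 0.0, 1.0)


def latent_attributes(p: TextureParams) -> dict[str, float]:
    """Ground-truth attribute scores and latent complexity of a texture.

    Repetitiveness is the grating cycle count normalized by the
    maximum resolvable count (period 2), so it lies in (0, 1].
    """
    att = {
        "randomness": p.noise_amplitude,
        "color_variation": p.chroma_amplitude,
        "strongness": p.contrast_amplitude,
        "regularity": 1.0 - p.noise_amplitude,
        "repetitiveness": (p.size_px / p.grating_period) / (p.size_px / 2.0),
    }
    att["complexity"] = float(sum(COMPLEXITY_WEIGHTS[k] * att[k] for k in ATTRIBUTE_NAMES))
    # homogeneity sits at the opposite extreme of the same perceptual
    # dimension as complexity, so its latent score is the mirror image
    att["homogeneity"] = -att["complexity"]
    return att


def sample_params(
    n: int,
    seed: int = 0,
    size_px: int = 128,
    period_range: tuple[int, int] = (3, 64),
) -> list[TextureParams]:
    """Draw n textures with independent uniform attribute amplitudes.

    Grating periods are log-uniform over ``period_range`` so the
    repetitiveness driver varies continuously across the set.
    """
    rng = np.random.default_rng(seed)
    lo, hi = period_range
    hi = min(hi, size_px // 2)
    out = []
    for i in range(n):
        out.append(
            TextureParams(
                size_px=size_px,
                grating_period=int(round(np.exp(rng.uniform(np.log(lo), np.log(hi))))),
                noise_amplitude=float(rng.uniform()),
                contrast_amplitude=float(rng.uniform()),
                chroma_amplitude=float(rng.uniform()),
                base_color=(0.45, 0.55, 0.5),
                seed=int(rng.integers(2**31 - 1)),
            )
        )
    return out


def attribute_table(params: list[TextureParams]) -> pd.DataFrame:
    """Latent attribute scores of a texture set, one row per sample."""
    rows = [latent_attributes(p) for p in params]
    return pd.DataFrame(rows, index=[f"s{i:03d}" for i in range(len(params))])


def simulate_rankings(
    scores: np.ndarray,
    panel: ObserverPanel,
    replicates: int = 1,
    attribute: str = "",
    seed: int | None = None,
) -> RankMatrix:
    """Rank matrix of a simulated panel judging the given latent scores.

    Each observer draws a persistent per-sample bias vector
    (sd = sigma_inter): their stable, idiosyncratic reading of each
    sample, shared by all their replicates.  Each replicate adds fresh
    perceptual noise (sd = sigma_intra) and sorts samples ascending by
    perceived score.  Ties occur only on exact equality of the
    perceived scores and share a single position value.
    """
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(panel.seed if seed is None else seed)
    bias = panel.sigma_inter * rng.standard_normal((panel.n_observers, len(scores)))
    rows, observers, reps = [], [], []
    for o in range(panel.n_observers):
        for rep in range(replicates):
            perceived = scores + bias[o] + panel.sigma_intra * rng.standard_normal(len(scores))
            rows.append(rankdata(perceived, method="dense").astype(int))
            observers.append(o)
            reps.append(rep)
    return RankMatrix(
        np.asarray(rows), attribute=attribute, observers=observers, replicates=reps
    )
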