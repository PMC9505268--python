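"""Gabor filter bank and rotation-invariant energy features.

A Gabor filter is a complex sinusoid carrier of spatial frequency F
(cycles/pixel) and orientation theta modulated by a Gaussian
envelope whose widths are set by the smoothing parameters gamma
(along the carrier) and eta (across it):

    g(x, y) = (F^2 / (pi * gamma * eta))
              * exp(-F^2 (x'^2 / gamma^2 + y'^2 / eta^2))
              * exp(i 2 pi F x')

with (x', y') the coordinates rotated by theta.  The default bank
follows the six-frequency {1, 0.7, 0.5, 0.35, 0.25, 0.18} x
six-orientation {0..150 deg} grid (36 filters), gamma = eta = 0.5.

"Energy" is the modulus of the complex convolution response
(a squared-modulus variant is available behind a flag); the texture
features are the image-wide mean and standard deviation of the
energy, averaged over orientations for rotation invariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .colorspaces import ChannelImage

DEFAULT_FREQUENCIES = (1.0, 0.7, 0.5, 0.35, 0.25, 0.18)
DEFAULT_ORIENTATIONS = (0.0, 30.0, 60.0, 90.0, 120.0, 150.0)


@dataclass(frozen=True)
class GaborFilter:
    F: float
    theta: float  # degrees
    gamma: float
    eta: float
    kernel: np.ndarray = field(repr=False)


@dataclass(frozen=True)
class GaborFeatures:
    """Orientation-averaged (mean, std) of filter-response energy at one frequency."""

    F: float
    mu: float
    sigma: float


def make_filter(F: float, theta: float, gamma: float = 0.5, eta: float = 0.5) -> GaborFilter:
    """Sampled complex Gabor kernel, truncated at 3 envelope standard deviations."""
    if not 0.0 < F <= 1.0:
        raise ValueError("F must lie in (0, 1] cycles/pixel")
    # envelope stds: exp(-F^2 x'^2/gamma^2) = exp(-x'^2/(2 s^2)) -> s = gamma/(F sqrt 2)
    s_max = max(gamma, eta) / (F * np.sqrt(2.0))
    half = max(int(np.ceil(3.0 * s_max)), 2)
    y, x = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
    t = np.deg2rad(theta)
    xp = x * np.cos(t) + y * np.sin(t)
    yp = -x * np.sin(t) + y * np.cos(t)
    env = np.exp(-(F**2) * (xp**2 / gamma**2 + yp**2 / eta**2))
    kernel = (F**2 / (np.pi * gamma * eta)) * env * np.exp(2j * np.pi * F * xp)
    return GaborFilter(F=F, theta=theta, gamma=gamma, eta=eta, kernel=kernel)


def make_bank(
    frequencies: tuple[float, ...] = DEFAULT_FREQUENCIES,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    gamma: float = 0.5,
    eta: float = 0.5,
) -> list[GaborFilter]:
    """One filter per (frequency, orientation) pair; 36 by default."""
    return [make_filter(F, th, gamma, eta) for F in frequencies for th in orientations]


def filter_energy(ch: ChannelImage, filt: GaborFilter, squared: bool = False) -> ChannelImage:
    """Per-pixel energy of the filtered channel.

    Same-size complex convolution with reflect padding (zero padding
    would fabricate edge energy); energy is the response modulus, or
    its square when ``squared``.
    """
    half = filt.kernel.shape[0] // 2
    padded = np.pad(ch.values, half, mode="reflect")
    resp = fftconvolve(padded, filt.kernel, mode="valid")
    energy = np.abs(resp)
    if squared:
        energy = energy**2
    return ChannelImage(energy, name=f"{ch.name}|energy", space=ch.space, role=ch.role)


def rotation_invariant_gabor_features(
    ch: ChannelImage,
    F: float,
    orientations: tuple[float, ...] = DEFAULT_ORIENTATIONS,
    gamma: float = 0.5,
    eta: float = 0.5,
    squared: bool = False,
) -> GaborFeatures:
    """(mean, std) of energy per orientation, averaged over orientations."""
    mus, sigmas = [], []
    for th in orientations:
        e = filter_energy(ch, make_filter(F, th, gamma, eta), squared=squared).values
        mus.append(e.mean())
        sigmas.append(e.std())
    return GaborFeatures(F=F, mu=float(np.mean(mus)), sigma=float(np.mean(sigmas)))
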