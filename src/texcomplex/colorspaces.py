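"""Color-space decomposition of sRGB images into per-channel rasters.

Five spaces are supported: sRGB itself (plus its intensity image),
HSV, YCbCr (BT.601 full range, zero-centered chroma), Ohta's I1I2I3,
and CIELAB (D65, 2 degree observer).  Each output channel carries a
role tag — ``luminance``, ``chrominance`` or ``raw`` — because the
downstream correlation analysis contrasts luminance against
chrominance channels: V, Y, I1, L* and the intensity image are
luminance; H, S, Cb, Cr, I2, I3, a*, b* are chrominance; R, G, B are
raw (the sRGB channels mix both kinds of information).

All transforms except CIELAB operate directly on the gamma-encoded
sRGB values in [0, 1]; CIELAB linearizes first (IEC 61966-2-1), as the
space is defined on tristimulus values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from skimage import color as _skcolor

Role = Literal["luminance", "chrominance", "raw"]

#: role of every channel label, used by the analysis layer
CHANNEL_ROLES: dict[str, Role] = {
    "R": "raw",
    "G": "raw",
    "B": "raw",
    "Int": "luminance",
    "H": "chrominance",
    "S": "chrominance",
    "V": "luminance",
    "Y": "luminance",
    "Cb": "chrominance",
    "Cr": "chrominance",
    "I1": "luminance",
    "I2": "chrominance",
    "I3": "chrominance",
    "L*": "luminance",
    "a*": "chrominance",
    "b*": "chrominance",
}

#: nominal value range of each channel, used for histogram/quantization bounds
CHANNEL_RANGES: dict[str, tuple[float, float]] = {
    "R": (0.0, 1.0),
    "G": (0.0, 1.0),
    "B": (0.0, 1.0),
    "Int": (0.0, 1.0),
    "H": (0.0, 1.0),
    "S": (0.0, 1.0),
    "V": (0.0, 1.0),
    "Y": (0.0, 1.0),
    "Cb": (-0.5, 0.5),
    "Cr": (-0.5, 0.5),
    "I1": (0.0, 1.0),
    "I2": (-0.5, 0.5),
    "I3": (-0.5, 0.5),
    "L*": (0.0, 100.0),
    "a*": (-128.0, 128.0),
    "b*": (-128.0, 128.0),
}

# BT.601 full-range luma weights; chroma rows scaled so Cb, Cr span [-0.5, 0.5]
# and are exactly 0 on achromatic pixels.
_YCBCR_MATRIX = np.array(
    [
        [0.299, 0.587, 0.114],
        [-0.299 / 1.772, -0.587 / 1.772, 0.886 / 1.772],
        [0.701 / 1.402, -0.587 / 1.402, -0.114 / 1.402],
    ]
)

_I1I2I3_MATRIX = np.array(
    [
        [1.0 / 3.0, 1.0 / 3.0, 1.0 / 3.0],
        [0.5, 0.0, -0.5],
        [-0.25, 0.5, -0.25],
    ]
)


@dataclass
class ChannelImage:
    """A single 2-D raster extracted from a color image.

    Parameters
    ----------
    values : ndarray
        2-D float array of channel values.
    name : str
        Channel label (one of ``CHANNEL_ROLES``).
    space : str
        Source color space.
    role : str, optional
        ``luminance`` / ``chrominance`` / ``raw``; inferred from
        ``name`` when omitted.
    """

    values: np.ndarray
    name: str
    space: str
    role: Role = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("ChannelImage requires a 2-D array")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ChannelImage values must be finite")
        if self.role is None:
            try:
                self.role = CHANNEL_ROLES[self.name]
            except KeyError:
                raise ValueError(f"unknown channel label {self.name!r}") from None
        if self.name in CHANNEL_ROLES and CHANNEL_ROLES[self.name] != self.role:
            raise ValueError(
                f"channel {self.name!r} must have role {CHANNEL_ROLES[self.name]!r}"
            )

    @property
    def value_range(self) -> tuple[float, float]:
        """Nominal (lo, hi) range of this channel."""
        return CHANNEL_RANGES.get(self.name, (float(self.values.min()), float(self.values.max())))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


def _check_rgb(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("expected an H x W x 3 sRGB array")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("sRGB values must lie in [0, 1]")
    return np.clip(img, 0.0, 1.0)


def srgb_channels(img: np.ndarray) -> list[ChannelImage]:
    """The raw R, G, B channels of an sRGB image."""
    img = _check_rgb(img)
    return [ChannelImage(img[..., i], name, "sRGB") for i, name in enumerate("RGB")]


def srgb_to_intensity(img: np.ndarray) -> ChannelImage:
    """Intensity image Int = (R + G + B) / 3 of the encoded values.

    The unweighted mean is the conventional "intensity image" and
    coincides with Ohta's I1, which the tests exploit as a
    cross-check.
    """
    img = _check_rgb(img)
    return ChannelImage(img.mean(axis=2), "Int", "intensity")


def srgb_to_hsv(img: np.ndarray) -> list[ChannelImage]:
    """Hexcone HSV of the encoded values; H normalized to [0, 1)."""
    img = _check_rgb(img)
    hsv = _skcolor.rgb2hsv(img)
    return [ChannelImage(hsv[..., i], name, "HSV") for i, name in enumerate(("H", "S", "V"))]


def srgb_to_ycbcr(img: np.ndarray) -> list[ChannelImage]:
    """BT.601 full-range YCbCr on encoded values, chroma centered at 0.

    Achromatic pixels (r = g = b) map to Cb = Cr = 0 exactly, and
    Y(1,1,1) = 1 because the luma weights sum to one.
    """
    img = _check_rgb(img)
    ycc = img @ _YCBCR_MATRIX.T
    return [ChannelImage(ycc[..., i], name, "YCbCr") for i, name in enumerate(("Y", "Cb", "Cr"))]


def srgb_to_i1i2i3(img: np.ndarray) -> list[ChannelImage]:
    """Ohta's I1I2I3: I1=(R+G+B)/3, I2=(R-B)/2, I3=(2G-R-B)/4."""
    img = _check_rgb(img)
    ohta = img @ _I1I2I3_MATRIX.T
    return [ChannelImage(ohta[..., i], name, "I1I2I3") for i, name in enumerate(("I1", "I2", "I3"))]


def srgb_to_cielab(img: np.ndarray) -> list[ChannelImage]:
    """CIELAB via linearized sRGB -> XYZ (D65) -> L*a*b*, 2 deg observer."""
    img = _check_rgb(img)
    lab = _skcolor.rgb2lab(img)
    return [ChannelImage(lab[..., i], name, "CIELAB") for i, name in enumerate(("L*", "a*", "b*"))]


def cielab_to_srgb(lab: np.ndarray) -> np.ndarray:
    """Inverse of :func:`srgb_to_cielab`; output clipped to [0, 1]."""
    return np.clip(_skcolor.lab2rgb(np.asarray(lab, dtype=float)), 0.0, 1.0)


def decompose(img: np.ndarray, spaces: list[str] | None = None) -> list[ChannelImage]:
    """All channels of ``img`` in the requested color spaces.

    Parameters
    ----------
    img : ndarray
        H x W x 3 sRGB image in [0, 1].
    spaces : list of str, optional
        Subset of ``{"sRGB", "intensity", "HSV", "YCbCr", "I1I2I3",
        "CIELAB"}``; all six by default.
    """
    dispatch = {
        "sRGB": srgb_channels,
        "intensity": lambda im: [srgb_to_intensity(im)],
        "HSV": srgb_to_hsv,
        "YCbCr": srgb_to_ycbcr,
        "I1I2I3": srgb_to_i1i2i3,
        "CIELAB": srgb_to_cielab,
    }
    if spaces is None:
        spaces = list(dispatch)
    out: list[ChannelImage] = []
    for space in spaces:
        if space not in dispatch:
            raise ValueError(f"unknown color space {space!r}")
        out.extend(dispatch[space](img))
    return out
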