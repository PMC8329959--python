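"""Filtration-histogram texture quantification for single-slice CT.

The method has two stages.  First, an optional band-pass filtration with a
Laplacian of Gaussian (LoG) kernel whose spatial scale factor (SSF) sets the
radius, in millimetres, of the image structures it highlights; SSF 0 denotes
no filtration.  Second, six first-order statistics of the (filtered) HU
histogram inside a region of interest (ROI): mean attenuation, standard
deviation (SD), mean of positive pixels (MPP), entropy, skewness and excess
kurtosis.

Conventions
-----------
* The zero-crossing radius of the LoG equals the SSF value in mm, i.e.
  ``sigma = ssf / sqrt(2)`` (the LoG of width sigma changes sign at
  ``r = sigma * sqrt(2)``).  The kernel is truncated at 4 sigma and shifted to
  sum exactly to zero, so it has no DC response.
* The whole image is filtered first (reflection padding at the borders) and
  the ROI is applied afterwards, which avoids edge artefacts from the ROI
  boundary.
* Entropy uses 1-HU-wide integer bins by default (configurable), log base 2.
* SD is the n-1 sample estimator; skewness and kurtosis use population
  central moments, with the excess-kurtosis convention (normal -> 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

__all__ = [
    "ImageSlice",
    "RoiMask",
    "TextureFeatures",
    "MIN_ROI_PIXELS",
    "FEATURE_NAMES",
    "validate_ssf",
    "log_sigma_mm",
    "log_kernel",
    "filter_image",
    "first_order_stats",
    "histogram_stats",
    "extract_features",
]

#: minimum number of ROI pixels for the histogram statistics to be defined
MIN_ROI_PIXELS = 9

#: the six first-order histogram statistics, in reporting order
FEATURE_NAMES = ("mean", "sd", "mpp", "entropy", "skewness", "kurtosis")

#: kernel support truncation, in units of sigma
_TRUNCATE = 4.0

#: absolute HU threshold for "strictly positive" in MPP; values this close to
#: zero are convolution round-off, ten orders below the 1-HU quantization
_POSITIVE_TOL = 1e-9


@dataclass(frozen=True)
class ImageSlice:
    """A 2D raster of Hounsfield units with isotropic in-plane spacing (mm)."""

    pixels: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2D array")
        if not np.all(np.isfinite(px)):
            raise ValueError("image contains non-finite HU values")
        if not (self.spacing > 0):
            raise ValueError(f"pixel spacing must be > 0 mm, got {self.spacing}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiMask:
    """A binary region-of-interest raster congruent with an :class:`ImageSlice`."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.ndim != 2 or m.size == 0:
            raise ValueError("mask must be a non-empty 2D array")
        if m.dtype != bool:
            uniq = np.unique(m)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValueError("mask must be binary (0/1)")
            m = m.astype(bool)
        object.__setattr__(self, "mask", m)

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def check_congruent(self, img: ImageSlice) -> None:
        if self.mask.shape != img.pixels.shape:
            raise ValueError(
                f"mask shape {self.mask.shape} does not match image shape "
                f"{img.pixels.shape}"
            )


@dataclass(frozen=True)
class TextureFeatures:
    """The six histogram statistics at one SSF scale.

    ``mpp``, ``skewness`` and ``kurtosis`` are ``None`` when undefined (no
    strictly positive pixels; zero variance within the ROI).
    """

    mean: float
    sd: float
    mpp: float | None
    entropy: float
    skewness: float | None
    kurtosis: float | None
    ssf: float
    n_pixels: int
    n_positive: int

    def as_dict(self) -> dict:
        return {
            "ssf": self.ssf,
            "mean": self.mean,
            "sd": self.sd,
            "mpp": self.mpp,
            "entropy": self.entropy,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "n_pixels": self.n_pixels,
            "n_positive": self.n_positive,
        }


def validate_ssf(value: float) -> float:
    """Check that an SSF value is 0 (no filtration) or in the 2-6 mm range."""
    v = float(value)
    if v == 0.0 or 2.0 <= v <= 6.0:
        return v
    raise ValueError(f"SSF must be 0 or in [2.0, 6.0] mm, got {value}")


def log_sigma_mm(ssf: float) -> float:
    """Gaussian width (mm) whose LoG zero-crossing radius equals ``ssf`` mm."""
    return float(ssf) / math.sqrt(2.0)


def log_kernel(ssf: float, spacing: float) -> np.ndarray:
    """Discrete 2D Laplacian-of-Gaussian kernel for one SSF scale.

    The kernel samples the continuous LoG

    .. math:: -\\frac{1}{\\pi\\sigma^4}\\Bigl(1-\\frac{r^2}{2\\sigma^2}\\Bigr)
              e^{-r^2/2\\sigma^2}

    at pixel centres (``r`` in mm), truncated at 4 sigma, then shifts all
    entries by a constant so they sum to zero exactly: a constant image maps
    to zero (no DC gain).

    Parameters
    ----------
    ssf : float
        Spatial scale factor in mm; must be > 0 (SSF 0 means no kernel).
    spacing : float
        Pixel spacing in mm/pixel.
    """
    ssf = validate_ssf(ssf)
    if ssf == 0.0:
        raise ValueError("SSF 0 denotes no filtration; no kernel exists")
    if not (spacing > 0):
        raise ValueError(f"pixel spacing must be > 0, got {spacing}")

    sigma = log_sigma_mm(ssf)
    radius_px = int(math.ceil(_TRUNCATE * sigma / spacing))
    offsets = np.arange(-radius_px, radius_px + 1, dtype=float)
    xx, yy = np.meshgrid(offsets * spacing, offsets * spacing)
    r2 = xx**2 + yy**2
    k = -1.0 / (math.pi * sigma**4) * (1.0 - r2 / (2.0 * sigma**2)) * np.exp(
        -r2 / (2.0 * sigma**2)
    )
    # remove residual DC gain; two passes to kill the fp remainder of the first
    k -= k.mean()
    k[radius_px, radius_px] -= k.sum()
    return k


def filter_image(img: ImageSlice, ssf: float) -> ImageSlice:
    """Convolve an image with the LoG kernel at one SSF scale.

    SSF 0 returns the input unchanged.  Borders use reflection (symmetric)
    padding; the output has the shape of the input.  The FFT route is used
    for speed; it agrees with direct spatial convolution to well below the
    HU quantization.
    """
    ssf = validate_ssf(ssf)
    if ssf == 0.0:
        return img
    kernel = log_kernel(ssf, img.spacing)
    r = kernel.shape[0] // 2
    padded = np.pad(img.pixels, r, mode="symmetric")
    out = fftconvolve(padded, kernel, mode="valid")
    return ImageSlice(out, img.spacing)


def _central_moments(values: np.ndarray) -> tuple[float, float, float, float]:
    mean = float(values.mean())
    d = values - mean
    m2 = float(np.mean(d**2))
    m3 = float(np.mean(d**3))
    m4 = float(np.mean(d**4))
    return mean, m2, m3, m4


def first_order_stats(
    values, ssf: float = 0.0, bin_width: float = 1.0
) -> TextureFeatures:
    """The six histogram statistics of a bare set of (filtered) HU values.

    This is the quantification half of :func:`histogram_stats`, exposed for
    use on pre-masked pixel sets; see there for the definitions.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size < 2:
        raise ValueError("need at least two values")
    if not (bin_width > 0):
        raise ValueError("entropy bin width must be > 0")
    n = values.size

    mean, m2, m3, m4 = _central_moments(values)
    sd = float(values.std(ddof=1))

    positive = values[values > _POSITIVE_TOL]
    mpp = float(positive.mean()) if positive.size else None

    bins = np.rint(values / bin_width)
    _, counts = np.unique(bins, return_counts=True)
    p = counts / n
    entropy = float(-np.sum(p * np.log2(p)))

    if m2 > 0:
        skewness: float | None = m3 / m2**1.5
        kurtosis: float | None = m4 / m2**2 - 3.0
    else:
        skewness = None
        kurtosis = None

    return TextureFeatures(
        mean=mean,
        sd=sd,
        mpp=mpp,
        entropy=entropy,
        skewness=skewness,
        kurtosis=kurtosis,
        ssf=float(ssf),
        n_pixels=int(n),
        n_positive=int(positive.size),
    )


def histogram_stats(
    img: ImageSlice,
    roi: RoiMask,
    ssf: float,
    bin_width: float = 1.0,
) -> TextureFeatures:
    """Six first-order statistics of the ROI histogram at one SSF scale.

    The whole image is filtered first, then statistics are computed over the
    masked pixels:

    * ``mean`` -- arithmetic mean (HU).
    * ``sd`` -- sample standard deviation (n-1 denominator).
    * ``mpp`` -- mean of pixels strictly greater than zero; ``None`` if no
      pixel is positive.
    * ``entropy`` -- Shannon entropy (bits) of the histogram of values
      binned to the nearest multiple of ``bin_width`` (default 1 HU); empty
      bins contribute nothing.
    * ``skewness`` / ``kurtosis`` -- g1 = m3 / m2^1.5 and excess
      g2 = m4 / m2^2 - 3 from population central moments; ``None`` when all
      masked pixels are identical (m2 = 0), never silently zero.
    """
    roi.check_congruent(img)
    if roi.n_pixels < MIN_ROI_PIXELS:
        raise ValueError(
            f"ROI has {roi.n_pixels} pixels; at least {MIN_ROI_PIXELS} required"
        )
    if not (bin_width > 0):
        raise ValueError("entropy bin width must be > 0")

    filtered = filter_image(img, ssf)
    return first_order_stats(
        filtered.pixels[roi.mask], ssf=ssf, bin_width=bin_width
    )


def extract_features(
    img: ImageSlice,
    roi: RoiMask,
    scales: Sequence[float],
    bin_width: float = 1.0,
) -> list[TextureFeatures]:
    """Histogram statistics at every requested SSF scale, in input order."""
    if len(scales) == 0:
        raise ValueError("scales must be non-empty")
    return [histogram_stats(img, roi, s, bin_width=bin_width) for s in scales]
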