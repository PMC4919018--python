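"""The eleven objective image measures behind the complexity score.

Measures M1-M6 are computed on the luma (grayscale) image and capture
spatial/texture structure; M7-M8 use the full colour image; M9-M11 are
colour statistics:

======  =======================  =============================================
name    quantity                 summary
======  =======================  =============================================
M1      GLCM contrast            intensity contrast between neighbour pixels
M2      GLCM correlation         neighbour-pixel correlation
M3      GLCM energy              sum of squared GLCM entries
M4      GLCM homogeneity         concentration of the GLCM on its diagonal
M5      frequency factor         99%-energy radius / Nyquist frequency
M6      edge density             Canny edge pixels / total pixels
M7      compression ratio        JPEG(Q=100) bytes / raw RGB bytes
M8      number of regions        mean-shift segment count
M9      colorfulness             opponent-axis spread + mean statistic
M10     number of colors         distinct RGB triplets
M11     color harmony            mean pairwise two-colour harmony score
======  =======================  =============================================

All knobs live in :class:`FeatureConfig`; :func:`extract_all` evaluates the
full vector.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from PIL import Image
from skimage.feature import canny

from .glcm import (
    UndefinedCorrelationError,
    compute_glcm,
    glcm_contrast,
    glcm_correlation,
    glcm_energy,
    glcm_homogeneity,
)
from .harmony import color_harmony
from .segmentation import num_regions

__all__ = [
    "FeatureConfig",
    "FeatureVector",
    "MEASURE_NAMES",
    "validate_rgb",
    "to_gray",
    "frequency_factor",
    "edge_density",
    "compression_ratio",
    "colorfulness",
    "number_of_colors",
    "extract_all",
]

MEASURE_NAMES = tuple(f"M{k}" for k in range(1, 12))


@dataclass
class FeatureConfig:
    """All tunable knobs of the feature extractors.

    Defaults mirror widely used texture/segmentation toolbox settings; every
    value is an explicit parameter so a run can be reproduced from its
    logged config.
    """

    # GLCM (M1-M4)
    glcm_levels: int = 8
    glcm_offset: tuple[int, int] = (0, 1)
    # Canny (M6): sigma in pixels; hysteresis thresholds on the [0, 1]
    # gradient-magnitude scale
    canny_sigma: float = 1.0
    canny_low: float = 0.11
    canny_high: float = 0.27
    # JPEG (M7)
    jpeg_quality: int = 100
    jpeg_subsampling: int = 0  # 4:4:4
    # Mean shift (M8)
    ms_spatial_bw: int = 8
    ms_range_bw: float = 7.0
    ms_min_size: int = 20
    ms_max_iter: int = 5
    ms_max_size: int = 256
    # Number of colors (M10): 0 disables quantization (exact 24-bit count)
    color_quant_levels: int = 0
    # Color harmony (M11)
    harmony_quant_levels: int = 16
    harmony_max_colors: int = 8
    harmony_min_area: float = 0.01

    def to_dict(self) -> dict:
        d = asdict(self)
        d["glcm_offset"] = list(d["glcm_offset"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureConfig":
        d = dict(d)
        if "glcm_offset" in d:
            d["glcm_offset"] = tuple(d["glcm_offset"])
        return cls(**d)


@dataclass(frozen=True)
class FeatureVector:
    """The eleven measures of one image, in M1..M11 order."""

    m1: float
    m2: float
    m3: float
    m4: float
    m5: float
    m6: float
    m7: float
    m8: int
    m9: float
    m10: int
    m11: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [
                self.m1,
                self.m2,
                self.m3,
                self.m4,
                self.m5,
                self.m6,
                self.m7,
                self.m8,
                self.m9,
                self.m10,
                self.m11,
            ],
            dtype=float,
        )


def validate_rgb(img: np.ndarray) -> np.ndarray:
    """Check an H x W x 3 8-bit RGB array (H, W >= 8) and return it as uint8."""
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected H x W x 3 RGB image, got shape {img.shape}")
    if img.shape[0] < 8 or img.shape[1] < 8:
        raise ValueError("image must be at least 8 x 8")
    if img.min() < 0 or img.max() > 255:
        raise ValueError("intensities must lie in [0, 255]")
    return img.astype(np.uint8)


def to_gray(img: np.ndarray) -> np.ndarray:
    """Luma conversion with ITU-R BT.601 weights, rounded to integers."""
    img = validate_rgb(img)
    y = 0.299 * img[..., 0] + 0.587 * img[..., 1] + 0.114 * img[..., 2]
    return np.clip(np.rint(y), 0, 255).astype(np.uint8)


def frequency_factor(img: np.ndarray) -> float:
    """M5: radius holding 99% of the (non-DC) spectral energy over Nyquist.

    The 2-D power spectrum of the grayscale image is computed, the DC term
    dropped (the mean carries no spatial structure), coefficients are sorted
    by radial frequency in cycles/pixel, and the smallest radius whose
    cumulative energy reaches 99% of the total is divided by the Nyquist
    frequency 0.5.  Result clipped to [0, 1]; a constant image returns 0.
    """
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("grayscale image must be 2-D")
    power = np.abs(np.fft.fft2(img)) ** 2
    power[0, 0] = 0.0
    total = power.sum()
    if total <= 0:
        return 0.0
    fy = np.fft.fftfreq(img.shape[0])
    fx = np.fft.fftfreq(img.shape[1])
    radius = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2).ravel()
    order = np.argsort(radius, kind="stable")
    cumulative = np.cumsum(power.ravel()[order])
    k = int(np.searchsorted(cumulative, 0.99 * total))
    r99 = radius[order][min(k, len(order) - 1)]
    return float(min(r99 / 0.5, 1.0))


def edge_density(
    img: np.ndarray,
    sigma: float = 1.0,
    low_threshold: float = 0.11,
    high_threshold: float = 0.27,
) -> float:
    """M6: fraction of pixels the Canny detector marks as edges."""
    img = np.asarray(img, dtype=float)
    if img.ndim != 2:
        raise ValueError("grayscale image must be 2-D")
    edges = canny(
        img / 255.0,
        sigma=sigma,
        low_threshold=low_threshold,
        high_threshold=high_threshold,
    )
    return float(edges.mean())


def compression_ratio(
    img: np.ndarray, quality: int = 100, subsampling: int = 0
) -> float:
    """M7: JPEG-compressed size over raw 24-bit size.

    The encoder dialect is pinned (baseline Huffman, 4:4:4 by default) since
    encoder variation shifts the ratio by a few percent.  On small or very
    noisy images the ratio can exceed 1 (header overhead).
    """
    img = validate_rgb(img)
    buf = io.BytesIO()
    Image.fromarray(img, mode="RGB").save(
        buf, format="JPEG", quality=quality, subsampling=subsampling
    )
    raw = 3 * img.shape[0] * img.shape[1]
    return buf.getbuffer().nbytes / raw


def colorfulness(img: np.ndarray) -> float:
    """M9: opponent-axis colorfulness (Hasler-Suesstrunk).

    With per-pixel rg = R - G and yb = (R + G)/2 - B:
    sqrt(var(rg) + var(yb)) + 0.3 sqrt(mean(rg)^2 + mean(yb)^2).
    Zero for any achromatic image.
    """
    img = validate_rgb(img).astype(float)
    rg = img[..., 0] - img[..., 1]
    yb = 0.5 * (img[..., 0] + img[..., 1]) - img[..., 2]
    sigma = np.sqrt(rg.var() + yb.var())
    mu = np.sqrt(rg.mean() ** 2 + yb.mean() ** 2)
    return float(sigma + 0.3 * mu)


def number_of_colors(img: np.ndarray, quant_levels: int = 0) -> int:
    """M10: count of distinct colours.

    Exact 24-bit triplet count by default; with ``quant_levels`` = q > 0 each
    channel is first binned into q levels (bounding the count by q^3).
    """
    img = validate_rgb(img).reshape(-1, 3).astype(np.int64)
    if quant_levels > 0:
        img = (img * quant_levels) // 256
    codes = (img[:, 0] << 16) | (img[:, 1] << 8) | img[:, 2]
    return int(np.unique(codes).size)


def extract_all(img: np.ndarray, cfg: FeatureConfig | None = None) -> FeatureVector:
    """Evaluate all eleven measures on one RGB image.

    GLCM correlation is undefined on a constant image; it is mapped to 1.0
    with a warning (a constant image is perfectly self-correlated).  Any
    other extractor error propagates annotated with the measure name.
    """
    cfg = cfg or FeatureConfig()
    img = validate_rgb(img)
    gray = to_gray(img)

    def run(name, fn):
        try:
            return fn()
        except UndefinedCorrelationError:
            raise
        except Exception as e:  # annotate with the measure that failed
            raise RuntimeError(f"{name} failed: {e}") from e

    g = run("M1-M4 (GLCM)", lambda: compute_glcm(gray, cfg.glcm_levels, cfg.glcm_offset))
    try:
        m2 = glcm_correlation(g)
    except UndefinedCorrelationError:
        warnings.warn(
            "GLCM correlation undefined (constant image); using 1.0", stacklevel=2
        )
        m2 = 1.0
    return FeatureVector(
        m1=run("M1 (contrast)", lambda: glcm_contrast(g)),
        m2=m2,
        m3=run("M3 (energy)", lambda: glcm_energy(g)),
        m4=run("M4 (homogeneity)", lambda: glcm_homogeneity(g)),
        m5=run("M5 (frequency factor)", lambda: frequency_factor(gray)),
        m6=run(
            "M6 (edge density)",
            lambda: edge_density(gray, cfg.canny_sigma, cfg.canny_low, cfg.canny_high),
        ),
        m7=run(
            "M7 (compression ratio)",
            lambda: compression_ratio(img, cfg.jpeg_quality, cfg.jpeg_subsampling),
        ),
        m8=run(
            "M8 (number of regions)",
            lambda: num_regions(
                img,
                cfg.ms_spatial_bw,
                cfg.ms_range_bw,
                cfg.ms_min_size,
                cfg.ms_max_iter,
                cfg.ms_max_size,
            ),
        ),
        m9=run("M9 (colorfulness)", lambda: colorfulness(img)),
        m10=run(
            "M10 (number of colors)",
            lambda: number_of_colors(img, cfg.color_quant_levels),
        ),
        m11=run(
            "M11 (color harmony)",
            lambda: color_harmony(
                img,
                cfg.harmony_quant_levels,
                cfg.harmony_max_colors,
                cfg.harmony_min_area,
            ),
        ),
    )
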