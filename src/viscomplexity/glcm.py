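"""Grey-level co-occurrence matrix (GLCM) construction and Haralick-style statistics.

The GLCM of a grayscale image at a pixel offset (dy, dx) is the joint
distribution of quantized intensity pairs ``(I[r, c], I[r+dy, c+dx])`` over
all pixel positions where both ends fall inside the image.  Intensities in
[0, 255] are quantized into ``levels`` equal-width bins before counting
(linear scaling, matching the common default of texture toolboxes).  Counts
are not symmetrized; the matrix is normalized to sum to one.

Four classic statistics are derived from the normalized matrix: contrast,
correlation, energy (angular second moment) and homogeneity (inverse
difference moment).  They are the first four objective measures of the
complexity model in :mod:`viscomplexity.features`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Glcm",
    "UndefinedCorrelationError",
    "quantize",
    "compute_glcm",
    "glcm_contrast",
    "glcm_correlation",
    "glcm_energy",
    "glcm_homogeneity",
]


class UndefinedCorrelationError(ValueError):
    """GLCM correlation is undefined: a marginal distribution has zero variance.

    Raised for constant (single-level) images.  Callers decide how to
    propagate; the feature extractor maps it to 1.0 with a warning, reading a
    constant image as perfectly self-correlated.
    """


@dataclass(frozen=True)
class Glcm:
    """Normalized co-occurrence matrix with its construction parameters.

    Attributes
    ----------
    p : ndarray of shape (levels, levels)
        Joint probability ``p[i, j]`` of level pair (i, j); entries are
        non-negative and sum to one.
    levels : int
        Number of quantization bins L (>= 2).
    offset : tuple of int
        Pixel offset (dy, dx), row-major with origin at the top-left.
    """

    p: np.ndarray
    levels: int
    offset: tuple[int, int]

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if p.shape != (self.levels, self.levels):
            raise ValueError(f"p must be ({self.levels}, {self.levels}), got {p.shape}")
        if np.any(p < 0):
            raise ValueError("GLCM entries must be non-negative")
        if not np.isclose(p.sum(), 1.0):
            raise ValueError("GLCM entries must sum to 1")
        object.__setattr__(self, "p", p)


def quantize(img: np.ndarray, levels: int) -> np.ndarray:
    """Quantize 8-bit intensities into ``levels`` equal-width bins (0..levels-1)."""
    img = np.asarray(img)
    q = (img.astype(np.int64) * levels) // 256
    return np.clip(q, 0, levels - 1)


def compute_glcm(
    img: np.ndarray, levels: int = 8, offset: tuple[int, int] = (0, 1)
) -> Glcm:
    """Build the normalized GLCM of a grayscale image.

    Parameters
    ----------
    img : ndarray of shape (H, W)
        Grayscale intensities in [0, 255].
    levels : int
        Quantization bin count L (default 8).
    offset : (dy, dx)
        Neighbor displacement; (0, 1) pairs each pixel with its right
        neighbor.  Either component may be negative.

    Raises
    ------
    ValueError
        If the offset leaves no valid pixel pairs (image smaller than offset).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("grayscale image must be 2-D")
    if levels < 2:
        raise ValueError("levels must be >= 2")
    dy, dx = offset
    h, w = img.shape
    if abs(dy) >= h or abs(dx) >= w:
        raise ValueError(f"offset {offset} exceeds image shape {(h, w)}")

    q = quantize(img, levels)
    # First-pixel window such that (r+dy, c+dx) stays in bounds.
    r0, r1 = max(0, -dy), min(h, h - dy)
    c0, c1 = max(0, -dx), min(w, w - dx)
    a = q[r0:r1, c0:c1].ravel()
    b = q[r0 + dy : r1 + dy, c0 + dx : c1 + dx].ravel()
    counts = np.bincount(a * levels + b, minlength=levels * levels).reshape(
        levels, levels
    )
    total = counts.sum()
    if total == 0:
        raise ValueError(f"offset {offset} leaves no pixel pairs")
    return Glcm(p=counts / total, levels=levels, offset=(dy, dx))


def glcm_contrast(g: Glcm) -> float:
    """Contrast: sum of p(i, j) * (i - j)^2. Zero for a diagonal matrix."""
    i, j = np.indices(g.p.shape)
    return float(np.sum(g.p * (i - j) ** 2))


def glcm_correlation(g: Glcm) -> float:
    """Correlation of the level pair under the joint distribution, in [-1, 1].

    Raises
    ------
    UndefinedCorrelationError
        If either marginal has zero variance (constant image).
    """
    i, j = np.indices(g.p.shape)
    mu_i = float(np.sum(g.p * i))
    mu_j = float(np.sum(g.p * j))
    var_i = float(np.sum(g.p * (i - mu_i) ** 2))
    var_j = float(np.sum(g.p * (j - mu_j) ** 2))
    if var_i <= 0 or var_j <= 0:
        raise UndefinedCorrelationError(
            "GLCM correlation undefined: zero marginal variance (constant image?)"
        )
    cov = float(np.sum(g.p * (i - mu_i) * (j - mu_j)))
    return cov / np.sqrt(var_i * var_j)


def glcm_energy(g: Glcm) -> float:
    """Energy (angular second moment): sum of squared entries, in (0, 1]."""
    return float(np.sum(g.p**2))


def glcm_homogeneity(g: Glcm) -> float:
    """Homogeneity (inverse difference moment): sum of p(i, j)/(1 + |i - j|)."""
    i, j = np.indices(g.p.shape)
    return float(np.sum(g.p / (1.0 + np.abs(i - j))))
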