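"""Two-colour harmony scoring (Ou-Luo model) aggregated over an image.

The pairwise score CH of two colours given in CIELCh (L*, C*ab, hab, D65)
is the sum of three effects:

* chromatic effect   HC = 0.04 + 0.53 tanh(0.8 - 0.045 dC), where
  dC = sqrt(dHab^2 + (dCab / 1.46)^2) combines the CIELAB hue and chroma
  differences of the pair;
* lightness effect   HL = Hlsum + HdL with
  Hlsum = 0.28 + 0.54 tanh(-3.88 + 0.029 (L1 + L2)) and
  HdL   = 0.14 + 0.15 tanh(-2 + 0.2 |L1 - L2|);
* hue effect         HH = Hsy(1) + Hsy(2) with, per colour,
  Hsy = Ec (Hs + Ey),
  Ec  = 0.5 + 0.5 tanh(-2 + 0.5 C),
  Hs  = -0.08 - 0.14 sin(h + 50 deg) - 0.07 sin(2h + 90 deg),
  Ey  = ((0.22 L - 12.8) / 10) exp((90 - h)/10 - exp((90 - h)/10)),
  h in degrees.

Higher CH means the pair is judged more harmonious.  An image score is the
area-weighted mean of CH over all pairs of its dominant colours: the image
is quantized per channel, the most frequent colours covering at least a
minimum area fraction are kept (up to a maximum count), and every unordered
pair is scored with weight equal to the product of the two areas.  A single
dominant colour falls back to the harmony of the colour with itself.
"""

from __future__ import annotations

import numpy as np
from skimage.color import rgb2lab

__all__ = ["pair_harmony", "dominant_colors", "color_harmony"]


def _hue_deg(a: float, b: float) -> float:
    return float(np.degrees(np.arctan2(b, a)) % 360.0)


def pair_harmony(lab1, lab2) -> float:
    """Harmony score CH of two colours given as CIELAB (L, a, b) triples.

    Symmetric in its arguments.  Inputs use the conventional CIELAB scale
    (L in [0, 100]).
    """
    L1, a1, b1 = (float(v) for v in lab1)
    L2, a2, b2 = (float(v) for v in lab2)
    C1 = float(np.hypot(a1, b1))
    C2 = float(np.hypot(a2, b2))

    dL = abs(L1 - L2)
    dCab = C1 - C2
    # CIELAB hue difference via dE decomposition; clamp against rounding.
    dHab_sq = max((a1 - a2) ** 2 + (b1 - b2) ** 2 - dCab**2, 0.0)
    dC = np.sqrt(dHab_sq + (dCab / 1.46) ** 2)
    hc = 0.04 + 0.53 * np.tanh(0.8 - 0.045 * dC)

    h_lsum = 0.28 + 0.54 * np.tanh(-3.88 + 0.029 * (L1 + L2))
    h_dl = 0.14 + 0.15 * np.tanh(-2.0 + 0.2 * dL)
    hl = h_lsum + h_dl

    def hsy(L: float, C: float, a: float, b: float) -> float:
        h = _hue_deg(a, b)
        ec = 0.5 + 0.5 * np.tanh(-2.0 + 0.5 * C)
        hs = (
            -0.08
            - 0.14 * np.sin(np.radians(h + 50.0))
            - 0.07 * np.sin(np.radians(2.0 * h + 90.0))
        )
        t = (90.0 - h) / 10.0
        ey = ((0.22 * L - 12.8) / 10.0) * np.exp(t - np.exp(t))
        return float(ec * (hs + ey))

    hh = hsy(L1, C1, a1, b1) + hsy(L2, C2, a2, b2)
    return float(hc + hl + hh)


def dominant_colors(
    img: np.ndarray,
    quant_levels: int = 16,
    max_colors: int = 8,
    min_area: float = 0.01,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract an image's dominant colours by per-channel quantization.

    Returns
    -------
    colors : ndarray of shape (k, 3)
        Bin-centre RGB values in [0, 255], most frequent first.
    areas : ndarray of shape (k,)
        Fraction of image pixels in each bin (not renormalized).

    At least one colour is always returned, even if no bin reaches
    ``min_area``.
    """
    img = np.asarray(img)
    n = img.shape[0] * img.shape[1]
    q = (img.reshape(-1, 3).astype(np.int64) * quant_levels) // 256
    q = np.clip(q, 0, quant_levels - 1)
    codes = (q[:, 0] * quant_levels + q[:, 1]) * quant_levels + q[:, 2]
    uniq, counts = np.unique(codes, return_counts=True)
    order = np.argsort(counts)[::-1]
    uniq, counts = uniq[order], counts[order]
    areas = counts / n
    keep = areas >= min_area
    keep[0] = True  # always keep the most frequent bin
    uniq, areas = uniq[keep][:max_colors], areas[keep][:max_colors]
    r = uniq // (quant_levels * quant_levels)
    g = (uniq // quant_levels) % quant_levels
    b = uniq % quant_levels
    # bin centres on the 0-255 scale
    centers = (np.stack([r, g, b], axis=1) + 0.5) * (256.0 / quant_levels)
    return centers, areas


def color_harmony(
    img: np.ndarray,
    quant_levels: int = 16,
    max_colors: int = 8,
    min_area: float = 0.01,
) -> float:
    """Image-level colour harmony: area-weighted mean pairwise CH.

    Dominant colours are extracted with :func:`dominant_colors`, converted to
    CIELAB (sRGB, D65), and every unordered pair is scored; weights are the
    products of the pair's area fractions.  With a single dominant colour the
    score is the colour's harmony with itself.
    """
    colors, areas = dominant_colors(img, quant_levels, max_colors, min_area)
    labs = rgb2lab(colors.reshape(1, -1, 3) / 255.0).reshape(-1, 3)
    k = len(labs)
    if k == 1:
        return pair_harmony(labs[0], labs[0])
    total = 0.0
    weight = 0.0
    for i in range(k):
        for j in range(i + 1, k):
            w = float(areas[i] * areas[j])
            total += w * pair_harmony(labs[i], labs[j])
            weight += w
    return total / weight
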