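"""Synthetic stimuli, feature tables and rating matrices with known ground truth.

Real complexity studies pair photographs with human ratings; neither ships
with the package, so every pipeline stage is exercised on synthetic
analogues instead:

* :func:`gen_image` builds mosaic-plus-noise images whose knobs map onto
  the drivers of perceived complexity: tile count feeds the region and edge
  measures, palette size feeds the colour count, noise feeds the frequency
  factor, and regularity controls grid jitter.
* :func:`gen_study` plants a known weight vector: features are i.i.d.
  uniform on [0, 1] and mean scores follow a monotone logistic link of the
  planted linear combination plus Gaussian noise — the statistical shape
  the fitting machinery assumes.
* :func:`gen_ratings` re-expands mean scores into a raw subjects x images
  matrix on the [0, 100] slider scale with per-subject bias and gain,
  rating noise, and a fraction of wild outlier cells.

Everything is bit-reproducible from its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MEASURE_NAMES
from .table import FeatureTable

__all__ = ["ImageRecipe", "SyntheticStudy", "gen_image", "gen_study", "gen_ratings"]


@dataclass(frozen=True)
class ImageRecipe:
    """Deterministic description of one synthetic mosaic image.

    tiles drives region/edge structure, palette the number of distinct
    colours, noise_sd (intensity units, 0-255 scale) the high-frequency
    content, and regularity in [0, 1] moves tile boundaries from fully
    jittered (0) to a perfect grid (1).
    """

    seed: int = 0
    size: tuple[int, int] = (128, 128)
    tiles: int = 16
    palette: int = 8
    noise_sd: float = 0.0
    regularity: float = 1.0

    def __post_init__(self) -> None:
        if self.tiles < 1 or self.palette < 1:
            raise ValueError("tiles and palette must be >= 1")
        if not 0.0 <= self.regularity <= 1.0:
            raise ValueError("regularity must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _cut_points(n_cells: int, length: int, jitter: float, rng) -> np.ndarray:
    """Grid boundaries along one axis, jittered within each cell."""
    base = np.linspace(0, length, n_cells + 1)
    if jitter > 0 and n_cells > 1:
        cell = length / n_cells
        base[1:-1] += rng.uniform(-0.45, 0.45, n_cells - 1) * cell * jitter
    return np.round(np.sort(base)).astype(int)


def gen_image(recipe: ImageRecipe) -> np.ndarray:
    """Render the mosaic as an H x W x 3 uint8 array."""
    rng = np.random.default_rng(recipe.seed)
    h, w = recipe.size
    rows = max(1, round(np.sqrt(recipe.tiles)))
    cols = max(1, -(-recipe.tiles // rows))  # ceil division
    jitter = 1.0 - recipe.regularity
    ys = _cut_points(rows, h, jitter, rng)
    xs = _cut_points(cols, w, jitter, rng)

    # palette: well-separated colours, deterministic for the seed
    colors = rng.integers(0, 256, size=(recipe.palette, 3))
    img = np.empty((h, w, 3), dtype=float)
    idx = 0
    for r in range(rows):
        for c in range(cols):
            color = colors[idx % recipe.palette]
            img[ys[r] : ys[r + 1], xs[c] : xs[c + 1]] = color
            idx += 1
    if recipe.noise_sd > 0:
        img += rng.normal(0.0, recipe.noise_sd, size=img.shape)
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class SyntheticStudy:
    """A planted-truth study: features, weights, link and noisy mean scores."""

    X: np.ndarray  # N x K features in [0, 1]
    weights: np.ndarray  # planted a_k
    y: np.ndarray  # noisy mean scores
    y_clean: np.ndarray  # link(LC) before noise
    link_center: float
    link_slope: float
    noise_sd: float
    seed: int

    def link(self, t) -> np.ndarray:
        """The planted monotone logistic link applied to raw LC values."""
        t = np.asarray(t, dtype=float)
        return 1.0 / (1.0 + np.exp(-self.link_slope * (t - self.link_center)))

    def table(self) -> FeatureTable:
        """The features as a normalized 11-column table (requires K = 11)."""
        if self.X.shape[1] != len(MEASURE_NAMES):
            raise ValueError("feature table requires K = 11")
        ids = [f"img{i + 1:03d}" for i in range(len(self.X))]
        df = pd.DataFrame(self.X, index=pd.Index(ids, name="image_id"),
                          columns=list(MEASURE_NAMES))
        return FeatureTable(
            data=df, normalized=True,
            norms={c: (0.0, 1.0) for c in MEASURE_NAMES},
        )


def gen_study(
    seed: int,
    n_images: int = 50,
    weights: np.ndarray | None = None,
    noise_sd: float = 0.05,
    link_slope_scale: float = 2.0,
) -> SyntheticStudy:
    """Generate a study with a planted weight vector.

    Features are i.i.d. uniform on [0, 1]; scores are a logistic link of
    the planted linear combination, centred at the median LC value with
    slope ``link_slope_scale / SD(LC)``, plus Gaussian noise of SD
    ``noise_sd`` (on the [0, 1] link-output scale).  With ``weights=None``
    a planted vector is drawn uniformly from [-1, 1]^11.
    """
    if n_images < 10:
        raise ValueError("n_images must be >= 10")
    rng = np.random.default_rng(seed)
    if weights is None:
        weights = rng.uniform(-1.0, 1.0, size=len(MEASURE_NAMES))
    weights = np.asarray(weights, dtype=float).ravel()
    X = rng.uniform(0.0, 1.0, size=(n_images, weights.size))
    lc = X @ weights
    center = float(np.median(lc))
    spread = float(lc.std())
    slope = link_slope_scale / spread if spread > 0 else 1.0
    y_clean = 1.0 / (1.0 + np.exp(-slope * (lc - center)))
    y = y_clean + rng.normal(0.0, noise_sd, size=n_images)
    return SyntheticStudy(
        X=X, weights=weights, y=y, y_clean=y_clean,
        link_center=center, link_slope=slope, noise_sd=noise_sd, seed=seed,
    )


def gen_ratings(
    y,
    n_subjects: int = 20,
    bias_sd: float = 5.0,
    scale_sd: float = 0.1,
    noise_sd: float = 0.3,
    outlier_rate: float = 0.02,
    seed: int = 0,
) -> pd.DataFrame:
    """Expand per-image scores into a raw subjects x images rating matrix.

    Image difficulties are the standardized input scores y*.  Subject i
    rates image j as

        r_ij = clip( gain_i (50 + 20 (y*_j + eps_ij)) + bias_i, 0, 100 )

    with gain_i ~ 1 + N(0, scale_sd), bias_i ~ N(0, bias_sd) and rating
    noise eps ~ N(0, noise_sd) on the standardized scale; a fraction
    ``outlier_rate`` of cells is then replaced by uniform [0, 100] values.
    """
    if n_subjects < 3:
        raise ValueError("need at least 3 subjects")
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    sd = y.std()
    ystar = (y - y.mean()) / sd if sd > 0 else np.zeros_like(y)
    gain = 1.0 + rng.normal(0.0, scale_sd, size=n_subjects)
    bias = rng.normal(0.0, bias_sd, size=n_subjects)
    eps = rng.normal(0.0, noise_sd, size=(n_subjects, y.size))
    r = gain[:, None] * (50.0 + 20.0 * (ystar[None, :] + eps)) + bias[:, None]
    if outlier_rate > 0:
        wild = rng.random((n_subjects, y.size)) < outlier_rate
        r[wild] = rng.uniform(0.0, 100.0, size=int(wild.sum()))
    r = np.clip(r, 0.0, 100.0)
    return pd.DataFrame(
        r,
        index=pd.Index([f"s{i + 1:02d}" for i in range(n_subjects)], name="subject_id"),
        columns=pd.Index([f"img{j + 1:03d}" for j in range(y.size)], name="image_id"),
    )
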