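"""Subjective-rating processing: per-subject Z-scores, outlier cleaning, means.

Raw complexity ratings r_ij (subject i, image j, on a [0, 100] slider) are
turned into per-image ground-truth scores in three steps:

1. each subject's ratings are standardized to Z-scores using that subject's
   own mean and standard deviation over the images they rated, removing
   per-subject bias and scale;
2. per image, Z-scores falling outside mean +/- half_width * SD across
   subjects are dropped (single pass; the image statistics are not
   recomputed after drops);
3. surviving Z-scores are averaged across subjects into the mean score y_j.

Ratings are held in a subjects x images DataFrame; NaN marks a missing or
removed cell.  Sample (n-1) standard deviations are used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ConstantRaterError",
    "zscore_per_subject",
    "remove_outliers",
    "mean_scores",
    "process_ratings",
]


class ConstantRaterError(ValueError):
    """A subject gave (near-)identical scores to every image: Z-scores undefined."""


def _check_matrix(r: pd.DataFrame) -> pd.DataFrame:
    r = pd.DataFrame(r)
    if r.shape[0] < 2 or r.shape[1] < 2:
        raise ValueError("need at least 2 subjects and 2 images")
    vals = r.to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if finite.size and (finite.min() < 0 or finite.max() > 100):
        raise ValueError("raw scores must lie in [0, 100]")
    return r


def zscore_per_subject(r: pd.DataFrame) -> pd.DataFrame:
    """Standardize each subject's row: z_ij = (r_ij - mean_i) / sd_i.

    Missing cells stay missing.  Raises :class:`ConstantRaterError` naming
    any subject whose ratings have zero spread.
    """
    r = _check_matrix(r)
    means = r.mean(axis=1)
    sds = r.std(axis=1, ddof=1)
    counts = r.notna().sum(axis=1)
    bad = r.index[(counts < 2) | (sds <= 0) | ~np.isfinite(sds)]
    if len(bad):
        raise ConstantRaterError(
            f"subjects with <2 ratings or zero spread: {list(bad)}"
        )
    return r.sub(means, axis=0).div(sds, axis=0)


def remove_outliers(
    z: pd.DataFrame, half_width_sd: float = 2.0, warn_fraction: float = 0.10
) -> pd.DataFrame:
    """Drop per-image outliers: cells outside mean +/- half_width_sd * SD.

    The mean and (sample) SD are taken per image across subjects, once; the
    pass is not repeated, so the operation is idempotent.  Requires at least
    3 ratings per image.  Warns if more than ``warn_fraction`` of cells are
    dropped.  ``half_width_sd=1.0`` gives the stricter total-width-2-SD
    reading of the rule.
    """
    z = pd.DataFrame(z)
    if (z.notna().sum(axis=0) < 3).any():
        raise ValueError("each image needs >= 3 ratings for outlier detection")
    mean = z.mean(axis=0)
    sd = z.std(axis=0, ddof=1)
    lo = mean - half_width_sd * sd
    hi = mean + half_width_sd * sd
    keep = z.le(hi, axis=1) & z.ge(lo, axis=1)
    out = z.where(keep)
    if (out.notna().sum(axis=0) == 0).any():
        empty = list(out.columns[out.notna().sum(axis=0) == 0])
        raise ValueError(f"outlier removal left no ratings for images: {empty}")
    n_cells = int(z.notna().sum().sum())
    dropped = n_cells - int(out.notna().sum().sum())
    if n_cells and dropped / n_cells > warn_fraction:
        warnings.warn(
            f"outlier removal dropped {dropped}/{n_cells} cells "
            f"({dropped / n_cells:.1%})",
            stacklevel=2,
        )
    return out


def mean_scores(z: pd.DataFrame) -> pd.DataFrame:
    """Average surviving Z-scores per image.

    Returns a DataFrame indexed by image id with columns ``y`` (mean score)
    and ``n_survivors``.
    """
    z = pd.DataFrame(z)
    n = z.notna().sum(axis=0)
    if (n == 0).any():
        raise ValueError("some images have no surviving ratings")
    return pd.DataFrame({"y": z.mean(axis=0), "n_survivors": n.astype(int)})


def process_ratings(
    r: pd.DataFrame, half_width_sd: float = 2.0, clean: bool = True
) -> pd.DataFrame:
    """Full chain: Z-scores -> (optional) outlier cleaning -> per-image means."""
    z = zscore_per_subject(r)
    if clean:
        z = remove_outliers(z, half_width_sd=half_width_sd)
    return mean_scores(z)
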