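"""Feature tables: N images x 11 measures, with min-max normalization state."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import MEASURE_NAMES

__all__ = ["FeatureTable"]


@dataclass
class FeatureTable:
    """Per-image measure values plus the column normalization metadata.

    ``data`` is a DataFrame indexed by image id with columns M1..M11.  After
    :meth:`normalize`, every column is min-max scaled to [0, 1] over the
    table's rows and ``norms`` stores the original (min, max) per column so
    the transform is invertible and reapplicable to new rows.
    """

    data: pd.DataFrame
    normalized: bool = False
    norms: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = [c for c in MEASURE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        if self.data[list(MEASURE_NAMES)].isna().any().any():
            raise ValueError("feature table has missing cells")

    @property
    def values(self) -> np.ndarray:
        """N x 11 float array in M1..M11 order."""
        return self.data[list(MEASURE_NAMES)].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)

    def normalize(self) -> "FeatureTable":
        """Min-max scale each column to [0, 1] over this table's rows.

        A constant column is degenerate (carries no ranking information); it
        is mapped to all zeros with a warning.
        """
        if self.normalized:
            return self
        if len(self.data) < 2:
            raise ValueError("normalization needs at least 2 rows")
        out = self.data.copy()
        norms: dict[str, tuple[float, float]] = {}
        for col in MEASURE_NAMES:
            lo = float(out[col].min())
            hi = float(out[col].max())
            norms[col] = (lo, hi)
            if hi == lo:
                warnings.warn(f"constant column {col}: normalized to 0", stacklevel=2)
                out[col] = 0.0
            else:
                out[col] = (out[col] - lo) / (hi - lo)
        return FeatureTable(data=out, normalized=True, norms=norms)

    def denormalize(self) -> "FeatureTable":
        """Invert :meth:`normalize` using the stored (min, max) pairs."""
        if not self.normalized:
            return self
        out = self.data.copy()
        for col, (lo, hi) in self.norms.items():
            out[col] = out[col] * (hi - lo) + lo if hi > lo else lo
        return FeatureTable(data=out, normalized=False)

    def apply_norms(self, new_rows: pd.DataFrame) -> pd.DataFrame:
        """Scale new rows with this table's stored normalization (clipping off)."""
        if not self.normalized:
            raise ValueError("table is not normalized; no stored norms")
        out = new_rows.copy()
        for col, (lo, hi) in self.norms.items():
            out[col] = (out[col] - lo) / (hi - lo) if hi > lo else 0.0
        return out
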