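"""Readers and writers for feature tables, ratings, scores and weights.

Formats
-------
* Feature table CSV: header ``image_id,M1,...,M11``.
* Study-table layout (the layout of published per-dataset workbooks): one
  sheet/table per dataset with an image identifier column, the 11 measure
  columns, and a final mean-subjective-score column.  Accepted as .xlsx or
  .csv; column order is what identifies the fields, so native headers are
  fine.
* Ratings: wide matrix (subjects x images, first column = subject id) or
  long form ``subject_id,image_id,score``.
* Mean scores CSV: ``image_id,y,n_survivors``.
* Weights JSON: ``{"name": ..., "a": [11 floats], "provenance": ...}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .features import MEASURE_NAMES
from .table import FeatureTable

__all__ = [
    "read_feature_table",
    "write_feature_table",
    "read_study_table",
    "read_ratings",
    "write_mean_scores",
    "read_weights",
    "write_weights",
]


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path)
    if "image_id" not in df.columns:
        raise ValueError("feature table CSV must have an image_id column")
    return FeatureTable(data=df.set_index("image_id"))


def write_feature_table(t: FeatureTable, path) -> None:
    out = t.data[list(MEASURE_NAMES)].copy()
    out.index.name = "image_id"
    out.to_csv(path)


def read_study_table(path, sheet=0) -> tuple[FeatureTable, pd.Series]:
    """Read a study-layout table: id, 11 measures, mean score (by position).

    Returns the feature table and the mean subjective scores, aligned by
    image id.  ``sheet`` selects the worksheet for .xlsx input.
    """
    path = Path(path)
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path)
    if df.shape[1] < 13:
        raise ValueError(
            f"study table needs >= 13 columns (id, 11 measures, score); "
            f"got {df.shape[1]}"
        )
    ids = df.iloc[:, 0].astype(str)
    feats = df.iloc[:, 1:12].apply(pd.to_numeric)
    feats.columns = list(MEASURE_NAMES)
    feats.index = pd.Index(ids, name="image_id")
    y = pd.to_numeric(df.iloc[:, 12])
    y.index = feats.index
    y.name = "y"
    return FeatureTable(data=feats), y


def read_ratings(path) -> pd.DataFrame:
    """Read a rating matrix from wide or long CSV into subjects x images."""
    df = pd.read_csv(path)
    cols = [c.lower() for c in df.columns]
    if cols[:3] == ["subject_id", "image_id", "score"]:
        wide = df.pivot(index=df.columns[0], columns=df.columns[1],
                        values=df.columns[2])
        return wide
    return df.set_index(df.columns[0])


def write_mean_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out.index.name = "image_id"
    out.to_csv(path)


def write_weights(a, path, name: str = "custom", provenance: str = "") -> None:
    a = np.asarray(a, dtype=float).ravel()
    payload = {"name": name, "a": a.tolist(), "provenance": provenance}
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_weights(path) -> tuple[str, np.ndarray]:
    d = json.loads(Path(path).read_text())
    return d.get("name", "custom"), np.asarray(d["a"], dtype=float)
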