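"""Screen-matrix I/O, drop-out filtering, KNN imputation and control QC.

The raw input of a two-dimensional screen is an N x M matrix of measurements
(N perturbations x M functional readouts) plus a per-row annotation that marks
each perturbation as a screened sample, a positive/negative control, or a
non-expressor (a gene not expressed in the assayed cell type, whose reagents
act as internal true negatives).  Before scoring, rows and columns with
excessive drop-outs are removed and remaining missing values are imputed with
a K-nearest-neighbour scheme.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

ROW_CLASSES = frozenset(
    {"sample", "positive_control", "negative_control", "non_expressor", "killer_control"}
)

__all__ = [
    "ROW_CLASSES",
    "ScreenMatrix",
    "QCReport",
    "read_screen_matrix",
    "read_annotation",
    "validate_annotation",
    "write_screen_matrix",
    "filter_dropouts",
    "impute_knn",
    "qc_screen",
    "ssmd",
]


@dataclass
class ScreenMatrix:
    """Labeled perturbation x readout matrix; NaN entries mark missing values."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate row ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate column ids: {dups}")

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def row_ids(self) -> pd.Index:
        return self.values.index

    @property
    def col_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class QCReport:
    """Per-readout SSMD quality summary for control separation.

    SSMD_j = (mean_pos_j - mean_neg_j) / sqrt(sd_pos_j^2 + sd_neg_j^2), with
    sample (n-1) standard deviations.  A screen is considered workable when
    more than 5% of readouts reach SSMD > 2.  The 2-D control embedding is
    advisory output only; pass/fail is decided by SSMD alone.
    """

    ssmd_per_readout: pd.Series
    frac_high_quality: float
    passed: bool
    separation_embedding: pd.DataFrame | None = None
    params: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "ssmd_per_readout": {str(k): float(v) for k, v in self.ssmd_per_readout.items()},
            "frac_high_quality": float(self.frac_high_quality),
            "passed": bool(self.passed),
            "params": self.params,
        }
        if self.separation_embedding is not None:
            payload["separation_embedding"] = {
                str(k): [float(x) for x in row]
                for k, row in self.separation_embedding.iterrows()
            }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def read_screen_matrix(path, annotation_path=None, sep: str = "\t"):
    """Read a delimited screen matrix (header of readout ids, first column of
    perturbation ids; empty cells or NA tokens mark missing values).

    Returns ``ScreenMatrix`` alone, or ``(ScreenMatrix, annotation)`` when
    ``annotation_path`` is given.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df = df.apply(pd.to_numeric, errors="coerce")
    m = ScreenMatrix(df)
    if annotation_path is None:
        return m
    ann = read_annotation(annotation_path, sep=sep)
    validate_annotation(m, ann)
    return m, ann


def read_annotation(path, sep: str = "\t") -> pd.Series:
    """Read a two-column annotation table (row_id, class) into a Series."""
    df = pd.read_csv(path, sep=sep)
    if not {"row_id", "class"}.issubset(df.columns):
        raise ValueError("annotation file must have columns 'row_id' and 'class'")
    ann = df.set_index("row_id")["class"]
    bad = set(ann.unique()) - ROW_CLASSES
    if bad:
        raise ValueError(f"unknown annotation classes: {sorted(bad)}")
    return ann


def validate_annotation(m: ScreenMatrix, ann: pd.Series) -> None:
    """Every matrix row must carry exactly one valid class label."""
    bad = set(pd.unique(ann)) - ROW_CLASSES
    if bad:
        raise ValueError(f"unknown annotation classes: {sorted(bad)}")
    missing = m.row_ids.difference(ann.index)
    if len(missing):
        raise ValueError(f"annotation missing for rows: {missing.tolist()[:10]}")
    if ann.index.has_duplicates:
        dups = ann.index[ann.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate annotation rows: {dups}")
    if (ann.loc[m.row_ids] == "negative_control").sum() < 1:
        raise ValueError("at least one negative_control row is required")


def write_screen_matrix(m: ScreenMatrix, path, sep: str = "\t") -> None:
    # %.17g + round_trip parsing makes write->read bit-exact for finite entries
    m.values.to_csv(path, sep=sep, index_label="id", float_format="%.17g")


def _iqr_fence(counts: np.ndarray) -> float:
    q1, q3 = np.percentile(counts, [25, 75])  # linear-interpolation quantiles
    return float(q3 + 3.0 * (q3 - q1))


def filter_dropouts(m: ScreenMatrix) -> tuple[ScreenMatrix, dict]:
    """Remove rows, then columns, whose missing-value count exceeds the
    Tukey-style fence Q3 + 3*(Q3 - Q1) over the per-row (resp. per-column)
    missing counts.  Returns the reduced matrix and a log of removed ids.
    """
    mask = m.missing_mask.to_numpy()
    row_counts = mask.sum(axis=1)
    row_fence = _iqr_fence(row_counts)
    keep_rows = row_counts <= row_fence
    rows_removed = m.row_ids[~keep_rows].tolist()

    reduced = m.values.loc[keep_rows]
    if reduced.shape[0] == 0:
        raise ValueError("matrix empty after filtering")
    col_counts = reduced.isna().to_numpy().sum(axis=0)
    col_fence = _iqr_fence(col_counts)
    keep_cols = col_counts <= col_fence
    cols_removed = m.col_ids[~keep_cols].tolist()
    reduced = reduced.loc[:, keep_cols]
    if reduced.shape[1] == 0:
        raise ValueError("matrix empty after filtering")

    log = {
        "rows_removed": rows_removed,
        "cols_removed": cols_removed,
        "row_fence": row_fence,
        "col_fence": col_fence,
    }
    return ScreenMatrix(reduced), log


def impute_knn(m: ScreenMatrix, k: int = 10) -> ScreenMatrix:
    """Impute each missing entry with the mean of that column over the k
    nearest rows (Euclidean distance on mutually observed columns, scaled by
    the fraction of columns observed; ties broken by row order).

    Only rows with the target column observed are neighbour candidates; when
    fewer than ``k`` exist, k is reduced with a warning.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    X = m.values.to_numpy(dtype=float)
    obs = ~np.isnan(X)
    if not (~obs).any():
        return ScreenMatrix(m.values.copy())
    if (obs.sum(axis=1) == 0).any():
        empty = m.row_ids[obs.sum(axis=1) == 0].tolist()
        raise ValueError(f"rows with no observed values cannot be imputed: {empty}")

    n, p = X.shape
    X0 = np.where(obs, X, 0.0)
    # pairwise squared distance over shared observed columns, divided by the
    # number of shared columns (equivalently scaled by fraction observed)
    shared = obs.astype(float) @ obs.T.astype(float)
    sq = (X0**2) @ obs.T.astype(float)
    cross = X0 @ X0.T
    d2 = sq + sq.T - 2.0 * cross
    with np.errstate(invalid="ignore", divide="ignore"):
        d2 = np.where(shared > 0, d2 / shared, np.inf)
    np.fill_diagonal(d2, np.inf)
    d2 = np.maximum(d2, 0.0)

    out = X.copy()
    warned = False
    for i, j in zip(*np.where(~obs)):
        cand = np.where(obs[:, j] & np.isfinite(d2[i]))[0]
        if cand.size == 0:
            raise ValueError(
                f"no neighbour with column {m.col_ids[j]!r} observed for row {m.row_ids[i]!r}"
            )
        kk = min(k, cand.size)
        if kk < k and not warned:
            warnings.warn(
                f"fewer than k={k} neighbour candidates available; using k={kk}",
                stacklevel=2,
            )
            warned = True
        order = cand[np.argsort(d2[i, cand], kind="stable")[:kk]]
        out[i, j] = X[order, j].mean()
    return ScreenMatrix(pd.DataFrame(out, index=m.row_ids, columns=m.col_ids))


def ssmd(pos: np.ndarray, neg: np.ndarray, axis: int = 0) -> np.ndarray:
    """Strictly standardized mean difference with sample (n-1) SDs."""
    mp = np.mean(pos, axis=axis)
    mn = np.mean(neg, axis=axis)
    sp = np.std(pos, axis=axis, ddof=1)
    sn = np.std(neg, axis=axis, ddof=1)
    return (mp - mn) / np.sqrt(sp**2 + sn**2)


def qc_screen(
    m: ScreenMatrix,
    ann: pd.Series,
    ssmd_threshold: float = 2.0,
    min_fraction: float = 0.05,
    seed: int = 0,
) -> QCReport:
    """Per-readout SSMD control separation plus an advisory 2-D PCA embedding
    of the control rows.  ``passed`` is true iff the fraction of readouts with
    SSMD above ``ssmd_threshold`` exceeds ``min_fraction``.
    """
    classes = ann.loc[m.row_ids]
    pos = m.values.loc[classes == "positive_control"]
    neg = m.values.loc[classes == "negative_control"]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need >= 2 positive and >= 2 negative control rows for QC")

    scores = pd.Series(
        ssmd(pos.to_numpy(float), neg.to_numpy(float), axis=0), index=m.col_ids, name="ssmd"
    )
    frac = float((scores > ssmd_threshold).mean())

    controls = pd.concat([pos, neg])
    embedding = None
    if controls.shape[1] >= 2 and len(controls) >= 3 and not controls.isna().any().any():
        from sklearn.decomposition import PCA

        coords = PCA(n_components=2, random_state=seed).fit_transform(controls.to_numpy(float))
        embedding = pd.DataFrame(coords, index=controls.index, columns=["dim1", "dim2"])

    return QCReport(
        ssmd_per_readout=scores,
        frac_high_quality=frac,
        passed=frac > min_fraction,
        separation_embedding=embedding,
        params={"ssmd_threshold": ssmd_threshold, "min_fraction": min_fraction, "seed": seed},
    )
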