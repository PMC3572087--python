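"""Per-feature min-max normalization and Student's t-test feature ranking.

Both are *fit on training data only* and then applied to held-out data, so
that no information from the evaluation fold leaks into scaling or feature
selection.  Held-out values falling outside the training range are clipped
to [0, 1]; a feature constant on the training set maps to 0 everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .encoders import FeatureMatrix
from .seqio import SglutError


@dataclass
class NormalizationModel:
    """Per-feature training minimum and maximum for min-max scaling."""

    feature_names: list[str]
    min_: np.ndarray
    max_: np.ndarray


def fit_normalizer(train: FeatureMatrix) -> NormalizationModel:
    if train.values.shape[0] == 0:
        raise SglutError("cannot fit a normalizer on an empty matrix")
    return NormalizationModel(
        feature_names=list(train.feature_names),
        min_=train.values.min(axis=0),
        max_=train.values.max(axis=0),
    )


def apply_normalizer(model: NormalizationModel, data: FeatureMatrix) -> FeatureMatrix:
    """Scale each feature to [0,1] by the training range, clipping overflow.

    Features constant on the training set (max == min) map to 0.
    """
    if list(data.feature_names) != model.feature_names:
        raise SglutError("feature names do not match the normalization model")
    span = model.max_ - model.min_
    safe = np.where(span > 0, span, 1.0)
    scaled = np.clip((data.values - model.min_) / safe, 0.0, 1.0)
    scaled[:, span == 0] = 0.0
    return FeatureMatrix(
        scheme=data.scheme,
        feature_names=list(data.feature_names),
        values=scaled,
        labels=list(data.labels),
        protein_ids=list(data.protein_ids),
        positions=list(data.positions),
    )


def t_statistic(values_pos: np.ndarray, values_neg: np.ndarray) -> tuple[float, float]:
    """Two-sample pooled-variance Student's t and its two-sided p-value.

    Degrees of freedom are n1 + n2 - 2.  When the pooled variance is zero the
    feature carries no usable spread and (t, p) = (0, 1) by convention.
    """
    x = np.asarray(values_pos, dtype=float)
    y = np.asarray(values_neg, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise SglutError("each group needs >= 2 values for a t-test")
    n1, n2 = len(x), len(y)
    df = n1 + n2 - 2
    pooled_var = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if pooled_var == 0:
        return 0.0, 1.0
    t = (x.mean() - y.mean()) / np.sqrt(pooled_var * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p)


@dataclass
class FeatureRanking:
    """Features ordered by decreasing |t|, ties broken by original index."""

    entries: list[tuple[str, float, float]]  # (feature_name, t, p)

    def names(self) -> list[str]:
        return [name for name, _, _ in self.entries]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("feature\tt\tp\trank\n")
            for rank, (name, t, p) in enumerate(self.entries, start=1):
                fh.write(f"{name}\t{t:.6g}\t{p:.6g}\t{rank}\n")


def rank_features(train: FeatureMatrix) -> FeatureRanking:
    """Rank every feature of a training matrix by |t| between the classes.

    Vectorized pooled-variance t over all columns; the per-feature results
    agree with :func:`t_statistic`.
    """
    y = train.y
    x_pos = train.values[y == 1]
    x_neg = train.values[y == 0]
    n1, n2 = len(x_pos), len(x_neg)
    if n1 < 2 or n2 < 2:
        raise SglutError("ranking needs >= 2 samples per class")
    df = n1 + n2 - 2
    pooled_var = (
        (n1 - 1) * x_pos.var(axis=0, ddof=1) + (n2 - 1) * x_neg.var(axis=0, ddof=1)
    ) / df
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (x_pos.mean(axis=0) - x_neg.mean(axis=0)) / np.sqrt(
            pooled_var * (1 / n1 + 1 / n2)
        )
    t = np.where(pooled_var == 0, 0.0, t)
    p = np.where(pooled_var == 0, 1.0, 2 * stats.t.sf(np.abs(t), df))
    # stable sort on -|t| keeps original index order among ties
    order = np.argsort(-np.abs(t), kind="stable")
    return FeatureRanking(
        [(train.feature_names[i], float(t[i]), float(p[i])) for i in order]
    )


def select_top_k(ranking: FeatureRanking, k: int) -> list[str]:
    """First k feature names of the ranking (deterministic)."""
    if not 1 <= k <= len(ranking.entries):
        raise SglutError(
            f"k must be in 1..{len(ranking.entries)}, got {k}"
        )
    return ranking.names()[:k]


def subset_features(matrix: FeatureMatrix, names: list[str]) -> FeatureMatrix:
    """Restrict a matrix to the named feature columns, in the given order."""
    index = {name: i for i, name in enumerate(matrix.feature_names)}
    missing = [n for n in names if n not in index]
    if missing:
        raise SglutError(f"features not in matrix: {missing[:5]}")
    cols = [index[n] for n in names]
    scheme = matrix.scheme
    return FeatureMatrix(
        scheme=type(scheme)(scheme.name, len(cols)),
        feature_names=list(names),
        values=matrix.values[:, cols],
        labels=list(matrix.labels),
        protein_ids=list(matrix.protein_ids),
        positions=list(matrix.positions),
    )
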