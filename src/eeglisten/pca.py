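"""Feature matrix assembly and SVD-based principal component analysis.

The long-format feature table (one row per participant x fragment x channel)
is pivoted into an observations x features matrix, power-based features are
mapped to natural-log scale, every column is z-scored, and the matrix is
decomposed as X = U S V^T.  PC scores are X V (= U S); explained variance
fractions are s_i^2 / sum s^2; feature coordinates on a component are the
correlations between feature columns and score columns.  Two normalizations
of squared coordinates are exposed: per-component contributions (each
component's contributions sum to 100%) and per-feature representation
quality (each feature's squared coordinates over the retained components
sum to 100%).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .montage import SUBREGIONS

ID_COLUMNS = ("participant", "fragment", "task", "background", "topic",
              "channel")

#: power-based features get a natural-log transform before z-scoring
LOG_PREFIXES = ("AP_", "MP")


def is_log_feature(name: str) -> bool:
    return name.startswith(LOG_PREFIXES)


@dataclass
class FeatureMatrix:
    """Normalized observations x features matrix with its row identifiers."""

    X: np.ndarray
    ids: pd.DataFrame
    feature_names: list
    mean: np.ndarray
    sd: np.ndarray
    log_applied: list

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def build_matrix(feature_table: pd.DataFrame,
                 registry: list | None = None) -> FeatureMatrix:
    """Normalize a long-format feature table into a FeatureMatrix.

    ``registry`` selects and orders the feature columns (default: every
    non-identifier column).  Rows containing excluded channels should be
    dropped before this call; rows with missing values in retained columns
    are rejected.  Natural log is applied to absolute/peak power columns,
    then each column is z-scored with sample (n-1) standard deviation.
    """
    id_cols = [c for c in ID_COLUMNS if c in feature_table.columns]
    features = registry or [c for c in feature_table.columns
                            if c not in ID_COLUMNS]
    missing = [c for c in features if c not in feature_table.columns]
    if missing:
        raise ValueError(f"features missing from table: {missing}")
    sub = feature_table[features]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValueError(f"missing values in feature columns: {bad}")
    X = sub.to_numpy(dtype=np.float64).copy()
    log_applied = []
    for j, name in enumerate(features):
        if is_log_feature(name):
            if np.any(X[:, j] <= 0):
                raise ValueError(
                    f"non-positive power in {name!r}: cannot log-transform")
            X[:, j] = np.log(X[:, j])
            log_applied.append(name)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    if np.any(sd == 0):
        const = [features[j] for j in np.flatnonzero(sd == 0)]
        raise ValueError(f"constant feature columns: {const}")
    X = (X - mean) / sd
    return FeatureMatrix(X=X, ids=feature_table[id_cols].reset_index(drop=True),
                         feature_names=list(features), mean=mean, sd=sd,
                         log_applied=log_applied)


@dataclass
class PCAModel:
    loadings: np.ndarray        # V, p x p (columns are components)
    singular_values: np.ndarray
    scores: np.ndarray          # n x p (= X V)
    explained_var: np.ndarray   # fractions, sum to 1
    coordinates: np.ndarray     # feature-score correlations, p x p
    feature_names: list
    ids: pd.DataFrame = field(repr=False, default=None)

    def contributions(self, k: int | None = None) -> pd.DataFrame:
        """Percent contribution of each feature to each component; every
        component's column sums to 100."""
        k = k or self.loadings.shape[1]
        c = 100.0 * self.loadings[:, :k] ** 2
        return pd.DataFrame(c, index=self.feature_names,
                            columns=[f"PC{i + 1}" for i in range(k)])

    def representation_quality(self, k: int = 10) -> pd.DataFrame:
        """Squared coordinates normalized per feature over the first ``k``
        components (each row sums to 100): how well a feature is represented
        in the retained component space."""
        k = min(k, self.coordinates.shape[1])
        sq = self.coordinates[:, :k] ** 2
        q = 100.0 * sq / sq.sum(axis=1, keepdims=True)
        return pd.DataFrame(q, index=self.feature_names,
                            columns=[f"PC{i + 1}" for i in range(k)])

    def scores_frame(self, k: int | None = None) -> pd.DataFrame:
        k = k or self.scores.shape[1]
        df = self.ids.copy()
        for i in range(k):
            df[f"PC{i + 1}"] = self.scores[:, i]
        return df


def fit_pca(fm: FeatureMatrix) -> PCAModel:
    """SVD-based PCA of the normalized matrix.

    Component signs are fixed so each loading vector's largest-magnitude
    element is positive (SVD signs are otherwise arbitrary).
    """
    X = fm.X
    if not np.any(X):
        raise ValueError("degenerate (all-zero) matrix")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    V = Vt.T
    flip = np.sign(V[np.argmax(np.abs(V), axis=0), np.arange(V.shape[1])])
    flip[flip == 0] = 1.0
    V = V * flip
    U = U * flip
    scores = X @ V
    explained = s ** 2 / np.sum(s ** 2)
    coords = V * s / np.sqrt(max(fm.n - 1, 1))
    return PCAModel(loadings=V, singular_values=s, scores=scores,
                    explained_var=explained, coordinates=coords,
                    feature_names=list(fm.feature_names), ids=fm.ids)


def subregion_scores(model: PCAModel, subregion_map: dict,
                     k: int = 9) -> pd.DataFrame:
    """Average channel-level PC scores within each scalp subregion.

    Returns one row per (participant, fragment, task, background, topic,
    subregion) with columns PC1..PCk: the arithmetic mean of the raw channel
    scores (averaging happens on scores, never on re-standardized values).
    """
    df = model.scores_frame(k)
    unmapped = set(df["channel"]) - set(subregion_map)
    if unmapped:
        raise ValueError(f"channels without subregion: {sorted(unmapped)}")
    df = df.copy()
    df["subregion"] = df["channel"].map(subregion_map)
    keys = [c for c in ("participant", "fragment", "task", "background",
                        "topic") if c in df.columns]
    pcs = [f"PC{i + 1}" for i in range(k)]
    out = (df.groupby(keys + ["subregion"], dropna=False, observed=True)
           [pcs].mean().reset_index())
    empty = set(SUBREGIONS) - set(out["subregion"])
    if empty:
        raise ValueError(f"empty subregions after exclusions: {sorted(empty)}")
    return out
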