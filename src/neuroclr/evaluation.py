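"""Consistency metrics, behavioural binning and kNN decoding of embeddings.

Consistency between two embeddings is the R² of a linear regression (with
intercept) mapping one onto the other — the practical test of
identifiability up to a linear transformation.  Embeddings of different
subjects (different neurons, different row counts) are first aligned by
behaviour: unit-norm embedding vectors are averaged within position ×
direction bins and renormalized onto the hypersphere, producing comparable
bin-feature matrices.  Decoding uses a plain kNN regressor/classifier with
the distance metric matching the training similarity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import LinearRegression
from sklearn.metrics import accuracy_score, r2_score
from sklearn.neighbors import KNeighborsClassifier, KNeighborsRegressor

DEFAULT_K_GRID = (1, 4, 9, 16, 25)


@dataclass
class ConsistencyReport:
    r2_matrix: np.ndarray            # [R x R], NaN on the diagonal
    alignment: str = "raw"           # or "behaviour_binned"

    @property
    def comparisons(self) -> int:
        r = self.r2_matrix.shape[0]
        return r * (r - 1)

    @property
    def values(self) -> np.ndarray:
        off = ~np.eye(self.r2_matrix.shape[0], dtype=bool)
        return self.r2_matrix[off]

    @property
    def mean(self) -> float:
        return float(self.values.mean())

    @property
    def std(self) -> float:
        return float(self.values.std())


@dataclass
class DecodingReport:
    task: str
    k: int
    metrics: dict = field(default_factory=dict)
    split: str = "train/valid/test"


def linear_consistency(source: np.ndarray, target: np.ndarray,
                       fit_mask: np.ndarray | None = None,
                       multioutput: str = "uniform_average") -> float:
    """R² of the least-squares linear map (with intercept) source -> target.

    In-sample by default (an alignment score, not a predictive model);
    ``fit_mask`` switches to out-of-sample scoring on the complement rows.
    """
    source = np.asarray(source, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if source.shape[0] != target.shape[0]:
        raise ValueError("source and target must have the same row count")
    reg = LinearRegression()
    if fit_mask is None:
        reg.fit(source, target)
        return float(r2_score(target, reg.predict(source),
                              multioutput=multioutput))
    fit_mask = np.asarray(fit_mask, dtype=bool)
    reg.fit(source[fit_mask], target[fit_mask])
    return float(r2_score(target[~fit_mask], reg.predict(source[~fit_mask]),
                          multioutput=multioutput))


def run_consistency(embeddings: list[np.ndarray],
                    alignment: str = "raw") -> ConsistencyReport:
    """All ordered pairwise consistencies among runs on identical data.

    R runs yield R·(R−1) comparisons (ten runs → 90).
    """
    r = len(embeddings)
    if r < 2:
        raise ValueError("need at least two embeddings")
    mat = np.full((r, r), np.nan)
    for i in range(r):
        for j in range(r):
            if i != j:
                mat[i, j] = linear_consistency(embeddings[i], embeddings[j])
    return ConsistencyReport(mat, alignment=alignment)


def behaviour_bin_average(embedding: np.ndarray, position: np.ndarray,
                          direction: np.ndarray, n_bins: int = 100,
                          position_range: tuple[float, float] | None = None
                          ) -> np.ndarray:
    """Direction × position bin features of a unit-norm embedding.

    Positions are binned into ``n_bins`` equal-width bins per direction; the
    member embeddings of each bin are averaged and the average renormalized
    onto the hypersphere.  An empty bin is imputed from the pooled members
    of its two adjacent bins (same direction).  Rows are ordered
    direction-major, bin-minor: ``[2 * n_bins x E]`` for binary directions.
    """
    embedding = np.asarray(embedding, dtype=np.float64)
    position = np.asarray(position, dtype=np.float64).ravel()
    direction = np.asarray(direction).ravel()
    if not (len(embedding) == len(position) == len(direction)):
        raise ValueError("embedding, position and direction must be aligned")
    norms = np.linalg.norm(embedding, axis=1)
    if not np.allclose(norms, 1.0, atol=1e-6):
        raise ValueError("behaviour binning expects unit-norm embeddings")
    lo, hi = (position.min(), position.max()) if position_range is None \
        else position_range
    edges = np.linspace(lo, hi, n_bins + 1)
    bin_idx = np.clip(np.searchsorted(edges, position, side="right") - 1,
                      0, n_bins - 1)
    dirs = np.unique(direction)
    rows = []
    for d in dirs:
        sel = direction == d
        members = [np.flatnonzero(sel & (bin_idx == b))
                   for b in range(n_bins)]
        for b in range(n_bins):
            idx = members[b]
            if idx.size == 0:  # pool the raw members of the two neighbours
                neighbours = []
                if b > 0:
                    neighbours.append(members[b - 1])
                if b < n_bins - 1:
                    neighbours.append(members[b + 1])
                idx = (np.concatenate(neighbours) if neighbours
                       else np.zeros(0, dtype=np.int64))
                if idx.size == 0:
                    raise ValueError(
                        f"bin {b} (direction {d!r}) and both neighbours are "
                        f"empty; use fewer bins")
            v = embedding[idx].mean(axis=0)
            nrm = np.linalg.norm(v)
            if nrm == 0:
                raise ValueError(f"bin {b} average has zero norm")
            rows.append(v / nrm)
    return np.asarray(rows)


def subject_consistency(embedding_a: np.ndarray, position_a, direction_a,
                        embedding_b: np.ndarray, position_b, direction_b,
                        n_bins: int = 100,
                        position_range: tuple[float, float] | None = None
                        ) -> float:
    """Linear consistency of two subjects after behavioural alignment."""
    fa = behaviour_bin_average(embedding_a, position_a, direction_a, n_bins,
                               position_range)
    fb = behaviour_bin_average(embedding_b, position_b, direction_b, n_bins,
                               position_range)
    return linear_consistency(fa, fb)


def knn_decode(train_emb: np.ndarray, train_labels: np.ndarray,
               valid_emb: np.ndarray, valid_labels: np.ndarray,
               test_emb: np.ndarray, test_labels: np.ndarray,
               task: str = "regression",
               k_grid: tuple[int, ...] = DEFAULT_K_GRID,
               metric: str = "cosine") -> DecodingReport:
    """kNN decoding with k selected on the validation split only.

    Regression selects k by validation R² and reports test R² and median
    absolute error (the positional-decoding metric); classification selects
    by validation accuracy and reports test accuracy.
    """
    train_emb = np.asarray(train_emb, dtype=np.float64)
    if not k_grid:
        raise ValueError("k_grid must be non-empty")
    n_train = train_emb.shape[0]
    ks = []
    for k in k_grid:
        if k > n_train:
            warnings.warn(f"k={k} exceeds the training size {n_train}; "
                          f"clipping")
            k = n_train
        if k not in ks:
            ks.append(k)
    cls = KNeighborsRegressor if task == "regression" else \
        KNeighborsClassifier
    best_k, best_score, best_model = None, -np.inf, None
    for k in ks:
        model = cls(n_neighbors=k, metric=metric)
        model.fit(train_emb, train_labels)
        pred = model.predict(valid_emb)
        score = (r2_score(valid_labels, pred) if task == "regression"
                 else accuracy_score(valid_labels, pred))
        if score > best_score:
            best_k, best_score, best_model = k, score, model
    pred = best_model.predict(test_emb)
    metrics = {"validation_score": float(best_score)}
    if task == "regression":
        metrics["r2"] = float(r2_score(test_labels, pred))
        metrics["median_abs_error"] = float(
            np.median(np.abs(np.asarray(test_labels) - pred)))
    else:
        metrics["accuracy"] = float(accuracy_score(test_labels, pred))
    return DecodingReport(task=task, k=best_k, metrics=metrics)


def shuffle_labels(labels: np.ndarray, rng: np.random.Generator
                   ) -> np.ndarray:
    """Permute whole context rows with a seeded permutation (marginals kept)."""
    labels = np.asarray(labels)
    return labels[rng.permutation(labels.shape[0])]
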