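"""Item/user similarity and collaborative-filtering completion.

Item-based collaborative filtering (IBCF) predicts the missing rating of
genotype *i* for item *j′* as the similarity-weighted average of that
genotype's observed ratings,

    P(i, j′) = Σ_j y_ij · w_jj′ / Σ_j |w_jj′|,

summing over the genotype's rated items.  Similarities w are pairwise-
complete cosine or Pearson weights between item columns; user-based
filtering (UBCF) is the same computation on the transposed matrix, and a
genomic relationship matrix can stand in for the user–user weights.

Pairs with fewer than ``min_overlap`` co-observed entries have undefined
similarity (NaN) and are excluded from neighborhoods.  A cell with no
usable neighbors falls back to the column training mean; fallback cells
are reported, not silently absorbed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import AlignmentError, DimensionError
from .ratings import RatingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityMatrix",
    "cosine_similarity",
    "pearson_similarity",
    "item_similarity_matrix",
    "user_similarity_matrix",
    "ibcf_predict_cell",
    "ibcf_complete",
    "ubcf_complete",
]

DEFAULT_MIN_OVERLAP = 2


@dataclass
class SimilarityMatrix:
    """Symmetric entity–entity weights with co-observation counts.

    ``weights`` holds NaN where a pair's similarity is undefined (overlap
    below the minimum, or zero variance for Pearson).  ``overlap`` counts
    co-observed rows (for item similarity) or columns (for user similarity)
    per pair.  ``method`` records provenance: cosine, pearson, or external
    (supplied weights such as a genomic relationship matrix).
    """

    ids: list[str]
    weights: np.ndarray
    overlap: np.ndarray
    method: str = "cosine"

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.overlap = np.asarray(self.overlap, dtype=int)
        k = len(self.ids)
        if self.weights.shape != (k, k) or self.overlap.shape != (k, k):
            raise DimensionError("weights/overlap must be square and match ids")
        defined = np.isfinite(self.weights)
        if not np.array_equal(defined, defined.T) or not np.allclose(
            np.where(defined, self.weights, 0.0),
            np.where(defined, self.weights, 0.0).T,
            atol=1e-12,
        ):
            raise ValueError("weights must be symmetric")
        if np.any(self.overlap < 0):
            raise ValueError("overlap counts must be nonnegative")
        if self.method in ("cosine", "pearson") and np.any(
            np.abs(self.weights[defined]) > 1 + 1e-12
        ):
            raise ValueError(f"|{self.method} weights| must be ≤ 1")

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.weights, index=self.ids, columns=self.ids)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="id", na_rep="NA")

    @classmethod
    def from_csv(cls, path, method: str = "external") -> "SimilarityMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"], float_precision="round_trip")
        w = df.to_numpy(dtype=float)
        k = len(df.index)
        return cls([str(i) for i in df.index], w, np.full((k, k), k, dtype=int), method)


def _overlap_mask(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    return np.isfinite(x) & np.isfinite(y)


def cosine_similarity(
    x: np.ndarray, y: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Pairwise-complete cosine similarity; NaN if the overlap is too small.

    Only positions observed in both vectors enter the inner product and the
    norms, so two items are compared on the genotypes they share.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("vectors must have equal length")
    ov = _overlap_mask(x, y)
    if ov.sum() < min_overlap:
        return np.nan
    xv, yv = x[ov], y[ov]
    denom = np.linalg.norm(xv) * np.linalg.norm(yv)
    if denom == 0:
        return np.nan
    return float(np.clip(np.dot(xv, yv) / denom, -1.0, 1.0))


def pearson_similarity(
    x: np.ndarray, y: np.ndarray, min_overlap: int = DEFAULT_MIN_OVERLAP
) -> float:
    """Pairwise-complete sample Pearson correlation; NaN when undefined."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DimensionError("vectors must have equal length")
    ov = _overlap_mask(x, y)
    if ov.sum() < min_overlap:
        return np.nan
    xv, yv = x[ov] - x[ov].mean(), y[ov] - y[ov].mean()
    denom = np.linalg.norm(xv) * np.linalg.norm(yv)
    if denom == 0:
        return np.nan
    return float(np.clip(np.dot(xv, yv) / denom, -1.0, 1.0))


_SIM_FUNCS = {"cosine": cosine_similarity, "pearson": pearson_similarity}


def item_similarity_matrix(
    R: RatingMatrix, method: str = "cosine", min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SimilarityMatrix:
    """All pairwise column similarities of a rating matrix."""
    if R.n_cols < 2:
        raise DimensionError("need at least 2 columns for item similarity")
    if method not in _SIM_FUNCS:
        raise ValueError(f"unknown similarity method {method!r}")
    sim = _SIM_FUNCS[method]
    m = R.n_cols
    W = np.full((m, m), np.nan)
    counts = np.zeros((m, m), dtype=int)
    for j in range(m):
        counts[j, j] = int(R.mask[:, j].sum())
        W[j, j] = 1.0 if counts[j, j] >= 1 else np.nan
        for jp in range(j + 1, m):
            counts[j, jp] = counts[jp, j] = int((R.mask[:, j] & R.mask[:, jp]).sum())
            w = sim(R.values[:, j], R.values[:, jp], min_overlap=min_overlap)
            W[j, jp] = W[jp, j] = w
    return SimilarityMatrix(list(R.col_ids), W, counts, method)


def user_similarity_matrix(
    R: RatingMatrix, method: str = "cosine", min_overlap: int = DEFAULT_MIN_OVERLAP
) -> SimilarityMatrix:
    """All pairwise row similarities (user–user weights for UBCF)."""
    return item_similarity_matrix(R.transposed(), method=method, min_overlap=min_overlap)


def _neighbor_weights(
    values_row: np.ndarray,
    mask_row: np.ndarray,
    weights_col: np.ndarray,
    jprime: int,
    neighborhood: str,
    top_k: Optional[int],
) -> tuple[np.ndarray, np.ndarray]:
    """Indices and weights of the usable neighbors for one cell prediction."""
    cand = np.flatnonzero(mask_row & np.isfinite(weights_col))
    cand = cand[cand != jprime]
    w = weights_col[cand]
    if neighborhood == "nonnegative":
        keep = w >= 0
        cand, w = cand[keep], w[keep]
    elif neighborhood == "top_k":
        if top_k is None:
            raise ValueError("top_k neighborhood requires top_k")
        order = np.argsort(-np.abs(w), kind="stable")[:top_k]
        cand, w = cand[order], w[order]
    elif neighborhood != "all":
        raise ValueError(f"unknown neighborhood {neighborhood!r}")
    return cand, w


def ibcf_predict_cell(
    R: RatingMatrix,
    S: SimilarityMatrix,
    i: int,
    jprime: int,
    neighborhood: str = "all",
    top_k: Optional[int] = None,
) -> float:
    """Weighted-average prediction for cell (i, j′); NaN signals fallback.

    The numerator keeps the sign of each weight while the denominator sums
    absolute weights, exactly as the weighted-average formula is written;
    pass ``neighborhood="nonnegative"`` to drop negative weights instead.
    """
    w_col = S.weights[:, jprime]
    cand, w = _neighbor_weights(R.values[i], R.mask[i], w_col, jprime, neighborhood, top_k)
    denom = np.sum(np.abs(w))
    if cand.size == 0 or denom == 0:
        return np.nan
    return float(np.dot(R.values[i, cand], w) / denom)


def _column_means(values: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Observed mean per column; 0 for empty columns."""
    counts = mask.sum(axis=0)
    sums = np.where(mask, values, 0.0).sum(axis=0)
    return np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)


def _complete_with_similarity(
    R: RatingMatrix,
    S: SimilarityMatrix,
    neighborhood: str,
    top_k: Optional[int],
    fallback_values: np.ndarray,
) -> tuple[RatingMatrix, list[tuple[str, str]]]:
    out = R.copy()
    fallback: list[tuple[str, str]] = []
    missing_rows, missing_cols = np.where(~R.mask)
    for i, j in zip(missing_rows, missing_cols):
        pred = ibcf_predict_cell(R, S, i, j, neighborhood=neighborhood, top_k=top_k)
        if not np.isfinite(pred):
            pred = fallback_values[i, j]
            fallback.append((R.row_ids[i], R.col_ids[j]))
        out.values[i, j] = pred
    out.mask = np.ones_like(out.mask)
    if fallback:
        logger.info("%d cells fell back to column means", len(fallback))
    return out, fallback


def ibcf_complete(
    R: RatingMatrix,
    similarity: Optional[SimilarityMatrix] = None,
    method: str = "cosine",
    neighborhood: str = "all",
    top_k: Optional[int] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[RatingMatrix, list[tuple[str, str]]]:
    """Fill every masked cell of R by item-based collaborative filtering.

    Returns the completed matrix (observed cells untouched) and the list of
    (genotype, item) cells that fell back to the column mean because no
    neighbor had a defined weight or the denominator was zero.

    ``similarity`` may be supplied externally (e.g. printed weights or
    precomputed matrices); otherwise it is computed from R with ``method``.
    """
    if R.n_cols < 2:
        raise DimensionError("need at least 2 columns for IBCF")
    if similarity is None:
        similarity = item_similarity_matrix(R, method=method, min_overlap=min_overlap)
    elif similarity.n != R.n_cols:
        raise DimensionError("similarity size does not match column count")
    col_means = _column_means(R.values, R.mask)
    fallback_values = np.broadcast_to(col_means, R.shape)
    return _complete_with_similarity(R, similarity, neighborhood, top_k, fallback_values)


def ubcf_complete(
    R: RatingMatrix,
    user_similarity: Optional[SimilarityMatrix] = None,
    method: str = "cosine",
    neighborhood: str = "all",
    top_k: Optional[int] = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[RatingMatrix, list[tuple[str, str]]]:
    """User-based completion: IBCF on the transposed matrix.

    ``user_similarity`` is typically external — a genomic relationship
    matrix used as a proxy for phenotypic similarity between genotypes —
    and its ids must match ``R.row_ids``; weights are used exactly as
    supplied.  When omitted, user–user weights are computed from R.
    """
    if user_similarity is not None:
        if set(user_similarity.ids) != set(R.row_ids):
            unmatched = sorted(
                set(user_similarity.ids).symmetric_difference(R.row_ids)
            )
            raise AlignmentError(f"genotype ids do not match: {unmatched[:10]}")
        if user_similarity.ids != R.row_ids:
            perm = [user_similarity.ids.index(g) for g in R.row_ids]
            idx = np.asarray(perm)
            user_similarity = SimilarityMatrix(
                list(R.row_ids),
                user_similarity.weights[np.ix_(idx, idx)],
                user_similarity.overlap[np.ix_(idx, idx)],
                user_similarity.method,
            )
    Rt = R.transposed()
    if user_similarity is None:
        user_similarity = item_similarity_matrix(Rt, method=method, min_overlap=min_overlap)
    # fallback stays the *item* training mean: in transposed space that is
    # the mean of the row the cell sits in
    col_means = _column_means(R.values, R.mask)
    fallback_t = np.broadcast_to(col_means[:, None], Rt.shape)
    completed_t, fallback_cells_t = _complete_with_similarity(
        Rt, user_similarity, neighborhood, top_k, fallback_t
    )
    completed = completed_t.transposed()
    fallback = [(g, item) for item, g in fallback_cells_t]
    return completed, fallback
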