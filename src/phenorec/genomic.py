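"""Marker matrices and the genomic relationship matrix (GRM).

Markers are coded −1 / 0 / 1 (homozygous minor, heterozygous, homozygous
major) in a J×p matrix W.  The GRM is the VanRaden-style cross-product
G = WWᵀ/p on the markers as coded; optional column centring by the marker
mean is offered but off by default, matching the uncentred form used as
the between-genotype covariance here.  The GRM doubles as an externally
supplied user–user similarity for user-based collaborative filtering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DimensionError
from .similarity import SimilarityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerMatrix",
    "GRM",
    "vanraden_grm",
    "compound_symmetry_grm",
    "grm_to_user_similarity",
]


@dataclass
class MarkerMatrix:
    """J genotypes × p markers, no missing entries (impute upstream)."""

    genotype_ids: list[str]
    marker_ids: list[str]
    W: np.ndarray

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.shape != (len(self.genotype_ids), len(self.marker_ids)):
            raise DimensionError("marker matrix shape does not match ids")
        if not np.all(np.isfinite(self.W)):
            raise ValueError("marker matrix must have no missing entries")

    def to_csv(self, path) -> None:
        pd.DataFrame(self.W, index=self.genotype_ids, columns=self.marker_ids).to_csv(
            path, index_label="genotype"
        )

    @classmethod
    def from_csv(cls, path) -> "MarkerMatrix":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            df.to_numpy(dtype=float),
        )


@dataclass
class GRM:
    """Symmetric genomic relationship matrix over J genotypes."""

    genotype_ids: list[str]
    G: np.ndarray

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G, dtype=float)
        J = len(self.genotype_ids)
        if self.G.shape != (J, J):
            raise DimensionError("GRM must be square and match ids")
        if not np.allclose(self.G, self.G.T, atol=1e-10):
            raise ValueError("GRM must be symmetric")
        if np.any(np.diag(self.G) < 0):
            raise ValueError("GRM diagonal must be nonnegative")

    @property
    def J(self) -> int:
        return len(self.genotype_ids)

    def to_csv(self, path) -> None:
        pd.DataFrame(self.G, index=self.genotype_ids, columns=self.genotype_ids).to_csv(
            path, index_label="genotype"
        )

    @classmethod
    def from_csv(cls, path) -> "GRM":
        df = pd.read_csv(path, index_col=0, float_precision="round_trip")
        return cls([str(i) for i in df.index], df.to_numpy(dtype=float))


def vanraden_grm(markers: MarkerMatrix, center: bool = False) -> GRM:
    """G = WWᵀ/p on the coded markers (optionally column-centred first)."""
    p = len(markers.marker_ids)
    if p < 1:
        raise ValueError("marker matrix has zero markers")
    W = markers.W - markers.W.mean(axis=0) if center else markers.W
    G = W @ W.T / p
    G = (G + G.T) / 2  # kill round-off asymmetry
    return GRM(list(markers.genotype_ids), G)


def compound_symmetry_grm(
    J: int,
    diag_total: float = 0.7,
    off: float = 0.3,
    genotype_ids: list[str] | None = None,
) -> GRM:
    """G = diag_total·I_J + off·J_J (so diagonal = diag_total + off).

    With the defaults this is the exchangeable relationship structure
    0.7 I + 0.3 J: unit diagonal, 0.3 everywhere else.  Eigenvalues are
    diag_total (J−1 times) and diag_total + J·off; parameters giving a
    negative eigenvalue trigger a warning but the matrix is returned.
    """
    if J < 1:
        raise ValueError("J must be positive")
    min_eig = min(diag_total, diag_total + J * off)
    if min_eig < 0:
        logger.warning(
            "compound-symmetry parameters give min eigenvalue %.4g < 0", min_eig
        )
    G = np.full((J, J), off, dtype=float)
    np.fill_diagonal(G, diag_total + off)
    ids = genotype_ids if genotype_ids is not None else [f"G{j + 1:04d}" for j in range(J)]
    return GRM(list(ids), G)


def grm_to_user_similarity(grm: GRM, normalize: bool = False) -> SimilarityMatrix:
    """Wrap a GRM as an external user–user similarity matrix.

    Entries are used directly as weights by default; ``normalize=True``
    rescales to G_jj′/√(G_jj·G_j′j′), bounding weights in [−1, 1] for a
    PSD matrix.  The diagonal is forced to 1 (self-pairs are excluded from
    neighborhoods anyway) and overlap is set to the full row count.
    """
    W = grm.G.copy()
    if normalize:
        d = np.sqrt(np.diag(grm.G))
        if np.any(d == 0):
            raise ValueError("cannot normalize a GRM with zero diagonal entries")
        W = W / np.outer(d, d)
    np.fill_diagonal(W, 1.0)
    J = grm.J
    return SimilarityMatrix(
        list(grm.genotype_ids), W, np.full((J, J), J, dtype=int), "external"
    )
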