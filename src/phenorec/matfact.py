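"""Regularized matrix factorization of the rating matrix by gradient descent.

The rating matrix R (n genotypes × m items) is approximated by a rank-K
product R ≈ PQᵀ fitted only on observed cells.  For each visited cell the
error e_ij = r_ij − pᵢ·qⱼ drives the stochastic updates

    p_ik ← p_ik + α(2 e_ij q_jk − λ p_ik)
    q_jk ← q_jk + α(2 e_ij p_ik − λ q_jk)

with learning rate α (small; 0.0002 is a safe default on scaled data) and
ridge penalty λ against overfitting.  One epoch sweeps all observed cells
in a seeded-shuffle order; fitting repeats epochs until the monitoring
loss Σ_obs e² + λ(‖P‖²_F + ‖Q‖²_F) stops changing.

Inside prediction pipelines the factorization always runs on the
column-scaled matrix; predictions are unscaled afterwards for reporting.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DimensionError, DivergenceError
from .ratings import RatingMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MFModel",
    "mf_init",
    "mf_epoch",
    "mf_loss",
    "mf_fit",
    "mf_predict",
    "mf_complete",
    "mf_tune",
]

DEFAULT_ALPHA = 0.0002
DEFAULT_MAX_ITER = 5000
DEFAULT_TOL = 1e-6


@dataclass
class MFModel:
    """Fitted factor matrices and the optimisation trace."""

    P: np.ndarray
    Q: np.ndarray
    K: int
    alpha: float
    lamda: float
    loss_trace: list[float] = field(default_factory=list)
    n_iter: int = 0
    seed: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        self.Q = np.asarray(self.Q, dtype=float)
        if self.P.shape[1] != self.K or self.Q.shape[1] != self.K:
            raise DimensionError("P/Q column count must equal K")
        if not (np.all(np.isfinite(self.P)) and np.all(np.isfinite(self.Q))):
            raise ValueError("factor matrices must be finite")

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "K": self.K,
            "alpha": self.alpha,
            "lamda": self.lamda,
            "seed": self.seed,
            "n_iter": self.n_iter,
            "converged": self.converged,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=1))
        pd.DataFrame(self.P).to_csv(d / "P.csv", index=False, float_format="%.17g")
        pd.DataFrame(self.Q).to_csv(d / "Q.csv", index=False, float_format="%.17g")
        pd.DataFrame({"loss": self.loss_trace}).to_csv(
            d / "loss_trace.csv", index=False, float_format="%.17g"
        )

    @classmethod
    def load(cls, directory) -> "MFModel":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        P = pd.read_csv(d / "P.csv", float_precision="round_trip").to_numpy(dtype=float)
        Q = pd.read_csv(d / "Q.csv", float_precision="round_trip").to_numpy(dtype=float)
        trace = pd.read_csv(d / "loss_trace.csv", float_precision="round_trip")["loss"].tolist()
        return cls(P=P, Q=Q, loss_trace=trace, **meta)


def mf_init(
    n: int,
    m: int,
    K: int,
    seed: int = 0,
    init: str = "random",
    base_matrix: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Starting factors: seeded U(0, 0.1) entries, or a rank-K truncated SVD
    of a supplied complete matrix (e.g. an IBCF completion used as warm start)."""
    if K > min(n, m):
        raise DimensionError(f"K={K} exceeds min(n, m)={min(n, m)}")
    if init == "random":
        rng = np.random.default_rng(seed)
        return rng.uniform(0, 0.1, (n, K)), rng.uniform(0, 0.1, (m, K))
    if init == "from_matrix":
        if base_matrix is None:
            raise ValueError("from_matrix init requires base_matrix")
        base = np.asarray(base_matrix, dtype=float)
        if base.shape != (n, m):
            raise DimensionError("base_matrix shape must be (n, m)")
        U, s, Vt = np.linalg.svd(base, full_matrices=False)
        root = np.sqrt(s[:K])
        return U[:, :K] * root, Vt[:K].T * root
    raise ValueError(f"unknown init {init!r}")


def mf_epoch(
    values: np.ndarray,
    mask: np.ndarray,
    P: np.ndarray,
    Q: np.ndarray,
    alpha: float,
    lamda: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One stochastic sweep over the observed cells in shuffled order.

    Updates are sequential and in place on copies of P and Q; the error is
    recomputed at each visited cell, and the q-update uses the pre-update
    p vector (the gradient at the current point).
    """
    P = P.copy()
    Q = Q.copy()
    rows, cols = np.nonzero(mask)
    order = rng.permutation(rows.size)
    for idx in order:
        i, j = rows[idx], cols[idx]
        p = P[i]
        q = Q[j]
        e = values[i, j] - p @ q
        p_old = p.copy()
        P[i] = p + alpha * (2 * e * q - lamda * p)
        Q[j] = q + alpha * (2 * e * p_old - lamda * q)
    if not (np.all(np.isfinite(P)) and np.all(np.isfinite(Q))):
        raise DivergenceError(
            "non-finite factors after epoch; reduce the learning rate alpha"
        )
    return P, Q


def mf_loss(
    values: np.ndarray,
    mask: np.ndarray,
    P: np.ndarray,
    Q: np.ndarray,
    lamda: float,
) -> float:
    """Monitoring loss: observed squared error plus the ridge penalty."""
    resid = values[mask] - (P @ Q.T)[mask]
    return float(resid @ resid + lamda * ((P * P).sum() + (Q * Q).sum()))


def mf_fit(
    R: RatingMatrix,
    K: int,
    alpha: float = DEFAULT_ALPHA,
    lamda: float = 0.0,
    max_iter: int = DEFAULT_MAX_ITER,
    tol: float = DEFAULT_TOL,
    seed: int = 0,
    init: str = "random",
    base_matrix: Optional[np.ndarray] = None,
) -> MFModel:
    """Fit R ≈ PQᵀ by repeated epochs until the loss change falls below tol.

    ``tol`` is a relative change in the monitoring loss between epochs.
    Non-convergence within ``max_iter`` epochs is logged, not raised; a
    non-finite loss raises :class:`DivergenceError`.
    """
    if not R.mask.any():
        raise ValueError("rating matrix has no observed cells")
    values = np.where(R.mask, R.values, 0.0)
    P, Q = mf_init(R.n_rows, R.n_cols, K, seed=seed, init=init, base_matrix=base_matrix)
    rng = np.random.default_rng(seed)
    trace = [mf_loss(values, R.mask, P, Q, lamda)]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        P, Q = mf_epoch(values, R.mask, P, Q, alpha, lamda, rng)
        loss = mf_loss(values, R.mask, P, Q, lamda)
        if not np.isfinite(loss):
            raise DivergenceError(
                f"loss diverged at epoch {it}; reduce the learning rate alpha"
            )
        trace.append(loss)
        prev = trace[-2]
        if abs(prev - loss) <= tol * max(abs(prev), 1e-12):
            converged = True
            break
    if not converged:
        logger.info("mf_fit did not converge in %d epochs (tol=%g)", max_iter, tol)
    return MFModel(
        P=P,
        Q=Q,
        K=K,
        alpha=alpha,
        lamda=lamda,
        loss_trace=trace,
        n_iter=it,
        seed=seed,
        converged=converged,
    )


def mf_predict(model: MFModel, i: int, j: int) -> float:
    """Predicted rating for cell (i, j): dot product of the factor rows."""
    if not (0 <= i < model.P.shape[0] and 0 <= j < model.Q.shape[0]):
        raise IndexError(f"cell ({i}, {j}) out of range")
    return float(model.P[i] @ model.Q[j])


def mf_complete(R: RatingMatrix, model: MFModel) -> RatingMatrix:
    """Fill masked cells with PQᵀ predictions; observed cells untouched."""
    if model.P.shape[0] != R.n_rows or model.Q.shape[0] != R.n_cols:
        raise DimensionError("model dimensions do not match matrix")
    out = R.copy()
    pred = model.P @ model.Q.T
    out.values = np.where(R.mask, R.values, pred)
    out.mask = np.ones_like(R.mask)
    return out


def _holdout_pearson(pred: np.ndarray, obs: np.ndarray) -> float:
    if pred.size < 3 or np.std(pred) == 0 or np.std(obs) == 0:
        return np.nan
    return float(np.corrcoef(pred, obs)[0, 1])


def mf_tune(
    R: RatingMatrix,
    K_grid: Sequence[int],
    lamda_grid: Sequence[float],
    cv_folds: int = 5,
    seed: int = 0,
    holdout_frac: float = 0.2,
    alpha: float = 0.02,
    max_iter: int = 200,
    tol: float = DEFAULT_TOL,
) -> tuple[int, float, pd.DataFrame]:
    """Grid search (K, λ) by held-out Pearson over random cell-mask folds.

    Each fold hides ``holdout_frac`` of the observed cells, refits on the
    rest, and scores the hidden cells; the (K, λ) pair with the highest
    mean correlation wins (ties go to the earlier grid entry).  Folds where
    the correlation is undefined are skipped and logged.
    """
    if not K_grid or not lamda_grid:
        raise ValueError("grids must be non-empty")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(R.mask)
    n_obs = obs_idx.shape[0]
    n_hide = max(1, int(round(holdout_frac * n_obs)))
    folds = []
    for _ in range(cv_folds):
        hide = obs_idx[rng.choice(n_obs, size=n_hide, replace=False)]
        folds.append(hide)
    rows = []
    for K in K_grid:
        for lam in lamda_grid:
            scores = []
            for f, hide in enumerate(folds):
                train_mask = R.mask.copy()
                train_mask[hide[:, 0], hide[:, 1]] = False
                if not train_mask.any():
                    logger.info("fold %d has no training cells; skipped", f)
                    continue
                R_train = RatingMatrix(
                    list(R.row_ids),
                    list(R.col_ids),
                    np.where(train_mask, R.values, np.nan),
                    train_mask,
                )
                model = mf_fit(
                    R_train, K, alpha=alpha, lamda=lam,
                    max_iter=max_iter, tol=tol, seed=seed,
                )
                pred = (model.P @ model.Q.T)[hide[:, 0], hide[:, 1]]
                obs = R.values[hide[:, 0], hide[:, 1]]
                r = _holdout_pearson(pred, obs)
                if np.isfinite(r):
                    scores.append(r)
                else:
                    logger.info("fold %d undefined correlation; skipped", f)
            rows.append(
                {
                    "K": K,
                    "lamda": lam,
                    "mean_pearson": np.mean(scores) if scores else np.nan,
                    "n_folds_used": len(scores),
                }
            )
    table = pd.DataFrame(rows)
    valid = table.dropna(subset=["mean_pearson"])
    if valid.empty:
        raise ValueError("no (K, lamda) pair produced a defined score")
    best = valid.loc[valid["mean_pearson"].idxmax()]
    return int(best["K"]), float(best["lamda"]), table
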