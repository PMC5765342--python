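"""Cross-validation schemes and prediction-accuracy metrics.

Two schemes mirror how breeders would meet missing phenotypes:

* **CV1** — random line-level partitions: a fraction of genotypes (default
  20%, in 20 independent partitions) is designated "new"; each test line
  keeps its observations in a small random subset of environments (default
  one) and is masked everywhere else, mimicking lines phenotyped in some
  environments but missing in the rest.
* **CV2** — forward prediction across years: rows are the lines of the
  target year and of up to ``years_back`` preceding years (no line is
  shared across years), columns are traits, and the target trait of the
  target-year lines is held out.

Accuracy is the per-item average Pearson correlation (APC) between
predicted and observed phenotypes across partitions, with its standard
error; for ranking-based selection, PCL reports the percentage of lines
shared by the predicted and observed top-k sets.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .matfact import mf_complete, mf_fit
from .ratings import (
    PhenotypeRecord,
    RatingMatrix,
    apply_scaler,
    build_rating_matrix,
    fit_column_scaler,
    invert_scaler,
    parse_item_label,
)
from .similarity import SimilarityMatrix, ibcf_complete, ubcf_complete

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "EvaluationReport",
    "cv1_plan",
    "cv2_plan",
    "run_cv",
    "pearson_by_item",
    "pcl_top_k",
]


@dataclass
class CVPlan:
    """Held-out cell masks per partition (True = held out)."""

    scheme: str
    partitions: list[np.ndarray]
    seed: int = 0
    test_frac: float = 0.2
    metadata: dict = field(default_factory=dict)
    rating_matrix: Optional[RatingMatrix] = None

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    def to_json(self, path, R: Optional[RatingMatrix] = None) -> None:
        R = R if R is not None else self.rating_matrix
        if R is None:
            raise ValueError("serializing a plan requires its rating matrix for labels")
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "test_frac": self.test_frac,
            "metadata": self.metadata,
            "partitions": [
                [
                    [R.row_ids[i], R.col_ids[j]]
                    for i, j in zip(*np.where(mask))
                ]
                for mask in self.partitions
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path, R: RatingMatrix) -> "CVPlan":
        with open(path) as fh:
            payload = json.load(fh)
        row_index = {g: i for i, g in enumerate(R.row_ids)}
        col_index = {c: j for j, c in enumerate(R.col_ids)}
        partitions = []
        for cells in payload["partitions"]:
            mask = np.zeros(R.shape, dtype=bool)
            for g, c in cells:
                mask[row_index[g], col_index[c]] = True
            partitions.append(mask)
        return cls(
            scheme=payload["scheme"],
            partitions=partitions,
            seed=payload["seed"],
            test_frac=payload["test_frac"],
            metadata=payload.get("metadata", {}),
        )


@dataclass
class EvaluationReport:
    """Per-item APC and SE over partitions, with optional top-k overlap."""

    table: pd.DataFrame  # columns: item, apc, se, n_partitions_used
    pcl: Optional[float] = None
    pcl_k: Optional[int] = None

    def to_csv(self, path) -> None:
        out = self.table.copy()
        if self.pcl is not None:
            out["pcl"] = self.pcl
            out["pcl_k"] = self.pcl_k
        out.to_csv(path, index=False)


def cv1_plan(
    R: RatingMatrix,
    n_partitions: int = 20,
    test_frac: float = 0.2,
    keep_environments: int = 1,
    seed: int = 0,
) -> CVPlan:
    """Random line-level partitions with per-line environment retention.

    Each partition samples ⌊test_frac·J⌋ test lines without replacement;
    every test line keeps its observed cells in ``keep_environments``
    randomly chosen environments and is held out everywhere else, so each
    test row always retains observed items to predict from.
    """
    envs = R.environments()
    if len(envs) < 2:
        raise ValueError("CV1 requires columns from at least 2 environments")
    if not 1 <= keep_environments < len(envs):
        raise ValueError(
            "keep_environments must be in [1, n_environments); keeping all "
            "environments leaves nothing to predict"
        )
    n_test = int(test_frac * R.n_rows)
    if n_test < 1:
        raise ValueError("test set is empty; increase test_frac or matrix size")
    col_env = np.array([parse_item_label(c)[0] for c in R.col_ids])
    rng = np.random.default_rng(seed)
    partitions = []
    for _ in range(n_partitions):
        mask = np.zeros(R.shape, dtype=bool)
        test_lines = rng.choice(R.n_rows, size=n_test, replace=False)
        for i in test_lines:
            kept = set(rng.choice(envs, size=keep_environments, replace=False))
            hold_cols = ~np.isin(col_env, list(kept))
            mask[i, hold_cols] = R.mask[i, hold_cols]
        if not mask.any():
            raise ValueError("partition holds out no observed cells")
        partitions.append(mask)
    return CVPlan(
        scheme="CV1",
        partitions=partitions,
        seed=seed,
        test_frac=test_frac,
        metadata={"keep_environments": keep_environments},
        rating_matrix=R,
    )


def cv2_plan(
    records: Sequence[PhenotypeRecord],
    target_trait: str,
    target_year: str,
    years_back: int = 2,
) -> CVPlan:
    """Forward-prediction plan: mask one trait for every target-year line.

    Builds a lines × traits rating matrix from the target year and up to
    ``years_back`` preceding years (years ordered by sorted label; lines
    are year-specific) and holds out the target trait of target-year
    lines.  Returns a single-partition plan carrying that matrix.
    """
    years = sorted({r.year for r in records if r.year is not None})
    if target_year not in years:
        raise ValueError(f"target year {target_year!r} not present in records")
    t_idx = years.index(target_year)
    included = set(years[max(0, t_idx - years_back) : t_idx + 1])
    subset = [r for r in records if r.year in included]
    target_lines = {r.genotype for r in subset if r.year == target_year}
    R = build_rating_matrix(subset, layout="by_trait")
    if target_trait not in R.col_ids:
        raise ValueError(f"target trait {target_trait!r} not present in records")
    j = R.col_ids.index(target_trait)
    mask = np.zeros(R.shape, dtype=bool)
    for i, g in enumerate(R.row_ids):
        if g in target_lines:
            mask[i, j] = R.mask[i, j]
    if not mask.any():
        raise ValueError("CV2 plan holds out no observed cells")
    return CVPlan(
        scheme="CV2",
        partitions=[mask],
        metadata={
            "target_trait": target_trait,
            "target_year": target_year,
            "years_back": years_back,
        },
        rating_matrix=R,
    )


def run_cv(
    R: Optional[RatingMatrix],
    plan: CVPlan,
    method: str = "ibcf",
    **method_params,
) -> pd.DataFrame:
    """Scale → complete → unscale per partition; report held-out cells only.

    For every partition the column scaler is fit on training cells alone,
    the scaled matrix is completed with the chosen method (``ibcf``,
    ``ubcf`` or ``mf``), and predictions are mapped back to the original
    trait scale.  Returns a tidy frame with one row per held-out cell:
    partition, genotype, item, y_pred, y_obs.
    """
    if R is None:
        R = plan.rating_matrix
    if R is None:
        raise ValueError("no rating matrix available")
    if not plan.partitions:
        raise ValueError("plan has no partitions")
    rows = []
    for p, held in enumerate(plan.partitions):
        if held.shape != R.shape:
            raise ValueError("partition mask shape does not match matrix")
        if not held.any():
            raise ValueError(f"partition {p} holds out no cells")
        train_mask = R.mask & ~held
        R_train = RatingMatrix(
            list(R.row_ids),
            list(R.col_ids),
            np.where(train_mask, R.values, np.nan),
            train_mask,
        )
        scaler = fit_column_scaler(R_train)
        Rs = apply_scaler(R_train, scaler)
        if method == "ibcf":
            completed, fb = ibcf_complete(Rs, **method_params)
        elif method == "ubcf":
            completed, fb = ubcf_complete(Rs, **method_params)
        elif method == "mf":
            model = mf_fit(Rs, **method_params)
            completed, fb = mf_complete(Rs, model), []
        else:
            raise ValueError(f"unknown method {method!r}")
        if fb and len(fb) == int((~train_mask).sum()):
            logger.warning("partition %d: every prediction fell back", p)
        unscaled = invert_scaler(completed, scaler)
        hi, hj = np.where(held)
        for i, j in zip(hi, hj):
            rows.append(
                {
                    "partition": p,
                    "genotype": R.row_ids[i],
                    "item": R.col_ids[j],
                    "y_pred": unscaled.values[i, j],
                    "y_obs": R.values[i, j],
                }
            )
    return pd.DataFrame(rows)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xd, yd = x - x.mean(), y - y.mean()
    denom = np.linalg.norm(xd) * np.linalg.norm(yd)
    if denom == 0:
        return np.nan
    return float(np.dot(xd, yd) / denom)


def pearson_by_item(results: pd.DataFrame, min_pairs: int = 3) -> EvaluationReport:
    """Per-item average Pearson correlation (APC) and its standard error.

    The correlation is computed per item per partition (requiring at least
    ``min_pairs`` prediction–observation pairs and nonzero variance);
    APC is the mean over partitions, SE the standard deviation of the
    partition correlations divided by √(partitions used).  Items with no
    defined partition are reported with NaN APC.
    """
    rows = []
    for item, g in results.groupby("item", sort=False):
        corrs = []
        for _, part in g.groupby("partition"):
            if len(part) < min_pairs:
                continue
            r = _pearson(part["y_pred"].to_numpy(), part["y_obs"].to_numpy())
            if np.isfinite(r):
                corrs.append(r)
        n_used = len(corrs)
        if n_used:
            apc = float(np.mean(corrs))
            se = float(np.std(corrs, ddof=1) / np.sqrt(n_used)) if n_used > 1 else 0.0
        else:
            apc, se = np.nan, np.nan
            logger.warning("item %s has no partition with a defined correlation", item)
        rows.append({"item": item, "apc": apc, "se": se, "n_partitions_used": n_used})
    return EvaluationReport(table=pd.DataFrame(rows))


def pcl_top_k(
    pred_scores: np.ndarray,
    obs_scores: np.ndarray,
    k: int = 2000,
    largest: bool = True,
) -> float:
    """Percentage of lines common to the predicted and observed top-k sets.

    Scores are ranked best-first (``largest=True`` for traits where more
    is better, e.g. grain yield); ties are broken by stable input order,
    so equal scores favour the earlier line label.
    """
    pred_scores = np.asarray(pred_scores, dtype=float)
    obs_scores = np.asarray(obs_scores, dtype=float)
    n = pred_scores.size
    if obs_scores.size != n:
        raise ValueError("score vectors must have equal length")
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range for {n} lines")
    sign = -1.0 if largest else 1.0
    top_pred = set(np.argsort(sign * pred_scores, kind="stable")[:k])
    top_obs = set(np.argsort(sign * obs_scores, kind="stable")[:k])
    return 100.0 * len(top_pred & top_obs) / k
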