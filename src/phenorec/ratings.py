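"""Genotype × (environment–trait) rating matrices.

Multi-trait, multi-environment (MTME) phenotype records are arranged as a
"rating matrix" in the recommender-system sense: rows are genotypes (users),
columns are environment–trait combinations (items), and unobserved
phenotypes are the missing ratings to be predicted.  Missingness is carried
in an explicit boolean mask, never a sentinel value, because a phenotype of
0 is legitimate data.

Column scaling (centre and divide by the SD of the *training* cells only)
puts all items on a comparable scale before collaborative filtering or
matrix factorization; the scaler is fit on training cells and inverted on
predictions so reported values are on the original trait scale.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConflictError, DimensionError

logger = logging.getLogger(__name__)

__all__ = [
    "PhenotypeRecord",
    "RatingMatrix",
    "ColumnScaler",
    "item_label",
    "parse_item_label",
    "build_rating_matrix",
    "fit_column_scaler",
    "apply_scaler",
    "invert_scaler",
    "read_phenotype_csv",
    "write_phenotype_csv",
]

_ENV_RE = re.compile(r"E\d+$")
_TRAIT_RE = re.compile(r"T\d+$")


@dataclass(frozen=True)
class PhenotypeRecord:
    """One phenotype observation: a genotype scored for one trait in one environment."""

    genotype: str
    environment: str
    trait: str
    value: Optional[float] = None
    year: Optional[str] = None

    def is_observed(self) -> bool:
        return self.value is not None and np.isfinite(self.value)


def item_label(environment: str, trait: str) -> str:
    """Canonical column label ``E{env}_T{trait}`` (environments outer, traits inner).

    Labels that already look like ``E1`` / ``T2`` are reused rather than
    double-prefixed, so both ("1", "2") and ("E1", "T2") map to "E1_T2".
    """
    e = environment if _ENV_RE.fullmatch(environment) else f"E{environment}"
    t = trait if _TRAIT_RE.fullmatch(trait) else f"T{trait}"
    return f"{e}_{t}"


def parse_item_label(label: str) -> tuple[str, str]:
    """Split an item label into its (environment, trait) parts."""
    if "_" not in label:
        raise ValueError(f"item label {label!r} is not of the form 'E*_T*'")
    env, trait = label.split("_", 1)
    return env, trait


@dataclass
class RatingMatrix:
    """A genotypes × items matrix with an explicit observation mask.

    ``values[~mask]`` is NaN by construction; ``mask`` is authoritative.
    """

    row_ids: list[str]
    col_ids: list[str]
    values: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        n, m = len(self.row_ids), len(self.col_ids)
        if self.values.shape != (n, m) or self.mask.shape != (n, m):
            raise DimensionError(
                f"values/mask shape {self.values.shape}/{self.mask.shape} "
                f"does not match ids {n}×{m}"
            )
        if len(set(self.row_ids)) != n:
            raise ConflictError("duplicate row ids")
        if len(set(self.col_ids)) != m:
            raise ConflictError("duplicate column ids")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed cells must be finite")
        self.values = self.values.copy()
        self.values[~self.mask] = np.nan

    @property
    def n_rows(self) -> int:
        return len(self.row_ids)

    @property
    def n_cols(self) -> int:
        return len(self.col_ids)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def copy(self) -> "RatingMatrix":
        return RatingMatrix(
            list(self.row_ids), list(self.col_ids), self.values.copy(), self.mask.copy()
        )

    def transposed(self) -> "RatingMatrix":
        return RatingMatrix(
            list(self.col_ids), list(self.row_ids), self.values.T.copy(), self.mask.T.copy()
        )

    def environments(self) -> list[str]:
        """Distinct environment parts of the column labels, in column order."""
        seen: dict[str, None] = {}
        for c in self.col_ids:
            seen.setdefault(parse_item_label(c)[0])
        return list(seen)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.row_ids, columns=self.col_ids)
        df.index.name = "genotype"
        return df

    def to_csv(self, path) -> None:
        # %.17g round-trips float64 exactly
        self.to_frame().to_csv(path, na_rep="NA", float_format="%.17g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "RatingMatrix":
        values = df.to_numpy(dtype=float)
        return cls(
            [str(i) for i in df.index],
            [str(c) for c in df.columns],
            values,
            np.isfinite(values),
        )

    @classmethod
    def from_csv(cls, path) -> "RatingMatrix":
        df = pd.read_csv(path, index_col=0, na_values=["NA"], keep_default_na=True, float_precision="round_trip")
        return cls.from_frame(df)


@dataclass
class ColumnScaler:
    """Per-column centre/SD fitted on training cells only.

    Columns with fewer than two training observations or zero variance are
    flagged constant: their SD is treated as 1 so scaling degenerates to
    centring and prediction can still proceed.
    """

    means: np.ndarray
    sds: np.ndarray
    constant_flags: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.constant_flags is None:
            self.constant_flags = np.zeros_like(self.means, dtype=bool)
        self.constant_flags = np.asarray(self.constant_flags, dtype=bool)
        if not (len(self.means) == len(self.sds) == len(self.constant_flags)):
            raise DimensionError("scaler component lengths differ")
        if np.any(self.sds[~self.constant_flags] <= 0):
            raise ValueError("sds must be positive where not flagged constant")

    @property
    def n_cols(self) -> int:
        return len(self.means)


def build_rating_matrix(
    records: Iterable[PhenotypeRecord],
    layout: str = "mtme",
) -> RatingMatrix:
    """Arrange long-format phenotype records as a rating matrix.

    Parameters
    ----------
    records
        Phenotype observations.  Records with missing values contribute
        their row/column labels but leave the cell masked.
    layout
        ``"mtme"`` — one column per (environment, trait) pair labelled
        ``E{env}_T{trait}``, environments outer and traits inner (the layout
        the completion methods expect); ``"by_trait"`` — one column per
        trait; ``"by_environment"`` — one column per environment.

    Raises
    ------
    ValueError
        If ``records`` is empty or the layout is unknown.
    ConflictError
        If two records map to the same (genotype, item) cell.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a rating matrix from an empty record set")
    if layout not in ("mtme", "by_trait", "by_environment"):
        raise ValueError(f"unknown layout {layout!r}")

    row_ids: dict[str, None] = {}
    envs: dict[str, None] = {}
    traits: dict[str, None] = {}
    for r in records:
        row_ids.setdefault(r.genotype)
        envs.setdefault(r.environment)
        traits.setdefault(r.trait)

    if layout == "mtme":
        col_ids = [item_label(e, t) for e in envs for t in traits]

        def col_of(r: PhenotypeRecord) -> str:
            return item_label(r.environment, r.trait)

    elif layout == "by_trait":
        col_ids = list(traits)

        def col_of(r: PhenotypeRecord) -> str:
            return r.trait

    else:
        col_ids = list(envs)

        def col_of(r: PhenotypeRecord) -> str:
            return r.environment

    row_index = {g: i for i, g in enumerate(row_ids)}
    col_index = {c: j for j, c in enumerate(col_ids)}
    n, m = len(row_index), len(col_index)
    values = np.full((n, m), np.nan)
    mask = np.zeros((n, m), dtype=bool)
    seen: set[tuple[str, str]] = set()
    for r in records:
        key = (r.genotype, col_of(r))
        if key in seen:
            raise ConflictError(f"duplicate record for genotype/item pair {key}")
        seen.add(key)
        if r.is_observed():
            i, j = row_index[r.genotype], col_index[col_of(r)]
            values[i, j] = r.value
            mask[i, j] = True
    return RatingMatrix(list(row_index), list(col_index), values, mask)


def fit_column_scaler(
    R: RatingMatrix, train_mask: Optional[np.ndarray] = None
) -> ColumnScaler:
    """Fit per-column mean/SD on training-observed cells only.

    ``train_mask`` defaults to ``R.mask`` (all observed cells are training).
    It must be a subset of the observation mask: statistics never touch
    held-out or missing cells, which is what keeps cross-validation honest.
    """
    if train_mask is None:
        train_mask = R.mask
    train_mask = np.asarray(train_mask, dtype=bool)
    if train_mask.shape != R.mask.shape:
        raise DimensionError("train_mask shape does not match matrix")
    if np.any(train_mask & ~R.mask):
        raise ValueError("train_mask marks cells that are not observed")

    m = R.n_cols
    means = np.zeros(m)
    sds = np.ones(m)
    flags = np.zeros(m, dtype=bool)
    for j in range(m):
        obs = R.values[train_mask[:, j], j]
        if obs.size == 0:
            flags[j] = True
            logger.warning("column %s has no training cells; not scaled", R.col_ids[j])
            continue
        means[j] = obs.mean()
        if obs.size < 2:
            flags[j] = True
            logger.warning("column %s has <2 training cells; sd treated as 1", R.col_ids[j])
            continue
        sd = obs.std(ddof=1)
        if sd == 0:
            flags[j] = True
            logger.warning("column %s is constant in training; sd treated as 1", R.col_ids[j])
        else:
            sds[j] = sd
    return ColumnScaler(means, sds, flags)


def _check_scaler(R: RatingMatrix, scaler: ColumnScaler) -> None:
    if scaler.n_cols != R.n_cols:
        raise DimensionError(
            f"scaler has {scaler.n_cols} columns, matrix has {R.n_cols}"
        )


def apply_scaler(R: RatingMatrix, scaler: ColumnScaler) -> RatingMatrix:
    """Transform observed cells to (value − mean) / sd; the mask is unchanged."""
    _check_scaler(R, scaler)
    out = R.copy()
    out.values = (out.values - scaler.means) / scaler.sds
    out.values[~out.mask] = np.nan
    return out


def invert_scaler(R_scaled: RatingMatrix, scaler: ColumnScaler) -> RatingMatrix:
    """Undo :func:`apply_scaler`: value · sd + mean on observed cells."""
    _check_scaler(R_scaled, scaler)
    out = R_scaled.copy()
    out.values = out.values * scaler.sds + scaler.means
    out.values[~out.mask] = np.nan
    return out


def read_phenotype_csv(path) -> list[PhenotypeRecord]:
    """Read long-format records from CSV (genotype, environment, trait, value[, year])."""
    df = pd.read_csv(path, dtype={"genotype": str, "environment": str, "trait": str}, float_precision="round_trip")
    required = {"genotype", "environment", "trait", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"phenotype CSV is missing columns: {sorted(missing)}")
    has_year = "year" in df.columns
    records = []
    for row in df.itertuples(index=False):
        value = None if pd.isna(row.value) else float(row.value)
        year = str(row.year) if has_year and not pd.isna(row.year) else None
        records.append(
            PhenotypeRecord(
                genotype=str(row.genotype),
                environment=str(row.environment),
                trait=str(row.trait),
                value=value,
                year=year,
            )
        )
    return records


def write_phenotype_csv(records: Sequence[PhenotypeRecord], path) -> None:
    """Write long-format records to CSV, omitting the year column if unused."""
    rows = [
        {
            "genotype": r.genotype,
            "environment": r.environment,
            "trait": r.trait,
            "value": r.value if r.is_observed() else None,
            "year": r.year,
        }
        for r in records
    ]
    df = pd.DataFrame(rows)
    if df["year"].isna().all():
        df = df.drop(columns=["year"])
    df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
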