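"""Forward simulation of multi-trait multi-environment (MTME) phenotypes.

Phenotypes for I environments × J genotypes × L traits are drawn from the
linear mixed model

    y_ijl = β_il + b1_jl + b2_ijl + e_ijl

where β holds the fixed environment–trait means, the genotype×trait
effects b1 have covariance Gg ⊗ Σt (Gg a genomic relationship matrix, Σt
the genetic between-trait covariance), the three-way genotype×environment
×trait effects b2 have covariance ΣE ⊗ Gg ⊗ Σt, and the residual rows
e_ij· are i.i.d. N(0, Re).  All Kronecker-structured draws apply the
per-factor Cholesky roots to a standard-normal tensor, so the full
(I·J·L)² covariance is never materialised.

Three preset covariance triples (Σt, ΣE, Re) induce pairwise trait and
environment correlations of 0.85, 0.5, and 0.25 — high, medium and low
information sharing between items.  Besides Gaussian errors (scenario
S1), scenarios S2 and S3 replace each error draw e with exp(−c·|e|) and
exp(+c·|e|) (c = 1.25 by default), producing negatively and positively
skewed data from the *same* underlying normal draws as S1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .genomic import GRM, compound_symmetry_grm
from .ratings import PhenotypeRecord

__all__ = [
    "MTMESimConfig",
    "SimOutput",
    "preset_config",
    "implied_correlations",
    "kron3_mvn_sample",
    "skew_transform",
    "simulate_mtme",
]

DEFAULT_SKEW_FACTOR = 1.25

# Preset (beta, Sigma_t, Sigma_E, Re) triples.  The printed set-1 ΣE and Re
# are asymmetric in their 4th decimal (truncation); off-diagonals are
# symmetrised by averaging.
_BETA = [15.0, 8.0, 7.0, 12.0, 6.0, 7.0, 14.0, 9.0, 8.0]

_PRESETS = {
    1: {
        "Sigma_t": [[0.900, 0.721, 0.765],
                    [0.721, 0.800, 0.721],
                    [0.765, 0.721, 0.900]],
        "Sigma_E": [[0.5000, 0.4846, 0.5205],
                    [0.4846, 0.6500, 0.59345],
                    [0.5205, 0.59345, 0.7500]],
        "Re": [[0.450, 0.3695, 0.32755],
               [0.3695, 0.4200, 0.3164],
               [0.32755, 0.3164, 0.330]],
    },
    2: {
        "Sigma_t": [[0.900, 0.424, 0.450],
                    [0.424, 0.800, 0.424],
                    [0.450, 0.424, 0.900]],
        "Sigma_E": [[0.5000, 0.2850, 0.30605],
                    [0.2850, 0.6500, 0.3490],
                    [0.30605, 0.3490, 0.7500]],
        "Re": [[0.450, 0.217, 0.193],
               [0.217, 0.4200, 0.186],
               [0.193, 0.186, 0.330]],
    },
    3: {
        "Sigma_t": [[0.900, 0.212, 0.225],
                    [0.212, 0.800, 0.212],
                    [0.225, 0.212, 0.900]],
        "Sigma_E": [[0.5000, 0.1425, 0.1531],
                    [0.1425, 0.6500, 0.1745],
                    [0.1531, 0.1745, 0.7500]],
        "Re": [[0.450, 0.1086, 0.0963],
               [0.1086, 0.4200, 0.0931],
               [0.0963, 0.0931, 0.330]],
    },
}

_SCENARIOS = ("S1", "S2", "S3")


def _as_psd(name: str, A) -> np.ndarray:
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    eigs = np.linalg.eigvalsh(A)
    if eigs.min() < -1e-8 * max(np.trace(A), 1.0):
        raise ValueError(f"{name} is not positive semidefinite (min eig {eigs.min():.3g})")
    return A


@dataclass
class MTMESimConfig:
    """Parameters of the MTME sampler.

    beta is laid out environment-outer, trait-inner (β_11…β_1L, β_21…),
    matching the rating-matrix column order.
    """

    I: int
    J: int
    L: int
    beta: np.ndarray
    Sigma_t: np.ndarray
    Sigma_E: np.ndarray
    Re: np.ndarray
    Gg: GRM
    scenario: str = "S1"
    skew_factor: float = DEFAULT_SKEW_FACTOR
    n_reps: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.I * self.L,):
            raise ValueError(f"beta must have length I·L = {self.I * self.L}")
        self.Sigma_t = _as_psd("Sigma_t", self.Sigma_t)
        self.Sigma_E = _as_psd("Sigma_E", self.Sigma_E)
        self.Re = _as_psd("Re", self.Re)
        if self.Sigma_t.shape[0] != self.L or self.Re.shape[0] != self.L:
            raise ValueError("Sigma_t and Re must be L×L")
        if self.Sigma_E.shape[0] != self.I:
            raise ValueError("Sigma_E must be I×I")
        if self.Gg.J != self.J:
            raise ValueError("Gg size must equal J")
        if self.scenario not in _SCENARIOS:
            raise ValueError(f"scenario must be one of {_SCENARIOS}")
        if self.skew_factor <= 0:
            raise ValueError("skew_factor must be positive")
        if self.n_reps != 1:
            raise ValueError("only one replicate per cell is supported")

    def to_dict(self) -> dict:
        return {
            "I": self.I,
            "J": self.J,
            "L": self.L,
            "beta": self.beta.tolist(),
            "Sigma_t": self.Sigma_t.tolist(),
            "Sigma_E": self.Sigma_E.tolist(),
            "Re": self.Re.tolist(),
            "Gg": self.Gg.G.tolist(),
            "genotype_ids": list(self.Gg.genotype_ids),
            "scenario": self.scenario,
            "skew_factor": self.skew_factor,
            "n_reps": self.n_reps,
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh)

    @classmethod
    def from_dict(cls, d: dict) -> "MTMESimConfig":
        gg = GRM(list(d["genotype_ids"]), np.asarray(d["Gg"], dtype=float))
        return cls(
            I=d["I"], J=d["J"], L=d["L"], beta=d["beta"],
            Sigma_t=d["Sigma_t"], Sigma_E=d["Sigma_E"], Re=d["Re"],
            Gg=gg, scenario=d.get("scenario", "S1"),
            skew_factor=d.get("skew_factor", DEFAULT_SKEW_FACTOR),
            n_reps=d.get("n_reps", 1), seed=d.get("seed", 0),
        )

    @classmethod
    def from_yaml(cls, path) -> "MTMESimConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class SimOutput:
    """Simulated records plus the per-record effect decomposition."""

    records: list[PhenotypeRecord]
    components: Optional[pd.DataFrame] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "genotype": [r.genotype for r in self.records],
                "environment": [r.environment for r in self.records],
                "trait": [r.trait for r in self.records],
                "value": [r.value for r in self.records],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def preset_config(
    set_id: int, scenario: str = "S1", J: int = 1000, seed: int = 0
) -> MTMESimConfig:
    """The three study covariance sets (pairwise correlations 0.85/0.5/0.25).

    I = L = 3; β = (15, 8, 7, 12, 6, 7, 14, 9, 8); Gg is the exchangeable
    0.7 I_J + 0.3 J_J relationship matrix, J defaulting to 1000.
    """
    if set_id not in _PRESETS:
        raise ValueError(f"set_id must be one of {sorted(_PRESETS)}")
    p = _PRESETS[set_id]
    return MTMESimConfig(
        I=3, J=J, L=3, beta=_BETA,
        Sigma_t=p["Sigma_t"], Sigma_E=p["Sigma_E"], Re=p["Re"],
        Gg=compound_symmetry_grm(J, 0.7, 0.3),
        scenario=scenario, seed=seed,
    )


def cov_to_corr(S: np.ndarray) -> np.ndarray:
    """Correlation matrix implied by a covariance matrix."""
    d = np.sqrt(np.diag(S))
    if np.any(d == 0):
        raise ValueError("covariance has a zero diagonal entry")
    return S / np.outer(d, d)


def implied_correlations(config: MTMESimConfig) -> tuple[np.ndarray, np.ndarray]:
    """(trait correlation, environment correlation) implied by Σt and ΣE."""
    return cov_to_corr(config.Sigma_t), cov_to_corr(config.Sigma_E)


def _cholesky_psd(A: np.ndarray) -> np.ndarray:
    """Cholesky root with a trace-scaled jitter retry for semidefinite inputs."""
    A = np.asarray(A, dtype=float)
    try:
        return np.linalg.cholesky(A)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * max(np.trace(A), 1.0)
        try:
            return np.linalg.cholesky(A + jitter * np.eye(A.shape[0]))
        except np.linalg.LinAlgError as exc:
            raise ValueError("covariance factorization failed even with jitter") from exc


def kron3_mvn_sample(
    A: np.ndarray, B: np.ndarray, C: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """One draw from N(0, A ⊗ B ⊗ C) of length n_a·n_b·n_c.

    The three Cholesky roots are applied along the axes of a standard-
    normal tensor; with row-major flattening (a outer, c inner) the
    resulting vector has exactly the Kronecker covariance.
    """
    La, Lb, Lc = _cholesky_psd(A), _cholesky_psd(B), _cholesky_psd(C)
    Z = rng.standard_normal((La.shape[0], Lb.shape[0], Lc.shape[0]))
    X = np.einsum("ai,bj,ck,ijk->abc", La, Lb, Lc, Z, optimize=True)
    return X.ravel()


def skew_transform(
    e: np.ndarray | float, direction: str, factor: float = DEFAULT_SKEW_FACTOR
) -> np.ndarray | float:
    """exp(∓factor·|e|): negative direction maps into (0, 1], positive into [1, ∞)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    if direction == "negative":
        return np.exp(-factor * np.abs(e))
    if direction == "positive":
        return np.exp(factor * np.abs(e))
    raise ValueError(f"direction must be 'negative' or 'positive', got {direction!r}")


def simulate_mtme(config: MTMESimConfig) -> SimOutput:
    """Draw one MTME data set (I·J·L records) from the configured model.

    All randomness flows from one generator seeded with ``config.seed``;
    component draws are ordered (b1, b2, e) so the three error scenarios
    share identical underlying draws at the same seed.
    """
    I, J, L = config.I, config.J, config.L
    rng = np.random.default_rng(config.seed)

    Lg = _cholesky_psd(config.Gg.G)
    Lt = _cholesky_psd(config.Sigma_t)
    Le = _cholesky_psd(config.Re)

    # b1 ~ N(0, Gg ⊗ Σt): J×L matrix-normal draw
    b1 = Lg @ rng.standard_normal((J, L)) @ Lt.T
    # b2 ~ N(0, ΣE ⊗ Gg ⊗ Σt)
    b2 = kron3_mvn_sample(config.Sigma_E, config.Gg.G, config.Sigma_t, rng).reshape(I, J, L)
    # e rows ~ N(0, Re), i.i.d. over (environment, genotype)
    e_norm = np.einsum("ijl,kl->ijk", rng.standard_normal((I, J, L)), Le)

    if config.scenario == "S1":
        err = e_norm
    elif config.scenario == "S2":
        err = skew_transform(e_norm, "negative", config.skew_factor)
    else:
        err = skew_transform(e_norm, "positive", config.skew_factor)

    beta_grid = config.beta.reshape(I, L)
    fixed = np.broadcast_to(beta_grid[:, None, :], (I, J, L))
    genetic = np.broadcast_to(b1[None, :, :], (I, J, L))
    Y = fixed + genetic + b2 + err

    genotype_ids = list(config.Gg.genotype_ids)
    env_ids = [f"E{i + 1}" for i in range(I)]
    trait_ids = [f"T{l + 1}" for l in range(L)]

    records = [
        PhenotypeRecord(
            genotype=genotype_ids[j],
            environment=env_ids[i],
            trait=trait_ids[l],
            value=float(Y[i, j, l]),
        )
        for i in range(I)
        for j in range(J)
        for l in range(L)
    ]
    components = pd.DataFrame(
        {
            "genotype": [r.genotype for r in records],
            "environment": [r.environment for r in records],
            "trait": [r.trait for r in records],
            "fixed": fixed.ravel(),
            "genetic": genetic.ravel(),
            "interaction": b2.ravel(),
            "error": err.ravel(),
        }
    )
    return SimOutput(records=records, components=components)
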