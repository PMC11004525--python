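"""Seeded synthetic cohorts emulating the dual-phase CT feature layout.

Real cohorts of this kind are private; the generator produces feature tables
with the same block structure (inspiratory/expiratory CNN and radiomics
blocks), a fixed stable/exacerbation split, a planted set of class-informative
columns spread across all four blocks, and a small set of high-effect
"risk-factor" columns.  Feature distributions are class-conditional Gaussians
with common variance and independent columns, the simplest structure under
which Lasso and GLM recovery behave predictably.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

from .feature_table import BLOCK_IDS, FeatureTable


class CohortConfigError(ValueError):
    """Raised when a cohort configuration violates its invariants."""


#: block sizes matching the original study's feature extraction
PAPER_BLOCK_DIMS = {"IN_CNN": 13824, "EX_CNN": 13824, "IN_RAD": 1785, "EX_RAD": 1785}
#: scaled-down layout for desk-scale experiments
DESK_BLOCK_DIMS = {"IN_CNN": 256, "EX_CNN": 256, "IN_RAD": 64, "EX_RAD": 64}


@dataclass
class CohortConfig:
    """Generator settings.

    ``effect_size`` and ``risk_effect_size`` are standardized mean differences
    (Cohen's d): the between-class mean gap of a planted column equals
    ``effect_size * noise_sd`` at common within-class SD ``noise_sd``.
    """

    n_patients: int = 200
    n_exacerbation: int = 70
    block_dims: Dict[str, int] = field(default_factory=lambda: dict(DESK_BLOCK_DIMS))
    n_informative_per_block: Dict[str, int] = field(
        default_factory=lambda: {b: 8 for b in BLOCK_IDS}
    )
    effect_size: float = 1.0
    n_risk_factor_features: int = 3
    risk_effect_size: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.n_exacerbation < self.n_patients:
            raise CohortConfigError(
                "n_exacerbation must satisfy 0 < n_exacerbation < n_patients "
                f"(got {self.n_exacerbation} of {self.n_patients})"
            )
        for name in ("effect_size", "risk_effect_size", "noise_sd"):
            if getattr(self, name) < 0:
                raise CohortConfigError(f"{name} must be >= 0")
        if set(self.block_dims) != set(BLOCK_IDS):
            raise CohortConfigError(
                f"block_dims must have exactly the keys {BLOCK_IDS}"
            )
        for b, d in self.block_dims.items():
            if d < 0:
                raise CohortConfigError(f"block_dims[{b!r}] must be >= 0")
        for b, d in self.n_informative_per_block.items():
            if b not in BLOCK_IDS:
                raise CohortConfigError(f"n_informative_per_block: unknown block {b!r}")
            if d < 0 or d > self.block_dims[b]:
                raise CohortConfigError(
                    f"n_informative_per_block[{b!r}]={d} must be in "
                    f"[0, block_dims[{b!r}]={self.block_dims[b]}]"
                )
        n_inf = sum(self.n_informative_per_block.values())
        if self.n_risk_factor_features < 0 or self.n_risk_factor_features > n_inf:
            raise CohortConfigError(
                "n_risk_factor_features must be between 0 and the total number "
                f"of informative columns ({n_inf})"
            )


def paper_scale_config(seed: int = 0, **overrides) -> CohortConfig:
    """Preset matching the study cohort: 202 patients (70 exacerbation) with
    13,824 + 13,824 + 1,785 + 1,785 = 31,218 features."""
    kw = dict(
        n_patients=202,
        n_exacerbation=70,
        block_dims=dict(PAPER_BLOCK_DIMS),
        seed=seed,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


def desk_scale_config(seed: int = 0, **overrides) -> CohortConfig:
    """Scaled-down preset (200 patients, 640 features) for fast experiments."""
    kw = dict(
        n_patients=200,
        n_exacerbation=70,
        block_dims=dict(DESK_BLOCK_DIMS),
        seed=seed,
    )
    kw.update(overrides)
    return CohortConfig(**kw)


@dataclass
class GroundTruth:
    """Planted-signal bookkeeping for recovery experiments."""

    informative_indices: Dict[str, np.ndarray]  # per block, global column indices
    risk_factor_indices: np.ndarray             # global column indices
    class_means: Dict[int, tuple]               # column -> (mean class 0, mean class 1)

    @property
    def all_informative(self) -> np.ndarray:
        parts = [v for v in self.informative_indices.values() if len(v)]
        return np.sort(np.concatenate(parts)) if parts else np.array([], dtype=int)


def generate_cohort(config: CohortConfig):
    """Draw one cohort.

    Returns ``(FeatureTable, GroundTruth)``.  Bit-for-bit reproducible for a
    given config+seed.  Labels contain exactly ``n_exacerbation`` ones; the
    label vector is a seeded permutation so class membership is not tied to
    row position.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    dims = [config.block_dims[b] for b in BLOCK_IDS]
    p = int(np.sum(dims))

    labels = np.zeros(n, dtype=int)
    labels[rng.choice(n, size=config.n_exacerbation, replace=False)] = 1

    values = rng.normal(0.0, config.noise_sd, size=(n, p))

    offsets = np.concatenate([[0], np.cumsum(dims)])
    informative: Dict[str, np.ndarray] = {}
    for b, off, d in zip(BLOCK_IDS, offsets[:-1], dims):
        k = config.n_informative_per_block.get(b, 0)
        cols = off + rng.choice(d, size=k, replace=False) if k else np.array([], dtype=int)
        informative[b] = np.sort(cols)

    # risk-factor columns: a round-robin pick across blocks from the planted set,
    # so risk factors exist in several phases by default
    pool: List[int] = []
    per_block = [list(informative[b]) for b in BLOCK_IDS]
    while any(per_block) and len(pool) < config.n_risk_factor_features:
        for blk in per_block:
            if blk and len(pool) < config.n_risk_factor_features:
                pool.append(blk.pop(0))
    risk_cols = np.sort(np.array(pool, dtype=int))

    class_means = {}
    for col in np.concatenate([informative[b] for b in BLOCK_IDS]).astype(int):
        d_eff = (
            config.risk_effect_size if col in risk_cols else config.effect_size
        )
        delta = d_eff * config.noise_sd
        mu0, mu1 = -delta / 2.0, delta / 2.0
        values[:, col] += np.where(labels == 1, mu1, mu0)
        class_means[int(col)] = (mu0, mu1)

    column_blocks = np.concatenate(
        [np.full(d, b, dtype=object) for b, d in zip(BLOCK_IDS, dims)]
    )
    width = max(6, len(str(p)))
    column_ids = [
        f"{b}_{i:0{width}d}"
        for b, off, d in zip(BLOCK_IDS, offsets[:-1], dims)
        for i in range(d)
    ]
    patient_ids = [f"P{i:04d}" for i in range(n)]

    table = FeatureTable(
        values=values,
        column_blocks=column_blocks,
        column_ids=column_ids,
        labels=labels,
        patient_ids=patient_ids,
    )
    truth = GroundTruth(
        informative_indices=informative,
        risk_factor_indices=risk_cols,
        class_means=class_means,
    )
    return table, truth
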