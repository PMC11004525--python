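"""Block-annotated patient feature tables and phase-variant assembly.

A cohort is stored as a patients x features matrix in which every column
belongs to one of four blocks: CNN or radiomics descriptors extracted from
the inspiratory (IN) or expiratory (EX) CT phase.  The seven "phase variant"
feature sets combine these blocks, optionally passing them through Lasso
selection fitted on training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

BLOCK_IDS = ("IN_CNN", "EX_CNN", "IN_RAD", "EX_RAD")

#: the seven phase-variant names
PHASE_VARIANTS = (
    "EX",
    "IN",
    "EX+IN",
    "EX_lasso",
    "IN_lasso",
    "EX_lasso+IN_lasso",
    "(EX+IN)_lasso",
)

EXTRACTOR_SETS = ("CNN", "RAD", "CNN+RAD")


class FeatureTableError(ValueError):
    """Raised on malformed tables or table files."""


@dataclass
class FeatureTable:
    """Patients x features matrix with per-column block annotation.

    Attributes
    ----------
    values : (n_patients, n_features) float array, no missing values.
    column_blocks : per-column block id, one of :data:`BLOCK_IDS`.
    column_ids : unique column names; by convention ``<BLOCK>_<index>``.
    labels : per-patient binary outcome (0 = stable, 1 = exacerbation).
    patient_ids : unique patient identifiers.
    """

    values: np.ndarray
    column_blocks: np.ndarray
    column_ids: list = field(default_factory=list)
    labels: np.ndarray = None
    patient_ids: list = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.column_blocks = np.asarray(self.column_blocks, dtype=object)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise FeatureTableError("values must be a 2-D matrix")
        n, p = self.values.shape
        if len(self.column_blocks) != p or len(self.column_ids) != p:
            raise FeatureTableError(
                "column_blocks/column_ids length must equal the number of columns"
            )
        bad = set(self.column_blocks) - set(BLOCK_IDS)
        if bad:
            raise FeatureTableError(f"unknown block ids: {sorted(bad)}")
        if len(set(self.column_ids)) != p:
            raise FeatureTableError("duplicate column ids")
        if len(self.labels) != n:
            raise FeatureTableError("labels length must equal the number of rows")
        if not np.isin(self.labels, (0, 1)).all():
            raise FeatureTableError("labels must be binary (0=stable, 1=exacerbation)")
        if len(self.patient_ids) != n or len(set(self.patient_ids)) != n:
            raise FeatureTableError("patient_ids must be unique, one per row")
        if not np.isfinite(self.values).all():
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FeatureTableError(
                f"non-finite value at row {i} (patient {self.patient_ids[i]}), "
                f"column {j} ({self.column_ids[j]})"
            )

    @property
    def n_patients(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def block_columns(self, block_id: str) -> np.ndarray:
        """0-based column indices belonging to one block."""
        if block_id not in BLOCK_IDS:
            raise FeatureTableError(f"unknown block id {block_id!r}")
        return np.flatnonzero(self.column_blocks == block_id)


def _block_of(column_name: str) -> str:
    """Block id encoded as the first two underscore tokens of a column name."""
    parts = column_name.split("_")
    if len(parts) >= 2 and "_".join(parts[:2]) in BLOCK_IDS:
        return "_".join(parts[:2])
    raise FeatureTableError(
        f"column {column_name!r} has an unknown block prefix "
        f"(expected one of {BLOCK_IDS})"
    )


def save_table(table: FeatureTable, path) -> None:
    """Write a table as comma-delimited UTF-8 text.

    Layout: header row; first column ``patient_id``, second ``label``, then
    one column per feature named by its column id.  Floats are printed with
    17 significant digits so that load(save(t)) is exact.
    """
    df = pd.DataFrame(table.values, columns=table.column_ids)
    df.insert(0, "label", table.labels)
    df.insert(0, "patient_id", table.patient_ids)
    df.to_csv(path, index=False, float_format="%.17g")


def load_table(path) -> FeatureTable:
    """Read a table written by :func:`save_table`, validating the schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    if list(df.columns[:2]) != ["patient_id", "label"]:
        raise FeatureTableError(
            "first two columns must be 'patient_id' and 'label'"
        )
    feature_cols = list(df.columns[2:])
    blocks = [_block_of(c) for c in feature_cols]
    values = df[feature_cols].to_numpy(dtype=float)
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FeatureTableError(
            f"missing value at row {i} (patient {df['patient_id'].iloc[i]}), "
            f"column {feature_cols[j]!r}"
        )
    return FeatureTable(
        values=values,
        column_blocks=np.array(blocks, dtype=object),
        column_ids=feature_cols,
        labels=df["label"].to_numpy(),
        patient_ids=[str(p) for p in df["patient_id"].tolist()],
    )


@dataclass
class PhaseVariant:
    """One of the seven phase-variant feature-set definitions."""

    name: str
    extractor_set: str = "CNN+RAD"

    def __post_init__(self):
        if self.name not in PHASE_VARIANTS:
            raise FeatureTableError(
                f"unknown phase variant {self.name!r}; valid names: "
                + ", ".join(PHASE_VARIANTS)
            )
        if self.extractor_set not in EXTRACTOR_SETS:
            raise FeatureTableError(
                f"unknown extractor set {self.extractor_set!r}; valid: "
                + ", ".join(EXTRACTOR_SETS)
            )

    @property
    def uses_lasso(self) -> bool:
        return "lasso" in self.name


def _phase_block_ids(phase: str, extractor_set: str) -> list:
    extractors = ("CNN", "RAD") if extractor_set == "CNN+RAD" else (extractor_set,)
    return [f"{phase}_{e}" for e in extractors]


def phase_columns(table: FeatureTable, phase: str, extractor_set: str) -> np.ndarray:
    """Column indices of one phase (EX or IN) under an extractor set.

    Order is the table's column order, so concatenations are reproducible.
    """
    wanted = set(_phase_block_ids(phase, extractor_set))
    return np.flatnonzero(np.isin(table.column_blocks, list(wanted)))


@dataclass
class PhaseVariantResult:
    """Variant feature matrix over all patients plus selection bookkeeping."""

    matrix: np.ndarray           # all rows x variant columns
    column_indices: np.ndarray   # original table column indices
    selection: object = None     # SelectionResult (or None for unselected variants)


def apply_phase_variant(
    table: FeatureTable,
    variant: PhaseVariant,
    selector: Optional[Callable] = None,
    train_rows: Optional[Sequence[int]] = None,
) -> PhaseVariantResult:
    """Assemble one phase-variant feature set.

    ``selector`` is a callable ``(X_train, y_train) -> SelectionResult`` used by
    the ``*_lasso`` variants; it is fitted on ``train_rows`` only (all rows when
    ``train_rows`` is None, which reproduces the original study's fit-on-all
    behaviour) and the resulting column subset is applied to every row.
    """
    ex_cols = phase_columns(table, "EX", variant.extractor_set)
    in_cols = phase_columns(table, "IN", variant.extractor_set)
    rows = (
        np.arange(table.n_patients)
        if train_rows is None
        else np.asarray(train_rows, dtype=int)
    )
    if variant.uses_lasso:
        if selector is None:
            raise FeatureTableError(f"variant {variant.name} requires a selector")
        if rows.size == 0:
            raise FeatureTableError("train_rows must be nonempty for lasso variants")
        if len(np.unique(table.labels[rows])) < 2:
            raise FeatureTableError(
                "training rows contain a single class; selection is undefined"
            )

    def _select(cols: np.ndarray):
        sel = selector(table.values[np.ix_(rows, cols)], table.labels[rows])
        return cols[sel.selected_indices], sel

    if variant.name == "EX":
        return PhaseVariantResult(table.values[:, ex_cols], ex_cols)
    if variant.name == "IN":
        return PhaseVariantResult(table.values[:, in_cols], in_cols)
    if variant.name == "EX+IN":
        cols = np.concatenate([ex_cols, in_cols])
        return PhaseVariantResult(table.values[:, cols], cols)
    if variant.name == "EX_lasso":
        cols, sel = _select(ex_cols)
        return PhaseVariantResult(table.values[:, cols], cols, sel)
    if variant.name == "IN_lasso":
        cols, sel = _select(in_cols)
        return PhaseVariantResult(table.values[:, cols], cols, sel)
    if variant.name == "EX_lasso+IN_lasso":
        ex_sel_cols, _ = _select(ex_cols)
        in_sel_cols, _ = _select(in_cols)
        cols = np.concatenate([ex_sel_cols, in_sel_cols])
        return PhaseVariantResult(table.values[:, cols], cols)
    # (EX+IN)_lasso
    cols_all = np.concatenate([ex_cols, in_cols])
    cols, sel = _select(cols_all)
    return PhaseVariantResult(table.values[:, cols], cols, sel)
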