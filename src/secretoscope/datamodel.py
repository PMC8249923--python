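"""Core data containers for explant secretome analysis.

The central objects are small wrappers around pandas DataFrames with
domain-specific validation:

* :class:`SecretomeMatrix` — cytokine/chemokine concentrations (pg/mL)
  measured per explant sample by a multiplex bead assay; rows are analytes,
  columns are samples.  Missing entries (below detection or not measured)
  are NaN, never zero.
* :class:`InfiltrateTable` — per-sample abundances of immune-cell
  populations (flow cytometry counts or percentages).
* :class:`SampleMetadata` — sample annotations: tumor model, animal of
  origin (grouping replicate explant fragments), and treatment arm.
* :class:`EdgeList` — a STRING-style functional interaction edge list used
  to draw process subnetworks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "TREATMENTS",
    "SecretomeMatrix",
    "InfiltrateTable",
    "SampleMetadata",
    "EdgeList",
]


class ValidationError(ValueError):
    """An input table violates a structural invariant."""


#: Declared treatment vocabulary for explant arms.
TREATMENTS = ("untreated", "anti-PD1", "anti-CTLA4", "anti-OX40", "combination")


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class SecretomeMatrix:
    """Measured concentrations X_i(k) of cytokine i in sample k.

    Parameters
    ----------
    values
        DataFrame of concentrations in pg/mL; index = cytokine ids, columns
        = sample ids.  NaN marks a missing measurement.
    detection_floor
        Assay detection floor in pg/mL, used as a pseudocount when taking
        logs (values are floored at this level inside the log transform
        only; raw data are never modified).
    """

    values: pd.DataFrame
    detection_floor: float = 1.0

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "cytokine ids")
        _check_unique(self.values.columns, "sample ids")
        if not self.detection_floor > 0:
            raise ValidationError(
                f"detection_floor must be > 0, got {self.detection_floor}"
            )
        arr = self.values.to_numpy()
        bad = np.argwhere(np.nan_to_num(arr, nan=0.0) < 0)
        if bad.size:
            i, k = bad[0]
            raise ValidationError(
                "negative concentration "
                f"{arr[i, k]} at cytokine {self.values.index[i]!r}, "
                f"sample {self.values.columns[k]!r}"
            )

    @property
    def cytokine_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_missing(self) -> int:
        return int(self.values.isna().to_numpy().sum())

    def subset_samples(self, sample_ids) -> "SecretomeMatrix":
        return SecretomeMatrix(
            self.values.loc[:, list(sample_ids)].copy(), self.detection_floor
        )


@dataclass
class InfiltrateTable:
    """Per-sample abundances of immune-cell populations.

    Rows are populations (CD4, CD8, CD90.2, TAM, Monocyte, Neutrophil,
    DC1, DC2, Treg, ...), columns are samples; ``unit`` records whether the
    numbers are counts or percentages (informational only).
    """

    values: pd.DataFrame
    unit: str = "count"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        self.values.columns = self.values.columns.astype(str)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.values.index, "population ids")
        _check_unique(self.values.columns, "sample ids")
        arr = self.values.to_numpy()
        bad = np.argwhere(np.nan_to_num(arr, nan=0.0) < 0)
        if bad.size:
            i, k = bad[0]
            raise ValidationError(
                f"negative abundance {arr[i, k]} at population "
                f"{self.values.index[i]!r}, sample {self.values.columns[k]!r}"
            )

    @property
    def population_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class SampleMetadata:
    """Sample annotations: tumor model, animal of origin, treatment arm.

    ``table`` is indexed by sample_id with columns ``tumor_model``,
    ``animal_id`` and ``treatment``.  ``animal_id`` groups the replicate
    explant fragments cut from one tumor, which is how per-fragment
    secretion is matched to per-tumor infiltrate measurements.
    """

    table: pd.DataFrame
    treatments: tuple[str, ...] = TREATMENTS

    def __post_init__(self) -> None:
        required = {"tumor_model", "animal_id", "treatment"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValidationError(f"metadata missing columns: {sorted(missing)}")
        self.table = self.table.copy()
        self.table.index = self.table.index.astype(str)
        self.validate()

    def validate(self) -> None:
        _check_unique(self.table.index, "sample ids")
        bad = set(self.table["treatment"]) - set(self.treatments)
        if bad:
            raise ValidationError(
                f"unknown treatment labels {sorted(bad)}; "
                f"declared vocabulary is {list(self.treatments)}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def animal_of(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "animal_id"])

    def samples_for(self, *, treatment=None, tumor_model=None, animal_id=None):
        """Sample ids matching every given annotation."""
        mask = pd.Series(True, index=self.table.index)
        if treatment is not None:
            mask &= self.table["treatment"] == treatment
        if tumor_model is not None:
            mask &= self.table["tumor_model"] == tumor_model
        if animal_id is not None:
            mask &= self.table["animal_id"] == animal_id
        return list(self.table.index[mask])


@dataclass
class EdgeList:
    """Undirected functional-interaction edges between protein identifiers.

    ``table`` has columns ``a``, ``b`` and optionally ``score`` (confidence
    in [0, 1], STRING-export style).  Self-loops are rejected.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["a", "b"])
    )

    def __post_init__(self) -> None:
        cols = list(self.table.columns)
        if cols[:2] != ["a", "b"]:
            if len(cols) < 2:
                raise ValidationError("edge list needs at least two columns")
            rename = {cols[0]: "a", cols[1]: "b"}
            if len(cols) > 2:
                rename[cols[2]] = "score"
            self.table = self.table.rename(columns=rename)
        self.table = self.table.copy()
        self.table["a"] = self.table["a"].astype(str)
        self.table["b"] = self.table["b"].astype(str)
        self.validate()

    def validate(self) -> None:
        loops = self.table["a"] == self.table["b"]
        if loops.any():
            raise ValidationError(
                f"self-loop on {self.table.loc[loops, 'a'].iloc[0]!r}"
            )
        if "score" in self.table.columns:
            s = self.table["score"].astype(float)
            ok = s.isna() | ((s >= 0) & (s <= 1))
            if not ok.all():
                raise ValidationError("edge scores must lie in [0, 1]")

    @property
    def has_scores(self) -> bool:
        return "score" in self.table.columns

    def __len__(self) -> int:
        return len(self.table)
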