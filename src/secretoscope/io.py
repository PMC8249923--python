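"""Delimited-text readers/writers and cross-table sample alignment.

All tables are UTF-8 CSV or TSV (chosen by file extension), decimal point
".".  Missing entries are an empty cell or "NA" on input; written output
always uses "NA".  Floats are written with 12 significant digits so a
write/read round trip is lossless at that precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    EdgeList,
    InfiltrateTable,
    SampleMetadata,
    SecretomeMatrix,
    ValidationError,
)

__all__ = [
    "read_secretome",
    "write_secretome",
    "read_infiltrates",
    "write_infiltrates",
    "read_metadata",
    "write_metadata",
    "read_edges",
    "write_edges",
    "AlignedSamples",
    "align_tables",
    "aggregate_by_animal",
]

_MISSING_TOKENS = ["", "NA"]
_FLOAT_FMT = "%.12g"


def _sep_for(path) -> str:
    return "\t" if Path(path).suffix.lower() in {".tsv", ".tab", ".txt"} else ","


def _read_numeric_table(path) -> pd.DataFrame:
    df = pd.read_csv(
        path,
        sep=_sep_for(path),
        index_col=0,
        na_values=_MISSING_TOKENS,
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str)
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        for row, cell in df[col].items():
            if cell is None or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                out.loc[row, col] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"non-numeric cell {cell!r} at row {row!r}, column {col!r} "
                    f"in {path}"
                ) from None
    return out


def read_secretome(path, detection_floor: float = 1.0) -> SecretomeMatrix:
    """Read a cytokines × samples concentration table (pg/mL).

    Header row holds sample ids; first column holds cytokine ids.  Empty
    cells and "NA" are recorded as missing, never as zero.
    """
    return SecretomeMatrix(_read_numeric_table(path), detection_floor)


def write_secretome(sec: SecretomeMatrix, path) -> None:
    sec.values.to_csv(
        path, sep=_sep_for(path), na_rep="NA", float_format=_FLOAT_FMT
    )


def read_infiltrates(path, unit: str = "count") -> InfiltrateTable:
    """Read a populations × samples abundance table."""
    return InfiltrateTable(_read_numeric_table(path), unit=unit)


def write_infiltrates(inf: InfiltrateTable, path) -> None:
    inf.values.to_csv(
        path, sep=_sep_for(path), na_rep="NA", float_format=_FLOAT_FMT
    )


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep=_sep_for(path), index_col=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.table.to_csv(path, sep=_sep_for(path))


def read_edges(path) -> EdgeList:
    """Read a STRING-style edge list: idA <tab> idB [<tab> score]."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValidationError(f"edge list {path} needs >= 2 columns")
    cols = ["a", "b"] + (["score"] if df.shape[1] >= 3 else [])
    df = df.iloc[:, : len(cols)]
    df.columns = cols
    if "score" in cols:
        df["score"] = df["score"].astype(float)
    return EdgeList(df)


def write_edges(edges: EdgeList, path) -> None:
    edges.table.to_csv(path, sep="\t", header=False, index=False)


@dataclass
class AlignedSamples:
    """Mapping from explant (secretome) samples to infiltrate records.

    Infiltrates are measured once per tumor while secretion is measured
    per explant fragment, so several secretome samples map to a single
    infiltrate sample through the animal id.
    """

    mapping: dict[str, str] = field(default_factory=dict)
    unmatched: list[str] = field(default_factory=list)

    def groups(self) -> dict[str, list[str]]:
        """Infiltrate sample -> list of matched explant samples."""
        out: dict[str, list[str]] = {}
        for exp, inf in self.mapping.items():
            out.setdefault(inf, []).append(exp)
        return out


def align_tables(
    secretome: SecretomeMatrix,
    infiltrates: InfiltrateTable,
    metadata: SampleMetadata,
) -> AlignedSamples:
    """Match explant samples to infiltrate records via the animal id.

    An infiltrate column whose id is itself a known sample id is resolved
    to its animal; otherwise the column id is taken to be the animal id
    directly.  Two infiltrate records resolving to the same animal make
    the mapping ambiguous and raise.
    """
    known = set(metadata.sample_ids)
    infil_by_animal: dict[str, str] = {}
    for inf_id in infiltrates.sample_ids:
        animal = metadata.animal_of(inf_id) if inf_id in known else inf_id
        if animal in infil_by_animal:
            raise ValidationError(
                f"ambiguous alignment: infiltrate records "
                f"{infil_by_animal[animal]!r} and {inf_id!r} both belong to "
                f"animal {animal!r}"
            )
        infil_by_animal[animal] = inf_id

    mapping: dict[str, str] = {}
    unmatched: list[str] = []
    for s in secretome.sample_ids:
        if s not in known:
            unmatched.append(s)
            continue
        animal = metadata.animal_of(s)
        if animal in infil_by_animal:
            mapping[s] = infil_by_animal[animal]
        else:
            unmatched.append(s)
    return AlignedSamples(mapping=mapping, unmatched=unmatched)


def aggregate_by_animal(
    secretome: SecretomeMatrix,
    metadata: SampleMetadata,
    agg: str = "mean",
) -> SecretomeMatrix:
    """Collapse replicate explant fragments of each animal to one column.

    ``agg`` is "mean" (default) or "median".  Samples absent from the
    metadata are dropped.  Missing values are ignored within each group.
    """
    if agg not in {"mean", "median"}:
        raise ValueError(f"agg must be 'mean' or 'median', got {agg!r}")
    keep = [s for s in secretome.sample_ids if s in set(metadata.sample_ids)]
    sub = secretome.values.loc[:, keep]
    animals = [metadata.animal_of(s) for s in keep]
    grouped = sub.T.groupby(pd.Index(animals, name="animal_id"), sort=False)
    out = (grouped.mean() if agg == "mean" else grouped.median()).T
    return SecretomeMatrix(out, secretome.detection_floor)
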