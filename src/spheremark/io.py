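"""Tabular input/output: quantification matrices, sample metadata, gene sets.

The central container is :class:`QuantMatrix` — a proteins × samples
abundance table with typed per-sample metadata and an explicit scale flag
(``linear`` intensities or ``log2`` abundances).  Two study designs are
recognised: the tumor-evolution design with ordered culture states
ADH < SPH1 < SPH3 (adherent monolayer, first- and third-passage
tumorspheres) and the two-group knockdown design CTRL vs KD.

Missing cells are honest missing values (``NaN``); zeros are valid linear
intensities and are never conflated with missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

#: Ordered culture states of the tumor-evolution design.
EVOLUTION_STATES: tuple[str, ...] = ("ADH", "SPH1", "SPH3")

#: Group labels of the knockdown design.
KNOCKDOWN_GROUPS: tuple[str, ...] = ("CTRL", "KD")

#: Tokens parsed as missing on read (case-insensitive); written back as "".
MISSING_TOKENS: tuple[str, ...] = ("", "NA", "NaN")

_META_COLUMNS = ("cell_line", "culture_state", "replicate")


@dataclass
class QuantMatrix:
    """Proteins × samples abundance matrix with sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by protein identifier with one column per sample.
        ``NaN`` marks a missing (non-identified) cell.
    meta
        DataFrame indexed by sample identifier with columns ``cell_line``,
        ``culture_state`` and ``replicate``.  Culture states must all come
        from one design (evolution or knockdown), never mixed.
    scale
        ``"linear"`` (non-negative intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scale: str = "linear"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        validate_quant_matrix(self)

    # -- convenience accessors -------------------------------------------------

    @property
    def protein_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def design(self) -> str:
        """``"evolution"`` or ``"knockdown"``, inferred from culture states."""
        states = set(self.meta["culture_state"])
        return "evolution" if states <= set(EVOLUTION_STATES) else "knockdown"

    def samples_for(self, cell_line: str | None = None,
                    culture_state: str | None = None) -> list[str]:
        """Sample ids matching the given metadata restriction."""
        mask = pd.Series(True, index=self.meta.index)
        if cell_line is not None:
            mask &= self.meta["cell_line"] == cell_line
        if culture_state is not None:
            mask &= self.meta["culture_state"] == culture_state
        return list(self.meta.index[mask])

    def copy_with(self, values: pd.DataFrame | None = None,
                  scale: str | None = None) -> "QuantMatrix":
        return QuantMatrix(
            values=(self.values if values is None else values).copy(),
            meta=self.meta.copy(),
            scale=self.scale if scale is None else scale,
        )


def validate_quant_matrix(qm: QuantMatrix) -> None:
    """Raise :class:`ValidationError` on any structural violation."""
    vals, meta = qm.values, qm.meta
    if qm.scale not in ("linear", "log2"):
        raise ValidationError(f"unknown scale flag {qm.scale!r}")
    dup = vals.index[vals.index.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate protein identifiers: {list(dup[:5])}")
    dup = vals.columns[vals.columns.duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate sample identifiers: {list(dup[:5])}")
    if meta.index.duplicated().any():
        raise ValidationError("duplicate sample ids in metadata")
    missing_meta = set(vals.columns) - set(meta.index)
    if missing_meta:
        raise ValidationError(f"samples without metadata: {sorted(missing_meta)}")
    extra_meta = set(meta.index) - set(vals.columns)
    if extra_meta:
        raise ValidationError(
            f"metadata lists samples absent from the matrix: {sorted(extra_meta)}")
    for col in _META_COLUMNS:
        if col not in meta.columns:
            raise ValidationError(f"metadata missing required column {col!r}")
    states = set(meta["culture_state"])
    if not (states <= set(EVOLUTION_STATES) or states <= set(KNOCKDOWN_GROUPS)):
        raise ValidationError(
            f"culture states {sorted(states)} mix or fall outside the declared "
            f"designs {EVOLUTION_STATES} / {KNOCKDOWN_GROUPS}")
    if qm.scale == "linear":
        arr = vals.to_numpy()
        neg = arr < 0
        if np.any(neg & ~np.isnan(arr)):
            r, c = np.argwhere(neg & ~np.isnan(arr))[0]
            raise ValidationError(
                f"negative linear intensity at protein {vals.index[r]!r}, "
                f"sample {vals.columns[c]!r}")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def _read_tabular(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(
        path, sep=_sep_for(path), na_values=list(MISSING_TOKENS),
        keep_default_na=False, dtype=str,
    )


def read_quant_matrix(matrix_path: str | Path, meta_path: str | Path,
                      scale: str = "linear",
                      protein_column: str | None = None,
                      sample_id_column: str = "sample_id") -> QuantMatrix:
    """Read a quantification matrix and its sample-metadata table.

    The matrix is TSV/CSV (by extension) with a header row; the first column
    (or ``protein_column``) holds protein identifiers and the remaining
    columns hold samples.  Empty cells and the tokens ``NA``/``NaN`` are
    parsed as missing, never as zero.
    """
    raw = _read_tabular(matrix_path)
    pcol = protein_column or raw.columns[0]
    if pcol not in raw.columns:
        raise ValidationError(f"protein column {pcol!r} not found in {matrix_path}")
    try:
        values = raw.set_index(pcol).astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance cell in {matrix_path}: {exc}") from exc

    meta_raw = _read_tabular(meta_path)
    if sample_id_column not in meta_raw.columns:
        raise ValidationError(
            f"metadata file {meta_path} lacks column {sample_id_column!r}")
    meta = meta_raw.set_index(sample_id_column)
    if "replicate" in meta.columns:
        meta["replicate"] = meta["replicate"].astype(int)
    return QuantMatrix(values=values, meta=meta, scale=scale)


def write_quant_matrix(qm: QuantMatrix, matrix_path: str | Path,
                       meta_path: str | Path,
                       protein_column: str = "protein") -> None:
    """Write matrix + metadata as TSV; missing cells become empty strings."""
    out = qm.values.copy()
    out.index.name = protein_column
    out.to_csv(matrix_path, sep="\t", na_rep="", float_format="%.12g")
    meta = qm.meta.copy()
    meta.index.name = "sample_id"
    meta.to_csv(meta_path, sep="\t")


@dataclass
class GeneSetCollection:
    """Named gene sets as read from a GMT file."""

    sets: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple[str, ...]:
        return self.sets[name][1]

    def items(self):
        return self.sets.items()


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one tab-separated line per set
    (name, description, members...).  Duplicate members within a line are
    dropped (first occurrence kept); duplicate set names are a format error.
    """
    sets: dict[str, tuple[str, tuple[str, ...]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description and at least one member")
            name, desc = fields[0], fields[1]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise FormatError(f"{path}:{lineno}: set {name!r} has no members")
            sets[name] = (desc, members)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def write_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write a result table as TSV with stable column order.

    Floats are written with 12 significant digits so that write → read
    round-trips are exact at that precision; missing cells become "".
    """
    records.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(path), na_values=list(MISSING_TOKENS),
                       keep_default_na=False)
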