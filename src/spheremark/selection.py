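"""Three-contrast fold-change cascade for stemness-marker selection.

For each cell line of the tumor-evolution design, three log2 fold changes
are computed per protein over the ordered culture states:
``fc_s1_adh`` (SPH1 − ADH), ``fc_s3_adh`` (SPH3 − ADH) and ``fc_s3_s1``
(SPH3 − SPH1).  A protein is then classified through an ordered cascade:

1. **Gate** — any |fc| ≥ ``gate`` (default 0.5) to enter consideration.
2. **Culture-artifact exclusion** — a protein altered in both sphere
   passages versus adherent culture (|fc_s1_adh| ≥ ``step`` and
   |fc_s3_adh| ≥ ``step``) but essentially unchanged between passages
   (|fc_s3_s1| < ``artifact_window``) is attributed to the medium change,
   not stemness, and discarded.  Exclusion wins over the selection criteria.
3. **Selection criteria** — criterion 1: both steps (SPH1−ADH and
   SPH3−SPH1) at least ``step`` in magnitude with a consistent sign (a
   constant drift across passages); criterion 2: |fc_s3_adh| ≥ ``endpoint``
   (default 1.5, i.e. at least a three-fold endpoint change).

A selected protein's direction is the sign of its endpoint change
``fc_s3_adh``.  Per-line selections are finally intersected across cell
lines, requiring one consistent direction, to yield shared markers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .io import EVOLUTION_STATES, QuantMatrix


@dataclass(frozen=True)
class SelectionThresholds:
    """Tunable thresholds of the cascade, all in log2 units.

    ``artifact_requires_same_sign`` restricts the exclusion to proteins
    shifted in the same direction in both sphere passages (off by default:
    "altered in both" is read direction-agnostically).
    ``criterion1_cumulative`` switches criterion 1 to the weaker reading
    that only the cumulative change must clear ``step`` while the steps are
    merely sign-consistent; the default demands each step clear ``step``.
    """

    gate: float = 0.5
    step: float = 0.5
    artifact_window: float = 0.5
    endpoint: float = 1.5
    artifact_requires_same_sign: bool = False
    criterion1_cumulative: bool = False

    def __post_init__(self) -> None:
        for name in ("gate", "step", "artifact_window", "endpoint"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")
        if self.endpoint < self.gate:
            raise ConfigurationError("endpoint threshold must be >= gate")


@dataclass(frozen=True)
class SelectionRecord:
    """Cascade decision for one protein in one cell line."""

    protein: str
    cell_line: str
    fc_s1_adh: float
    fc_s3_adh: float
    fc_s3_s1: float
    gated: bool
    artifact_discarded: bool
    criterion1: bool
    criterion2: bool
    selected: bool
    direction: str  # "up" | "down" | "none"


class ContrastResult(NamedTuple):
    table: pd.DataFrame          # index protein; fc_s1_adh, fc_s3_adh, fc_s3_s1
    dropped: list[str]           # proteins with an all-missing condition


class SelectionResult(NamedTuple):
    records: pd.DataFrame        # one row per protein, SelectionRecord schema
    summary: dict                # counts: selected / up / down / discarded


def compute_contrasts(matrix: QuantMatrix, cell_line: str) -> ContrastResult:
    """Condition-mean log2 fold changes for one cell line.

    Each fold change is the difference of condition means over non-missing
    replicates, so additivity ``fc_s3_adh = fc_s1_adh + fc_s3_s1`` holds
    exactly.  Proteins with zero non-missing replicates in any condition
    are dropped from the table and reported.
    """
    if matrix.scale != "log2":
        raise ValidationError("compute_contrasts expects a log2-scale matrix")
    cond_means: dict[str, pd.Series] = {}
    for state in EVOLUTION_STATES:
        sids = matrix.samples_for(cell_line=cell_line, culture_state=state)
        if not sids:
            raise ValidationError(
                f"cell line {cell_line!r} has no {state} samples")
        cond_means[state] = matrix.values[sids].mean(axis=1, skipna=True)
    table = pd.DataFrame({
        "fc_s1_adh": cond_means["SPH1"] - cond_means["ADH"],
        "fc_s3_adh": cond_means["SPH3"] - cond_means["ADH"],
        "fc_s3_s1": cond_means["SPH3"] - cond_means["SPH1"],
    })
    incomplete = table.isna().any(axis=1)
    dropped = list(table.index[incomplete])
    return ContrastResult(table=table.loc[~incomplete], dropped=dropped)


def classify_protein(fc_s1_adh: float, fc_s3_adh: float, fc_s3_s1: float,
                     thresholds: SelectionThresholds = SelectionThresholds(),
                     protein: str = "", cell_line: str = "") -> SelectionRecord:
    """Apply the cascade to one fold-change triple."""
    for name, v in (("fc_s1_adh", fc_s1_adh), ("fc_s3_adh", fc_s3_adh),
                    ("fc_s3_s1", fc_s3_s1)):
        if not math.isfinite(v):
            raise ValidationError(f"non-finite fold change {name}={v!r}")
    t = thresholds
    a1, a3, a31 = abs(fc_s1_adh), abs(fc_s3_adh), abs(fc_s3_s1)

    gated = a1 >= t.gate or a3 >= t.gate or a31 >= t.gate

    artifact = a1 >= t.step and a3 >= t.step and a31 < t.artifact_window
    if t.artifact_requires_same_sign:
        artifact = artifact and (fc_s1_adh * fc_s3_adh > 0)

    same_sign = fc_s1_adh * fc_s3_s1 > 0
    if t.criterion1_cumulative:
        criterion1 = same_sign and a3 >= t.step
    else:
        criterion1 = same_sign and a1 >= t.step and a31 >= t.step
    criterion2 = a3 >= t.endpoint

    selected = gated and not artifact and (criterion1 or criterion2)
    direction = "none"
    if selected:
        direction = "up" if fc_s3_adh > 0 else "down"
    return SelectionRecord(
        protein=protein, cell_line=cell_line,
        fc_s1_adh=fc_s1_adh, fc_s3_adh=fc_s3_adh, fc_s3_s1=fc_s3_s1,
        gated=gated, artifact_discarded=artifact,
        criterion1=criterion1, criterion2=criterion2,
        selected=selected, direction=direction,
    )


def select_markers(contrasts: pd.DataFrame,
                   thresholds: SelectionThresholds = SelectionThresholds(),
                   cell_line: str = "") -> SelectionResult:
    """Classify every protein of one cell line's contrast table (vectorised)."""
    if len(contrasts) == 0:
        raise ValidationError("empty contrast table")
    required = ("fc_s1_adh", "fc_s3_adh", "fc_s3_s1")
    for col in required:
        if col not in contrasts.columns:
            raise ValidationError(f"contrast table lacks column {col!r}")
    f1 = contrasts["fc_s1_adh"].to_numpy(dtype=float)
    f3 = contrasts["fc_s3_adh"].to_numpy(dtype=float)
    f31 = contrasts["fc_s3_s1"].to_numpy(dtype=float)
    if not np.all(np.isfinite(np.concatenate([f1, f3, f31]))):
        raise ValidationError("non-finite fold change in contrast table")
    t = thresholds
    a1, a3, a31 = np.abs(f1), np.abs(f3), np.abs(f31)

    gated = (a1 >= t.gate) | (a3 >= t.gate) | (a31 >= t.gate)
    artifact = (a1 >= t.step) & (a3 >= t.step) & (a31 < t.artifact_window)
    if t.artifact_requires_same_sign:
        artifact &= f1 * f3 > 0
    same_sign = f1 * f31 > 0
    if t.criterion1_cumulative:
        criterion1 = same_sign & (a3 >= t.step)
    else:
        criterion1 = same_sign & (a1 >= t.step) & (a31 >= t.step)
    criterion2 = a3 >= t.endpoint
    selected = gated & ~artifact & (criterion1 | criterion2)
    direction = np.where(selected, np.where(f3 > 0, "up", "down"), "none")

    records = pd.DataFrame({
        "protein": contrasts.index,
        "cell_line": cell_line,
        "fc_s1_adh": f1, "fc_s3_adh": f3, "fc_s3_s1": f31,
        "gated": gated, "artifact_discarded": artifact,
        "criterion1": criterion1, "criterion2": criterion2,
        "selected": selected, "direction": direction,
    }).reset_index(drop=True)
    summary = {
        "cell_line": cell_line,
        "n_proteins": int(len(records)),
        "n_selected": int(selected.sum()),
        "n_up": int((direction == "up").sum()),
        "n_down": int((direction == "down").sum()),
        "n_artifact_discarded": int(artifact.sum()),
    }
    return SelectionResult(records=records, summary=summary)


def intersect_lines(selections: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Shared markers: proteins selected in every cell line with one
    consistent direction.

    ``selections`` maps cell line → its SelectionRecord table.  Proteins
    absent from any line's table are excluded.  The output carries the
    shared direction and, per line, which criterion fired.
    """
    if not selections:
        raise ValidationError("no per-line selections given")
    lines = list(selections)
    per_line = {ln: df.set_index("protein") for ln, df in selections.items()}
    common = set.intersection(*(set(df.index) for df in per_line.values()))
    rows = []
    for protein in sorted(common):
        recs = {ln: per_line[ln].loc[protein] for ln in lines}
        if not all(bool(r["selected"]) for r in recs.values()):
            continue
        directions = {r["direction"] for r in recs.values()}
        if len(directions) != 1:
            continue
        row = {"protein": protein, "direction": directions.pop()}
        for ln in lines:
            row[f"criterion1_{ln}"] = bool(recs[ln]["criterion1"])
            row[f"criterion2_{ln}"] = bool(recs[ln]["criterion2"])
        rows.append(row)
    columns = ["protein", "direction"] + [
        f"{c}_{ln}" for ln in lines for c in ("criterion1", "criterion2")]
    if not rows:
        import warnings
        warnings.warn("no shared markers across the given cell lines")
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows, columns=columns)


def run_marker_selection(matrix: QuantMatrix,
                         thresholds: SelectionThresholds = SelectionThresholds(),
                         ) -> tuple[dict[str, SelectionResult], pd.DataFrame]:
    """Full cascade over every cell line of a log2 evolution matrix."""
    results: dict[str, SelectionResult] = {}
    for line in sorted(set(matrix.meta["cell_line"])):
        contrasts = compute_contrasts(matrix, line)
        results[line] = select_markers(contrasts.table, thresholds,
                                       cell_line=line)
    shared = intersect_lines({ln: r.records for ln, r in results.items()})
    return results, shared
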