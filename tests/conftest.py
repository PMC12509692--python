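"""Shared fixtures: small hand-built matrices and simulated studies."""

import numpy as np
import pandas as pd
import pytest

from spheremark.io import QuantMatrix
from spheremark.simulate import SimConfig, simulate_knockdown_study


def build_matrix(values, sample_meta, proteins=None, scale="linear"):
    """Assemble a QuantMatrix from a 2-D array and (cell_line, state, rep)
    triples (one per column, in order)."""
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    proteins = proteins or [f"P{i}" for i in range(n)]
    sample_ids = [f"{cl}_{st}_r{rep}" for cl, st, rep in sample_meta]
    meta = pd.DataFrame(
        {"sample_id": sample_ids,
         "cell_line": [cl for cl, _, _ in sample_meta],
         "culture_state": [st for _, st, _ in sample_meta],
         "replicate": [rep for _, _, rep in sample_meta]}
    ).set_index("sample_id")
    return QuantMatrix(
        values=pd.DataFrame(values, index=proteins, columns=sample_ids),
        meta=meta, scale=scale)


def evolution_meta(cell_lines=("CL1",), n_reps=2):
    return [(cl, st, r) for cl in cell_lines
            for st in ("ADH", "SPH1", "SPH3") for r in range(1, n_reps + 1)]


def knockdown_meta(n_reps=3):
    return [("CL1", g, r) for g in ("CTRL", "KD") for r in range(1, n_reps + 1)]


@pytest.fixture
def kd_matrix_missing():
    """Small knockdown study with left-censored missingness."""
    cfg = SimConfig(n_proteins=300, noise_sd=0.3, missing_rate=0.08,
                    censor_steepness=1.0, seed=11)
    return simulate_knockdown_study(cfg, n_de=30, de_effect_range=(0.8, 2.5))
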