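"""The fold-change cascade against an independent rule enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spheremark.errors import ValidationError
from spheremark.preprocess import log2_transform
from spheremark.selection import (SelectionThresholds, classify_protein,
                                  compute_contrasts, intersect_lines,
                                  run_marker_selection, select_markers)
from spheremark.simulate import SimConfig, simulate_evolution_study

from conftest import build_matrix, evolution_meta


def cascade_oracle(f1, f3, f31):
    """Brute-force restatement of the selection rules, written directly from
    their verbal definition and independent of the implementation.

    A protein enters consideration if any of its three fold changes reaches
    0.5 in magnitude.  It is discarded as a culture artifact if it is
    altered (|fc| >= 0.5) in both sphere passages versus adherent culture
    but does not change (|fc| < 0.5) between passages.  Otherwise it is
    selected if it either drifts constantly in one direction with each step
    at least 0.5 (criterion 1) or shows at least a three-fold endpoint
    change, |fc| >= 1.5, between third spheres and adherent (criterion 2).
    """
    considered = abs(f1) >= 0.5 or abs(f3) >= 0.5 or abs(f31) >= 0.5
    medium_artifact = abs(f1) >= 0.5 and abs(f3) >= 0.5 and abs(f31) < 0.5
    constant_up = f1 >= 0.5 and f31 >= 0.5
    constant_down = f1 <= -0.5 and f31 <= -0.5
    criterion1 = constant_up or constant_down
    criterion2 = f3 >= 1.5 or f3 <= -1.5
    selected = considered and not medium_artifact and (criterion1 or criterion2)
    if not selected:
        direction = "none"
    else:
        direction = "up" if f3 > 0 else "down"
    return medium_artifact, criterion1, criterion2, selected, direction


def test_classifier_matches_oracle_on_random_triples():
    rng = np.random.default_rng(2024)
    fcs = rng.uniform(-3, 3, size=(10_000, 3))
    mismatches = 0
    for f1, f3, f31 in fcs:
        rec = classify_protein(f1, f3, f31)
        art, c1, c2, sel, direction = cascade_oracle(f1, f3, f31)
        if (rec.artifact_discarded, rec.criterion1, rec.criterion2,
                rec.selected, rec.direction) != (art, c1, c2, sel, direction):
            mismatches += 1
    assert mismatches == 0


@pytest.mark.parametrize("fcs,expect", [
    # (f1, f3, f31) -> (artifact, criterion1, criterion2, selected, direction)
    ((0.6, 1.3, 0.7), (False, True, False, True, "up")),
    ((0.8, 0.9, 0.1), (True, False, False, False, "none")),
    ((0.2, 1.6, 1.4), (False, False, True, True, "up")),
    ((0.0, 0.0, 0.0), (False, False, False, False, "none")),
    ((-0.6, -1.2, -0.6), (False, True, False, True, "down")),
])
def test_classifier_worked_examples(fcs, expect):
    rec = classify_protein(*fcs)
    assert (rec.artifact_discarded, rec.criterion1, rec.criterion2,
            rec.selected, rec.direction) == expect
    if fcs == (0.0, 0.0, 0.0):
        assert not rec.gated


def test_non_finite_fold_change_rejected():
    with pytest.raises(ValidationError):
        classify_protein(float("nan"), 1.0, 1.0)


@settings(max_examples=300, derandomize=True)
@given(f1=st.floats(-3, 3), f31=st.floats(-3, 3))
def test_vectorised_selection_agrees_with_scalar_classifier(f1, f31):
    f3 = f1 + f31
    table = pd.DataFrame({"fc_s1_adh": [f1], "fc_s3_adh": [f3],
                          "fc_s3_s1": [f31]}, index=["P0"])
    rec = select_markers(table).records.iloc[0]
    scalar = classify_protein(f1, f3, f31)
    assert bool(rec["selected"]) == scalar.selected
    assert bool(rec["artifact_discarded"]) == scalar.artifact_discarded
    assert rec["direction"] == scalar.direction


class TestComputeContrasts:
    def test_hand_computed_contrasts(self):
        vals = 2.0 ** np.array([[10, 10, 10.8, 10.8, 11.5, 11.5]])
        qm = build_matrix(vals, evolution_meta())
        qml, _ = log2_transform(qm)
        res = compute_contrasts(qml, "CL1")
        row = res.table.loc["P0"]
        assert row["fc_s1_adh"] == pytest.approx(0.8, abs=1e-9)
        assert row["fc_s3_adh"] == pytest.approx(1.5, abs=1e-9)
        assert row["fc_s3_s1"] == pytest.approx(0.7, abs=1e-9)

    def test_identical_conditions_give_zero(self):
        qm = build_matrix(np.full((3, 6), 12.0), evolution_meta(), scale="log2")
        res = compute_contrasts(qm, "CL1")
        assert (res.table.to_numpy() == 0).all()

    def test_additivity_identity(self):
        rng = np.random.default_rng(8)
        qm = build_matrix(rng.normal(20, 2, (50, 6)), evolution_meta(),
                          scale="log2")
        t = compute_contrasts(qm, "CL1").table
        np.testing.assert_allclose(t["fc_s3_adh"],
                                   t["fc_s1_adh"] + t["fc_s3_s1"], atol=1e-12)

    def test_all_missing_condition_drops_protein(self):
        vals = np.random.default_rng(0).normal(20, 2, (3, 6))
        vals[1, 2:4] = np.nan  # both SPH1 replicates of P1
        qm = build_matrix(vals, evolution_meta(), scale="log2")
        res = compute_contrasts(qm, "CL1")
        assert res.dropped == ["P1"]
        assert "P1" not in res.table.index

    def test_absent_culture_state_rejected(self):
        qm = build_matrix(np.ones((2, 2)),
                          [("CL1", "ADH", 1), ("CL1", "SPH1", 1)], scale="log2")
        with pytest.raises(ValidationError, match="SPH3"):
            compute_contrasts(qm, "CL1")


class TestSelectMarkers:
    def test_zero_noise_planted_counts(self):
        cfg = SimConfig(
            n_proteins=1000, noise_sd=0.0, seed=7,
            class_proportions={"null": 0.9, "monotone_up": 0.05,
                               "artifact": 0.02, "jump_up": 0.03})
        qm, truth = simulate_evolution_study(cfg)
        qml, _ = log2_transform(qm)
        res = select_markers(compute_contrasts(qml, "CL1").table,
                             cell_line="CL1")
        assert res.summary["n_selected"] == 80
        assert res.summary["n_artifact_discarded"] == 20
        recs = res.records
        assert int((recs["selected"] & recs["criterion1"]).sum()) == 50
        assert int((recs["selected"] & ~recs["criterion1"]
                    & recs["criterion2"]).sum()) == 30

    def test_infinite_gate_selects_nothing(self):
        table = pd.DataFrame({"fc_s1_adh": [0.9], "fc_s3_adh": [2.0],
                              "fc_s3_s1": [1.1]}, index=["P0"])
        thr = SelectionThresholds(gate=1e9, endpoint=1e9)
        assert select_markers(table, thr).summary["n_selected"] == 0

    def test_protein_order_invariance(self):
        rng = np.random.default_rng(5)
        f1 = rng.uniform(-2, 2, 200)
        f31 = rng.uniform(-2, 2, 200)
        table = pd.DataFrame({"fc_s1_adh": f1, "fc_s3_adh": f1 + f31,
                              "fc_s3_s1": f31},
                             index=[f"P{i}" for i in range(200)])
        sel_a = select_markers(table).records
        shuffled = table.sample(frac=1, random_state=1)
        sel_b = select_markers(shuffled).records
        assert (set(sel_a.loc[sel_a.selected, "protein"])
                == set(sel_b.loc[sel_b.selected, "protein"]))

    def test_scale_invariance_of_linear_matrix(self):
        cfg = SimConfig(n_proteins=200, seed=13)
        qm, _ = simulate_evolution_study(cfg)
        qml, _ = log2_transform(qm)
        base, _ = run_marker_selection(qml)
        scaled = qm.copy_with(values=qm.values * 37.5)
        scaled_l, _ = log2_transform(scaled)
        other, _ = run_marker_selection(scaled_l)
        for line in base:
            a = base[line].records
            b = other[line].records
            assert (set(a.loc[a.selected, "protein"])
                    == set(b.loc[b.selected, "protein"]))

    def test_threshold_relaxation_is_monotone(self):
        rng = np.random.default_rng(17)
        f1 = rng.uniform(-3, 3, 2000)
        f31 = rng.uniform(-3, 3, 2000)
        table = pd.DataFrame({"fc_s1_adh": f1, "fc_s3_adh": f1 + f31,
                              "fc_s3_s1": f31},
                             index=[f"P{i}" for i in range(2000)])
        tight = select_markers(table, SelectionThresholds()).records
        relaxed = select_markers(
            table, SelectionThresholds(gate=0.4, step=0.4, endpoint=1.2)).records
        tight_set = set(tight.loc[tight.selected, "protein"])
        relaxed_set = set(relaxed.loc[relaxed.selected, "protein"])
        assert tight_set <= relaxed_set

    def test_empty_table_rejected(self):
        with pytest.raises(ValidationError):
            select_markers(pd.DataFrame(columns=["fc_s1_adh", "fc_s3_adh",
                                                 "fc_s3_s1"]))


class TestIntersectLines:
    @staticmethod
    def fake_records(selected_dirs):
        rows = []
        for protein, direction in selected_dirs.items():
            rows.append({"protein": protein, "cell_line": "x",
                         "fc_s1_adh": 1.0, "fc_s3_adh": 2.0, "fc_s3_s1": 1.0,
                         "gated": True, "artifact_discarded": False,
                         "criterion1": direction != "none",
                         "criterion2": False,
                         "selected": direction != "none",
                         "direction": direction})
        return pd.DataFrame(rows)

    def test_direction_conflict_excluded(self):
        sels = {
            "L1": self.fake_records({"A": "up", "B": "up"}),
            "L2": self.fake_records({"A": "up", "B": "up"}),
            "L3": self.fake_records({"A": "down", "B": "up"}),
        }
        shared = intersect_lines(sels)
        assert list(shared["protein"]) == ["B"]
        assert shared["direction"].tolist() == ["up"]

    def test_single_line_is_identity(self):
        sels = {"L1": self.fake_records({"A": "up", "B": "none", "C": "down"})}
        shared = intersect_lines(sels)
        assert set(shared["protein"]) == {"A", "C"}

    def test_protein_absent_from_one_line_excluded(self):
        sels = {"L1": self.fake_records({"A": "up", "B": "up"}),
                "L2": self.fake_records({"A": "up"})}
        assert set(intersect_lines(sels)["protein"]) == {"A"}

    def test_zero_noise_shared_set_recovered_exactly(self):
        cfg = SimConfig(n_proteins=500, noise_sd=0.0, seed=31,
                        shared_fraction=0.5)
        qm, truth = simulate_evolution_study(cfg)
        qml, _ = log2_transform(qm)
        results, shared = run_marker_selection(qml)
        for line, res in results.items():
            recs = res.records
            assert (set(recs.loc[recs.selected, "protein"])
                    == truth.planted_markers(line))
            assert (set(recs.loc[recs.artifact_discarded, "protein"])
                    == truth.planted_artifacts(line))
        assert set(shared["protein"]) == truth.shared_markers()

    def test_no_common_selection_warns_and_returns_empty(self):
        sels = {"L1": self.fake_records({"A": "up"}),
                "L2": self.fake_records({"B": "up"})}
        with pytest.warns(UserWarning):
            shared = intersect_lines(sels)
        assert shared.empty
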