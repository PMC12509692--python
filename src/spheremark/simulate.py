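"""Synthetic proteomics data with planted ground truth.

Two generators mirror the two experimental designs of the study system:

* :func:`simulate_evolution_study` — three cell lines of a sarcoma
  progression model, each cultured as adherent monolayer (ADH) and as
  tumorspheres at passage 1 (SPH1) and 3 (SPH3), with replicates.  Proteins
  are planted in one of six behavioural classes: ``null`` (no change),
  ``monotone_up``/``monotone_down`` (constant drift across passages — the
  stemness-marker signature), ``artifact`` (shifted in both sphere passages
  versus adherent but flat between passages — the culture-medium signature
  the cascade must discard), and ``jump_up``/``jump_down`` (a large endpoint
  change concentrated in the late step).
* :func:`simulate_knockdown_study` — a two-group (CTRL vs KD) design with
  planted differential proteins and left-censored (abundance-dependent)
  missingness, the regime EM imputation is meant for.

Effects are planted additively on the log2 scale and the matrix is exported
on the linear scale (``2**x``), mimicking reporter-ion-like intensities.
All randomness flows through one seeded generator: identical configs give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .io import EVOLUTION_STATES, KNOCKDOWN_GROUPS, QuantMatrix

#: Behavioural classes a protein can be planted with.
CLASSES: tuple[str, ...] = (
    "null", "monotone_up", "monotone_down", "artifact", "jump_up", "jump_down",
)

_MARKER_CLASSES = frozenset({"monotone_up", "monotone_down", "jump_up", "jump_down"})

_DEFAULT_PROPORTIONS: dict[str, float] = {
    "null": 0.90,
    "monotone_up": 0.04,
    "monotone_down": 0.02,
    "artifact": 0.02,
    "jump_up": 0.01,
    "jump_down": 0.01,
}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic study.

    All effect sizes and noise are in log2 units.  ``step_effect_range``
    bounds each per-passage step of a monotone marker;
    ``artifact_shift_range`` bounds the shared sphere-vs-adherent shift of a
    culture artifact (its residual SPH3−SPH1 drift is drawn from
    ``artifact_residual_range``, kept well inside the exclusion window);
    ``jump_total_range`` bounds the endpoint change of a jump marker, whose
    early step is drawn small from ``jump_minor_step_range``.

    ``shared_fraction`` is the fraction of each non-null class planted with
    the same class in every cell line (flagged ``shared_marker`` in the
    truth); the remainder are planted in a single cell line only.

    ``missing_rate`` / ``censor_steepness`` parameterise the left-censored
    missingness of the knockdown design: the probability that a cell is
    missing follows a logistic curve in its log2 abundance with the given
    steepness, with the intercept solved so the expected overall rate equals
    ``missing_rate``.  ``censor_steepness=0`` degrades to missing
    completely at random.
    """

    n_proteins: int = 1000
    n_cell_lines: int = 3
    n_replicates_per_condition: int = 3
    class_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_PROPORTIONS))
    step_effect_range: tuple[float, float] = (0.6, 2.0)
    artifact_shift_range: tuple[float, float] = (0.6, 2.0)
    artifact_residual_range: tuple[float, float] = (0.0, 0.3)
    jump_total_range: tuple[float, float] = (1.6, 3.0)
    jump_minor_step_range: tuple[float, float] = (0.0, 0.3)
    noise_sd: float = 0.15
    baseline_mean: float = 20.0
    baseline_sd: float = 2.0
    shared_fraction: float = 1.0
    missing_rate: float = 0.0
    censor_steepness: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_proteins <= 0 or self.n_cell_lines <= 0:
            raise ConfigurationError("n_proteins and n_cell_lines must be positive")
        if self.n_replicates_per_condition <= 0:
            raise ConfigurationError("n_replicates_per_condition must be positive")
        unknown = set(self.class_proportions) - set(CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown protein classes: {sorted(unknown)}")
        total = float(sum(self.class_proportions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class proportions sum to {total!r}, expected 1")
        if any(v < 0 for v in self.class_proportions.values()):
            raise ConfigurationError("class proportions must be non-negative")
        for name in ("step_effect_range", "artifact_shift_range",
                     "artifact_residual_range", "jump_total_range",
                     "jump_minor_step_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ConfigurationError(f"{name} has lower bound > upper bound")
        if self.noise_sd < 0 or self.baseline_sd < 0:
            raise ConfigurationError("standard deviations must be non-negative")
        if not 0.0 <= self.shared_fraction <= 1.0:
            raise ConfigurationError("shared_fraction must lie in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must lie in [0, 1)")
        if self.censor_steepness < 0:
            raise ConfigurationError("censor_steepness must be non-negative")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated matrix.

    ``labels`` gives the global class per protein.  For the evolution
    design, ``effects`` holds one row per (protein, cell line) with the
    class realised in that line and the two step effects (log2 units,
    ADH→SPH1 and SPH1→SPH3); ``shared`` flags proteins planted in every
    line.  For the knockdown design, ``de_effect`` holds the signed planted
    log2 shift (0 for nulls).
    """

    labels: pd.Series
    shared: pd.Series | None = None
    effects: pd.DataFrame | None = None
    de_effect: pd.Series | None = None

    # -- oracle views ---------------------------------------------------------

    def planted_markers(self, cell_line: str) -> set[str]:
        """Proteins planted with a marker class in the given cell line."""
        eff = self._line_effects(cell_line)
        return set(eff.index[eff["line_class"].isin(_MARKER_CLASSES)])

    def planted_artifacts(self, cell_line: str) -> set[str]:
        eff = self._line_effects(cell_line)
        return set(eff.index[eff["line_class"] == "artifact"])

    def shared_markers(self) -> set[str]:
        """Marker proteins planted in every cell line (the shared set)."""
        if self.shared is None:
            raise ValueError("truth has no shared flags (knockdown design?)")
        return set(self.labels.index[
            self.shared & self.labels.isin(_MARKER_CLASSES)])

    def _line_effects(self, cell_line: str) -> pd.DataFrame:
        if self.effects is None:
            raise ValueError("truth has no per-line effects (knockdown design?)")
        eff = self.effects[self.effects["cell_line"] == cell_line]
        return eff.set_index("protein")

    def to_frame(self) -> pd.DataFrame:
        """Flat table for serialisation."""
        out = self.labels.rename("class").rename_axis("protein").reset_index()
        if self.shared is not None:
            out["shared_marker"] = self.shared.reindex(out["protein"]).to_numpy()
        if self.de_effect is not None:
            out["de_effect"] = self.de_effect.reindex(out["protein"]).to_numpy()
        return out


def largest_remainder_counts(proportions: Mapping[str, float], n: int) -> dict[str, int]:
    """Apportion ``n`` items to classes by largest-remainder rounding.

    Deterministic: remainder ties are broken by the canonical class order.
    The counts sum to ``n`` exactly.
    """
    classes = [c for c in CLASSES if c in proportions]
    quotas = np.array([proportions[c] * n for c in classes])
    counts = np.floor(quotas).astype(int)
    short = n - int(counts.sum())
    remainders = quotas - counts
    # stable sort descending by remainder; ties keep canonical order
    order = np.argsort(-remainders, kind="stable")
    for i in order[:short]:
        counts[i] += 1
    return dict(zip(classes, (int(c) for c in counts)))


def _signed_uniform(rng: np.random.Generator, lo: float, hi: float,
                    sign: int) -> float:
    return sign * float(rng.uniform(lo, hi))


def _draw_steps(rng: np.random.Generator, cls: str, cfg: SimConfig
                ) -> tuple[float, float]:
    """Realised (ADH→SPH1, SPH1→SPH3) step effects for one protein/line."""
    if cls == "null":
        return 0.0, 0.0
    if cls in ("monotone_up", "monotone_down"):
        s = 1 if cls == "monotone_up" else -1
        return (_signed_uniform(rng, *cfg.step_effect_range, s),
                _signed_uniform(rng, *cfg.step_effect_range, s))
    if cls == "artifact":
        s = 1 if rng.random() < 0.5 else -1
        shift = _signed_uniform(rng, *cfg.artifact_shift_range, s)
        # residual drift keeps the same sign so |SPH3-ADH| stays >= the shift
        resid = _signed_uniform(rng, *cfg.artifact_residual_range, s)
        return shift, resid
    if cls in ("jump_up", "jump_down"):
        s = 1 if cls == "jump_up" else -1
        total = _signed_uniform(rng, *cfg.jump_total_range, s)
        minor = _signed_uniform(rng, *cfg.jump_minor_step_range, s)
        return minor, total - minor
    raise ConfigurationError(f"unknown class {cls!r}")


def _protein_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"P{i:0{width}d}" for i in range(n)]


def simulate_evolution_study(config: SimConfig) -> tuple[QuantMatrix, SyntheticTruth]:
    """Simulate the three-line ADH/SPH1/SPH3 tumor-evolution proteome.

    Returns the linear-scale :class:`~spheremark.io.QuantMatrix` and the
    planted :class:`SyntheticTruth`.  Abundance is baseline + cumulative
    planted step effects + Gaussian noise on the log2 scale.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = _protein_ids(n)
    lines = [f"CL{i + 1}" for i in range(config.n_cell_lines)]

    counts = largest_remainder_counts(config.class_proportions, n)
    labels_list: list[str] = []
    for cls in CLASSES:
        labels_list.extend([cls] * counts.get(cls, 0))
    # shuffle class assignment over protein ids so classes are not contiguous
    perm = rng.permutation(n)
    labels = pd.Series(np.array(labels_list, dtype=object)[np.argsort(perm)],
                       index=proteins, name="class")

    # shared vs line-private planting for non-null proteins
    shared = pd.Series(True, index=proteins, name="shared_marker")
    host_line = pd.Series("", index=proteins, dtype=object)
    for cls in CLASSES:
        if cls == "null":
            continue
        members = list(labels.index[labels == cls])
        n_shared = int(round(config.shared_fraction * len(members)))
        private = members[n_shared:]
        shared[private] = False
        for p in private:
            host_line[p] = lines[int(rng.integers(len(lines)))]
    shared[labels == "null"] = False

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    effect_rows: list[dict] = []
    col_data: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for line in lines:
        steps = np.zeros((n, 2))
        for i, p in enumerate(proteins):
            cls = labels[p]
            planted = cls != "null" and (shared[p] or host_line[p] == line)
            line_cls = cls if planted else "null"
            s1, s2 = _draw_steps(rng, line_cls, config) if planted else (0.0, 0.0)
            steps[i] = (s1, s2)
            effect_rows.append({"protein": p, "cell_line": line,
                                "line_class": line_cls,
                                "step_adh_sph1": s1, "step_sph1_sph3": s2})
        cum = {"ADH": np.zeros(n), "SPH1": steps[:, 0],
               "SPH3": steps[:, 0] + steps[:, 1]}
        for state in EVOLUTION_STATES:
            for rep in range(1, config.n_replicates_per_condition + 1):
                sid = f"{line}_{state}_r{rep}"
                noise = (rng.normal(0.0, config.noise_sd, size=n)
                         if config.noise_sd > 0 else np.zeros(n))
                col_data[sid] = 2.0 ** (baseline + cum[state] + noise)
                meta_rows.append({"sample_id": sid, "cell_line": line,
                                  "culture_state": state, "replicate": rep})

    values = pd.DataFrame(col_data, index=proteins)
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    qm = QuantMatrix(values=values, meta=meta, scale="linear")
    truth = SyntheticTruth(labels=labels, shared=shared,
                           effects=pd.DataFrame(effect_rows))
    return qm, truth


def simulate_knockdown_study(config: SimConfig, n_de: int,
                             de_effect_range: tuple[float, float] = (1.0, 2.5),
                             ) -> tuple[QuantMatrix, SyntheticTruth]:
    """Simulate the two-group (CTRL vs KD) triplicate knockdown proteome.

    ``n_de`` proteins receive a signed log2 shift drawn from
    ``de_effect_range`` in the KD group.  Left-censored missingness is then
    applied per :class:`SimConfig`.
    """
    if n_de > config.n_proteins:
        raise ConfigurationError(
            f"n_de={n_de} exceeds n_proteins={config.n_proteins}")
    if n_de < 0:
        raise ConfigurationError("n_de must be non-negative")
    lo, hi = de_effect_range
    if lo > hi:
        raise ConfigurationError("de_effect_range has lower bound > upper bound")

    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = _protein_ids(n)

    de_idx = rng.choice(n, size=n_de, replace=False)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    effect = np.zeros(n)
    effect[de_idx] = signs * rng.uniform(lo, hi, size=n_de)

    baseline = rng.normal(config.baseline_mean, config.baseline_sd, size=n)

    col_data: dict[str, np.ndarray] = {}
    meta_rows: list[dict] = []
    for group in KNOCKDOWN_GROUPS:
        shift = effect if group == "KD" else np.zeros(n)
        for rep in range(1, config.n_replicates_per_condition + 1):
            sid = f"{group}_r{rep}"
            noise = (rng.normal(0.0, config.noise_sd, size=n)
                     if config.noise_sd > 0 else np.zeros(n))
            col_data[sid] = baseline + shift + noise
            meta_rows.append({"sample_id": sid, "cell_line": "CL1",
                              "culture_state": group, "replicate": rep})

    log2_vals = pd.DataFrame(col_data, index=proteins)
    mask = _censor_mask(log2_vals.to_numpy(), config, rng)
    values = pd.DataFrame(2.0 ** log2_vals.to_numpy(), index=proteins,
                          columns=log2_vals.columns)
    values = values.mask(pd.DataFrame(mask, index=values.index,
                                      columns=values.columns))

    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    qm = QuantMatrix(values=values, meta=meta, scale="linear")
    labels = pd.Series(np.where(effect > 0, "de_up",
                       np.where(effect < 0, "de_down", "null")),
                       index=proteins, name="class")
    truth = SyntheticTruth(labels=labels,
                           de_effect=pd.Series(effect, index=proteins,
                                               name="de_effect"))
    return qm, truth


def _censor_mask(log2_vals: np.ndarray, cfg: SimConfig,
                 rng: np.random.Generator) -> np.ndarray:
    """Boolean mask of cells to censor, MNAR-logistic in log2 abundance."""
    if cfg.missing_rate == 0.0:
        return np.zeros_like(log2_vals, dtype=bool)
    if cfg.censor_steepness == 0.0:
        return rng.random(log2_vals.shape) < cfg.missing_rate
    k = cfg.censor_steepness

    def mean_rate(x0: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(k * (log2_vals - x0)))))

    # bisect the logistic midpoint so the expected rate hits missing_rate
    lo = float(log2_vals.min()) - 50.0 / k
    hi = float(log2_vals.max()) + 50.0 / k
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < cfg.missing_rate:
            lo = mid
        else:
            hi = mid
    x0 = 0.5 * (lo + hi)
    p = 1.0 / (1.0 + np.exp(k * (log2_vals - x0)))
    return rng.random(log2_vals.shape) < p
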