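"""IHC semiquantitative scoring, association tests, survival, tumor volume.

Immunohistochemical staining of a marker (here GPX1 in sarcoma tissue
microarrays) is scored as extent × intensity, each graded 0/1/2 (extent:
0 = no stained cells, 1 = <50%, 2 = >50%; intensity: none/low/high).  The
product lies in {0, 1, 2, 4} (3 is unattainable) and maps to expression
classes negative (0), low (1–2) and high (4).  Association of the class
with clinicopathological covariates uses the chi-square test (Yates
continuity correction available for 2×2 tables); survival is summarised by
Kaplan–Meier curves compared with the log-rank test.  Survival times are
in months.  Xenograft tumor volume follows the caliper formula
(D × d²)/6 × 3.14 with D, d the maximum and minimum diameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .errors import ConfigurationError, ValidationError

IHC_CLASSES = ("negative", "low", "high")


def ihc_score_and_class(extent: int, intensity: int) -> tuple[int, str]:
    """Score = extent × intensity; class negative (0) / low (1–2) / high (4)."""
    for name, v in (("extent", extent), ("intensity", intensity)):
        if v not in (0, 1, 2):
            raise ValidationError(f"{name} category must be 0, 1 or 2, got {v!r}")
    score = extent * intensity
    if score == 0:
        cls = "negative"
    elif score in (1, 2):
        cls = "low"
    else:
        cls = "high"
    return score, cls


def score_ihc_table(table: pd.DataFrame, extent_col: str = "extent",
                    intensity_col: str = "intensity") -> pd.DataFrame:
    """Vectorised scoring of a whole IHC table; adds score and class columns."""
    out = table.copy()
    scored = [ihc_score_and_class(int(e), int(i))
              for e, i in zip(out[extent_col], out[intensity_col])]
    out["score"] = [s for s, _ in scored]
    out["ihc_class"] = [c for _, c in scored]
    return out


class ChisqResult(NamedTuple):
    statistic: float
    df: int
    p: float
    expected: np.ndarray
    low_expected: bool  # any expected count < 5 (validity caveat, not fatal)


def chisq_test(table: Sequence[Sequence[float]], yates: bool = False,
               ) -> ChisqResult:
    """Pearson chi-square test of independence on a contingency table.

    ``yates`` applies the continuity correction and is only admissible for
    2×2 tables.  Expected counts of zero are a validation error; expected
    counts below 5 merely set the ``low_expected`` flag.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValidationError("contingency table must be at least 2×2")
    if np.any(obs < 0) or not np.all(np.isfinite(obs)):
        raise ValidationError("counts must be finite and non-negative")
    if yates and obs.shape != (2, 2):
        raise ConfigurationError("Yates correction applies only to 2×2 tables")
    expected = stats.contingency.expected_freq(obs)
    if np.any(expected == 0):
        raise ValidationError("table has a zero expected count "
                              "(empty row or column)")
    stat, p, df, _ = stats.chi2_contingency(obs, correction=yates)
    return ChisqResult(statistic=float(stat), df=int(df), p=float(p),
                       expected=expected, low_expected=bool((expected < 5).any()))


@dataclass
class SurvivalCurve:
    """Kaplan–Meier product-limit estimate as a right-continuous step function."""

    times: np.ndarray          # distinct event/censor times, ascending
    at_risk: np.ndarray        # subjects at risk just before each time
    survival: np.ndarray       # S(t) just after each time
    censor_times: np.ndarray   # times with at least one censoring

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: Sequence[float], events: Sequence[bool]) -> SurvivalCurve:
    """Kaplan–Meier estimator (deaths precede censorings at tied times)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValidationError("empty survival input")
    if t.shape != e.shape:
        raise ValidationError("times and events differ in length")
    if np.any(t < 0) or not np.all(np.isfinite(t)):
        raise ValidationError("times must be finite and non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    grid = np.asarray(table.index, dtype=float)
    keep = grid > 0  # drop the implicit t=0 row; S(0)=1 by definition
    return SurvivalCurve(
        times=grid[keep],
        at_risk=table["at_risk"].to_numpy()[keep],
        survival=sf.reindex(table.index).to_numpy()[keep],
        censor_times=np.unique(t[~e]),
    )


class LogrankResult(NamedTuple):
    statistic: float
    df: int
    p: float


def logrank_test(times: Sequence[float], events: Sequence[bool],
                 groups: Sequence) -> LogrankResult:
    """Log-rank test across ≥2 groups (observed − expected with
    hypergeometric variance at each distinct event time; df = groups − 1)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    if not (t.size == e.size == g.size) or t.size == 0:
        raise ValidationError("times, events and groups must be equal, non-empty")
    if np.any(t < 0):
        raise ValidationError("times must be non-negative")
    levels, counts = np.unique(g, return_counts=True)
    if len(levels) < 2:
        raise ValidationError("need at least two groups")
    if e.sum() == 0:
        raise ValidationError("need at least one event overall")
    res = multivariate_logrank_test(t, g, e)
    return LogrankResult(statistic=float(res.test_statistic),
                         df=len(levels) - 1, p=float(res.p_value))


def survival_by_group(table: pd.DataFrame, group_col: str,
                      time_col: str = "time_months",
                      event_col: str = "event") -> dict[str, SurvivalCurve]:
    """One Kaplan–Meier curve per level of ``group_col``."""
    return {
        str(level): km_estimate(sub[time_col].to_numpy(),
                                sub[event_col].astype(bool).to_numpy())
        for level, sub in table.groupby(group_col, observed=True)
    }


def tumor_volume(D: float, d: float) -> float:
    """Caliper tumor volume (D × d²)/6 × 3.14, D ≥ d > 0."""
    if not (d > 0):
        raise ValidationError("minimum diameter d must be positive")
    if d > D:
        raise ValidationError("minimum diameter d exceeds maximum diameter D")
    return (D * d * d) / 6.0 * 3.14
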