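"""Empirical-Bayes moderated-t differential expression for a two-group design.

Per protein a pooled two-sample variance s² with d = n1 + n2 − 2 degrees of
freedom is computed; an inverse-chi-square prior (d0, s0²) is estimated by
moment-matching the distribution of log s² against a scaled-F model
(digamma/trigamma matching, with the trigamma inverse solved by damped
Newton iteration).  The posterior variance

    s̃² = (d0·s0² + d·s²) / (d0 + d)

replaces s² in the t-statistic, whose null distribution gains the prior
degrees of freedom: t ~ t(d0 + d).  Differential proteins are then called
at an FDR (Benjamini–Hochberg) and absolute log2-fold-change threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError
from .io import QuantMatrix


@dataclass(frozen=True)
class EBayesParams:
    """Shared variance prior: degrees of freedom d0 (may be inf) and s0²."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ValidationError("prior degrees of freedom d0 must be > 0")
        if not (np.isfinite(self.s0_sq) and self.s0_sq > 0):
            raise ValidationError("prior variance s0_sq must be finite and > 0")


class DiffExpResult(NamedTuple):
    params: EBayesParams
    records: pd.DataFrame  # protein, log2fc, s2, df, s2_post, t, p, fdr
    notes: list[str]


def trigamma_inverse(x: float, tol: float = 1e-8, max_iter: int = 50) -> float:
    """Solve ψ′(y) = x for y > 0 by damped Newton iteration.

    Uses the asymptotic inverses 1/x (x large ⇒ y small) and 1/sqrt(x)
    as guards, and the Newton update on the reciprocal scale, which is
    monotone and converges in a handful of iterations.
    """
    if x <= 0:
        raise ValidationError("trigamma_inverse needs a positive argument")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(max_iter):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) / y < tol:
            break
    return float(y)


def fit_f_dist(s2: np.ndarray, df: float) -> EBayesParams:
    """Moment-match log s² against a scaled-F model to estimate (d0, s0²).

    When the empirical spread of log s² does not exceed its pure sampling
    floor trigamma(df/2), the prior is degenerate: d0 = ∞ and s0² equals the
    (geometric-mean-based) common variance.
    """
    s2 = np.asarray(s2, dtype=float)
    if np.any(s2 <= 0):
        raise ValidationError("all variances must be positive at this stage")
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * trigamma_inverse(evar)
        s0_sq = float(np.exp(emean + special.digamma(d0 / 2.0)
                             - np.log(d0 / 2.0)))
    else:
        # degenerate prior: the common variance is the geometric mean of the
        # observed s², so identical s² collapse to the ordinary pooled t
        d0 = np.inf
        s0_sq = float(np.exp(np.mean(z)))
    return EBayesParams(d0=d0, s0_sq=s0_sq)


def moderated_stats(delta: np.ndarray, s2: np.ndarray, df: float,
                    n1: int, n2: int, params: EBayesParams,
                    ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Posterior variances, moderated t and two-sided p for given prior.

    Exposed separately so the d0 → 0 (ordinary t) and d0 → ∞ (pooled
    common variance, normal reference) limits can be evaluated directly.
    """
    delta = np.asarray(delta, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.isinf(params.d0):
        s2_post = np.full_like(s2, params.s0_sq)
        total_df = np.inf
    else:
        s2_post = (params.d0 * params.s0_sq + df * s2) / (params.d0 + df)
        total_df = params.d0 + df
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = delta / se
    if np.isinf(total_df):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), total_df)
    return s2_post, t, p


def fit_moderated_t(matrix: QuantMatrix,
                    group_labels: Sequence[str] | None = None,
                    reference: str | None = None) -> DiffExpResult:
    """Fit the two-group moderated-t model to a complete log2 matrix.

    ``group_labels`` (aligned to ``matrix.sample_ids``) defaults to the
    metadata ``culture_state`` column.  ``reference`` names the control
    level; the reported log2FC is other − reference (defaults to ``CTRL``
    when present, else the lexicographically first level).
    """
    if matrix.scale != "log2":
        raise ValidationError("fit_moderated_t expects a log2-scale matrix")
    if matrix.values.isna().any().any():
        raise ValidationError(
            "matrix contains missing values; filter and impute first")
    labels = pd.Series(
        list(group_labels) if group_labels is not None
        else matrix.meta.loc[matrix.sample_ids, "culture_state"].tolist(),
        index=matrix.sample_ids)
    levels = sorted(labels.unique())
    if len(levels) != 2:
        raise ValidationError(f"expected exactly two groups, got {levels}")
    if reference is None:
        reference = "CTRL" if "CTRL" in levels else levels[0]
    if reference not in levels:
        raise ValidationError(f"reference level {reference!r} not among {levels}")
    other = levels[0] if levels[1] == reference else levels[1]
    g_ref = labels.index[labels == reference]
    g_oth = labels.index[labels == other]
    n1, n2 = len(g_ref), len(g_oth)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each group needs at least 2 replicates")

    X_ref = matrix.values[g_ref].to_numpy(dtype=float)
    X_oth = matrix.values[g_oth].to_numpy(dtype=float)
    delta = X_oth.mean(axis=1) - X_ref.mean(axis=1)
    ss = (X_ref.var(axis=1, ddof=1) * (n1 - 1)
          + X_oth.var(axis=1, ddof=1) * (n2 - 1))
    df = float(n1 + n2 - 2)
    s2 = ss / df

    notes: list[str] = []
    zero = s2 <= 0
    if zero.all():
        raise ValidationError("all per-protein variances are zero")
    if zero.any():
        floor = float(s2[~zero].min()) * 1e-3
        s2 = np.where(zero, floor, s2)
        notes.append(f"{int(zero.sum())} zero-variance protein(s) floored "
                     f"to {floor:.3g} (smallest positive s² × 1e-3)")

    params = fit_f_dist(s2, df)
    s2_post, t, p = moderated_stats(delta, s2, df, n1, n2, params)
    fdr = bh_adjust(p)
    records = pd.DataFrame({
        "protein": matrix.protein_ids,
        "log2fc": delta,
        "s2": s2,
        "df": df,
        "s2_post": s2_post,
        "t": t,
        "p": p,
        "fdr": fdr,
    })
    return DiffExpResult(params=params, records=records, notes=notes)


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deps(records: pd.DataFrame, alpha: float = 0.05,
              fc_min: float = 0.5) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition significant records (FDR ≤ alpha, |log2FC| ≥ fc_min) by sign.

    Returns the up- and down-regulated differential proteins.  A
    ``significant`` column is added to ``records`` in place.
    """
    sig = (records["fdr"] <= alpha) & (records["log2fc"].abs() >= fc_min)
    records["significant"] = sig
    up = records[sig & (records["log2fc"] > 0)].copy()
    down = records[sig & (records["log2fc"] < 0)].copy()
    return up, down
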