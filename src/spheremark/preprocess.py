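"""Normalisation, log transform, presence filtering and EM imputation.

The differential-expression branch applies these in the fixed order
log-transform → presence filter → EM imputation; the marker-selection
branch needs only total-amount normalisation and the log transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigurationError, StateError, ValidationError
from .io import QuantMatrix


@dataclass
class PreprocessReport:
    """What a preprocessing step did, for provenance and QC.

    Only the fields relevant to the step that produced the report are
    populated; the rest stay at their defaults.
    """

    scale_factors: pd.Series | None = None
    n_removed: int = 0
    n_retained: int = 0
    n_zeros_to_missing: int = 0
    n_imputed: int = 0
    n_iterations: int = 0
    loglik_delta: float = float("nan")
    loglik_trace: list[float] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        out = {
            "n_removed": self.n_removed,
            "n_retained": self.n_retained,
            "n_zeros_to_missing": self.n_zeros_to_missing,
            "n_imputed": self.n_imputed,
            "n_iterations": self.n_iterations,
            "loglik_delta": self.loglik_delta,
            "warnings": list(self.warnings),
        }
        if self.scale_factors is not None:
            out["scale_factors"] = {k: float(v)
                                    for k, v in self.scale_factors.items()}
        return out


def normalize_total(matrix: QuantMatrix) -> tuple[QuantMatrix, PreprocessReport]:
    """Rescale each sample to the grand mean of sample totals.

    Emulates normalisation on the total peptide amount: each sample's
    non-missing column total is brought to the grand mean of all column
    totals, so relative within-sample structure is untouched.  Missing
    cells stay missing.  Idempotent: a second application yields unit
    factors.
    """
    if matrix.scale != "linear":
        raise StateError("normalize_total expects a linear-scale matrix")
    totals = matrix.values.sum(axis=0, skipna=True)
    counts = matrix.values.notna().sum(axis=0)
    empty = counts[counts == 0]
    if len(empty):
        raise ValidationError(
            f"sample(s) with no observed values: {list(empty.index)}")
    target = float(totals.mean())
    factors = target / totals
    scaled = matrix.values.mul(factors, axis=1)
    report = PreprocessReport(scale_factors=factors,
                              n_retained=matrix.values.shape[0])
    return matrix.copy_with(values=scaled), report


def log2_transform(matrix: QuantMatrix, pseudocount: float = 0.0,
                   ) -> tuple[QuantMatrix, PreprocessReport]:
    """log2(value + pseudocount); flips the scale flag to ``log2``.

    With pseudocount 0, zero intensities (non-identifications in isobaric
    data) become missing values and are counted in the report.
    """
    if matrix.scale == "log2":
        raise StateError("matrix is already on the log2 scale")
    if pseudocount < 0:
        raise ConfigurationError("pseudocount must be non-negative")
    shifted = matrix.values + pseudocount
    report = PreprocessReport(n_retained=matrix.values.shape[0])
    zero = shifted == 0
    n_zero = int(zero.sum().sum())
    if n_zero:
        shifted = shifted.mask(zero)
        report.n_zeros_to_missing = n_zero
        report.warnings.append(
            f"{n_zero} zero cell(s) converted to missing (log of zero undefined)")
    out = np.log2(shifted)
    return matrix.copy_with(values=out, scale="log2"), report


def filter_min_present(matrix: QuantMatrix, min_present: int = 2,
                       ) -> tuple[QuantMatrix, PreprocessReport]:
    """Keep proteins observed in at least ``min_present`` replicates of
    EVERY condition (condition = cell line × culture state)."""
    if min_present < 0:
        raise ConfigurationError("min_present must be non-negative")
    groups = matrix.meta.groupby(["cell_line", "culture_state"],
                                 observed=True).groups
    for key, sample_ids in groups.items():
        if min_present > len(sample_ids):
            raise ConfigurationError(
                f"min_present={min_present} exceeds the {len(sample_ids)} "
                f"replicates of condition {key}")
    keep = pd.Series(True, index=matrix.values.index)
    for sample_ids in groups.values():
        present = matrix.values[list(sample_ids)].notna().sum(axis=1)
        keep &= present >= min_present
    filtered = matrix.values.loc[keep]
    report = PreprocessReport(n_removed=int((~keep).sum()),
                              n_retained=int(keep.sum()))
    return matrix.copy_with(values=filtered), report


# ---------------------------------------------------------------------------
# EM imputation under a multivariate normal model over samples
# ---------------------------------------------------------------------------

def impute_em(matrix: QuantMatrix, tol: float = 1e-6, max_iter: int = 100,
              ) -> tuple[QuantMatrix, PreprocessReport]:
    """Maximum-likelihood imputation of missing log2 abundances by EM.

    Model: each protein's sample vector is an i.i.d. draw from a
    multivariate normal over the samples (dimensions = samples, observations
    = proteins), which is estimable because proteins vastly outnumber
    samples.  Missing cells are replaced by their conditional expectations
    given the observed cells under the fitted model; observed cells are
    never altered and the procedure involves no randomness.

    Convergence is declared when the relative change in observed-data
    log-likelihood drops below ``tol``.  A singular covariance triggers an
    automatic ridge (1e-6 × mean diagonal), noted in the report; hitting
    ``max_iter`` returns the best iterate with a warning.
    """
    if matrix.scale != "log2":
        raise StateError("impute_em expects a log2-scale matrix")
    X = matrix.values.to_numpy(dtype=float).copy()
    n, p = X.shape
    miss = np.isnan(X)
    report = PreprocessReport(n_retained=n, n_imputed=int(miss.sum()))
    if not miss.any():
        report.loglik_delta = 0.0
        return matrix.copy_with(values=matrix.values.copy()), report
    if np.any(miss.all(axis=1)):
        raise ValidationError("protein(s) with no observed values cannot be "
                              "imputed; apply filter_min_present first")

    # group rows by missingness pattern to vectorise the E-step
    pattern_codes = miss.dot(1 << np.arange(p))
    patterns: dict[int, np.ndarray] = {
        code: np.flatnonzero(pattern_codes == code)
        for code in np.unique(pattern_codes)
    }

    # init: observed column means; diagonal covariance from observed variances
    mu = np.nanmean(X, axis=0)
    var0 = np.nanvar(X, axis=0)
    var0[var0 <= 0] = max(float(np.max(var0)), 1.0) * 1e-3
    Sigma = np.diag(var0)
    Xc = X.copy()
    Xc[miss] = np.take(mu, np.where(miss)[1])

    ridge_used = False
    loglik_prev = -np.inf
    for it in range(1, max_iter + 1):
        Sigma_w, ridged = _ensure_pd(Sigma)
        ridge_used = ridge_used or ridged
        # E-step
        loglik = 0.0
        cond_cov = np.zeros((p, p))
        for code, rows in patterns.items():
            m = miss[rows[0]]
            o = ~m
            xo = X[np.ix_(rows, np.flatnonzero(o))]
            Soo = Sigma_w[np.ix_(np.flatnonzero(o), np.flatnonzero(o))]
            co, lower = linalg.cho_factor(Soo, lower=True)
            dev = xo - mu[o]
            solved = linalg.cho_solve((co, lower), dev.T)  # Soo^-1 (x-mu)^T
            logdet = 2.0 * float(np.sum(np.log(np.diag(co))))
            k = int(o.sum())
            loglik += float(
                -0.5 * (np.einsum("ij,ji->i", dev, solved).sum()
                        + len(rows) * (logdet + k * np.log(2.0 * np.pi))))
            if m.any():
                mi = np.flatnonzero(m)
                oi = np.flatnonzero(o)
                Smo = Sigma_w[np.ix_(mi, oi)]
                xm = mu[mi] + (Smo @ solved).T
                Xc[np.ix_(rows, mi)] = xm
                C = (Sigma_w[np.ix_(mi, mi)]
                     - Smo @ linalg.cho_solve((co, lower), Smo.T))
                cond_cov[np.ix_(mi, mi)] += len(rows) * C
        report.loglik_trace.append(loglik)
        # M-step
        mu = Xc.mean(axis=0)
        dev = Xc - mu
        Sigma = (dev.T @ dev + cond_cov) / n
        delta = loglik - loglik_prev
        report.n_iterations = it
        report.loglik_delta = delta
        if np.isfinite(loglik_prev) and abs(delta) <= tol * (1.0 + abs(loglik)):
            break
        loglik_prev = loglik
    else:
        report.warnings.append(
            f"EM did not converge in {max_iter} iterations "
            f"(last log-likelihood change {report.loglik_delta:.3g}); "
            "best iterate returned")
    if ridge_used:
        report.warnings.append(
            "singular covariance stabilised with ridge 1e-6 × mean diagonal")

    out = pd.DataFrame(Xc, index=matrix.values.index,
                       columns=matrix.values.columns)
    # observed cells are passed through untouched by construction
    return matrix.copy_with(values=out), report


def _ensure_pd(Sigma: np.ndarray) -> tuple[np.ndarray, bool]:
    """Return a Cholesky-factorable covariance, ridging if needed."""
    try:
        linalg.cho_factor(Sigma, lower=True)
        return Sigma, False
    except linalg.LinAlgError:
        ridge = 1e-6 * float(np.mean(np.diag(Sigma)))
        fixed = Sigma + ridge * np.eye(Sigma.shape[0])
        for _ in range(8):
            try:
                linalg.cho_factor(fixed, lower=True)
                return fixed, True
            except linalg.LinAlgError:
                ridge *= 10.0
                fixed = Sigma + ridge * np.eye(Sigma.shape[0])
        raise
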