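"""Interobserver statistics: random-intercept mixed model, LRT, SD summaries.

The commissioning question is whether a validation metric (MSD, DSC, a dose
statistic, ...) depends on contour type (automatic vs human). Per patient i and
contour j the model is

    y_ij = beta0 + beta1 * I(auto) + b_i + e_ij,
    b_i ~ N(0, sigma_b^2),  e_ij ~ N(0, sigma^2),

with patient as a random intercept. Both the full model and the reduced model
(without the contour-type effect) are fitted by *maximum likelihood* — not
REML — because the likelihood-ratio test of a fixed effect is only valid when
both fits maximise the same likelihood. The LRT statistic 2*(ll_full -
ll_reduced) is referred to chi-square(1).

Fitting profiles the likelihood over the variance ratio lambda =
sigma_b^2/sigma^2: for fixed lambda the GLS estimate of beta and the residual
variance are closed-form (Sherman–Morrison per patient block), leaving a 1-D
maximisation over lambda >= 0 that handles the sigma_b^2 = 0 boundary without
failure.

``observer_sd_summary`` reproduces the commissioning-table spread column: the
sample SD over manual observers computed per patient, then averaged over
patients.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import ParameterError, ValidationError

REQUIRED_COLUMNS = ("patient", "contour_type", "observer", "metric", "value")
_VAR_FLOOR = 1e-12  # residual-variance floor: degenerate zero-spread data fits at the boundary


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format metric table contract (one value per
    patient/observer/metric; contour_type in {manual, auto})."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"metric table missing columns {missing}")
    bad = set(table["contour_type"].unique()) - {"manual", "auto"}
    if bad:
        raise ValidationError(f"contour_type must be 'manual' or 'auto', found {sorted(bad)}")
    dup = table.duplicated(subset=["patient", "observer", "metric"])
    if dup.any():
        raise ValidationError("metric table has duplicate (patient, observer, metric) records")
    return table


@dataclass(frozen=True)
class LmmFit:
    """ML fit of the random-intercept model (a reduced fit has beta1=None)."""

    beta0: float
    beta1: float | None
    sigma_b: float
    sigma: float
    loglik: float
    n_obs: int
    n_patients: int
    method: str = "ML (profiled variance ratio)"

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (ML)",
            f"  observations: {self.n_obs}   patients: {self.n_patients}",
            f"  intercept (beta0):      {self.beta0: .6g}",
        ]
        if self.beta1 is not None:
            lines.append(f"  contour-type effect (beta1, auto - manual): {self.beta1: .6g}")
        lines += [
            f"  patient SD (sigma_b):   {self.sigma_b: .6g}",
            f"  residual SD (sigma):    {self.sigma: .6g}",
            f"  log-likelihood:         {self.loglik: .6g}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class LrtResult:
    statistic: float
    p_value: float
    df: int = 1


def _profile_loglik(lam: float, y_groups, x_groups):
    """Profiled ML log-likelihood at variance ratio lam, plus (beta, sigma2)."""
    p = x_groups[0].shape[1]
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet = 0.0
    n = 0
    for y_i, x_i in zip(y_groups, x_groups):
        n_i = y_i.size
        a_i = lam / (1.0 + n_i * lam)
        sx = x_i.sum(axis=0)
        sy = y_i.sum()
        xtvx += x_i.T @ x_i - a_i * np.outer(sx, sx)
        xtvy += x_i.T @ y_i - a_i * sx * sy
        ytvy += y_i @ y_i - a_i * sy * sy
        logdet += np.log1p(n_i * lam)
        n += n_i
    beta = np.linalg.solve(xtvx, xtvy)
    rss = max(ytvy - 2.0 * beta @ xtvy + beta @ xtvx @ beta, 0.0)
    sigma2 = max(rss / n, _VAR_FLOOR)
    ll = -0.5 * (n * np.log(2.0 * np.pi * sigma2) + logdet + n)
    return ll, beta, sigma2


def _fit_random_intercept(y: np.ndarray, x: np.ndarray, groups: np.ndarray):
    """Maximise the profiled likelihood over lam in [0, inf)."""
    uniq = np.unique(groups)
    y_groups = [y[groups == g] for g in uniq]
    x_groups = [x[groups == g] for g in uniq]

    def neg(log_lam: float) -> float:
        return -_profile_loglik(np.exp(log_lam), y_groups, x_groups)[0]

    # coarse grid over log-lambda, then local refinement; lam=0 evaluated exactly
    grid = np.linspace(-14.0, 8.0, 45)
    vals = [neg(t) for t in grid]
    best = int(np.argmin(vals))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg, bounds=(lo, hi), method="bounded", options={"xatol": 1e-10})
    candidates = [0.0, float(np.exp(res.x)), float(np.exp(grid[best]))]
    lls = [_profile_loglik(lam, y_groups, x_groups) for lam in candidates]
    k = int(np.argmax([ll for ll, _, _ in lls]))
    lam = candidates[k]
    ll, beta, sigma2 = lls[k]
    return beta, float(np.sqrt(lam * sigma2)), float(np.sqrt(sigma2)), float(ll), len(uniq)


def fit_lmm(table: pd.DataFrame, metric: str, use_type_effect: bool = True) -> LmmFit:
    """Fit the (full or reduced) random-intercept model for one metric.

    The full model carries the contour-type fixed effect (auto vs manual);
    the reduced model is intercept-only. Needs >= 2 patients.
    """
    validate_metric_table(table)
    sub = table[table["metric"] == metric]
    if sub.empty:
        raise ParameterError(f"no records for metric {metric!r}")
    patients = sub["patient"].to_numpy()
    if np.unique(patients).size < 2:
        raise ParameterError("mixed-model fit needs at least 2 patients")
    y = sub["value"].to_numpy(dtype=float)
    if use_type_effect:
        x = np.column_stack(
            [np.ones(len(sub)), (sub["contour_type"].to_numpy() == "auto").astype(float)]
        )
    else:
        x = np.ones((len(sub), 1))
    beta, sigma_b, sigma, ll, n_pat = _fit_random_intercept(y, x, patients)
    return LmmFit(
        beta0=float(beta[0]),
        beta1=float(beta[1]) if use_type_effect else None,
        sigma_b=sigma_b,
        sigma=sigma,
        loglik=ll,
        n_obs=len(sub),
        n_patients=n_pat,
    )


def lrt_contour_type(full: LmmFit, reduced: LmmFit) -> LrtResult:
    """Likelihood-ratio test of the contour-type effect: 2*(ll_f - ll_r) ~ chi2(1)."""
    if full.beta1 is None or reduced.beta1 is not None:
        raise ParameterError("pass the full fit (with type effect) first, the reduced fit second")
    if full.n_obs != reduced.n_obs:
        raise ParameterError("full and reduced fits must be on identical data")
    delta = full.loglik - reduced.loglik
    if delta < -1e-6:
        raise ParameterError(
            f"full-model likelihood below reduced ({delta:.3g}): optimisation failure"
        )
    statistic = max(2.0 * delta, 0.0)
    return LrtResult(statistic=statistic, p_value=float(stats.chi2.sf(statistic, df=1)))


def observer_sd_summary(table: pd.DataFrame, metric: str) -> float:
    """Mean over patients of the per-patient sample SD across manual observers.

    Patients with fewer than two manual observers are excluded with a warning.
    All manual observers are perfectly correlated -> 0.
    """
    validate_metric_table(table)
    sub = table[(table["metric"] == metric) & (table["contour_type"] == "manual")]
    if sub.empty:
        raise ParameterError(f"no manual records for metric {metric!r}")
    sds = []
    for patient, grp in sub.groupby("patient", sort=True):
        if len(grp) < 2:
            warnings.warn(
                f"patient {patient!r} has a single manual observer for {metric!r}; excluded",
                stacklevel=2,
            )
            continue
        sds.append(float(grp["value"].std(ddof=1)))
    if not sds:
        raise ParameterError(f"no patient has >= 2 manual observers for metric {metric!r}")
    return float(np.mean(sds))


def multiplicity_adjust(p_values, method: str = "holm") -> np.ndarray:
    """Bonferroni / Holm step-down adjustment (or 'none'); Holm dominates
    Bonferroni elementwise."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ParameterError("p-values must lie in [0, 1]")
    m = p.size
    if method == "none":
        return p.copy()
    if method == "bonferroni":
        return np.minimum(m * p, 1.0)
    if method == "holm":
        order = np.argsort(p, kind="stable")
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(running, 1.0)
        return adj
    raise ParameterError(f"unknown adjustment method {method!r}")
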