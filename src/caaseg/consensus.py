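"""STAPLE consensus: simultaneous truth and performance level estimation.

Given J binary rater masks d_j on one grid, STAPLE treats the unknown true
segmentation T as a latent per-voxel Bernoulli variable and each rater as a
noisy channel with sensitivity p_j = P(d_j=1 | T=1) and specificity
q_j = P(d_j=0 | T=0). EM alternates:

E-step:  W_i = a_i / (a_i + b_i), with
         a_i = gamma * prod_j p_j^{d_ij} (1-p_j)^{1-d_ij}
         b_i = (1-gamma) * prod_j (1-q_j)^{d_ij} q_j^{1-d_ij}

M-step:  p_j = sum_i W_i d_ij / sum_i W_i
         q_j = sum_i (1-W_i)(1-d_ij) / sum_i (1-W_i)

The incomplete-data log-likelihood sum_i log(a_i + b_i) is non-decreasing
across iterations. The foreground prior gamma is a global scalar, by default
the mean foreground fraction across raters.

For tractability the dense E/M computation is restricted to the union bounding
box dilated by a margin; voxels outside it are all-background for every rater
and therefore share a single analytic posterior, which is carried through the
E-step, M-step and log-likelihood exactly — the result equals a full-grid run
to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateInputError, GridMismatchError, ParameterError

_EPS = 1e-12
_PCLIP = 1e-7  # probabilities clamped to [_PCLIP, 1-_PCLIP] inside logs


@dataclass
class StapleResult:
    """Consensus probability map plus per-rater performance estimates."""

    probability: np.ndarray  # per-voxel P(T=1 | data), full grid
    sensitivity: np.ndarray  # p_j, shape (J,)
    specificity: np.ndarray  # q_j, shape (J,)
    prior: float  # gamma
    iterations: int
    converged: bool
    log_likelihood: list[float] = field(default_factory=list)


def _log(x: np.ndarray | float) -> np.ndarray:
    return np.log(np.clip(x, _PCLIP, 1.0 - _PCLIP))


def staple(
    masks: list[np.ndarray],
    prior: float | None = None,
    init_p: float = 0.99999,
    init_q: float = 0.99999,
    tol: float = 1e-7,
    max_iter: int = 100,
    spacing=(1.0, 1.0, 1.0),
    roi_margin_mm: float = 10.0,
) -> StapleResult:
    """Run STAPLE on >= 2 binary masks sharing one grid."""
    if len(masks) < 2:
        raise ParameterError("STAPLE needs at least 2 rater masks")
    shape = np.asarray(masks[0]).shape
    stack = []
    for m in masks:
        m = np.asarray(m)
        if m.shape != shape:
            raise GridMismatchError("all rater masks must share one grid")
        stack.append(m.astype(bool))
    union = np.logical_or.reduce(stack)
    if not union.any():
        raise DegenerateInputError("all rater masks are empty")

    # union bounding box dilated by the margin (in voxels per axis)
    spacing = np.asarray(spacing, dtype=float)
    margin = np.ceil(roi_margin_mm / spacing).astype(int)
    nz = np.argwhere(union)
    lo = np.maximum(nz.min(axis=0) - margin, 0)
    hi = np.minimum(nz.max(axis=0) + margin + 1, shape)
    roi = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    d = np.stack([m[roi].reshape(-1) for m in stack]).astype(np.float64)  # (J, N)
    J, n_roi = d.shape
    n_total = int(np.prod(shape))
    n_out = n_total - n_roi  # all-background voxels handled analytically

    if prior is None:
        prior = float(d.mean() * n_roi / n_total)  # mean foreground fraction over the full grid
    if not 0.0 < prior < 1.0:
        raise ParameterError(f"prior gamma must be in (0,1), got {prior}")

    p = np.full(J, float(init_p))
    q = np.full(J, float(init_q))
    w = np.full(n_roi, prior)
    w_out = prior
    ll_trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step (log domain)
        log_a = np.log(prior) + _log(1.0 - p).sum() + (_log(p) - _log(1.0 - p)) @ d
        log_b = np.log(1.0 - prior) + _log(q).sum() + (_log(1.0 - q) - _log(q)) @ d
        w_new = 1.0 / (1.0 + np.exp(log_b - log_a))
        la_out = np.log(prior) + _log(1.0 - p).sum()
        lb_out = np.log(1.0 - prior) + _log(q).sum()
        w_out_new = 1.0 / (1.0 + np.exp(lb_out - la_out))

        ll = float(np.logaddexp(log_a, log_b).sum() + n_out * np.logaddexp(la_out, lb_out))
        ll_trace.append(ll)

        delta = (np.abs(w_new - w).sum() + n_out * abs(w_out_new - w_out)) / n_total
        w, w_out = w_new, w_out_new

        # M-step (outside-ROI voxels: d=0, weight w_out each)
        sum_w = w.sum() + n_out * w_out
        sum_1mw = (1.0 - w).sum() + n_out * (1.0 - w_out)
        p = (d @ w) / max(sum_w, _EPS)
        q = ((1.0 - d) @ (1.0 - w) + n_out * (1.0 - w_out)) / max(sum_1mw, _EPS)

        if delta < tol:
            converged = True
            break

    prob = np.full(shape, w_out, dtype=np.float64)
    prob[roi] = w.reshape(tuple(int(b - a) for a, b in zip(lo, hi)))
    return StapleResult(
        probability=prob,
        sensitivity=p,
        specificity=q,
        prior=prior,
        iterations=it,
        converged=converged,
        log_likelihood=ll_trace,
    )


def binarize_consensus(result: StapleResult, threshold: float = 0.5) -> np.ndarray:
    """Threshold the consensus probability map; ties (W == threshold) are included."""
    if not 0.0 < threshold < 1.0:
        raise ParameterError(f"threshold must lie in (0,1), got {threshold}")
    return (result.probability >= threshold).astype(np.uint8)
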