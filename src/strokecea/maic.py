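"""Unanchored matching-adjusted indirect comparison (MAIC).

Individual patient data (IPD) from one trial are reweighted so that the
weighted summary statistics of chosen baseline covariates match the
published aggregate baseline of a comparator trial.  Weights are
exponential-tilting propensity weights ``w_i = exp(z_i · b)`` where ``z_i``
is the patient's centered covariate vector; the coefficient vector ``b``
minimises the convex objective

    Q(b) = sum_i exp(z_i · b)

whose stationarity condition is exactly the method-of-moments constraint:
the weighted mean of every centered column is zero.  The weighted day-90
mRS outcome distribution is then recomputed under the fitted weights.

Matching-target types:

* ``mean`` (continuous): column ``x - target``.
* ``proportion`` (binary): column ``indicator - target``.
* ``median``: column ``I[x <= target] - 0.5`` so that under the fitted
  weights half of the weighted sample lies at or below the target median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .params import MRSDistribution

__all__ = [
    "AggregateTarget",
    "MAICError",
    "MAICResult",
    "prepare_matching_matrix",
    "fit_maic_weights",
    "effective_sample_size",
    "weighted_outcome_distribution",
    "run_maic",
    "OUTCOME_COLUMN",
]

OUTCOME_COLUMN = "mrs_d90"


class MAICError(RuntimeError):
    """Raised when the matching problem is ill-posed or the solver fails."""


@dataclass
class AggregateTarget:
    """One matching target: covariate name, summary type, target value."""

    covariate: str
    kind: str          # "mean" | "proportion" | "median"
    value: float

    def __post_init__(self) -> None:
        if self.kind not in ("mean", "proportion", "median"):
            raise MAICError(f"{self.covariate}: unknown target kind {self.kind!r}")
        if self.kind == "proportion" and not 0.0 <= self.value <= 1.0:
            raise MAICError(f"{self.covariate}: proportion target {self.value} outside [0, 1]")


@dataclass
class MAICResult:
    weights: np.ndarray          # rescaled to mean 1
    coefficients: np.ndarray
    ess: float
    balance: pd.DataFrame        # covariate, kind, target, unweighted, weighted
    weighted_outcome: MRSDistribution


def prepare_matching_matrix(
    ipd: pd.DataFrame, targets: list[AggregateTarget]
) -> tuple[np.ndarray, list[str]]:
    """Build the centered design matrix Z whose weighted column means must vanish."""
    cols = []
    names = []
    for t in targets:
        if t.covariate not in ipd.columns:
            raise MAICError(f"matching covariate {t.covariate!r} not found in IPD")
        x = ipd[t.covariate].to_numpy(dtype=float)
        if np.isnan(x).any():
            raise MAICError(f"covariate {t.covariate!r} has missing values; complete cases required")
        if t.kind in ("mean", "proportion"):
            z = x - t.value
        else:  # median
            z = (x <= t.value).astype(float) - 0.5
        if np.ptp(z) == 0.0 and abs(z.mean()) > 1e-12:
            raise MAICError(
                f"covariate {t.covariate!r} is constant at an off-target value; moment unmatchable"
            )
        cols.append(z)
        names.append(t.covariate)
    if not cols:
        raise MAICError("no matching targets given")
    return np.column_stack(cols), names


def fit_maic_weights(
    z: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
) -> tuple[np.ndarray, np.ndarray]:
    """Solve for exponential-tilting weights with zero weighted column means.

    Damped Newton iteration on ``Q(b) = sum_i exp(z_i b)`` with analytic
    gradient ``Z' w`` and Hessian ``Z' diag(w) Z``; falls back to BFGS on a
    singular Hessian.  Returns ``(weights rescaled to mean 1, b)``.

    Raises :class:`MAICError` on non-convergence (including separation,
    where some moment is unattainable and ``b`` diverges).
    """
    z = np.asarray(z, dtype=float)
    if not np.isfinite(z).all():
        raise MAICError("non-finite values in the centered matching matrix")
    n, m = z.shape
    if n <= m:
        raise MAICError(f"need more patients ({n}) than matched moments ({m})")

    b = np.zeros(m)
    for _ in range(max_iter):
        w = np.exp(np.clip(z @ b, -700, 700))
        grad = z.T @ w
        gnorm = np.linalg.norm(grad, ord=np.inf) / max(w.sum(), 1e-300)
        if gnorm < tol:
            break
        hess = (z * w[:, None]).T @ z
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = None
        if step is None or not np.isfinite(step).all():
            res = minimize(
                lambda bb: np.exp(np.clip(z @ bb, -700, 700)).sum(),
                b, method="BFGS",
                jac=lambda bb: z.T @ np.exp(np.clip(z @ bb, -700, 700)),
                options={"gtol": tol, "maxiter": max_iter},
            )
            b = res.x
            break
        # damped Newton: halve until the objective decreases
        q0 = w.sum()
        lam = 1.0
        while lam > 1e-12:
            cand = b - lam * step
            if np.exp(np.clip(z @ cand, -700, 700)).sum() < q0:
                b = cand
                break
            lam /= 2.0
        else:
            if gnorm < 1e-8:   # at numerical precision; accept
                break
            raise MAICError(f"line search failed; gradient norm {gnorm:.3e}")
        if np.linalg.norm(b) > 1e4:
            raise MAICError(
                "coefficients diverging; a matched moment is likely unattainable (separation)"
            )
    w = np.exp(np.clip(z @ b, -700, 700))
    gnorm = np.linalg.norm(z.T @ w, ord=np.inf) / w.sum()
    if gnorm > 1e-8:
        raise MAICError(f"did not converge: weighted-moment gap {gnorm:.3e} after {max_iter} iterations")
    return w / w.mean(), b


def effective_sample_size(weights: np.ndarray) -> float:
    """Kish effective sample size ``(sum w)^2 / sum w^2``."""
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("negative weights")
    if w.sum() <= 0:
        raise ValueError("all weights are zero")
    w = w / w.max()   # scale invariance, avoids under/overflow in the squares
    return float(w.sum() ** 2 / (w * w).sum())


def weighted_outcome_distribution(
    ipd: pd.DataFrame, weights: np.ndarray, outcome: str = OUTCOME_COLUMN
) -> MRSDistribution:
    """Weighted day-90 mRS distribution under the given patient weights."""
    w = np.asarray(weights, dtype=float)
    if len(w) != len(ipd):
        raise ValueError(f"{len(w)} weights for {len(ipd)} patients")
    y = ipd[outcome].to_numpy(dtype=int)
    mass = np.bincount(y, weights=w, minlength=7)[:7]
    return MRSDistribution(mass / mass.sum())


def run_maic(ipd: pd.DataFrame, targets: list[AggregateTarget]) -> MAICResult:
    """Full unanchored MAIC: weights, ESS, balance table, reweighted outcome."""
    z, names = prepare_matching_matrix(ipd, targets)
    weights, b = fit_maic_weights(z)
    rows = []
    for t in targets:
        x = ipd[t.covariate].to_numpy(dtype=float)
        if t.kind == "median":
            raw = float((x <= t.value).mean())
            wtd = float(np.average(x <= t.value, weights=weights))
            tgt = 0.5
        else:
            raw = float(x.mean())
            wtd = float(np.average(x, weights=weights))
            tgt = t.value
        rows.append({"covariate": t.covariate, "kind": t.kind, "target": tgt,
                     "unweighted": raw, "weighted": wtd, "gap": wtd - tgt})
    return MAICResult(
        weights=weights,
        coefficients=b,
        ess=effective_sample_size(weights),
        balance=pd.DataFrame(rows),
        weighted_outcome=weighted_outcome_distribution(ipd, weights),
    )
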