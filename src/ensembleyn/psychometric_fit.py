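"""Log-logistic psychometric fits and BIC model comparison.

Each participant's p(No)-by-distance curve is fitted twice: once with
trials classified by ordinal distance from the mean (the perceptual
averaging account) and once by distance from the nearest old item (the
similarity account).  The two fits are compared by BIC; the scheme with
the lower BIC is the better-supported classification.

The psychometric function is the three-parameter log-logistic

    p(No; x) = a + (1 - a) / (1 + exp(b - c*x))

with ``a`` in [0, 1] the floor rejection rate, ``b`` a location parameter
and ``c`` >= 0 the slope over ordinal distance ``x``.  p(Yes) is its
complement.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize

from .descriptives import FROM_MEAN, FROM_OLD, SCHEMES, condition_table

logger = logging.getLogger(__name__)

#: Bounds of the parameter box used by the bounded local searches.
PARAM_BOUNDS = ((0.0, 1.0), (-20.0, 20.0), (0.0, 20.0))

#: Fixed coarse grid of starting points (4 x 4 x 4), chosen once; the fit
#: is deterministic given the data.
START_GRID_A = np.linspace(0.0, 0.6, 4)
START_GRID_B = np.linspace(-2.0, 6.0, 4)
START_GRID_C = np.linspace(0.1, 4.0, 4)

_EXP_CLIP = 500.0


def loglogistic(x, a: float, b: float, c: float):
    """p(No) at ordinal distance ``x`` for parameters (a, b, c).

    Vectorized over ``x``; the exponent is clipped so extreme parameters
    saturate instead of overflowing.
    """
    x = np.asarray(x, dtype=float)
    z = np.clip(b - c * x, -_EXP_CLIP, _EXP_CLIP)
    out = a + (1.0 - a) / (1.0 + np.exp(z))
    return out if out.ndim else float(out)


def loglogistic_yes(x, a: float, b: float, c: float):
    """p(Yes) complement of :func:`loglogistic`."""
    return 1.0 - loglogistic(x, a, b, c)


@dataclass
class FitResult:
    """One participant's log-logistic fit under one classificatory scheme."""

    participant_id: str
    scheme: str
    a: float
    b: float
    c: float
    rss: float
    r_squared: float
    bic: float
    n_points: int
    converged: bool
    degenerate: bool = False

    @property
    def params(self) -> Tuple[float, float, float]:
        return (self.a, self.b, self.c)


def _objective_grid(x: np.ndarray, p: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted RSS on the full start grid, vectorized (64 x n)."""
    aa, bb, cc = np.meshgrid(START_GRID_A, START_GRID_B, START_GRID_C, indexing="ij")
    abc = np.stack([aa.ravel(), bb.ravel(), cc.ravel()], axis=1)
    z = np.clip(abc[:, 1:2] - abc[:, 2:3] * x[None, :], -_EXP_CLIP, _EXP_CLIP)
    pred = abc[:, 0:1] + (1.0 - abc[:, 0:1]) / (1.0 + np.exp(z))
    rss = ((pred - p[None, :]) ** 2 * w[None, :]).sum(axis=1)
    return abc, rss


def fit_curve(
    x: Sequence[float],
    p_no: Sequence[float],
    weights: Optional[Sequence[float]] = None,
    n_local_starts: int = 8,
) -> Tuple[Tuple[float, float, float], float, bool]:
    """Bounded weighted least-squares fit of the log-logistic.

    Starting points come from a fixed 4x4x4 coarse grid over (a, b, c); the
    ``n_local_starts`` best grid points seed bounded L-BFGS-B searches and
    the best local optimum wins.  Returns ``((a, b, c), weighted_rss,
    converged)``.  Deterministic given the data.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p_no, dtype=float)
    if weights is None:
        w = np.ones_like(p)
    else:
        w = np.asarray(weights, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 categories with data to fit 3 parameters")
    w = w / w.sum()

    abc, grid_rss = _objective_grid(x, p, w)
    order = np.argsort(grid_rss, kind="stable")[:n_local_starts]

    def objective(theta: np.ndarray) -> float:
        pred = loglogistic(x, *theta)
        return float(((pred - p) ** 2 * w).sum())

    best_theta, best_rss, converged = abc[order[0]], grid_rss[order[0]], False
    for idx in order:
        res = optimize.minimize(
            objective,
            abc[idx],
            method="L-BFGS-B",
            bounds=PARAM_BOUNDS,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 200},
        )
        if res.fun < best_rss - 1e-15 or (res.success and not converged and res.fun <= best_rss + 1e-12):
            best_theta, best_rss = res.x, float(res.fun)
            converged = converged or bool(res.success)
    return (float(best_theta[0]), float(best_theta[1]), float(best_theta[2])), best_rss, converged


def bic_gaussian(rss: float, n: int, k: int = 3) -> float:
    """Least-squares BIC: ``n*ln(RSS/n) + k*ln(n)``.

    An exactly-zero RSS returns ``-inf`` (logged) rather than raising.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if rss <= 0.0:
        logger.warning("BIC of a zero-RSS fit is -inf (n=%d)", n)
        return -math.inf
    return n * math.log(rss / n) + k * math.log(n)


def bic_binomial(k_no: Sequence[int], n_trials: Sequence[int], p_model: Sequence[float], k: int = 3) -> float:
    """Binomial-likelihood BIC variant on category counts.

    ``-2*logL + k*ln(N)`` with ``N`` the total trial count; model
    probabilities are clipped away from 0/1 to keep the likelihood finite.
    """
    k_no = np.asarray(k_no, dtype=float)
    n_tr = np.asarray(n_trials, dtype=float)
    p = np.clip(np.asarray(p_model, dtype=float), 1e-9, 1.0 - 1e-9)
    ll = float((k_no * np.log(p) + (n_tr - k_no) * np.log(1.0 - p)).sum())
    return -2.0 * ll + k * math.log(float(n_tr.sum()))


def fit(
    table: pd.DataFrame,
    scheme: str,
    weight_by_counts: bool = True,
    bic_variant: str = "gaussian",
    n_local_starts: int = 8,
) -> FitResult:
    """Fit one participant's condition table under one scheme.

    ``table`` is a condition table as produced by
    :func:`ensembleyn.descriptives.condition_table` for a single
    participant (columns ``x``, ``n_trials``, ``n_no``, ``p_no``).  Rows
    sharing an ``x`` value (M and N1 under the from-old scheme) are pooled
    by their trial counts before fitting, following the "N1 & Mean"
    category of the similarity classification.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme: {scheme!r}")
    pooled = (
        table.groupby("x", as_index=False)
        .agg(n_trials=("n_trials", "sum"), n_no=("n_no", "sum"))
        .sort_values("x")
    )
    pooled["p_no"] = pooled["n_no"] / pooled["n_trials"]
    x = pooled["x"].to_numpy(dtype=float)
    p = pooled["p_no"].to_numpy(dtype=float)
    n_tr = pooled["n_trials"].to_numpy(dtype=float)
    w = n_tr if weight_by_counts else None

    (a, b, c), _, converged = fit_curve(x, p, weights=w, n_local_starts=n_local_starts)
    pred = loglogistic(x, a, b, c)
    rss = float(((pred - p) ** 2).sum())
    tss = float(((p - p.mean()) ** 2).sum())
    r_squared = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else -math.inf)
    degenerate = c <= PARAM_BOUNDS[2][0] + 1e-9 or tss == 0.0
    if bic_variant == "gaussian":
        bic = bic_gaussian(rss, len(x))
    elif bic_variant == "binomial":
        bic = bic_binomial(pooled["n_no"], pooled["n_trials"], pred)
    else:
        raise ValueError(f"unknown BIC variant: {bic_variant!r}")
    pid = table["participant_id"].iloc[0] if "participant_id" in table else ""
    return FitResult(
        participant_id=str(pid),
        scheme=scheme,
        a=a,
        b=b,
        c=c,
        rss=rss,
        r_squared=r_squared,
        bic=bic,
        n_points=len(x),
        converged=converged,
        degenerate=degenerate,
    )


def fit_all(
    trials: pd.DataFrame,
    schemes: Iterable[str] = (FROM_MEAN, FROM_OLD),
    bic_variant: str = "gaussian",
    n_local_starts: int = 8,
) -> pd.DataFrame:
    """Fit every participant under each scheme; tidy one-row-per-fit frame."""
    rows = []
    for pid, sub in trials.groupby("participant_id", sort=True):
        for scheme in schemes:
            tab = condition_table(sub, scheme)
            res = fit(tab, scheme, bic_variant=bic_variant, n_local_starts=n_local_starts)
            res.participant_id = str(pid)
            rows.append(res.__dict__.copy())
    return pd.DataFrame(rows)


def compare_schemes(fits: pd.DataFrame, r_scale: float = math.sqrt(2) / 2):
    """Paired test on per-participant BIC values, from-mean minus from-old.

    A negative mean difference favours the averaging classification, a
    positive one the similarity classification.  Returns the
    :class:`~ensembleyn.inference.TestResult` plus a per-scheme summary
    frame (mean BIC and mean r^2).
    """
    from .inference import paired_t

    wide_bic = fits.pivot(index="participant_id", columns="scheme", values="bic")
    missing = wide_bic.isna().any(axis=1)
    if missing.any():
        raise ValueError(
            f"both schemes must be fitted for every participant; missing for "
            f"{list(wide_bic.index[missing])}"
        )
    result = paired_t(
        wide_bic[FROM_MEAN].to_numpy(),
        wide_bic[FROM_OLD].to_numpy(),
        label="BIC(from_mean) - BIC(from_old)",
        bayes_factor=True,
        r_scale=r_scale,
    )
    summary = (
        fits.groupby("scheme")
        .agg(mean_bic=("bic", "mean"), mean_r_squared=("r_squared", "mean"))
        .reset_index()
    )
    return result, summary
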