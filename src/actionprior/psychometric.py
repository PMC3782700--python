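"""Maximum-likelihood cumulative-Gaussian psychometric fitting.

Responses are tabulated per contrast level into (n_trials, n_downward)
counts; the psychometric function

    P(down | x) = lapse/2 + (1 - lapse) * Phi((x - pse) / slope_sd)

is fitted by maximising the binomial log-likelihood. The PSE is the
location parameter (50% "downward" point, lapse = 0); the slope is the SD
of the cumulative Gaussian. Optimisation uses a fixed deterministic
multi-start so fits carry no RNG state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

__all__ = [
    "ResponseTable",
    "PsychometricFit",
    "tabulate_responses",
    "fit_cumulative_gaussian",
    "pse_difference",
]

_PCLIP = 1e-10  # probability floor to keep the log-likelihood finite
_MAX_LAPSE = 0.06


@dataclass(frozen=True)
class ResponseTable:
    """Per-level response counts for one observer x condition."""

    levels: tuple
    n_trials: tuple
    n_downward: tuple

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        nt = np.asarray(self.n_trials, dtype=int)
        nd = np.asarray(self.n_downward, dtype=int)
        if not (lv.size == nt.size == nd.size):
            raise ValueError("levels, n_trials and n_downward must align")
        if not np.all(np.diff(lv) > 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(nd < 0) or np.any(nd > nt):
            raise ValueError("need 0 <= n_downward <= n_trials at every level")

    @property
    def total(self) -> int:
        return int(np.sum(self.n_trials))

    def proportions(self) -> np.ndarray:
        nt = np.asarray(self.n_trials, dtype=float)
        with np.errstate(invalid="ignore"):
            return np.asarray(self.n_downward) / nt


@dataclass(frozen=True)
class PsychometricFit:
    """Fitted cumulative-Gaussian parameters with diagnostics.

    ``pse`` is the 50% point, ``slope_sd`` the Gaussian SD (smaller = steeper),
    ``lapse`` the fitted (or fixed) lapse rate. ``reliable`` is False when the
    PSE falls outside the tested level range.
    """

    pse: float
    slope_sd: float
    lapse: float
    loglik: float
    converged: bool
    n_total: int
    reliable: bool = True


def tabulate_responses(trials: pd.DataFrame, condition: str | None = None) -> ResponseTable:
    """Aggregate trial records into per-level (n_trials, n_downward) counts.

    ``trials`` must carry ``downward_contrast`` and ``response`` columns
    (response coded 0 = upward, 1 = downward); an optional
    ``bias_condition`` filter selects one condition first. Counts are
    conserved and the result is invariant to trial order.
    """
    if "response" not in trials.columns:
        raise ValueError("trial table missing required column 'response'")
    if "downward_contrast" not in trials.columns:
        raise ValueError("trial table missing required column 'downward_contrast'")
    df = trials
    if condition is not None:
        df = df[df["bias_condition"] == condition]
    if df.empty:
        raise ValueError(f"no trials left after filtering (condition={condition!r})")
    grouped = df.groupby("downward_contrast")["response"].agg(["count", "sum"]).sort_index()
    return ResponseTable(
        levels=tuple(float(x) for x in grouped.index),
        n_trials=tuple(int(x) for x in grouped["count"]),
        n_downward=tuple(int(x) for x in grouped["sum"]),
    )


def _predicted(levels, pse, slope_sd, lapse):
    core = norm.cdf((levels - pse) / slope_sd)
    return lapse / 2 + (1 - lapse) * core


def _neg_loglik(params, levels, nt, nd, lapse_fixed):
    if lapse_fixed is None:
        pse, slope_sd, lapse = params
    else:
        pse, slope_sd = params
        lapse = lapse_fixed
    p = np.clip(_predicted(levels, pse, slope_sd, lapse), _PCLIP, 1 - _PCLIP)
    return -float(np.sum(nd * np.log(p) + (nt - nd) * np.log1p(-p)))


def _neg_ls(params, levels, nt, nd, lapse_fixed):
    # least-squares on proportions, trial-count weighted (sensitivity mode)
    if lapse_fixed is None:
        pse, slope_sd, lapse = params
    else:
        pse, slope_sd = params
        lapse = lapse_fixed
    p = _predicted(levels, pse, slope_sd, lapse)
    obs = nd / nt
    return float(np.sum(nt * (obs - p) ** 2))


def fit_cumulative_gaussian(
    table: ResponseTable,
    lapse_mode: str = "fixed",
    method: str = "ml",
) -> PsychometricFit:
    """Fit the psychometric function to a response table.

    Parameters
    ----------
    table
        Per-level counts; needs >= 3 informative levels and non-constant
        responses.
    lapse_mode
        ``"fixed"`` (lapse pinned at 0, the default) or ``"free"`` (lapse
        estimated within [0, 0.06]).
    method
        ``"ml"`` for binomial maximum likelihood (default) or ``"ls"`` for
        trial-weighted least squares on proportions (sensitivity check).

    The optimiser runs from a fixed 3x3 grid of starting values spanning the
    level range, so the fit is deterministic. A failed optimisation returns
    ``converged=False`` rather than raising; statistically degenerate input
    (all responses identical) raises ``ValueError``.
    """
    if lapse_mode not in ("fixed", "free"):
        raise ValueError(f"unknown lapse_mode {lapse_mode!r}")
    if method not in ("ml", "ls"):
        raise ValueError(f"unknown method {method!r}")
    levels = np.asarray(table.levels, dtype=float)
    nt = np.asarray(table.n_trials, dtype=float)
    nd = np.asarray(table.n_downward, dtype=float)
    keep = nt > 0
    levels, nt, nd = levels[keep], nt[keep], nd[keep]
    if levels.size < 3:
        raise ValueError("need at least 3 levels with trials to fit")
    if nd.sum() == 0 or nd.sum() == nt.sum():
        raise ValueError("responses are all identical; psychometric fit is non-identifiable")

    span = levels[-1] - levels[0]
    lapse_fixed = 0.0 if lapse_mode == "fixed" else None
    objective = _neg_loglik if method == "ml" else _neg_ls
    args = (levels, nt, nd, lapse_fixed)

    pse_starts = np.quantile(levels, [0.25, 0.5, 0.75])
    slope_starts = span * np.array([0.1, 0.3, 0.8])
    bounds = [(levels[0] - span, levels[-1] + span), (1e-4 * span, 10 * span)]
    if lapse_fixed is None:
        bounds.append((0.0, _MAX_LAPSE))

    best = None
    for p0 in pse_starts:
        for s0 in slope_starts:
            x0 = [p0, s0] if lapse_fixed is not None else [p0, s0, 0.01]
            res = minimize(objective, x0, args=args, method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res

    if lapse_fixed is None:
        pse, slope_sd, lapse = best.x
    else:
        (pse, slope_sd), lapse = best.x, lapse_fixed
    loglik = -_neg_loglik(
        best.x if lapse_fixed is None else [pse, slope_sd], levels, nt, nd, lapse_fixed
    )
    return PsychometricFit(
        pse=float(pse),
        slope_sd=float(slope_sd),
        lapse=float(lapse),
        loglik=float(loglik),
        converged=bool(best.success and slope_sd > 0),
        n_total=int(nt.sum()),
        reliable=bool(levels[0] <= pse <= levels[-1]),
    )


def pse_difference(fit_up: PsychometricFit, fit_down: PsychometricFit) -> float:
    """Per-observer PSE effect: downward-bias PSE minus upward-bias PSE.

    Under prior learning the shift is repulsive — the upward-bias PSE sits
    above 0.5 and the downward-bias PSE below — so this difference is
    *negative* when learning occurred.
    """
    for name, fit in (("fit_up", fit_up), ("fit_down", fit_down)):
        if not fit.converged:
            raise ValueError(f"{name} did not converge; PSE difference undefined")
    return float(fit_down.pse - fit_up.pse)
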