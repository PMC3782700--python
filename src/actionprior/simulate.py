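"""Synthetic observers: generative model for Experiments 1-3.

Each simulated observer carries a sensory noise SD, a learning weight
lambda in [0, 1] (how much of the key-associated contrast prior has been
acquired; lambda=1 is the full Bayesian observer, lambda=0 a prior-free
observer), and a lapse rate. On each trial the observer draws a noisy
measurement of the presented contrast, forms the lambda-attenuated
posterior estimate, and responds "downward" iff the estimate exceeds 0.5
(exact ties: fair coin; with probability lapse the response is replaced by
a uniform coin flip).

Cohorts mirror the experiments' structure: 10 observers, 400-trial
sessions (200 per key), key-to-bias counterbalance reversed for half the
cohort, prior SD 0.06 (Experiments 1 and 3) or 0.15 (Experiment 2), and a
2-s action-outcome delay flag in Experiment 3. Learning is modelled as
asymptotic: a static attenuated prior for the whole session.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .design import (
    PriorSpec,
    SessionPlan,
    build_level_grid,
    build_session,
    discretize_gaussian,
    session_to_frame,
)
from .ideal import posterior_estimate, IdealObserver

__all__ = [
    "SimObserverParams",
    "SimCohortConfig",
    "EXPERIMENT_DEFAULTS",
    "simulate_trial",
    "simulate_session",
    "simulate_cohort",
    "build_experiment_plan",
]

#: Study conditions per experiment: prior SD, action-outcome delay, and the
#: default learning weight used to emulate each experiment's outcome.
#: Experiments 1-2 assume full acquisition (lambda=1); the Experiment-3 delay
#: has no mechanistic model here and is emulated by a strongly attenuated
#: lambda=0.1 by default — a modelling choice, not an empirical claim.
EXPERIMENT_DEFAULTS = {
    1: {"prior_sd": 0.06, "delay_s": 0.0, "learning_weight": 1.0},
    2: {"prior_sd": 0.15, "delay_s": 0.0, "learning_weight": 1.0},
    3: {"prior_sd": 0.06, "delay_s": 2.0, "learning_weight": 0.1},
}

#: Standard design constants shared by all three experiments.
MEAN_OFFSET = 0.06
GRID_STEP = 0.03
N_LEVELS = 11
TRIALS_PER_KEY = 200
KEYS = ("Z", "M")


@dataclass(frozen=True)
class SimObserverParams:
    """Parameters of one simulated observer."""

    sensory_sd: float
    learning_weight: float = 1.0
    lapse: float = 0.0
    key_mapping_reversed: bool = False
    seed: int = 0

    def __post_init__(self):
        if not self.sensory_sd > 0:
            raise ValueError("sensory_sd must be positive")
        if not 0.0 <= self.learning_weight <= 1.0:
            raise ValueError("learning_weight must lie in [0, 1]")
        if not 0.0 <= self.lapse < 0.5:
            raise ValueError("lapse must lie in [0, 0.5)")


@dataclass(frozen=True)
class SimCohortConfig:
    """Configuration of a simulated cohort for one experiment.

    ``sensory_sd_range`` induces between-observer spread; lapse and learning
    weight are shared across the cohort unless overridden. ``free_key_choice``
    replaces the exact 200-per-key balance with per-trial Bernoulli(0.5) key
    choice (contrasts then sampled from each key's prior with replacement) for
    sensitivity analyses.
    """

    n_observers: int = 10
    experiment: int = 1
    sensory_sd_range: tuple = (0.04, 0.09)
    learning_weight: float | None = None  # None -> experiment default
    lapse: float = 0.0
    master_seed: int = 0
    free_key_choice: bool = False

    def __post_init__(self):
        if self.n_observers < 1:
            raise ValueError("n_observers must be >= 1")
        if self.experiment not in EXPERIMENT_DEFAULTS:
            raise ValueError(f"experiment must be one of {sorted(EXPERIMENT_DEFAULTS)}")

    @property
    def prior_sd(self) -> float:
        return EXPERIMENT_DEFAULTS[self.experiment]["prior_sd"]

    @property
    def delay_s(self) -> float:
        return EXPERIMENT_DEFAULTS[self.experiment]["delay_s"]

    @property
    def effective_learning_weight(self) -> float:
        if self.learning_weight is not None:
            return self.learning_weight
        return EXPERIMENT_DEFAULTS[self.experiment]["learning_weight"]


def experiment_priors(prior_sd: float) -> dict:
    """Upward- and downward-bias prior specs at a given prior SD."""
    return {
        "upward": PriorSpec(-MEAN_OFFSET, prior_sd, "upward"),
        "downward": PriorSpec(+MEAN_OFFSET, prior_sd, "downward"),
    }


def build_experiment_plan(
    prior_sd: float,
    delay_s: float,
    seed: int,
    key_mapping_reversed: bool = False,
) -> tuple[SessionPlan, dict]:
    """Build the standard 400-trial session plan and its key->prior mapping."""
    priors = experiment_priors(prior_sd)
    conditions = ("upward", "downward")
    if key_mapping_reversed:
        conditions = conditions[::-1]
    schedules = []
    for key, cond in zip(KEYS, conditions):
        prior = priors[cond]
        grid = build_level_grid(prior.mean_offset, GRID_STEP, N_LEVELS)
        schedules.append(
            discretize_gaussian(grid, prior, TRIALS_PER_KEY, condition=cond, key=key)
        )
    plan = build_session(schedules, delay_s=delay_s, seed=seed)
    key_priors = {key: priors[cond] for key, cond in zip(KEYS, conditions)}
    return plan, key_priors


def _responses(contrasts: np.ndarray, params: SimObserverParams, prior: PriorSpec,
               rng: np.random.Generator) -> np.ndarray:
    observer = IdealObserver(prior.mean, prior.sd, params.sensory_sd)
    m = rng.normal(contrasts, params.sensory_sd)
    est = np.asarray(posterior_estimate(m, observer, params.learning_weight))
    resp = est > 0.5
    ties = est == 0.5
    if np.any(ties):
        resp = resp | (ties & (rng.random(ties.shape) < 0.5))
    if params.lapse > 0:
        lapsed = rng.random(contrasts.shape) < params.lapse
        resp = np.where(lapsed, rng.integers(0, 2, size=contrasts.shape).astype(bool), resp)
    return resp.astype(int)


def simulate_trial(
    contrast: float,
    params: SimObserverParams,
    prior: PriorSpec,
    rng: np.random.Generator | None = None,
) -> int:
    """Simulate one 2AFC response (0 = upward, 1 = downward) at a contrast."""
    if not 0 < contrast < 1:
        raise ValueError("contrast must lie in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(params.seed)
    return int(_responses(np.asarray([contrast]), params, prior, rng)[0])


def simulate_session(
    plan: SessionPlan,
    params: SimObserverParams,
    priors: dict,
) -> pd.DataFrame:
    """Simulate every trial of a session plan.

    ``priors`` maps each response key to the PriorSpec the observer acquired
    for that key. Returns the session frame with a ``response`` column
    appended; reproducible given ``params.seed``. The recorded delay acts only
    through the learning weight supplied by the caller.
    """
    df = session_to_frame(plan)
    rng = np.random.default_rng(params.seed)
    response = np.empty(len(df), dtype=int)
    # one vectorized draw per key keeps the trial-level RNG stream reproducible
    for key in sorted(priors):
        mask = (df["key"] == key).to_numpy()
        response[mask] = _responses(
            df.loc[mask, "downward_contrast"].to_numpy(), params, priors[key], rng
        )
    df["response"] = response
    return df


def _free_choice_session(
    delay_s: float,
    params: SimObserverParams,
    key_priors: dict,
    n_trials: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Session with Bernoulli key choice; contrasts sampled from the priors."""
    keys = sorted(key_priors)
    key_idx = rng.integers(0, len(keys), size=n_trials)
    rows = []
    for i in range(n_trials):
        key = keys[key_idx[i]]
        prior = key_priors[key]
        grid = build_level_grid(prior.mean_offset, GRID_STEP, N_LEVELS)
        sched = discretize_gaussian(grid, prior, TRIALS_PER_KEY, condition=prior.label, key=key)
        probs = np.asarray(sched.counts) / sched.total
        contrast = rng.choice(grid.as_array(), p=probs)
        rows.append((i, key, prior.label, float(contrast), delay_s))
    df = pd.DataFrame(
        rows, columns=["trial_index", "key", "bias_condition", "downward_contrast", "delay_s"]
    )
    response = np.empty(len(df), dtype=int)
    for key in keys:
        mask = (df["key"] == key).to_numpy()
        response[mask] = _responses(
            df.loc[mask, "downward_contrast"].to_numpy(), params, key_priors[key], rng
        )
    df["response"] = response
    return df


def simulate_cohort(config: SimCohortConfig) -> tuple[pd.DataFrame, list]:
    """Simulate a full cohort for one experiment.

    Returns ``(trials, manifest)``: a long trial table with an
    ``observer_id`` column, and a per-observer manifest (parameters and
    derived seeds). Sensory SDs are drawn uniformly from the configured
    range; observer seeds derive deterministically from ``master_seed``; the
    key-to-bias mapping is reversed for every other observer
    (counterbalance).
    """
    master = np.random.default_rng(config.master_seed)
    lam = config.effective_learning_weight
    frames, manifest = [], []
    for i in range(config.n_observers):
        sd = float(master.uniform(*config.sensory_sd_range))
        seed = int(master.integers(0, 2**31 - 1))
        plan_seed = int(master.integers(0, 2**31 - 1))
        params = SimObserverParams(
            sensory_sd=sd,
            learning_weight=lam,
            lapse=config.lapse,
            key_mapping_reversed=bool(i % 2),
            seed=seed,
        )
        if config.free_key_choice:
            _, key_priors = build_experiment_plan(
                config.prior_sd, config.delay_s, plan_seed, params.key_mapping_reversed
            )
            df = _free_choice_session(
                config.delay_s, params, key_priors,
                2 * TRIALS_PER_KEY, np.random.default_rng(seed),
            )
        else:
            plan, key_priors = build_experiment_plan(
                config.prior_sd, config.delay_s, plan_seed, params.key_mapping_reversed
            )
            df = simulate_session(plan, params, key_priors)
        df.insert(0, "observer_id", i)
        frames.append(df)
        manifest.append(
            {
                "observer_id": i,
                "experiment": config.experiment,
                "sensory_sd": sd,
                "learning_weight": lam,
                "lapse": config.lapse,
                "key_mapping_reversed": bool(i % 2),
                "seed": seed,
                "plan_seed": plan_seed,
            }
        )
    return pd.concat(frames, ignore_index=True), manifest


def simulate_calibration(
    params: SimObserverParams,
    n_trials: int = TRIALS_PER_KEY,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a neutral (unbiased-prior, lambda=0) calibration block.

    Used to estimate an observer's sensory SD from a psychometric fit, the
    way per-observer ideal predictions are anchored. The block uses the
    symmetric grid centred on 0.5 with a narrow generating Gaussian.
    """
    neutral = PriorSpec(0.0, 0.06, "neutral")
    grid = build_level_grid(0.0, GRID_STEP, N_LEVELS)
    sched = discretize_gaussian(grid, neutral, n_trials, condition="neutral", key="C")
    plan = build_session([sched], delay_s=0.0, seed=params.seed if seed is None else seed)
    flat = replace(params, learning_weight=0.0)
    return simulate_session(plan, flat, {"C": neutral})
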