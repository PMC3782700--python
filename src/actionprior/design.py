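"""Experimental design: contrast grids, discretized Gaussian priors, sessions.

The experiments use the method of constant stimuli over an 11-level grid of
downward-grating contrasts. Each response key is associated with a Gaussian
"prior" distribution over that grid (mean displaced from 0.5 by +/-0.06,
SD 0.06 or 0.15), realised as exact per-level trial counts within a
200-trial condition. A session interleaves the two conditions in a seeded
random order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PriorSpec",
    "LevelGrid",
    "TrialSchedule",
    "SessionPlan",
    "StimulusMetadata",
    "build_level_grid",
    "discretize_gaussian",
    "build_session",
    "stimulus_metadata",
    "session_to_frame",
    "read_session_csv",
    "write_session_csv",
]

#: Columns of the session-plan CSV schema.
SESSION_COLUMNS = ["trial_index", "key", "bias_condition", "downward_contrast", "delay_s"]


@dataclass(frozen=True)
class PriorSpec:
    """Generating Gaussian over downward-grating contrast for one bias condition.

    Parameters
    ----------
    mean_offset
        Signed deviation of the Gaussian mean from 0.5, in contrast units.
        Negative offsets put more mass on low downward contrasts and therefore
        favour *upward* percepts.
    sd
        Standard deviation of the Gaussian, in contrast units.
    label
        Bias direction: ``"upward"`` (mean_offset < 0), ``"downward"``
        (mean_offset > 0) or ``"neutral"`` (mean_offset == 0, used for
        calibration blocks).
    """

    mean_offset: float
    sd: float
    label: str = field(default="")

    def __post_init__(self):
        if not self.sd > 0:
            raise ValueError(f"prior sd must be positive, got {self.sd}")
        if not abs(self.mean_offset) < 0.5:
            raise ValueError(f"|mean_offset| must be < 0.5, got {self.mean_offset}")
        expected = (
            "upward" if self.mean_offset < 0
            else "downward" if self.mean_offset > 0
            else "neutral"
        )
        if self.label == "":
            object.__setattr__(self, "label", expected)
        elif self.label != expected:
            raise ValueError(
                f"label {self.label!r} inconsistent with mean_offset "
                f"{self.mean_offset} (expected {expected!r})"
            )

    @property
    def mean(self) -> float:
        """Gaussian mean on the contrast scale (0.5 + mean_offset)."""
        return 0.5 + self.mean_offset


@dataclass(frozen=True)
class LevelGrid:
    """Ordered, evenly spaced grid of downward-grating contrast levels."""

    levels: tuple
    step: float
    center: float

    def __post_init__(self):
        lv = np.asarray(self.levels, dtype=float)
        if lv.size < 3 or lv.size % 2 == 0:
            raise ValueError("grid must have an odd number (>= 3) of levels")
        if not (np.all(lv > 0) and np.all(lv < 1)):
            raise ValueError("all levels must lie strictly within (0, 1)")
        diffs = np.diff(lv)
        if not np.all(diffs > 0) or not np.allclose(diffs, self.step):
            raise ValueError("levels must be strictly increasing with even spacing")
        if not np.isclose(lv[lv.size // 2], self.center):
            raise ValueError("middle level must equal center")

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.levels, dtype=float)


@dataclass(frozen=True)
class TrialSchedule:
    """Per-level trial counts for one key/condition within a session."""

    grid: LevelGrid
    counts: tuple
    total: int
    condition: str
    key: str

    def __post_init__(self):
        cnt = np.asarray(self.counts, dtype=int)
        if cnt.size != self.grid.n_levels:
            raise ValueError("counts length must match grid")
        if np.any(cnt < 0):
            raise ValueError("counts must be non-negative")
        if int(cnt.sum()) != self.total:
            raise ValueError(f"sum(counts)={cnt.sum()} != total={self.total}")

    def expand(self) -> np.ndarray:
        """Contrast of every trial, grouped by level (not yet randomized)."""
        return np.repeat(self.grid.as_array(), np.asarray(self.counts, dtype=int))


@dataclass(frozen=True)
class SessionPlan:
    """Randomized sequence of (key, contrast) trials for one observer session."""

    schedules: tuple  # of TrialSchedule, one per key
    trial_order: tuple  # of (key, contrast)
    key_mapping: dict  # key -> bias condition label
    delay_s: float
    seed: int

    @property
    def n_trials(self) -> int:
        return len(self.trial_order)


@dataclass(frozen=True)
class StimulusMetadata:
    """Derived timing properties of the drifting-grating stimulus."""

    duration_ms: float
    temporal_freq_hz: float
    speed_deg_per_s: float


def build_level_grid(mean_offset: float, step: float, n_levels: int) -> LevelGrid:
    """Build an odd-count contrast grid centred on ``0.5 + mean_offset``.

    The standard grids use step 0.03 and 11 levels: the upward-bias grid runs
    0.29–0.59 (centre 0.44), the downward-bias grid 0.41–0.71 (centre 0.56).

    Raises
    ------
    ValueError
        If ``n_levels`` is even or < 3, ``step`` is not positive, or any
        resulting level falls outside (0, 1).
    """
    if n_levels < 3 or n_levels % 2 == 0:
        raise ValueError(f"n_levels must be odd and >= 3, got {n_levels}")
    if not step > 0:
        raise ValueError(f"step must be positive, got {step}")
    center = 0.5 + mean_offset
    half = n_levels // 2
    levels = center + step * np.arange(-half, half + 1)
    levels = np.round(levels, 12)  # kill float dust so grid levels compare cleanly
    if levels[0] <= 0 or levels[-1] >= 1:
        raise ValueError(
            f"grid [{levels[0]:.3f}, {levels[-1]:.3f}] leaves the open interval (0, 1)"
        )
    return LevelGrid(levels=tuple(levels.tolist()), step=step, center=center)


def discretize_gaussian(
    grid: LevelGrid,
    prior: PriorSpec,
    total: int,
    *,
    block: int = 2,
    condition: str | None = None,
    key: str = "",
) -> TrialSchedule:
    """Allocate ``total`` trials across grid levels proportional to the prior density.

    Allocation uses largest-remainder (Hamilton) rounding on the Gaussian
    density evaluated at each level, in blocks of ``block`` trials. The default
    block of 2 reproduces the published Experiment-1 frequency table
    (2, 6, 12, 24, 36, 40, 36, 24, 12, 6, 2 of 200) exactly; plain per-trial
    allocation (``block=1``) differs from it by one trial at four levels.
    When the prior mean coincides with the grid centre, densities are
    evaluated from exact index offsets so mirror-image levels tie exactly;
    remainder ties are broken toward levels nearer the prior mean, then toward
    0.5 (making the allocation equivariant under reflecting grid and prior
    about 0.5), then toward lower contrast.

    Parameters
    ----------
    grid, prior, total
        Level grid, generating Gaussian, and condition trial total
        (must be divisible by ``block``).
    block
        Allocation quantum in trials.
    condition, key
        Labels carried into the returned :class:`TrialSchedule`; ``condition``
        defaults to the prior's bias label.
    """
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if block <= 0 or total % block:
        raise ValueError(f"total={total} must be a positive multiple of block={block}")
    if not np.isclose(prior.mean, grid.center):
        warnings.warn(
            f"prior mean {prior.mean:.3f} does not coincide with grid center "
            f"{grid.center:.3f}; counts will be asymmetric",
            stacklevel=2,
        )
    levels = grid.as_array()
    aligned = np.isclose(prior.mean, grid.center)
    if aligned:
        # exact index offsets: mirror-image levels get bitwise-equal density
        mid = grid.n_levels // 2
        offsets = (np.arange(grid.n_levels) - mid) * grid.step
        density = np.exp(-0.5 * (offsets / prior.sd) ** 2)
        dist = np.abs(offsets)
    else:
        density = norm.pdf(levels, loc=prior.mean, scale=prior.sd)
        dist = np.abs(levels - prior.mean)
    units = total // block
    quota = density / density.sum() * units
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    short = units - int(counts.sum())
    if short:
        order = sorted(
            range(levels.size),
            key=lambda i: (-remainder[i], dist[i], abs(levels[i] - 0.5), levels[i]),
        )
        for i in order[:short]:
            counts[i] += 1
    counts *= block
    return TrialSchedule(
        grid=grid,
        counts=tuple(int(c) for c in counts),
        total=total,
        condition=condition if condition is not None else prior.label,
        key=key,
    )


def build_session(
    schedules: list,
    delay_s: float = 0.0,
    seed: int = 0,
) -> SessionPlan:
    """Interleave the per-key schedules into one seeded random trial order.

    The full session is a uniformly random permutation of every (key,
    contrast) pair implied by the schedules, so per-(key, level)
    multiplicities are preserved exactly. Deterministic given ``seed``.
    """
    if not schedules:
        raise ValueError("need at least one schedule")
    keys = [s.key for s in schedules]
    if len(set(keys)) != len(keys):
        raise ValueError(f"duplicate key labels in schedules: {keys}")
    pairs = [
        (sched.key, float(contrast))
        for sched in schedules
        for contrast in sched.expand()
    ]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    trial_order = tuple(pairs[i] for i in order)
    key_mapping = {s.key: s.condition for s in schedules}
    return SessionPlan(
        schedules=tuple(schedules),
        trial_order=trial_order,
        key_mapping=key_mapping,
        delay_s=float(delay_s),
        seed=int(seed),
    )


def stimulus_metadata(
    frame_ms: float,
    n_frames: int,
    phase_step: float,
    spatial_freq: float,
) -> StimulusMetadata:
    """Derive stimulus duration, temporal frequency and drift speed.

    ``phase_step`` is the per-frame phase shift in radians. With the standard
    parameters (100 ms frames, 8 frames, 0.5*pi per frame, 0.22 cpd) this
    yields 800 ms, 2.5 Hz and ~11.36 deg/s. The speed is computed from first
    principles as temporal frequency / spatial frequency; note this differs
    slightly from the commonly rounded 11.2 deg/s.
    """
    if min(frame_ms, n_frames, phase_step, spatial_freq) <= 0:
        raise ValueError("all stimulus parameters must be positive")
    duration_ms = n_frames * frame_ms
    temporal_freq_hz = (phase_step / (2 * np.pi)) * (1000.0 / frame_ms)
    speed = temporal_freq_hz / spatial_freq
    return StimulusMetadata(
        duration_ms=float(duration_ms),
        temporal_freq_hz=float(temporal_freq_hz),
        speed_deg_per_s=float(speed),
    )


def session_to_frame(plan: SessionPlan) -> pd.DataFrame:
    """Tabulate a session plan as a DataFrame in the session CSV schema."""
    rows = [
        {
            "trial_index": i,
            "key": key,
            "bias_condition": plan.key_mapping[key],
            "downward_contrast": contrast,
            "delay_s": plan.delay_s,
        }
        for i, (key, contrast) in enumerate(plan.trial_order)
    ]
    return pd.DataFrame(rows, columns=SESSION_COLUMNS)


def write_session_csv(plan: SessionPlan, path) -> None:
    session_to_frame(plan).to_csv(path, index=False)


def read_session_csv(path) -> pd.DataFrame:
    """Read a session (or trial) CSV, validating the schema columns."""
    df = pd.read_csv(path)
    missing = [c for c in SESSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"session CSV missing required columns: {missing}")
    return df
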