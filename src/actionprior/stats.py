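"""Group-level inference: paired t, Cohen's d, 2x(2) mixed ANOVA.

The experiments' inferential toolkit: a paired t-test on per-observer PSEs
between bias directions, Cohen's d for that contrast, and a two-way mixed
ANOVA (one between-subject factor such as data source or distribution
width, one within-subject factor: bias direction) with simple main
effects tested against the corresponding omnibus error terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "EffectRow",
    "MixedAnovaResult",
    "paired_t",
    "cohens_d",
    "mixed_anova",
    "simple_main_effects",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float


@dataclass(frozen=True)
class EffectRow:
    """One line of an ANOVA table (or a simple-main-effect slice)."""

    effect: str
    ss: float
    df_num: int
    df_den: int
    F: float
    p: float
    degenerate: bool = False


@dataclass(frozen=True)
class MixedAnovaResult:
    """Between, within and interaction effects of the 2-factor mixed design."""

    between: EffectRow
    within: EffectRow
    interaction: EffectRow

    def rows(self) -> list:
        return [self.between, self.within, self.interaction]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.rows()])


def paired_t(x, y) -> TTestResult:
    """Two-sided paired t-test on per-subject differences (df = n - 1)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    if np.std(x - y, ddof=1) == 0:
        raise ValueError("zero-variance differences; paired t undefined")
    res = sps.ttest_rel(x, y)
    return TTestResult(t=float(res.statistic), df=int(x.size - 1), p=float(res.pvalue))


def cohens_d(x, y, method: str = "pooled") -> tuple[float, float]:
    """Cohen's d for a paired contrast; returns ``(d, method)``.

    ``"pooled"`` divides the mean difference by the pooled SD of the two
    samples (the convention consistent with the modest effect sizes reported
    alongside large paired t values); ``"diff"`` divides by the SD of the
    difference scores (always larger when the samples correlate positively).
    The method is returned alongside d so reports can never omit it.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    delta = float(np.mean(x) - np.mean(y))
    if method == "pooled":
        denom = float(np.sqrt((np.var(x, ddof=1) + np.var(y, ddof=1)) / 2))
    elif method == "diff":
        denom = float(np.std(x - y, ddof=1))
    else:
        raise ValueError(f"unknown method {method!r}")
    if denom == 0:
        raise ValueError("zero dispersion; Cohen's d undefined")
    return delta / denom, method


def _check_layout(values: np.ndarray, group: np.ndarray):
    values = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if values.ndim != 2:
        raise ValueError("values must be subjects x within-levels (2-D)")
    if np.any(np.isnan(values)):
        raise ValueError("within-factor data are unbalanced (missing cells)")
    if group.shape[0] != values.shape[0]:
        raise ValueError("group labels must align with the rows of values")
    labels, counts = np.unique(group, return_counts=True)
    if labels.size < 2:
        raise ValueError("need at least 2 between-subject groups")
    if np.any(counts < 2):
        raise ValueError("need at least 2 subjects per group")
    return values, group, labels


def _ss_components(values: np.ndarray, group: np.ndarray, labels: np.ndarray):
    """Classical sums-of-squares for an (a groups) x (b within levels) design."""
    n_sub, b = values.shape
    grand = values.mean()
    subj_means = values.mean(axis=1)
    level_means = values.mean(axis=0)
    group_means = np.array([values[group == g].mean() for g in labels])
    n_g = np.array([(group == g).sum() for g in labels])
    cell_means = np.vstack([values[group == g].mean(axis=0) for g in labels])

    ss_between_subjects = b * np.sum((subj_means - grand) ** 2)
    ss_A = b * np.sum(n_g * (group_means - grand) ** 2)
    ss_subj_within = ss_between_subjects - ss_A
    ss_B = np.sum([n_g.sum() * (level_means[j] - grand) ** 2 for j in range(b)])
    ss_AB = float(
        np.sum(
            n_g[:, None]
            * (cell_means - group_means[:, None] - level_means[None, :] + grand) ** 2
        )
    )
    ss_within_total = float(np.sum((values - subj_means[:, None]) ** 2))
    ss_err_within = ss_within_total - ss_B - ss_AB
    a = labels.size
    return {
        "a": a,
        "b": b,
        "N": n_sub,
        "n_g": n_g,
        "cell_means": cell_means,
        "group_means": group_means,
        "level_means": level_means,
        "ss_A": float(ss_A),
        "ss_subj_within": float(ss_subj_within),
        "ss_B": float(ss_B),
        "ss_AB": float(ss_AB),
        "ss_err_within": float(ss_err_within),
        "df_A": a - 1,
        "df_subj_within": n_sub - a,
        "df_B": b - 1,
        "df_AB": (a - 1) * (b - 1),
        "df_err_within": (n_sub - a) * (b - 1),
    }


def _f_row(effect: str, ss: float, df_num: int, ss_err: float, df_den: int) -> EffectRow:
    ms_err = ss_err / df_den if df_den > 0 else 0.0
    if ms_err <= 0:
        # zero error variance: F is undefined; flag rather than emit infinities
        return EffectRow(effect, ss, df_num, df_den, float("nan"), float("nan"), True)
    F = (ss / df_num) / ms_err
    p = float(sps.f.sf(F, df_num, df_den))
    return EffectRow(effect, float(ss), df_num, df_den, float(F), p)


def mixed_anova(values, group) -> MixedAnovaResult:
    """Two-way mixed ANOVA on a subjects x within-levels table.

    Parameters
    ----------
    values
        2-D array, one row per subject, one column per within-factor level
        (every subject measured at every level).
    group
        Between-subject group label per subject (>= 2 groups, >= 2 subjects
        each).

    The between effect is tested against subjects-within-groups; the within
    and interaction effects against the within-subjects residual. Degenerate
    zero-error decompositions return flagged rows with NaN F.
    """
    values, group, labels = _check_layout(np.asarray(values, dtype=float), np.asarray(group))
    c = _ss_components(values, group, labels)
    return MixedAnovaResult(
        between=_f_row("between", c["ss_A"], c["df_A"], c["ss_subj_within"], c["df_subj_within"]),
        within=_f_row("within", c["ss_B"], c["df_B"], c["ss_err_within"], c["df_err_within"]),
        interaction=_f_row(
            "interaction", c["ss_AB"], c["df_AB"], c["ss_err_within"], c["df_err_within"]
        ),
    )


def simple_main_effects(values, group, factor: str) -> list[EffectRow]:
    """Simple main effects of one factor at each level of the other.

    ``factor="within"`` tests the within-factor contrast separately in each
    between-subject group, against the omnibus within-subjects residual;
    ``factor="between"`` tests the group contrast separately at each
    within-factor level, against the omnibus subjects-within-groups error.
    With two groups of 10 subjects all simple effects have denominator df 18.
    The two slices of either factor satisfy the pooling identity
    sum(SS_slices) == SS_main + SS_interaction.
    """
    values, group, labels = _check_layout(np.asarray(values, dtype=float), np.asarray(group))
    c = _ss_components(values, group, labels)
    rows = []
    if factor == "within":
        for gi, g in enumerate(labels):
            cell = c["cell_means"][gi]
            ss = float(c["n_g"][gi] * np.sum((cell - cell.mean()) ** 2))
            rows.append(
                _f_row(f"within @ {g}", ss, c["df_B"], c["ss_err_within"], c["df_err_within"])
            )
    elif factor == "between":
        for j in range(c["b"]):
            col = c["cell_means"][:, j]
            wmean = float(np.sum(c["n_g"] * col) / c["n_g"].sum())
            ss = float(np.sum(c["n_g"] * (col - wmean) ** 2))
            rows.append(
                _f_row(
                    f"between @ level {j}",
                    ss,
                    c["df_A"],
                    c["ss_subj_within"],
                    c["df_subj_within"],
                )
            )
    else:
        raise ValueError(f"factor must be 'within' or 'between', got {factor!r}")
    return rows
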