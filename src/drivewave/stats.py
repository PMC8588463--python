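"""Descriptive and inferential statistics over the feature table.

Mirrors the study design the package models: per-state means with 95%
t-based confidence intervals, paired-samples t-tests between states on
subject-level means (epochs are unbalanced across states, so pairing is
only well defined at the subject level), and simple band-vs-band linear
regressions per state and lobe (slope, Pearson r, R^2, p).  Two-sided
tests at alpha = 0.05 throughout; no multiple-testing correction is
applied (the report carries the number of tests performed instead).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StateDescription",
    "StateComparison",
    "RegressionResult",
    "describe_by_state",
    "paired_compare",
    "regress_bands",
    "state_report",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StateDescription:
    feature: str
    state: str
    n: int
    mean: float
    sd: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class StateComparison:
    feature: str
    state_a: str
    state_b: str
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    relative_difference: float  # (mean_b - mean_a) / mean_a
    t: float
    p: float
    n_pairs: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


@dataclass(frozen=True)
class RegressionResult:
    x: str
    y: str
    state: str
    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int


def describe_by_state(
    table: pd.DataFrame, feature: str
) -> dict[str, StateDescription]:
    """Per-state mean, SD and 95% CI (mean +/- t_{.975,n-1} SD/sqrt(n))."""
    out = {}
    for state, sub in table.groupby("state"):
        v = sub[feature].dropna().to_numpy()
        n = len(v)
        if n < 2:
            raise ValueError(f"state {state!r} has fewer than 2 epochs")
        mean = float(v.mean())
        sd = float(v.std(ddof=1))
        half = sps.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        out[state] = StateDescription(
            feature, state, n, mean, sd, mean - half, mean + half
        )
    return out


def paired_compare(
    table: pd.DataFrame, feature: str, state_a: str, state_b: str
) -> StateComparison:
    """Paired-samples t-test on subject-level means of ``feature``.

    Epoch values are first averaged per subject within each state; only
    subjects present in both states are paired (others are dropped with a
    warning).  The relative difference is (mean_b - mean_a)/mean_a of the
    paired subject-level means.
    """
    per_subj = (
        table[table["state"].isin([state_a, state_b])]
        .groupby(["subject", "state"], observed=True)[feature]
        .mean()
        .unstack("state")
    )
    paired = per_subj.dropna()
    dropped = len(per_subj) - len(paired)
    if dropped:
        warnings.warn(f"{dropped} unpaired subjects dropped")
    if len(paired) < 2:
        raise ValueError("need at least 2 paired subjects")
    a = paired[state_a].to_numpy()
    b = paired[state_b].to_numpy()
    if np.allclose(a, b):
        t, p = 0.0, 1.0
    elif np.allclose(b - a, (b - a)[0]):
        # zero variance of differences with a non-zero shift: degenerate
        warnings.warn("zero variance of paired differences; p -> 0")
        t, p = np.inf, 0.0
    else:
        t, p = sps.ttest_rel(b, a)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    rel = (mean_b - mean_a) / mean_a if mean_a != 0 else np.nan
    return StateComparison(
        feature, state_a, state_b, mean_a, mean_b,
        float(a.std(ddof=1)), float(b.std(ddof=1)),
        float(rel), float(t), float(p), len(paired),
    )


def regress_bands(
    table: pd.DataFrame,
    x: str,
    y: str,
    state: str | None = None,
) -> RegressionResult:
    """OLS of ``y`` on ``x`` over epochs (optionally within one state).

    Reports slope and Pearson r separately: for simple linear regression
    R^2 equals r^2, but the slope is a different quantity and is never
    labelled as a correlation.
    """
    sub = table if state is None else table[table["state"] == state]
    pts = sub[[x, y]].dropna()
    if len(pts) < 3:
        raise ValueError("need at least 3 points for a regression")
    xv = pts[x].to_numpy()
    yv = pts[y].to_numpy()
    if np.ptp(xv) == 0:
        raise ValueError("zero variance in x: slope undefined")
    res = sps.linregress(xv, yv)
    return RegressionResult(
        x, y, state if state is not None else "all",
        float(res.slope), float(res.intercept),
        float(res.rvalue), float(res.rvalue**2), float(res.pvalue), len(pts),
    )


def state_report(
    table: pd.DataFrame,
    features: list[str],
    baseline_state: str = "resting",
) -> pd.DataFrame:
    """Tabular summary: per-state descriptives plus paired tests vs baseline.

    One row per (feature, state) with mean, SD, 95% CI and — for
    non-baseline states — the relative difference from baseline and the
    paired t-test p-value.  The frame's ``attrs['n_tests']`` records how
    many tests were run (no multiplicity correction is applied).
    """
    rows = []
    n_tests = 0
    states = list(dict.fromkeys(table["state"]))
    for feat in features:
        desc = describe_by_state(table, feat)
        for state in states:
            d = desc[state]
            row = dict(
                feature=feat, state=state, n=d.n, mean=d.mean, sd=d.sd,
                ci_low=d.ci_low, ci_high=d.ci_high,
                relative_difference=np.nan, t=np.nan, p=np.nan,
            )
            if state != baseline_state and baseline_state in desc:
                cmp = paired_compare(table, feat, baseline_state, state)
                row.update(
                    relative_difference=cmp.relative_difference,
                    t=cmp.t, p=cmp.p,
                )
                n_tests += 1
            rows.append(row)
    out = pd.DataFrame(rows)
    out.attrs["n_tests"] = n_tests
    return out
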