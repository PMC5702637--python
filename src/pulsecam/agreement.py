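"""Sensor-pair agreement statistics.

Given beat trains from two sensors (e.g. ECG and a camera-derived pulse), the
battery is: beat matching across sensors (after removing the pulse-transit
lag), Bland-Altman differences with limits of agreement and a bias t-test,
ordinary least-squares regression of one sensor on the other, a one-way
repeated-measures effect size (partial eta-squared for the task factor), and
change-from-baseline scores.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cpvd import IbiSeries

__all__ = [
    "MatchedPairs",
    "BlandAltmanResult",
    "RegressionResult",
    "RmAnovaResult",
    "match_beats",
    "bland_altman",
    "linear_fit",
    "partial_eta_squared",
    "change_scores",
    "bland_altman_plot",
    "scatter_plot",
]

LOA_FACTOR = 1.96  # limits of agreement at mean +/- 1.96 SD


@dataclass
class MatchedPairs:
    """Interbeat intervals paired across two sensors on matched beats."""

    ibi_a: np.ndarray  # ms
    ibi_b: np.ndarray  # ms
    beat_times: np.ndarray  # s, leading beat time (sensor a clock)
    lag_s: float = 0.0  # removed inter-train lag (pulse transit delay)
    n_unmatched_a: int = 0
    n_unmatched_b: int = 0

    def __post_init__(self) -> None:
        self.ibi_a = np.asarray(self.ibi_a, dtype=float)
        self.ibi_b = np.asarray(self.ibi_b, dtype=float)
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        if not len(self.ibi_a) == len(self.ibi_b) == len(self.beat_times):
            raise ValueError("pair arrays must have equal length")

    def __len__(self) -> int:
        return len(self.ibi_a)


@dataclass
class BlandAltmanResult:
    mean_diff: float  # ms
    sd_diff: float  # ms
    loa_low: float  # ms
    loa_high: float  # ms
    t_stat: float
    dof: int
    p_value: float
    exact_agreement: bool = False

    @property
    def means(self):  # pragma: no cover - plotting convenience
        return None


@dataclass
class RegressionResult:
    slope: float
    intercept: float  # ms
    r_squared: float


@dataclass
class RmAnovaResult:
    ss_time: float
    ss_subjects: float
    ss_error: float
    partial_eta_squared: float
    f_stat: float
    dof: tuple
    p_value: float


def match_beats(a: IbiSeries, b: IbiSeries, tolerance_ms: float = 250.0) -> MatchedPairs:
    """Pair beats across sensors and return the IBIs of jointly observed
    intervals.

    The median inter-train lag (the pulse transit delay, when pairing a
    cardiac train with a peripheral one) is removed first; beats are then
    greedily matched to the nearest counterpart within the tolerance, one to
    one. An IBI pair is kept only when both of its bounding beats matched and
    the beats are consecutive in *both* trains, so a missing beat drops the
    interval it bounds on each side rather than corrupting it.
    """
    ta, tb = a.beat_times, b.beat_times
    if ta[-1] < tb[0] or tb[-1] < ta[0]:
        raise ValueError("beat trains do not overlap in time")
    # lag: median offset from each a-beat to its nearest b-beat
    idx = np.clip(np.searchsorted(tb, ta), 1, len(tb) - 1)
    nearest = np.where(np.abs(tb[idx] - ta) < np.abs(tb[idx - 1] - ta), idx, idx - 1)
    lag = float(np.median(tb[nearest] - ta))
    tb_shift = tb - lag

    tol = tolerance_ms / 1000.0
    # greedy one-to-one nearest matching
    order = []
    j_used = np.full(len(tb), False)
    idx = np.clip(np.searchsorted(tb_shift, ta), 1, len(tb) - 1)
    for i, t in enumerate(ta):
        j = idx[i] if abs(tb_shift[idx[i]] - t) < abs(tb_shift[idx[i] - 1] - t) else idx[i] - 1
        if abs(tb_shift[j] - t) <= tol and not j_used[j]:
            j_used[j] = True
            order.append((i, j))
    pairs_a, pairs_b, times = [], [], []
    for (i0, j0), (i1, j1) in zip(order, order[1:]):
        if i1 == i0 + 1 and j1 == j0 + 1:
            pairs_a.append(a.ibis[i0])
            pairs_b.append(b.ibis[j0])
            times.append(ta[i0])
    matched = MatchedPairs(
        ibi_a=np.array(pairs_a),
        ibi_b=np.array(pairs_b),
        beat_times=np.array(times),
        lag_s=lag,
        n_unmatched_a=len(ta) - len(order),
        n_unmatched_b=len(tb) - len(order),
    )
    if len(matched) < 10:
        raise ValueError(f"only {len(matched)} matched IBI pairs; need at least 10")
    return matched


def bland_altman(p: MatchedPairs) -> BlandAltmanResult:
    """Differences a - b: mean, sample SD, limits of agreement at +/- 1.96 SD,
    and a one-sample t-test of the differences against zero (sensor bias)."""
    if len(p) < 3:
        raise ValueError("need at least 3 pairs")
    diffs = p.ibi_a - p.ibi_b
    mean = float(np.mean(diffs))
    sd = float(np.std(diffs, ddof=1))
    dof = len(diffs) - 1
    if sd == 0:
        return BlandAltmanResult(
            mean_diff=mean, sd_diff=0.0, loa_low=mean, loa_high=mean,
            t_stat=float("nan"), dof=dof, p_value=float("nan"),
            exact_agreement=(mean == 0.0),
        )
    t_stat, p_value = stats.ttest_1samp(diffs, 0.0)
    return BlandAltmanResult(
        mean_diff=mean,
        sd_diff=sd,
        loa_low=mean - LOA_FACTOR * sd,
        loa_high=mean + LOA_FACTOR * sd,
        t_stat=float(t_stat),
        dof=dof,
        p_value=float(p_value),
    )


def linear_fit(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """Ordinary least squares y on x; R^2 is the squared correlation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need at least 3 (x, y) points")
    if np.var(x) == 0:
        raise ValueError("degenerate x: zero variance")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def partial_eta_squared(values: np.ndarray) -> RmAnovaResult:
    """One-way repeated-measures decomposition of a subject x condition matrix.

    SS_time is the between-condition sum of squares, SS_subjects the
    between-subject one, and SS_error the subject-by-condition residual;
    partial eta-squared for the task (time) factor is
    SS_time / (SS_time + SS_error), with F on ((c-1), (c-1)(s-1)) degrees of
    freedom. Missing cells are not imputed.
    """
    m = np.asarray(values, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need a 2-D matrix with >= 2 subjects and >= 2 conditions")
    if np.any(~np.isfinite(m)):
        raise ValueError("missing cells are not allowed (no imputation)")
    s, c = m.shape
    grand = m.mean()
    ss_time = s * float(np.sum((m.mean(axis=0) - grand) ** 2))
    ss_subj = c * float(np.sum((m.mean(axis=1) - grand) ** 2))
    ss_total = float(np.sum((m - grand) ** 2))
    ss_error = ss_total - ss_time - ss_subj
    df1, df2 = c - 1, (c - 1) * (s - 1)
    denom = ss_time + ss_error
    eta = ss_time / denom if denom > 0 else 0.0
    if ss_error <= 0 or ss_time == 0:
        f_stat = float("inf") if ss_time > 0 else 0.0
        p_value = 0.0 if ss_time > 0 else 1.0
    else:
        f_stat = (ss_time / df1) / (ss_error / df2)
        p_value = float(stats.f.sf(f_stat, df1, df2))
    return RmAnovaResult(
        ss_time=ss_time,
        ss_subjects=ss_subj,
        ss_error=max(ss_error, 0.0),
        partial_eta_squared=eta,
        f_stat=f_stat,
        dof=(df1, df2),
        p_value=p_value,
    )


def change_scores(estimates: dict, baseline_label: str) -> dict:
    """Per-segment change from the baseline segment (value - baseline)."""
    if baseline_label not in estimates:
        raise ValueError(f"baseline segment '{baseline_label}' missing")
    base = estimates[baseline_label]
    return {label: value - base for label, value in estimates.items()}


# --- optional plotting ------------------------------------------------------

def bland_altman_plot(p: MatchedPairs, result: BlandAltmanResult, path) -> None:
    """Differences vs means with the bias line and limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    means = (p.ibi_a + p.ibi_b) / 2.0
    diffs = p.ibi_a - p.ibi_b
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(means, diffs, s=8, alpha=0.6)
    ax.axhline(result.mean_diff, color="k", lw=1)
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="r", lw=1, ls="--")
    ax.set_xlabel("mean IBI of pair (ms)")
    ax.set_ylabel("IBI difference (ms)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_plot(x, y, fit: RegressionResult, path, xlabel="sensor A IBI (ms)", ylabel="sensor B IBI (ms)") -> None:
    """Scatter with the fitted regression line and the identity line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.asarray(x, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(x, y, s=8, alpha=0.6)
    xs = np.array([x.min(), x.max()])
    ax.plot(xs, fit.slope * xs + fit.intercept, "r-", lw=1,
            label=f"y = {fit.slope:.2f}x + {fit.intercept:.1f} (R$^2$={fit.r_squared:.2f})")
    ax.plot(xs, xs, "k:", lw=1, label="y = x")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
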