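"""Patient stratification on hub-gene expression and survival comparison.

Subjects are split into low/high expressors of selected marker genes either
by fuzzy C-means soft clustering (c = 2) on the joint expression, or by a
per-marker median split into four high/low combinations.  Groups are then
compared with the Kaplan-Meier estimator, the two-group log-rank test and a
Mantel-Haenszel hazard ratio (O1/E1)/(O2/E2) with a log-scale normal
confidence interval.

The fuzzy C-means implementation is the standard alternating optimization:
centroids are membership-weighted means with fuzzifier exponent m, and
memberships follow the inverse-distance rule with exponent 2/(m-1); the
iteration stops when the largest membership change drops below tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats

__all__ = [
    "ClusterAssignment",
    "SurvivalTable",
    "fuzzy_cmeans",
    "tag_clusters",
    "median_split_groups",
    "km_estimate",
    "logrank_test",
    "hazard_ratio",
    "load_clinical",
]


@dataclass
class ClusterAssignment:
    """Soft cluster memberships with hard argmax labels and low/high tags."""

    subjects: list[str]
    memberships: pd.DataFrame  # subjects x clusters, rows sum to 1
    hard_labels: pd.Series  # subject -> cluster index
    cluster_tags: dict[int, str] = field(default_factory=dict)
    objective: float = float("nan")
    objective_trace: list[float] = field(default_factory=list)
    n_iter: int = 0

    @property
    def tags_per_subject(self) -> pd.Series:
        if not self.cluster_tags:
            raise ValueError("clusters are untagged; run tag_clusters first")
        return self.hard_labels.map(self.cluster_tags).rename("group")


@dataclass
class SurvivalTable:
    """Per-subject follow-up time (months), event flag and group label."""

    data: pd.DataFrame  # columns: time, event, group

    def __post_init__(self) -> None:
        required = {"time", "event", "group"}
        if not required.issubset(self.data.columns):
            raise ValueError(f"survival table needs columns {sorted(required)}")
        if (self.data["time"] <= 0).any():
            raise ValueError("survival times must be positive")

    def subset(self, groups: list[str]) -> "SurvivalTable":
        return SurvivalTable(self.data[self.data["group"].isin(groups)].copy())

    @property
    def groups(self) -> list[str]:
        return sorted(self.data["group"].unique())


def load_clinical(path: str | Path) -> pd.DataFrame:
    """Read a clinical TSV with subject_id, os_months, event (+ markers)."""
    df = pd.read_csv(path, sep="\t", index_col="subject_id")
    for col in ("os_months", "event"):
        if col not in df.columns:
            raise ValueError(f"clinical table missing column {col!r}")
    return df


def fuzzy_cmeans(
    expr: pd.DataFrame,
    c: int = 2,
    m: float = 2.0,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> ClusterAssignment:
    """Fuzzy C-means over a subjects x genes matrix.

    Returns soft memberships (rows sum to 1), hard argmax labels (ties go
    to the lower cluster index) and the converged objective value.
    Centroids are initialized on ``c`` distinct subjects drawn with the
    given seed, so the result is deterministic.
    """
    if c < 2:
        raise ValueError("need at least 2 clusters")
    x = expr.to_numpy(dtype=float)
    n = x.shape[0]
    if n < c:
        raise ValueError("fewer subjects than clusters")
    if expr.isna().any().any():
        raise ValueError("expression matrix contains missing values")
    if len(np.unique(x, axis=0)) < c:
        raise ValueError("fewer distinct points than clusters")
    rng = np.random.default_rng(seed)
    # seed centroids on distinct observed points
    uniq = np.unique(x, axis=0)
    centroids = uniq[rng.choice(len(uniq), size=c, replace=False)]
    exponent = 2.0 / (m - 1.0)

    def _objective(u_: np.ndarray, cent: np.ndarray) -> float:
        d2 = ((x[:, None, :] - cent[None, :, :]) ** 2).sum(axis=2)
        return float(((u_**m) * d2).sum())

    u = _memberships(x, centroids, exponent)
    trace = [_objective(u, centroids)]
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        w = u**m
        centroids = (w.T @ x) / w.sum(axis=0)[:, None]
        u_new = _memberships(x, centroids, exponent)
        shift = np.abs(u_new - u).max()
        u = u_new
        trace.append(_objective(u, centroids))
        if shift < tol:
            break
    memberships = pd.DataFrame(u, index=expr.index, columns=range(c))
    hard = pd.Series(np.argmax(u, axis=1), index=expr.index, name="cluster")
    return ClusterAssignment(subjects=list(expr.index), memberships=memberships,
                             hard_labels=hard, objective=trace[-1],
                             objective_trace=trace, n_iter=n_iter)


def _memberships(x: np.ndarray, centroids: np.ndarray, exponent: float) -> np.ndarray:
    d2 = ((x[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    zero = d2 <= 1e-300
    with np.errstate(divide="ignore", invalid="ignore"):
        inv = d2 ** (-exponent / 2.0)
        u = inv / inv.sum(axis=1, keepdims=True)
    # points sitting on a centroid get full membership there
    on_centroid = zero.any(axis=1)
    if on_centroid.any():
        u[on_centroid] = 0.0
        u[on_centroid, np.argmax(zero[on_centroid], axis=1)] = 1.0
    return u


def tag_clusters(assignment: ClusterAssignment, expr: pd.DataFrame) -> ClusterAssignment:
    """Tag the two clusters low/high by mean summed marker expression."""
    clusters = list(assignment.memberships.columns)
    if len(clusters) != 2:
        raise ValueError("low/high tagging requires exactly 2 clusters")
    combined = expr.sum(axis=1)
    means = combined.groupby(assignment.hard_labels).mean()
    if len(means) < 2:
        raise ValueError("one cluster is empty; cannot tag low/high")
    if np.isclose(means.iloc[0], means.iloc[1]):
        raise ValueError("cluster means tie; tag clusters manually")
    low = int(means.idxmin())
    high = int(means.idxmax())
    assignment.cluster_tags = {low: "low", high: "high"}
    return assignment


def median_split_groups(
    markers: pd.DataFrame,
    thresholds: dict[str, float] | None = None,
) -> pd.Series:
    """Four-way hi/lo grouping on two marker columns.

    "High" means strictly above the per-marker median (or an explicit
    threshold); values exactly at the cut go to the low side.  Labels are
    ``"<m1>-hi/<m2>-lo"`` style combinations.
    """
    if markers.shape[1] != 2:
        raise ValueError("median split needs exactly two marker columns")
    if len(markers) < 2:
        raise ValueError("need at least 2 subjects")
    labels = []
    for col in markers.columns:
        vals = markers[col]
        if vals.nunique() == 1:
            raise ValueError(f"marker {col!r} is constant; no split possible")
        cut = thresholds[col] if thresholds else float(vals.median())
        labels.append(np.where(vals > cut, "hi", "lo"))
    combined = pd.Series(
        [f"{a}/{b}" for a, b in zip(*labels)], index=markers.index, name="group"
    )
    return combined


@dataclass
class KMEstimate:
    """Product-limit survival curve; callable as S(t)."""

    times: np.ndarray
    survival: np.ndarray  # S(t) just after each time in `times`
    group: str

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        s = np.concatenate([[1.0], self.survival])[idx]
        return float(s) if np.isscalar(t) else s

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "survival": self.survival})


def km_estimate(tbl: SurvivalTable, group: str) -> KMEstimate:
    """Kaplan-Meier estimate for one group, censoring honored."""
    sub = tbl.data[tbl.data["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} is empty")
    kmf = KaplanMeierFitter()
    kmf.fit(sub["time"], event_observed=sub["event"].astype(bool))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times > 0
    return KMEstimate(times=times[keep], survival=surv[keep], group=group)


def _two_group_arrays(tbl: SurvivalTable) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    groups = tbl.groups
    if len(groups) != 2:
        raise ValueError(f"expected exactly 2 groups, found {groups}")
    a = tbl.data[tbl.data["group"] == groups[0]]
    b = tbl.data[tbl.data["group"] == groups[1]]
    return a, b, groups


def logrank_test(tbl: SurvivalTable) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square statistic, 1-df p-value)."""
    a, b, _ = _two_group_arrays(tbl)
    if not tbl.data["event"].any():
        raise ValueError("log-rank needs at least one event")
    res = _ll_logrank(a["time"], b["time"],
                      event_observed_A=a["event"].astype(bool),
                      event_observed_B=b["event"].astype(bool))
    return float(res.test_statistic), float(res.p_value)


def observed_expected(tbl: SurvivalTable) -> pd.DataFrame:
    """Observed and expected event counts per group from the risk tables.

    At each distinct event time t the expected events in group g are
    d(t) * n_g(t) / n(t); summing over event times gives E_g.  These
    quantities drive both the log-rank statistic and the Mantel-Haenszel
    hazard ratio.
    """
    a, b, groups = _two_group_arrays(tbl)
    event_times = np.sort(tbl.data.loc[tbl.data["event"].astype(bool), "time"].unique())
    O = {g: 0.0 for g in groups}
    E = {g: 0.0 for g in groups}
    V = 0.0
    for t in event_times:
        n1 = float((a["time"] >= t).sum())
        n2 = float((b["time"] >= t).sum())
        d1 = float(((a["time"] == t) & a["event"].astype(bool)).sum())
        d2 = float(((b["time"] == t) & b["event"].astype(bool)).sum())
        n, d = n1 + n2, d1 + d2
        if n == 0:
            continue
        O[groups[0]] += d1
        O[groups[1]] += d2
        E[groups[0]] += d * n1 / n
        E[groups[1]] += d * n2 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    out = pd.DataFrame({"observed": O, "expected": E})
    out.attrs["variance"] = V
    return out


def hazard_ratio(tbl: SurvivalTable) -> tuple[float, tuple[float, float]]:
    """Mantel-Haenszel hazard ratio (first group vs second, sorted labels).

    HR = (O1/E1) / (O2/E2) with 95% CI exp(log HR +/- 1.96 *
    sqrt(1/E1 + 1/E2)).
    """
    oe = observed_expected(tbl)
    if (oe["expected"] <= 0).any():
        raise ValueError("a group has zero expected events; HR undefined")
    if (oe["observed"] <= 0).any():
        raise ValueError("a group has zero observed events; HR degenerate")
    (o1, e1), (o2, e2) = oe[["observed", "expected"]].to_numpy()
    hr = (o1 / e1) / (o2 / e2)
    se = np.sqrt(1.0 / e1 + 1.0 / e2)
    lo, hi = np.exp(np.log(hr) - 1.96 * se), np.exp(np.log(hr) + 1.96 * se)
    return float(hr), (float(lo), float(hi))
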