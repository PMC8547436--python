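"""Richness, accumulation curves, extrapolation and coverage solving.

Sample-based (incidence) rarefaction: the expected number of distinct
items among t of T isolates drawn without replacement is

    E[S(t)] = S_obs - sum_i C(T - T_i, t) / C(T, t),

the exact hypergeometric expectation over all size-t subsets, where T_i
is the number of isolates containing item i. Extrapolation beyond T uses
the incidence-based Chao2 estimate of unseen richness

    Q0_hat = ((T-1)/T) * Q1^2 / (2 Q2)          if Q2 > 0
    Q0_hat = ((T-1)/T) * Q1 (Q1 - 1) / 2        if Q2 = 0

and S(T + t*) = S_obs + Q0_hat * [1 - (1 - Q1 / (Q1 + T*Q0_hat))^t*].

The coverage solver inverts the interpolated curve: the smallest t whose
expected richness reaches a stated fraction of the observed total. All
binomial coefficients are evaluated in log space so T in the hundreds is
safe.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .containers import IncidenceMatrix
from .errors import DegenerateDataError

__all__ = [
    "AccumulationCurve",
    "RichnessSummary",
    "alpha_richness",
    "compare_richness",
    "balanced_subsample",
    "analytic_rarefaction",
    "collector_curve",
    "chao2_unseen",
    "extrapolate_richness",
    "rarefaction_curve",
    "coverage_targets",
    "end_slope",
]


@dataclass
class AccumulationCurve:
    """Expected richness versus number of isolates.

    ``data`` has columns t, richness and method, where method is
    "interpolated", "extrapolated" or "collector".
    """

    group: str
    data: pd.DataFrame
    n_perm: int | None = None
    seed: int | None = None

    def at(self, t: int) -> float:
        row = self.data.loc[self.data["t"] == t, "richness"]
        if row.empty:
            raise KeyError(f"t={t} not on the curve")
        return float(row.iloc[0])


@dataclass
class RichnessSummary:
    """Per-isolate observed richness with group comparisons."""

    richness: pd.Series
    groups: pd.Series
    group_stats: pd.DataFrame  # median, q1, q3, n per group
    anova_F: float
    anova_p: float
    tukey: pd.DataFrame = field(default_factory=pd.DataFrame)


def alpha_richness(incidence: IncidenceMatrix) -> pd.Series:
    """Observed chemical richness: items present per isolate."""
    counts = incidence.presence.sum(axis=0)
    counts.name = "richness"
    return counts


def compare_richness(richness: pd.Series, groups: pd.Series) -> RichnessSummary:
    """One-way ANOVA plus Tukey HSD across groups of isolates.

    Requires at least two groups with at least two members each. Tukey
    p-values come from the studentized range distribution with
    Tukey-Kramer standard errors, so unequal group sizes are handled.
    """
    groups = pd.Series(groups).loc[richness.index]
    by_group = [richness[groups == g].to_numpy(float) for g in groups.unique()]
    if len(by_group) < 2 or any(len(g) < 2 for g in by_group):
        raise DegenerateDataError("need >= 2 groups with >= 2 members each")
    if all(np.var(g) == 0 for g in by_group):
        raise DegenerateDataError("zero within-group variance everywhere")
    f_stat, p_val = stats.f_oneway(*by_group)
    tukey_res = pairwise_tukeyhsd(
        endog=richness.to_numpy(float), groups=groups.to_numpy(), alpha=0.05
    )
    tukey = pd.DataFrame(
        tukey_res.summary().data[1:], columns=tukey_res.summary().data[0]
    )
    group_stats = (
        richness.groupby(groups)
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            n="count",
        )
        .sort_index()
    )
    return RichnessSummary(
        richness=richness,
        groups=groups,
        group_stats=group_stats,
        anova_F=float(f_stat),
        anova_p=float(p_val),
        tukey=tukey,
    )


def balanced_subsample(
    incidence: IncidenceMatrix,
    n: int,
    seed: int = 0,
) -> IncidenceMatrix:
    """Draw n isolates without replacement from every group larger than n.

    Groups at or below n are kept whole (with a warning via logging is
    unnecessary — the behavior is the documented contract for comparing
    unevenly sized clades on an equal footing).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if incidence.groups is None:
        raise DegenerateDataError("balanced subsampling needs group labels")
    rng = np.random.default_rng(seed)
    keep: list = []
    for group in pd.unique(incidence.groups):
        members = list(incidence.groups.index[incidence.groups == group])
        if len(members) > n:
            members = list(rng.choice(members, size=n, replace=False))
        keep.extend(members)
    keep = [iso for iso in incidence.isolates if iso in set(keep)]
    return incidence.subset_isolates(keep)


def _log_choose(n: np.ndarray, k: float) -> np.ndarray:
    """log C(n, k), defined as -inf where k > n."""
    n = np.asarray(n, dtype=float)
    out = np.full(n.shape, -np.inf)
    valid = n >= k
    nv = n[valid]
    out[valid] = gammaln(nv + 1) - gammaln(k + 1) - gammaln(nv - k + 1)
    return out


def analytic_rarefaction(incidence: IncidenceMatrix, t) -> float | np.ndarray:
    """Exact expected richness among t randomly chosen isolates.

    Computes ``S_obs - sum_i C(T - T_i, t) / C(T, t)`` with log-space
    binomial coefficients; the expectation over all size-t subsets, so
    no Monte Carlo noise.
    """
    T = incidence.T
    t_arr = np.atleast_1d(np.asarray(t, dtype=int))
    if (t_arr < 1).any() or (t_arr > T).any():
        raise ValueError(f"t must lie in [1, {T}]")
    Ti = incidence.incidence_freq.to_numpy(float)
    Ti = Ti[Ti >= 1]
    S_obs = Ti.size
    out = np.empty(t_arr.shape, dtype=float)
    for idx, tt in enumerate(t_arr):
        log_miss = _log_choose(T - Ti, float(tt)) - _log_choose(
            np.array([T], dtype=float), float(tt)
        )
        out[idx] = S_obs - np.exp(log_miss).sum()
    return out if np.ndim(t) else float(out[0])


def collector_curve(
    incidence: IncidenceMatrix,
    order=None,
    n_perm: int | None = None,
    seed: int = 0,
    group: str = "all",
    balance_first: bool = True,
) -> AccumulationCurve:
    """Cumulative distinct-item counts along isolate orderings.

    With ``order`` given, returns the raw collector's curve for that
    ordering. With ``n_perm`` given, returns the mean curve over that
    many seeded random orderings — the resampled estimate of the
    rarefaction expectation. ``balance_first`` allocates first positions
    evenly across isolates over the permutations (a stratification that
    leaves every curve point unbiased while removing most of the Monte
    Carlo variance at small t, where it is largest).
    """
    presence = incidence.presence.to_numpy(dtype=bool)
    T = incidence.T
    isolates = list(incidence.isolates)
    if (order is None) == (n_perm is None):
        raise ValueError("give exactly one of order or n_perm")
    if order is not None:
        positions = [isolates.index(o) for o in order]
        if sorted(positions) != list(range(T)):
            raise ValueError("order is not a permutation of the isolates")
        curve = _one_collector(presence, np.asarray(positions))
        data = pd.DataFrame(
            {"t": np.arange(1, T + 1), "richness": curve.astype(float), "method": "collector"}
        )
        return AccumulationCurve(group=group, data=data)
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    if balance_first:
        reps = n_perm // T
        firsts = np.tile(np.arange(T), reps)
        remainder = n_perm - reps * T
        if remainder:
            firsts = np.concatenate(
                [firsts, rng.choice(T, size=remainder, replace=False)]
            )
    else:
        firsts = rng.integers(T, size=n_perm)
    total = np.zeros(T)
    for first in firsts:
        perm = rng.permutation(T)
        pos = np.nonzero(perm == first)[0][0]
        perm[0], perm[pos] = perm[pos], perm[0]
        total += _one_collector(presence, perm)
    data = pd.DataFrame(
        {"t": np.arange(1, T + 1), "richness": total / n_perm, "method": "collector"}
    )
    return AccumulationCurve(group=group, data=data, n_perm=n_perm, seed=seed)


def _one_collector(presence: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Distinct-item counts along one ordering (items x isolates input)."""
    first_seen = np.argmax(presence[:, order], axis=1)
    counts = np.bincount(first_seen, minlength=order.size)
    return np.cumsum(counts)


def chao2_unseen(Q1: int, Q2: int, T: int) -> float:
    """Chao2 estimate of the number of unseen items.

    ``((T-1)/T) * Q1^2 / (2 Q2)`` when duplicates exist, else the
    bias-corrected ``((T-1)/T) * Q1 (Q1 - 1) / 2``.
    """
    if T < 2:
        raise ValueError("T must be >= 2")
    if Q1 < 0 or Q2 < 0:
        raise ValueError("Q1 and Q2 must be nonnegative")
    factor = (T - 1) / T
    if Q2 > 0:
        return factor * Q1**2 / (2 * Q2)
    return factor * Q1 * (Q1 - 1) / 2


def extrapolate_richness(incidence: IncidenceMatrix, t_star) -> float | np.ndarray:
    """Expected richness at T + t* additional isolates.

    ``S_obs + Q0_hat * [1 - (1 - Q1/(Q1 + T*Q0_hat))^t*]``; approaches
    the Chao2 asymptote ``S_obs + Q0_hat`` as t* grows and returns
    S_obs at t* = 0 or when no unseen richness is estimated.
    """
    t_arr = np.atleast_1d(np.asarray(t_star, dtype=float))
    if (t_arr < 0).any():
        raise ValueError("t_star must be >= 0")
    S_obs = incidence.S_obs
    Q1, Q2, T = incidence.Q1, incidence.Q2, incidence.T
    q0 = chao2_unseen(Q1, Q2, T)
    if q0 == 0 or Q1 == 0:
        out = np.full(t_arr.shape, float(S_obs))
    else:
        rate = Q1 / (Q1 + T * q0)
        out = S_obs + q0 * (1.0 - (1.0 - rate) ** t_arr)
    return out if np.ndim(t_star) else float(out[0])


def rarefaction_curve(
    incidence: IncidenceMatrix,
    endpoint: int | None = 500,
    group: str = "all",
) -> AccumulationCurve:
    """Interpolated curve over 1..T, extrapolated out to ``endpoint`` isolates."""
    T = incidence.T
    t_interp = np.arange(1, T + 1)
    interp = analytic_rarefaction(incidence, t_interp)
    frames = [
        pd.DataFrame({"t": t_interp, "richness": interp, "method": "interpolated"})
    ]
    if endpoint is not None and endpoint > T:
        t_extra = np.arange(T + 1, endpoint + 1)
        extra = extrapolate_richness(incidence, t_extra - T)
        frames.append(
            pd.DataFrame({"t": t_extra, "richness": extra, "method": "extrapolated"})
        )
    return AccumulationCurve(group=group, data=pd.concat(frames, ignore_index=True))


def coverage_targets(incidence: IncidenceMatrix, fractions) -> dict[float, int]:
    """Smallest isolate counts reaching target fractions of observed richness.

    For each fraction p the solver returns the least t with
    ``E[S(t)] >= p * S_obs`` on the interpolated curve — coverage is
    relative to the observed total, so p = 1 requires all T isolates
    whenever uniques exist.
    """
    fractions = list(fractions)
    if any(not (0 < p <= 1) for p in fractions):
        raise ValueError("fractions must lie in (0, 1]")
    T = incidence.T
    curve = analytic_rarefaction(incidence, np.arange(1, T + 1))
    S_obs = incidence.S_obs
    out: dict[float, int] = {}
    for p in fractions:
        target = p * S_obs
        reached = np.nonzero(curve >= target - 1e-9)[0]
        out[p] = int(reached[0] + 1) if reached.size else T
    return out


def end_slope(incidence: IncidenceMatrix) -> float:
    """Slope of the interpolated curve at its end: E[S(T)] - E[S(T-1)].

    Equals Q1/T (the per-isolate rate of still-unique items); a group
    near zero is close to saturation of its observed chemistry.
    """
    T = incidence.T
    if T < 2:
        raise ValueError("need at least two isolates")
    values = analytic_rarefaction(incidence, np.array([T - 1, T]))
    return float(values[1] - values[0])
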