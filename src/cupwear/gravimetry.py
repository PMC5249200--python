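"""Gravimetric reference workflow.

Soak-corrected cumulative weight loss, steady-state wear-rate regression,
and the nonparametric Kruskal-Wallis comparison between materials — the
gold-standard workflow against which CT wear estimates are validated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "WeightSeries",
    "GravimetricResult",
    "soak_correct",
    "wear_rate",
    "kruskal_wallis",
    "KruskalWallisResult",
    "analyze_series",
    "read_weight_series_csv",
    "write_weight_series_csv",
]


class GravimetryError(ValueError):
    pass


@dataclass
class WeightSeries:
    """Per-specimen weighings on the cycle grid plus the paired soak control.

    ``weights`` are the reported masses in mg (each already the mean of the
    triplicate weighings); ``control_weights`` come from the unloaded soak
    control cup kept in lubricant, weighed at the same stops.
    """

    specimen_id: str
    material_label: str
    cycles: np.ndarray
    weights: np.ndarray
    control_weights: np.ndarray

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        self.control_weights = np.asarray(self.control_weights, dtype=float)
        if self.cycles.ndim != 1 or len(self.cycles) < 2:
            raise GravimetryError("need at least two weighing stops")
        if self.cycles[0] != 0.0 or np.any(np.diff(self.cycles) <= 0):
            raise GravimetryError("cycles must be strictly increasing from 0")
        if len(self.weights) != len(self.cycles):
            raise GravimetryError("weights and cycles length mismatch")
        if len(self.control_weights) != len(self.cycles):
            raise GravimetryError("control grid must match specimen grid")
        if np.any(self.weights <= 0) or np.any(self.control_weights <= 0):
            raise GravimetryError("weights must be positive")


@dataclass
class GravimetricResult:
    specimen_id: str
    material_label: str
    cycles: np.ndarray
    cumulative_loss: np.ndarray  # mg, soak corrected, loss[0] == 0
    wear_rate: float             # mg/Mc
    rate_fit_r2: float
    steady_state_from: float = 0.4

    @property
    def total_loss(self) -> float:
        """Soak-corrected loss at the final stop (mg)."""
        return float(self.cumulative_loss[-1])


def soak_correct(series: WeightSeries) -> np.ndarray:
    """Soak-corrected cumulative mass loss (mg) at each stop.

    loss(t) = (w(0) - w(t)) + (c(t) - c(0)): the specimen's apparent weight
    loss plus the control cup's fluid-uptake gain over the same interval
    (standard practice for simulator wear testing).  Exactly additive:
    shifting all specimen weights by a constant leaves losses unchanged.
    """
    w, c = series.weights, series.control_weights
    return (w[0] - w) + (c - c[0])


def wear_rate(
    losses: np.ndarray,
    cycles: np.ndarray,
    steady_state_from: float = 0.4,
) -> tuple[float, float]:
    """Steady-state wear rate (mg/Mc) by ordinary least squares.

    Fits loss vs cycles over the stops with ``cycles >= steady_state_from``
    (default drops only the zero point, treating everything past the first
    weighing interval as steady state).  Returns ``(slope, r_squared)``.
    """
    losses = np.asarray(losses, dtype=float)
    cycles = np.asarray(cycles, dtype=float)
    sel = cycles >= steady_state_from
    if sel.sum() < 2:
        raise GravimetryError(
            f"need >= 2 stops at/after {steady_state_from} Mc, have {int(sel.sum())}"
        )
    if np.ptp(losses[sel]) == 0:  # constant losses: define slope 0, perfect fit
        return 0.0, 1.0
    res = stats.linregress(cycles[sel], losses[sel])
    return float(res.slope), float(res.rvalue**2)


def analyze_series(series: WeightSeries, steady_state_from: float = 0.4) -> GravimetricResult:
    """Full gravimetric reduction of one specimen: correction + regression."""
    losses = soak_correct(series)
    slope, r2 = wear_rate(losses, series.cycles, steady_state_from)
    return GravimetricResult(
        specimen_id=series.specimen_id,
        material_label=series.material_label,
        cycles=series.cycles,
        cumulative_loss=losses,
        wear_rate=slope,
        rate_fit_r2=r2,
        steady_state_from=steady_state_from,
    )


@dataclass
class KruskalWallisResult:
    H: float
    p_value: float
    method: str  # "exact" or "chi-square"
    n_groups: int
    n_total: int


def _h_statistic(ranks_by_group: list[np.ndarray], tie_correction: float, n: int) -> float:
    h = 0.0
    for r in ranks_by_group:
        h += r.sum() ** 2 / len(r)
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    return h / tie_correction if tie_correction > 0 else math.nan


def kruskal_wallis(groups: list, exact_max_n: int = 12) -> KruskalWallisResult:
    """Kruskal-Wallis H test with tie correction.

    For total sample size N <= ``exact_max_n`` the p-value is computed
    exactly, by full enumeration of every assignment of the pooled ranks to
    the groups (1680 partitions for three groups of three) — the chi-square
    approximation is unreliable at the tiny per-group sizes typical of
    simulator studies (n = 3).  Larger samples use the chi-square
    approximation.  The method actually used is reported in the result.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise GravimetryError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise GravimetryError("empty group")
    sizes = [len(g) for g in groups]
    n = sum(sizes)
    if n < 3:
        raise GravimetryError("need at least 3 observations in total")

    pooled = np.concatenate(groups)
    ranks = stats.rankdata(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n**3 - n)
    if tie_corr == 0.0:  # all observations identical
        return KruskalWallisResult(0.0, 1.0, "exact", len(groups), n)

    bounds = np.cumsum([0] + sizes)
    obs_groups = [ranks[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
    h_obs = _h_statistic(obs_groups, tie_corr, n)

    if n <= exact_max_n:
        p = _exact_pvalue(ranks, sizes, tie_corr, h_obs)
        return KruskalWallisResult(float(h_obs), p, "exact", len(groups), n)

    p = stats.distributions.chi2.sf(h_obs, len(groups) - 1)
    return KruskalWallisResult(float(h_obs), float(p), "chi-square", len(groups), n)


def _exact_pvalue(ranks: np.ndarray, sizes: list[int], tie_corr: float,
                  h_obs: float) -> float:
    """Exact permutation p-value P(H >= H_obs) by full enumeration of every
    assignment of the pooled ranks to groups of the given sizes.

    The outer groups are enumerated recursively; the final two groups are
    evaluated vectorized (the second-to-last as a combination batch, the
    last as the complement), which keeps N = 15 with three groups of five
    (756,756 partitions) to well under a second.
    """
    n = len(ranks)
    k = len(sizes)
    coef = 12.0 / (n * (n + 1))
    eps = 1e-12
    count_ge = 0
    total = 0

    def recurse(remaining: np.ndarray, level: int, prefix: float) -> None:
        nonlocal count_ge, total
        if level == k - 2:
            rem_ranks = ranks[remaining]
            pos = np.fromiter(
                (i for c in combinations(range(len(remaining)), sizes[level]) for i in c),
                dtype=np.intp,
            ).reshape(-1, sizes[level])
            s_pen = rem_ranks[pos].sum(axis=1)
            s_last = rem_ranks.sum() - s_pen
            h = (coef * (prefix + s_pen**2 / sizes[level]
                         + s_last**2 / sizes[level + 1]) - 3.0 * (n + 1)) / tie_corr
            count_ge += int(np.count_nonzero(h >= h_obs - eps))
            total += len(h)
            return
        for chosen in combinations(range(len(remaining)), sizes[level]):
            chosen = np.asarray(chosen, dtype=np.intp)
            s = ranks[remaining[chosen]].sum()
            mask = np.ones(len(remaining), dtype=bool)
            mask[chosen] = False
            recurse(remaining[mask], level + 1, prefix + s**2 / sizes[level])

    recurse(np.arange(n), 0, 0.0)
    return count_ge / total


def _rank_partitions(ranks: np.ndarray, sizes: list[int]):
    """Yield every distinct assignment of the pooled ranks to groups of the
    given sizes (multiset partitions by index, so ties are handled by
    position)."""
    idx = tuple(range(len(ranks)))

    def recurse(remaining: tuple, k: int):
        if k == len(sizes) - 1:
            yield [np.asarray(remaining)]
            return
        for chosen in combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in chosen)
            for tail in recurse(rest, k + 1):
                yield [np.asarray(chosen)] + tail

    for parts in recurse(idx, 0):
        yield [ranks[p] for p in parts]


# ---------------------------------------------------------------- CSV I/O

_CSV_COLUMNS = ["specimen_id", "material", "cycles_Mc", "weight_mg", "control_weight_mg"]


def write_weight_series_csv(path, series_list: list[WeightSeries]) -> None:
    """Write weight series in the long-form schema (one row per stop)."""
    rows = []
    for s in series_list:
        for t, w, c in zip(s.cycles, s.weights, s.control_weights):
            rows.append((s.specimen_id, s.material_label, t, w, c))
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_weight_series_csv(path) -> list[WeightSeries]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise GravimetryError(f"weight-series CSV missing columns: {sorted(missing)}")
    out = []
    for sid, sub in df.groupby("specimen_id", sort=False):
        sub = sub.sort_values("cycles_Mc")
        out.append(
            WeightSeries(
                specimen_id=str(sid),
                material_label=str(sub["material"].iloc[0]),
                cycles=sub["cycles_Mc"].to_numpy(),
                weights=sub["weight_mg"].to_numpy(),
                control_weights=sub["control_weight_mg"].to_numpy(),
            )
        )
    return out
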