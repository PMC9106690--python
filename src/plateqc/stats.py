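"""Repeatability summaries and rank-based condition comparison.

Repeatability is quantified per compound and condition by the relative
standard deviation, RSD = 100 * s / x̄ (sample standard deviation over the
arithmetic mean of the retained normalized values), with 15% as the usual
acceptance tolerance in targeted LC–MS work.

Conditions are compared non-parametrically: for each compound the chosen
metric (RSD by default) is ranked 1..n across the conditions (1 = best,
ties averaged, missing conditions absent), and a Kruskal–Wallis test is run
on the condition columns of that rank matrix, followed by a Tukey–Kramer
studentized-range comparison of the mean ranks.  Ranking per compound first
keeps compounds with large RSDs from dominating the test.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .config import RunConfig
from .errors import ConfigError
from .panel import FIA, LC, Panel
from .qc import QCResult


# ---------------------------------------------------------------- RSD ----

def compound_rsd(values) -> float:
    """Percent RSD: 100 * sample sd (n-1 denominator) / arithmetic mean.

    Returns NaN when the mean is non-positive or fewer than two values
    remain.
    """
    vals = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(vals) < 2:
        return float("nan")
    mean = vals.mean()
    if mean <= 0:
        return float("nan")
    return 100.0 * vals.std(ddof=1) / mean


@dataclass
class RepeatabilitySummary:
    """The tables surface: detected counts, RSDs and below-threshold rates."""

    #: compound x condition percent RSD (NaN where not detected)
    rsd: pd.DataFrame
    #: class x condition detected-compound counts
    detected_counts: pd.DataFrame
    #: LC/FIA x condition median RSD
    median_rsd_by_type: pd.DataFrame
    #: class x condition median RSD
    median_rsd_by_class: pd.DataFrame
    #: (measurement_type, condition) -> (n_below_threshold, n_detected)
    below_threshold: dict[tuple[str, str], tuple[int, int]]
    rsd_threshold_pct: float


def summarize(qc: QCResult, config: RunConfig | None = None
              ) -> RepeatabilitySummary:
    """Build the repeatability summary from a completed QC run."""
    config = config or qc.config
    panel = qc.panel
    conditions: list[str] = []
    for c in qc.sample_meta["condition"]:
        if c not in conditions:
            conditions.append(c)
    compounds = list(qc.normalized.columns)

    rsd = pd.DataFrame(np.nan, index=compounds, columns=conditions)
    for (name, cond), vals in qc.retained.items():
        rsd.loc[name, cond] = compound_rsd(vals)

    detected = pd.DataFrame(
        0, index=[c.name for c in panel.classes], columns=conditions)
    for (name, cond), vals in qc.retained.items():
        if len(vals):
            detected.loc[panel.class_of(name), cond] += 1

    by_type = pd.DataFrame(np.nan, index=[LC, FIA], columns=conditions)
    below: dict[tuple[str, str], tuple[int, int]] = {}
    for mtype in (LC, FIA):
        names = [n for n in compounds
                 if panel.measurement_type_of(n) == mtype]
        sub = rsd.loc[names]
        for cond in conditions:
            col = sub[cond].dropna()
            if len(col):
                by_type.loc[mtype, cond] = float(col.median())
            below[(mtype, cond)] = (
                int((col < config.rsd_threshold_pct).sum()), int(len(col)))

    by_class = pd.DataFrame(np.nan, index=[c.name for c in panel.classes],
                            columns=conditions)
    for cls in by_class.index:
        names = [n for n in compounds if panel.class_of(n) == cls]
        if names:
            by_class.loc[cls] = rsd.loc[names].median(axis=0, skipna=True)

    return RepeatabilitySummary(
        rsd=rsd, detected_counts=detected, median_rsd_by_type=by_type,
        median_rsd_by_class=by_class, below_threshold=below,
        rsd_threshold_pct=config.rsd_threshold_pct)


# ------------------------------------------------------------- ranking ----

MISSING_IGNORE = "ignore"
MISSING_WORST = "worst_rank"


def rank_conditions(metric: pd.DataFrame,
                    missing: str = MISSING_IGNORE) -> pd.DataFrame:
    """Rank each compound's metric across conditions (1 = lowest).

    Ties receive averaged ranks.  With ``missing="ignore"`` (default) a
    missing condition gets no rank and the remaining conditions are ranked
    1..m; with ``missing="worst_rank"`` every missing cell is assigned the
    worst-category rank n_conditions.  Compounds missing everywhere are
    dropped.
    """
    if missing not in (MISSING_IGNORE, MISSING_WORST):
        raise ConfigError(f"unknown missing mode {missing!r}")
    n = metric.shape[1]
    if n < 2:
        raise ConfigError("need at least 2 conditions to rank")
    rows = {}
    for compound, row in metric.iterrows():
        present = row.dropna()
        if present.empty:
            continue
        ranks = pd.Series(np.nan, index=metric.columns)
        ranks[present.index] = sps.rankdata(present.to_numpy())
        if missing == MISSING_WORST:
            ranks[row.isna()] = float(n)
        rows[compound] = ranks
    return pd.DataFrame(rows).T.reindex(columns=metric.columns)


# ------------------------------------------------------ Kruskal–Wallis ----

@dataclass
class KruskalResult:
    H: float
    p: float
    dof: int
    n_total: int
    method: str
    group_sizes: tuple[int, ...] = ()
    mean_ranks: tuple[float, ...] = ()


def _h_from_ranks(ranks: np.ndarray, sizes: list[int],
                  tie_term: float) -> float:
    n_total = len(ranks)
    h = 0.0
    start = 0
    for n_i in sizes:
        mean_rank = ranks[start:start + n_i].mean()
        h += n_i * (mean_rank - (n_total + 1) / 2.0) ** 2
        start += n_i
    h *= 12.0 / (n_total * (n_total + 1))
    correction = 1.0 - tie_term / (n_total ** 3 - n_total)
    if correction <= 0:  # every pooled value identical
        return 0.0
    return h / correction


def _tie_term(pooled: np.ndarray) -> float:
    _, counts = np.unique(pooled, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups, p_method: str = "chi2") -> KruskalResult:
    """Kruskal–Wallis H test with tie correction.

    ``H = 12 / (N (N+1)) * sum n_i (R̄_i - (N+1)/2)^2`` divided by the tie
    correction ``1 - sum(t^3 - t) / (N^3 - N)``; when every value is
    identical the statistic is 0 and p = 1 by convention.

    ``p_method="chi2"`` uses the chi-squared approximation with k-1 degrees
    of freedom; ``p_method="exact"`` enumerates every assignment of the
    pooled values to groups of the observed sizes (only feasible for small
    N) and reports the exact permutation probability of ``H >= H_obs``.
    """
    arrays = [np.asarray(pd.Series(g).dropna(), dtype=float) for g in groups]
    arrays = [a for a in arrays if len(a)]
    if len(arrays) < 2:
        raise ConfigError("need at least 2 non-empty groups")
    sizes = [len(a) for a in arrays]
    pooled = np.concatenate(arrays)
    n_total = len(pooled)
    ranks = sps.rankdata(pooled)
    tie_term = _tie_term(pooled)
    h = _h_from_ranks(ranks, sizes, tie_term)
    dof = len(arrays) - 1

    mean_ranks = []
    start = 0
    for n_i in sizes:
        mean_ranks.append(float(ranks[start:start + n_i].mean()))
        start += n_i

    if np.all(pooled == pooled[0]):
        return KruskalResult(0.0, 1.0, dof, n_total, p_method, tuple(sizes),
                             tuple(mean_ranks))

    if p_method == "chi2":
        p = float(sps.chi2.sf(h, dof))
    elif p_method == "exact":
        if n_total > 10:
            raise ConfigError("exact enumeration limited to N <= 10")
        p = _exact_p(ranks, sizes, tie_term, h)
    else:
        raise ConfigError(f"unknown p_method {p_method!r}")
    return KruskalResult(float(h), p, dof, n_total, p_method, tuple(sizes),
                         tuple(mean_ranks))


def _exact_p(ranks: np.ndarray, sizes: list[int], tie_term: float,
             h_obs: float) -> float:
    """Exact permutation p by enumerating group assignments of the ranks."""
    idx = tuple(range(len(ranks)))
    count = 0
    total = 0

    def recurse(remaining: tuple[int, ...], k: int,
                chosen: list[np.ndarray]) -> None:
        nonlocal count, total
        if k == len(sizes):
            perm = np.concatenate(chosen)
            h = _h_from_ranks(perm, sizes, tie_term)
            total += 1
            if h >= h_obs - 1e-9:
                count += 1
            return
        if k == len(sizes) - 1:
            recurse((), k + 1, chosen + [ranks[list(remaining)]])
            return
        for combo in itertools.combinations(remaining, sizes[k]):
            rest = tuple(i for i in remaining if i not in set(combo))
            recurse(rest, k + 1, chosen + [ranks[list(combo)]])

    recurse(idx, 0, [])
    return count / total


# -------------------------------------------------------- Tukey–Kramer ----

@dataclass
class PairwiseResult:
    group_i: int
    group_j: int
    diff: float      # mean rank (or mean value) difference, i - j
    q: float         # studentized-range statistic
    p: float
    significant: bool


def tukey_kramer_on_ranks(groups, alpha: float = 0.05,
                          use_ranks: bool = True) -> list[PairwiseResult]:
    """All-pairs post-hoc comparison after a Kruskal–Wallis test.

    Pools all values, ranks them, and compares mean ranks R̄_i - R̄_j
    against ``q_{alpha,k,inf} * sqrt(N(N+1)/12 * (1/n_i + 1/n_j) / 2)``
    (studentized-range quantile with infinite degrees of freedom,
    accommodating unequal group sizes).  With ``use_ranks=False`` the same
    comparison is made on the raw group means with a pooled-variance
    standard error (classic Tukey–Kramer).
    """
    arrays = [np.asarray(pd.Series(g).dropna(), dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ConfigError("Tukey–Kramer needs at least 2 groups")
    k = len(arrays)
    sizes = np.array([len(a) for a in arrays])
    if (sizes == 0).any():
        raise ConfigError("empty group")
    n_total = int(sizes.sum())

    if use_ranks:
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        means, start = [], 0
        for n_i in sizes:
            means.append(ranks[start:start + n_i].mean())
            start += n_i
        variance = n_total * (n_total + 1) / 12.0
        df = np.inf
    else:
        means = [a.mean() for a in arrays]
        df = n_total - k
        if df <= 0:
            raise ConfigError("not enough values for within-group variance")
        variance = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df

    results = []
    for i, j in itertools.combinations(range(k), 2):
        diff = means[i] - means[j]
        se = math.sqrt(variance * (1.0 / sizes[i] + 1.0 / sizes[j]) / 2.0)
        if se == 0:
            q = 0.0 if diff == 0 else math.inf
        else:
            q = abs(diff) / se
        p = float(sps.studentized_range.sf(q, k, df)) if math.isfinite(q) else 0.0
        results.append(PairwiseResult(i, j, float(diff), float(q), p,
                                      p <= alpha))
    return results


# ------------------------------------------------------- rank-based KW ----

@dataclass
class RankTestResult:
    """Per-compound ranking of a metric across conditions plus the tests."""

    ranks: pd.DataFrame
    H: float
    p: float
    posthoc: dict[tuple[str, str], PairwiseResult] = field(default_factory=dict)
    alpha: float = 0.05


def compare_conditions(metric: pd.DataFrame, alpha: float = 0.05,
                       missing: str = MISSING_IGNORE,
                       use_ranks: bool = True) -> RankTestResult:
    """Rank a compound x condition metric, then test the condition columns.

    This is the full rank-based procedure: per-compound ranks 1..n across
    conditions, Kruskal–Wallis over the condition columns of the rank
    matrix, then Tukey–Kramer post-hoc on the same columns.
    """
    ranks = rank_conditions(metric, missing=missing)
    columns = list(ranks.columns)
    groups = [ranks[c].dropna().to_numpy() for c in columns]
    kw = kruskal_wallis(groups)
    pairs = tukey_kramer_on_ranks(groups, alpha=alpha, use_ranks=use_ranks)
    posthoc = {(columns[r.group_i], columns[r.group_j]): r for r in pairs}
    return RankTestResult(ranks=ranks, H=kw.H, p=kw.p, posthoc=posthoc,
                          alpha=alpha)
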