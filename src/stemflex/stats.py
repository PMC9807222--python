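"""Diameter-class pooling and nonparametric group comparisons.

Stems are pooled into three diameter classes (narrow 1.8-3.9 mm, medium
3.9-5.9 mm, large > 5.9 mm) and each trait is compared across the four growth
categories within a class with a tie-corrected Kruskal-Wallis test, Dunn's
post-hoc pairwise z-tests on mean ranks, and a compact letter display.
Monotone trait relations are summarized by the Spearman rank correlation with
its t-statistic t = R_s sqrt((n-2)/(1-R_s^2)).
"""

from __future__ import annotations

import itertools
import math
import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps


@dataclass(frozen=True)
class ClassBounds:
    """Diameter class edges in mm.

    Boundary rule: a diameter equal to ``narrow_medium`` (3.9) is Medium and
    one equal to ``medium_large`` (5.9) is Medium; Large is strictly > 5.9.
    Diameters below ``lower`` fall in a below-range class that downstream
    analyses exclude.
    """

    lower: float = 1.8
    narrow_medium: float = 3.9
    medium_large: float = 5.9


CLASS_ORDER = ("narrow", "medium", "large")


def assign_diameter_class(d: float, bounds: ClassBounds = ClassBounds()) -> str:
    """Map a stem diameter (mm) to its class label."""
    if d <= 0:
        raise ValueError("diameter must be positive")
    if d < bounds.lower:
        return "below"
    if d < bounds.narrow_medium:
        return "narrow"
    if d <= bounds.medium_large:
        return "medium"
    return "large"


@dataclass
class KWResult:
    """Tie-corrected Kruskal-Wallis outcome."""

    H: float
    df: int
    p: float
    groups: list[str]
    excluded: dict[str, str] = field(default_factory=dict)


def _mid_ranks(groups: dict[str, np.ndarray]):
    names = list(groups)
    values = np.concatenate([groups[g] for g in names])
    ranks = _sps.rankdata(values)  # mid-ranks
    out, i = {}, 0
    for g in names:
        n = len(groups[g])
        out[g] = ranks[i:i + n]
        i += n
    return out, ranks


def _tie_term(ranks: np.ndarray) -> float:
    # sum of t^3 - t over tie groups
    _, counts = np.unique(ranks, return_counts=True)
    return float(np.sum(counts.astype(float) ** 3 - counts))


def kruskal_wallis(groups: dict[str, "np.ndarray | list"],
                   min_size: int = 3) -> KWResult:
    """Tie-corrected Kruskal-Wallis H test across named groups.

    Groups smaller than ``min_size`` are excluded (with a recorded reason)
    rather than failing the whole comparison, mirroring field practice of
    dropping undersampled cells. H is computed on mid-ranks and divided by
    the tie correction 1 - sum(t^3 - t)/(N^3 - N); the p-value comes from
    the chi-squared distribution with k-1 degrees of freedom. If all values
    are identical the test degenerates to H = 0, p = 1.
    """
    cleaned: dict[str, np.ndarray] = {}
    excluded: dict[str, str] = {}
    for g, v in groups.items():
        arr = np.asarray(v, dtype=float)
        if not np.isfinite(arr).all():
            raise ValueError(f"group {g!r} contains non-finite values")
        if len(arr) < min_size:
            excluded[g] = f"n={len(arr)} < min_size={min_size}"
        else:
            cleaned[g] = arr
    if len(cleaned) < 2:
        raise ValueError("need at least 2 groups of sufficient size")
    per_group, ranks = _mid_ranks(cleaned)
    N = len(ranks)
    H = (12.0 / (N * (N + 1))
         * sum(len(r) * (r.mean() - (N + 1) / 2.0) ** 2
               for r in per_group.values()))
    tie = _tie_term(ranks)
    denom = 1.0 - tie / (N ** 3 - N)
    if denom <= 0:  # every value identical
        H_corr, p = 0.0, 1.0
    else:
        H_corr = H / denom
        p = float(_sps.chi2.sf(H_corr, df=len(cleaned) - 1))
    return KWResult(H=float(H_corr), df=len(cleaned) - 1, p=p,
                    groups=list(cleaned), excluded=excluded)


def dunn_posthoc(groups: dict[str, "np.ndarray | list"],
                 adjustment: str = "none") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Dunn's post-hoc pairwise z-tests on mean ranks.

    z_ij = (Rbar_i - Rbar_j) / sqrt([N(N+1)/12 - sum(t^3-t)/(12(N-1))]
    (1/n_i + 1/n_j)) with mid-ranks over the pooled sample and the usual tie
    correction; two-sided p from the standard normal. ``adjustment`` is one
    of ``"none"``, ``"bonferroni"``, ``"holm"``.

    Returns (z, p) as symmetric DataFrames indexed by group name.
    """
    cleaned = {g: np.asarray(v, dtype=float) for g, v in groups.items()
               if len(v) > 0}
    if len(cleaned) < 2:
        raise ValueError("need at least 2 non-empty groups")
    per_group, ranks = _mid_ranks(cleaned)
    N = len(ranks)
    tie = _tie_term(ranks)
    var_base = N * (N + 1) / 12.0 - tie / (12.0 * (N - 1))
    names = list(cleaned)
    z = pd.DataFrame(0.0, index=names, columns=names)
    p = pd.DataFrame(1.0, index=names, columns=names)
    pairs = list(itertools.combinations(names, 2))
    raw = []
    for i, j in pairs:
        se = math.sqrt(var_base * (1.0 / len(per_group[i])
                                   + 1.0 / len(per_group[j])))
        zij = (per_group[i].mean() - per_group[j].mean()) / se if se > 0 else 0.0
        z.loc[i, j] = z.loc[j, i] = zij
        raw.append(2.0 * _sps.norm.sf(abs(zij)))
    adj = _adjust_pvalues(np.array(raw), adjustment)
    for (i, j), pv in zip(pairs, adj):
        p.loc[i, j] = p.loc[j, i] = pv
    return z, p


def _adjust_pvalues(p: np.ndarray, method: str) -> np.ndarray:
    m = len(p)
    if method == "none" or m == 0:
        return p
    if method == "bonferroni":
        return np.minimum(1.0, m * p)
    if method == "holm":
        order = np.argsort(p)
        adj = np.empty_like(p)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * p[idx])
            adj[idx] = min(1.0, running)
        return adj
    raise ValueError(f"unknown adjustment {method!r}")


def compact_letter_display(p: pd.DataFrame, alpha: float = 0.05) -> dict[str, str]:
    """Assign compact letters so that two groups share a letter iff their
    pairwise p-value is >= alpha (insert-and-absorb algorithm).

    Non-transitive significance patterns (A differs from C but neither
    differs from B) are expressed with multiple letters per group, e.g.
    A:"a", B:"ab", C:"b".
    """
    names = list(p.index)
    if list(p.columns) != names:
        raise ValueError("p matrix must be square with matching index/columns")
    # start with one set holding everything; split on each significant pair
    columns: list[set[str]] = [set(names)]
    for i, j in itertools.combinations(names, 2):
        if p.loc[i, j] < alpha:
            new_cols: list[set[str]] = []
            for col in columns:
                if i in col and j in col:
                    new_cols.append(col - {i})
                    new_cols.append(col - {j})
                else:
                    new_cols.append(col)
            # absorb: drop columns contained in another
            columns = [c for c in new_cols
                       if c and not any(c < d for d in new_cols if d != c)]
            # deduplicate
            seen, uniq = set(), []
            for c in columns:
                key = frozenset(c)
                if key not in seen:
                    seen.add(key)
                    uniq.append(c)
            columns = uniq
    # stable letter order: by first member's position in the input
    columns.sort(key=lambda c: min(names.index(g) for g in c))
    alphabet = string.ascii_lowercase
    letters = {g: "" for g in names}
    for k, col in enumerate(columns):
        ch = alphabet[k % 26] * (1 + k // 26)
        for g in names:
            if g in col:
                letters[g] += ch
    return letters


@dataclass
class CorrelationResult:
    """Spearman rank correlation with its t-statistic."""

    rs: float
    n: int
    t: float
    p: float
    unbounded_t: bool = False   # |R_s| == 1: t diverges, p pinned to 0


def spearman_t_from_r(rs: float, n: int) -> float:
    """t = R_s sqrt((n-2)/(1-R_s^2)) for a given coefficient and sample size."""
    if not -1 <= rs <= 1:
        raise ValueError("R_s must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(rs) == 1:
        return math.inf if rs > 0 else -math.inf
    return rs * math.sqrt((n - 2) / (1.0 - rs * rs))


def spearman_t(x, y) -> CorrelationResult:
    """Spearman rank-order correlation with t-approximation p-value.

    R_s is the Pearson correlation of mid-ranks; the two-sided p-value uses
    the t distribution with n-2 degrees of freedom, the approximation
    appropriate at the cohort sizes this package targets (hundreds of stem
    segments). A perfect monotone relation (|R_s| = 1) is reported with an
    unbounded-t flag and p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be paired 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    rx, ry = _sps.rankdata(x), _sps.rankdata(y)
    rs = float(np.corrcoef(rx, ry)[0, 1])
    rs = max(-1.0, min(1.0, rs))
    if abs(rs) == 1.0:
        return CorrelationResult(rs=rs, n=n,
                                 t=math.inf if rs > 0 else -math.inf,
                                 p=0.0, unbounded_t=True)
    t = spearman_t_from_r(rs, n)
    p = float(2.0 * _sps.t.sf(abs(t), df=n - 2))
    return CorrelationResult(rs=rs, n=n, t=t, p=p)
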