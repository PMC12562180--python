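"""Cross-trait gene-set overlap enrichment statistics.

Two gene sets drawn from a common background of N protein-coding genes
(default 20,000) form a 2x2 contingency table

                in B    not in B
    in A          a        b          a = |A ∩ B|, b = |A| - a
    not in A      c        d          c = |B| - a, d = N - |A| - |B| + a

Significance is assessed with the two-sided Fisher exact test
(point-probability rule) and the upper-tail hypergeometric probability;
effect size with the cross-product odds ratio (Haldane-Anscombe corrected
when a cell is zero, Wald interval on the log scale) and the enrichment
ratio observed/expected where expected = |A|·|B|/N.  Families of tests are
corrected with the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats
from scipy.special import logsumexp

DEFAULT_BACKGROUND_N = 20000

# relative slack on the point-probability comparison; absorbs floating-point
# noise when tables tie with the observed table's probability
_TIE_RTOL = 1e-7


class DomainError(ValueError):
    """Raised when inputs violate a contingency-table precondition."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 overlap table against a fixed gene background."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            if getattr(self, name) < 0:
                raise DomainError(f"cell {name} is negative")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class OverlapResult:
    """One pairwise gene-set comparison."""

    set_a_name: str
    set_b_name: str
    n_a: int
    n_b: int
    overlap: int
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    fisher_p: float
    hyper_p: float
    expected: float
    enrichment_ratio: float
    p_adjusted: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "set_a": self.set_a_name,
            "set_b": self.set_b_name,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "overlap": self.overlap,
            "expected": self.expected,
            "odds_ratio": self.odds_ratio,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "fisher_p": self.fisher_p,
            "hyper_p": self.hyper_p,
            "enrichment_ratio": self.enrichment_ratio,
            "p_adjusted": self.p_adjusted,
            "significant": self.significant,
        }


def contingency(n_a: int, n_b: int, overlap: int, n_background: int) -> ContingencyTable:
    """Build the 2x2 table from set sizes, overlap, and background size."""
    if not (0 <= overlap <= min(n_a, n_b)):
        raise DomainError("requires 0 <= overlap <= min(n_a, n_b)")
    if n_a + n_b - overlap > n_background:
        raise DomainError("requires n_a + n_b - overlap <= background N")
    return ContingencyTable(
        a=overlap, b=n_a - overlap, c=n_b - overlap, d=n_background - n_a - n_b + overlap
    )


def odds_ratio_ci(table: ContingencyTable, level: float = 0.95) -> tuple[float, float, float]:
    """Cross-product odds ratio with a Wald confidence interval on log-OR.

    With any zero cell, the Haldane-Anscombe 0.5 correction is added to all
    cells for both the estimate and the interval.
    """
    a, b, c, d = table.cells()
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(1 - (1 - level) / 2)
    log_or = math.log(or_)
    return or_, math.exp(log_or - z * se), math.exp(log_or + z * se)


def _log_support_pmf(table: ContingencyTable) -> tuple[np.ndarray, np.ndarray]:
    """Hypergeometric log-pmf over the full support for the table's margins."""
    r1 = table.a + table.b
    c1 = table.a + table.c
    n = table.n
    lo = max(0, r1 + c1 - n)
    hi = min(r1, c1)
    ks = np.arange(lo, hi + 1)
    logp = stats.hypergeom.logpmf(ks, n, c1, r1)
    return ks, logp


def fisher_two_sided(table: ContingencyTable) -> float:
    """Two-sided Fisher exact p by the point-probability rule.

    Sums (in log space) the probabilities of all tables with the observed
    margins whose point probability does not exceed the observed one, within
    relative tolerance 1e-7.  Degenerate margins give p = 1.
    """
    ks, logp = _log_support_pmf(table)
    if len(ks) == 1:
        return 1.0
    log_obs = logp[ks == table.a][0]
    include = logp <= log_obs + math.log1p(_TIE_RTOL)
    return float(min(1.0, math.exp(logsumexp(logp[include]))))


def hypergeom_upper(n_a: int, n_b: int, overlap: int, n_background: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts the overlap of a random n_a-subset with a fixed n_b-subset of
    the background; summation in log space.
    """
    table = contingency(n_a, n_b, overlap, n_background)
    ks, logp = _log_support_pmf(table)
    if overlap <= ks[0]:
        return 1.0  # whole support: the event is certain
    tail = logp[ks >= overlap]
    if len(tail) == 0:
        return 0.0
    return float(min(1.0, math.exp(logsumexp(tail))))


def enrichment_ratio(n_a: int, n_b: int, overlap: int, n_background: int) -> tuple[float, float]:
    """Expected overlap under independence and the observed/expected ratio."""
    if n_background <= 0:
        raise DomainError("background N must be positive")
    expected = n_a * n_b / n_background
    if expected == 0:
        raise DomainError("enrichment ratio undefined: expected overlap is zero")
    return expected, overlap / expected


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    q_(i) = p_(i)·m/i on the ascending sort, made monotone non-decreasing
    from the largest rank downward and capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise DomainError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    q = p[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


def pairwise_overlap(
    sets: Mapping[str, set],
    n_background: int = DEFAULT_BACKGROUND_N,
    alpha: float = 0.05,
) -> list[OverlapResult]:
    """All-pairs overlap enrichment with BH correction over the pair family.

    One result per unordered pair of set names (C(k, 2) results, in the
    mapping's iteration order); the BH family is exactly the pairs of this
    call, and significance is flagged at adjusted p < alpha.
    """
    names = list(sets)
    if len(names) < 2:
        raise DomainError("pairwise_overlap needs at least two sets")
    for name in names:
        if len(sets[name]) > n_background:
            raise DomainError(f"set {name!r} is larger than the background N")
    partial = []
    for na, nb in itertools.combinations(names, 2):
        sa, sb = sets[na], sets[nb]
        ov = len(sa & sb)
        tbl = contingency(len(sa), len(sb), ov, n_background)
        or_, lo, hi = odds_ratio_ci(tbl)
        fp = fisher_two_sided(tbl)
        hp = hypergeom_upper(len(sa), len(sb), ov, n_background)
        exp, ratio = enrichment_ratio(len(sa), len(sb), ov, n_background)
        partial.append((na, nb, sa, sb, ov, tbl, or_, lo, hi, fp, hp, exp, ratio))
    adj = bh_adjust([row[9] for row in partial])
    results = []
    for (na, nb, sa, sb, ov, tbl, or_, lo, hi, fp, hp, exp, ratio), q in zip(partial, adj):
        results.append(
            OverlapResult(
                set_a_name=na,
                set_b_name=nb,
                n_a=len(sa),
                n_b=len(sb),
                overlap=ov,
                table=tbl,
                odds_ratio=or_,
                ci_low=lo,
                ci_high=hi,
                fisher_p=fp,
                hyper_p=hp,
                expected=exp,
                enrichment_ratio=ratio,
                p_adjusted=float(q),
                significant=bool(q < alpha),
            )
        )
    return results


def exclusive_intersections(sets: Mapping[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive (UpSet-style) intersection counts.

    For every non-empty subset of set names, the number of elements belonging
    to exactly those sets; zero-count regions are omitted.  Keys are tuples
    of names in the mapping's order; counts sum to the size of the union.
    """
    names = list(sets)
    if not names:
        raise DomainError("exclusive_intersections needs at least one set")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(set(sets[c]) for c in combo))
            for other in names:
                if other not in combo:
                    inside -= sets[other]
            if inside:
                out[combo] = len(inside)
    return out
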