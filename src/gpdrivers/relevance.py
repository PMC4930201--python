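"""Statistical selection of relevant variables from the population pool.

A candidate variable is *relevant* when it appears in more pool functions
than chance would allow.  Under the null every variable is equally likely
to appear in a pool function (presence probability p0 = 1/V for V
candidates), so the number of functions containing a given variable is
Binomial(N, p0) for a pool of N functions.  The relevance threshold is the
smallest occurrence count whose exact upper-tail probability falls at or
below the significance level (default 0.001); the tail is computed by
exact summation, never a normal approximation.

Pool members whose referenced variables are all relevant are the
*modelling functions* — the only functions admitted to gradient analysis,
because they contain no randomly selected components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "OccurrenceCounts",
    "RelevanceReport",
    "count_occurrences",
    "binomial_tail",
    "relevance_threshold",
    "relevant_set",
    "modelling_functions",
]


@dataclass
class OccurrenceCounts:
    """Per-variable presence counts across pool functions (binary per function)."""

    counts: dict[str, int]
    pool_size: int


@dataclass
class RelevanceReport:
    alpha: float
    p0: float
    threshold: int
    counts: OccurrenceCounts
    relevant: list[str]
    modelling_functions: list = field(default_factory=list)

    def to_rows(self) -> list[dict]:
        """Table rows: variable, occurrence, relevant flag (descending count)."""
        ordered = sorted(self.counts.counts.items(), key=lambda kv: (-kv[1], kv[0]))
        return [
            {"variable": v, "occurrence": c, "relevant": v in set(self.relevant)}
            for v, c in ordered
        ]


def count_occurrences(pool, all_variables: list[str]) -> OccurrenceCounts:
    """Number of distinct pool functions containing each variable.

    Presence is binary per function: a variable used twice inside one
    function still counts once for that function.
    """
    if not pool.members:
        raise ValueError("empty pool")
    counts = {v: 0 for v in all_variables}
    for m in pool.members:
        for v in m.individual.variables():
            if v in counts:
                counts[v] += 1
            else:
                counts[v] = counts.get(v, 0) + 1
    return OccurrenceCounts(counts=counts, pool_size=len(pool.members))


def binomial_tail(n: int, p: float, t: int) -> float:
    """Exact upper tail P(X >= t) for X ~ Binomial(n, p), by direct summation."""
    if t <= 0:
        return 1.0
    if t > n:
        return 0.0
    q = 1.0 - p
    return math.fsum(
        math.comb(n, k) * (p ** k) * (q ** (n - k)) for k in range(t, n + 1)
    )


def relevance_threshold(
    pool_size: int, n_variables: int, alpha: float = 0.001, p0: float | None = None
) -> int:
    """Smallest occurrence count t with P(X >= t) <= alpha, X ~ Binomial(N, p0).

    ``p0`` defaults to the equiprobable-variable null 1/V.  Returns N + 1
    when no attainable count reaches significance.
    """
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    if p0 is None:
        if n_variables < 1:
            raise ValueError("n_variables must be >= 1 when p0 is not given")
        p0 = 1.0 / n_variables
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must lie in (0, 1)")
    for t in range(pool_size + 1):
        if binomial_tail(pool_size, p0, t) <= alpha:
            return t
    return pool_size + 1  # alpha unattainable even at full occurrence


def relevant_set(counts: OccurrenceCounts, threshold: int) -> list[str]:
    """Variables meeting the threshold, ordered by descending count then name."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    hits = [(v, c) for v, c in counts.counts.items() if c >= threshold]
    hits.sort(key=lambda kv: (-kv[1], kv[0]))
    return [v for v, _ in hits]


def modelling_functions(pool, relevant: list[str]) -> list:
    """Pool members whose (non-empty) variable set is within the relevant set."""
    rel = set(relevant)
    out = []
    for m in pool.members:
        used = m.individual.variables()
        if used and used <= rel:
            out.append(m)
    return out


def relevance_report(
    pool, all_variables: list[str], alpha: float = 0.001, p0: float | None = None
) -> RelevanceReport:
    """Full relevance analysis of a pool against its candidate variables."""
    counts = count_occurrences(pool, all_variables)
    threshold = relevance_threshold(counts.pool_size, len(all_variables), alpha, p0)
    relevant = relevant_set(counts, threshold)
    return RelevanceReport(
        alpha=alpha,
        p0=p0 if p0 is not None else 1.0 / len(all_variables),
        threshold=threshold,
        counts=counts,
        relevant=relevant,
        modelling_functions=modelling_functions(pool, relevant),
    )
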