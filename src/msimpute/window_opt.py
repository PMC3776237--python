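"""Optimal haplotype window selection per MS marker.

For each candidate window size the reference haplotypes are tallied: a
haplotype counts if it was observed at least ``min_count`` times and is
linked to one MS allele 100% of the time, or matches one MS allele at least
``concordance`` (default 90%) of the time, pooled across all breeds.  The
scan over increasing sizes stops when either

1. the tallied count reaches a maximum (a strict maximum confirmed by a
   decrease at the next size), or
2. growing the window yields a relative increase in tallied haplotypes of
   at most ``plateau_tol`` (default 1%).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from .panel import AssociationTable, build_table
from .phasing import HaplotypeSet

STOP_MAX_TALLY = "max-tally"
STOP_PLATEAU = "plateau"


@dataclass(frozen=True)
class TallyResult:
    """Tally statistics for one window size."""

    window_size: int
    n_unique_haplotypes: int
    n_tallied: int
    pct_tallied: float
    pct_population: float

    def __post_init__(self) -> None:
        if not (0 <= self.pct_tallied <= 1 and 0 <= self.pct_population <= 1):
            raise ValueError("tally fractions must lie in [0, 1]")
        if self.n_tallied > self.n_unique_haplotypes:
            raise ValueError("n_tallied exceeds n_unique_haplotypes")


@dataclass
class OptimizationTrace:
    """Full scan record for one marker."""

    marker: str
    candidate_sizes: list[int]
    tallies: list[TallyResult]
    chosen_size: int
    stop_reason: str


#: default candidate grid of total window sizes (SNP counts)
DEFAULT_SIZES = (20, 40, 50, 60, 70, 80, 90, 100, 110)


def tally_window(
    haps: HaplotypeSet,
    breeds: dict[str, str] | None = None,
    min_count: float = 4,
    concordance: float = 0.90,
) -> TallyResult:
    """Tally a phased haplotype set carrying MS linkage (see module doc)."""
    if not haps.pairs:
        raise ValueError("empty haplotype set")
    table = build_table(haps, breeds or {}, min_count=min_count, concordance=concordance)
    return tally_table(table)


def tally_table(table: AssociationTable) -> TallyResult:
    """Tally directly from an association table."""
    n_unique = len(table.entries)
    if n_unique == 0:
        raise ValueError("empty association table")
    tallied = table.tallied_haplotypes()
    tallied_obs = sum(table.entries[h].total_count for h in tallied)
    total_obs = table.total_observations
    return TallyResult(
        window_size=table.hap_length,
        n_unique_haplotypes=n_unique,
        n_tallied=len(tallied),
        pct_tallied=len(tallied) / n_unique,
        pct_population=tallied_obs / total_obs if total_obs else 0.0,
    )


def optimize_window(
    marker: str,
    provider: Callable[[int], HaplotypeSet],
    sizes: Sequence[int] = DEFAULT_SIZES,
    breeds: dict[str, str] | None = None,
    min_count: float = 4,
    concordance: float = 0.90,
    plateau_tol: float = 0.01,
) -> OptimizationTrace:
    """Scan window sizes in increasing order and pick the optimum.

    ``provider`` maps a window size to the phased (MS-linked) haplotype set
    at that size.  Sizes must be strictly increasing.  The scan evaluates
    lazily and stops as soon as a criterion triggers; the earlier-triggering
    size wins (a confirmed maximum at the previous size beats a plateau at
    the current one).
    """
    sizes = list(sizes)
    if len(sizes) < 2:
        raise ValueError("need at least 2 candidate window sizes")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("candidate sizes must be strictly increasing")

    tallies: list[TallyResult] = []
    evaluated: list[int] = []
    chosen = None
    reason = None
    for size in sizes:
        t = tally_window(provider(size), breeds, min_count, concordance)
        tallies.append(t)
        evaluated.append(size)
        if len(tallies) < 2:
            continue
        prev, cur = tallies[-2], tallies[-1]
        # criterion 1: previous size was a strict maximum, confirmed by a
        # decrease at this size
        prev_is_max = all(t0.n_tallied < prev.n_tallied for t0 in tallies[:-2]) if len(tallies) > 2 else True
        if cur.n_tallied < prev.n_tallied and prev_is_max:
            chosen, reason = evaluated[-2], STOP_MAX_TALLY
            break
        # criterion 2: relative growth <= plateau_tol
        if prev.n_tallied > 0:
            growth = (cur.n_tallied - prev.n_tallied) / prev.n_tallied
            if 0 <= growth <= plateau_tol:
                chosen, reason = size, STOP_PLATEAU
                break
    if chosen is None:
        # scan exhausted: the largest tally wins (first size achieving it)
        best = max(t.n_tallied for t in tallies)
        chosen = next(s for s, t in zip(evaluated, tallies) if t.n_tallied == best)
        reason = STOP_MAX_TALLY
    return OptimizationTrace(
        marker=marker,
        candidate_sizes=evaluated,
        tallies=tallies,
        chosen_size=chosen,
        stop_reason=reason,
    )
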