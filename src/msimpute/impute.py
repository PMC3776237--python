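"""MS genotype imputation by haplotype table lookup, with back-off.

Each of an animal's two phased window haplotypes is looked up independently
in the association table; a hit on a ``unique`` or ``concordant`` entry
returns that entry's most common MS allele.  A haplotype absent from the
table (e.g. a recombinant flank) is retried at progressively shorter,
centered sub-windows — the table is re-aggregated at each depth — down to a
floor; every back-off match is flagged with its depth so no shortened match
masquerades as a full-length one.  Imputation is a pure function of
(haplotype pair, table, settings).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import (
    AssociationTable,
    CLASS_AMBIGUOUS,
    CLASS_RARE,
    aggregate_trim,
)
from .phasing import HaplotypeSet, phase_window
from .types import MISSING_ALLELE, MsGenotype, PedigreeRecord, SnpGenotypeMatrix

STATUS_MATCHED = "matched"
STATUS_AMBIGUOUS = "ambiguous"
STATUS_UNMATCHED = "unmatched"


def status_backoff(depth: int) -> str:
    return f"backoff({depth})"


@dataclass(frozen=True)
class AlleleCall:
    """One imputed allele with its provenance."""

    allele: int  # bp, MISSING_ALLELE if unmatched
    confidence: float  # primary_fraction of the matched entry
    support: float  # total_count of the matched entry
    status: str
    backoff_depth: int = 0


@dataclass(frozen=True)
class ImputationResult:
    """Imputed diploid MS genotype for one animal at one marker."""

    animal_id: str
    marker: str
    call_1: AlleleCall
    call_2: AlleleCall
    strategy: str = ""

    @property
    def alleles(self) -> tuple[int, int]:
        return tuple(sorted((self.call_1.allele, self.call_2.allele)))

    @property
    def complete(self) -> bool:
        return (
            self.call_1.allele != MISSING_ALLELE
            and self.call_2.allele != MISSING_ALLELE
        )


class _BackoffCache:
    """Aggregated tables per back-off depth, built lazily."""

    def __init__(self, table: AssociationTable, step: int):
        self.table = table
        self.step = step
        self._cache: dict[int, AssociationTable] = {0: table}

    def at_depth(self, depth: int) -> AssociationTable:
        if depth not in self._cache:
            total = depth * self.step
            left = total // 2
            right = total - left
            self._cache[depth] = aggregate_trim(self.table, left, right)
        return self._cache[depth]


def _lookup(
    hap: str,
    cache: _BackoffCache,
    allow_ambiguous: bool,
    allow_rare: bool,
    backoff_floor: int,
) -> AlleleCall:
    length = cache.table.hap_length
    depth = 0
    while True:
        window_len = length - depth * cache.step
        if window_len < backoff_floor and depth > 0:
            return AlleleCall(MISSING_ALLELE, 0.0, 0.0, STATUS_UNMATCHED, depth - 1)
        table = cache.at_depth(depth)
        total_trim = depth * cache.step
        lo = total_trim // 2
        core = hap[lo : lo + window_len]
        entry = table.entries.get(core)
        if entry is not None:
            cls = entry.classify(table.min_count, table.concordance)
            usable = cls in ("unique", "concordant")
            if cls == CLASS_AMBIGUOUS and allow_ambiguous:
                usable = True
            if cls == CLASS_RARE and allow_rare:
                usable = True
            if usable:
                status = (
                    STATUS_AMBIGUOUS
                    if cls == CLASS_AMBIGUOUS or entry.primary_tied
                    else (status_backoff(depth) if depth else STATUS_MATCHED)
                )
                return AlleleCall(
                    allele=entry.primary_allele,
                    confidence=entry.primary_fraction,
                    support=entry.total_count,
                    status=status,
                    backoff_depth=depth,
                )
        depth += 1
        if length - depth * cache.step < backoff_floor:
            return AlleleCall(MISSING_ALLELE, 0.0, 0.0, STATUS_UNMATCHED, depth - 1)


def impute_animal(
    haps: tuple[str, str],
    table: AssociationTable,
    animal_id: str = "",
    allow_ambiguous: bool = False,
    allow_rare: bool = False,
    backoff_floor: int = 20,
    backoff_step: int = 10,
    strategy: str = "",
    _cache: _BackoffCache | None = None,
) -> ImputationResult:
    """Impute one animal's diploid MS genotype from its haplotype pair."""
    h1, h2 = (str(h) for h in haps)
    if len(h1) != table.hap_length or len(h2) != table.hap_length:
        raise ValueError(
            f"haplotype length {len(h1)}/{len(h2)} != table window "
            f"{table.hap_length}"
        )
    cache = _cache or _BackoffCache(table, backoff_step)
    c1 = _lookup(h1, cache, allow_ambiguous, allow_rare, backoff_floor)
    c2 = _lookup(h2, cache, allow_ambiguous, allow_rare, backoff_floor)
    return ImputationResult(
        animal_id=animal_id,
        marker=table.marker,
        call_1=c1,
        call_2=c2,
        strategy=strategy,
    )


@dataclass
class StrategyConfig:
    """Imputation run settings; recorded in each result's strategy string."""

    reference_taxon: str = "BT"
    window_source: str = "min"  # "min" (optimized) or "1Mb" (full region)
    iterations: int = 20
    restarts: int = 5
    seed: int = 0
    allow_ambiguous: bool = False
    allow_rare: bool = False
    backoff_floor: int = 20
    backoff_step: int = 10

    @property
    def label(self) -> str:
        return f"{self.reference_taxon}/{self.window_source}/{self.iterations}"


def impute_cohort(
    matrix: SnpGenotypeMatrix,
    tables: dict[str, AssociationTable],
    pedigree: list[PedigreeRecord] | None = None,
    config: StrategyConfig | None = None,
    phased: dict[str, HaplotypeSet] | None = None,
) -> list[ImputationResult]:
    """Phase the cohort per marker window and impute every animal.

    ``phased`` may supply externally phased haplotype sets per marker,
    bypassing the internal phaser.  Animals that cannot be phased for a
    window are reported as unmatched rather than dropped.
    """
    config = config or StrategyConfig()
    results: list[ImputationResult] = []
    for marker in sorted(tables):
        table = tables[marker]
        if phased and marker in phased:
            haps = phased[marker]
        else:
            if table.window is None:
                raise ValueError(f"table for {marker} has no window; pass phased sets")
            haps = phase_window(
                matrix,
                table.window,
                pedigree=pedigree,
                seed=config.seed,
                max_iter=config.iterations,
                restarts=config.restarts,
            )
        cache = _BackoffCache(table, config.backoff_step)
        for animal in matrix.animal_ids:
            if animal not in haps.pairs:
                reason = haps.excluded.get(animal, "not phased")
                miss = AlleleCall(MISSING_ALLELE, 0.0, 0.0, f"{STATUS_UNMATCHED}:{reason}")
                results.append(
                    ImputationResult(animal, marker, miss, miss, config.label)
                )
                continue
            h1, h2 = haps.pairs[animal]
            results.append(
                impute_animal(
                    (h1.allele_string, h2.allele_string),
                    table,
                    animal_id=animal,
                    allow_ambiguous=config.allow_ambiguous,
                    allow_rare=config.allow_rare,
                    backoff_floor=config.backoff_floor,
                    backoff_step=config.backoff_step,
                    strategy=config.label,
                    _cache=cache,
                )
            )
    return results


def results_to_frame(results: list[ImputationResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {
                "animal": r.animal_id,
                "marker": r.marker,
                "allele1": r.call_1.allele,
                "allele2": r.call_2.allele,
                "conf1": r.call_1.confidence,
                "conf2": r.call_2.confidence,
                "status1": r.call_1.status,
                "status2": r.call_2.status,
                "strategy": r.strategy,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class ConcordanceReport:
    """Full-diploid-match concordance between imputed and reported MS."""

    per_genotype: pd.DataFrame  # animal, marker, breed, concordant
    per_breed: pd.DataFrame  # breed, mean/max/min per-animal concordance %
    overall: float  # mean per-animal concordance %
    n_compared: int
    n_unpaired: int

    @property
    def mean_pct(self) -> float:
        return self.overall


def is_concordant(result: ImputationResult, truth: MsGenotype) -> bool:
    """Both imputed alleles must match the reported pair (unordered)."""
    if not result.complete or truth.missing:
        return False
    return result.alleles == truth.alleles


def score_concordance(
    imputed: list[ImputationResult],
    truth: list[MsGenotype],
    breeds: dict[str, str] | None = None,
) -> ConcordanceReport:
    """Score imputed genotypes against reported ones, paired by
    (animal, marker); unpaired records are skipped but counted."""
    breeds = breeds or {}
    truth_by_key = {(t.animal_id, t.marker): t for t in truth if not t.missing}
    rows = []
    matched_keys = set()
    for r in imputed:
        key = (r.animal_id, r.marker)
        t = truth_by_key.get(key)
        if t is None:
            continue
        matched_keys.add(key)
        rows.append(
            {
                "animal": r.animal_id,
                "marker": r.marker,
                "breed": breeds.get(r.animal_id, "unknown"),
                "concordant": is_concordant(r, t),
            }
        )
    n_unpaired = (len(imputed) - len(rows)) + (len(truth_by_key) - len(matched_keys))
    per_genotype = pd.DataFrame(rows)
    if per_genotype.empty:
        return ConcordanceReport(per_genotype, pd.DataFrame(), float("nan"), 0, n_unpaired)
    per_animal = (
        per_genotype.groupby(["animal", "breed"], as_index=False)["concordant"]
        .mean()
        .rename(columns={"concordant": "pct"})
    )
    per_animal["pct"] *= 100.0
    per_breed = (
        per_animal.groupby("breed")["pct"]
        .agg(mean="mean", max="max", min="min", n="count")
        .reset_index()
    )
    overall = float(per_animal["pct"].mean())
    return ConcordanceReport(
        per_genotype=per_genotype,
        per_breed=per_breed,
        overall=overall,
        n_compared=len(rows),
        n_unpaired=n_unpaired,
    )
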