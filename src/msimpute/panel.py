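"""MS-SNP haplotype association tables: the imputation reference.

Each table row associates one phased SNP haplotype (a string over {A,B})
with the MS alleles observed in cis with it, counted per breed.  Counts may
be fractional: an animal whose MS phase stayed ambiguous contributes 0.5 to
each compatible allele, and every diploid animal contributes exactly two
haplotype observations in total.

Classification of a haplotype entry (``min_count`` defaults to 4,
``concordance`` to 0.90):

* ``rare`` — seen fewer than ``min_count`` times;
* ``unique`` — seen >= ``min_count`` times, one single MS allele (100%);
* ``concordant`` — seen >= ``min_count`` times, the most common allele
  accounts for at least ``concordance`` of observations (but not all);
* ``ambiguous`` — everything else.

``unique`` and ``concordant`` entries are the "tallied" haplotypes used for
imputation; ``rare`` entries are retained (the self-correcting workflow
promotes them as confirmations accumulate) but not imputed from by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .phasing import HaplotypeSet, WindowSpec

CLASS_UNIQUE = "unique"
CLASS_CONCORDANT = "concordant"
CLASS_AMBIGUOUS = "ambiguous"
CLASS_RARE = "rare"

_TOL = 1e-9


@dataclass
class TableEntry:
    """Per-breed MS-allele counts for one haplotype, with derived stats."""

    counts: dict[str, dict[int, float]] = field(default_factory=dict)

    def add(self, breed: str, allele: int, weight: float = 1.0) -> None:
        self.counts.setdefault(breed, {}).setdefault(allele, 0.0)
        self.counts[breed][allele] += weight

    @property
    def total_count(self) -> float:
        return sum(v for d in self.counts.values() for v in d.values())

    @property
    def allele_totals(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for d in self.counts.values():
            for a, v in d.items():
                out[a] = out.get(a, 0.0) + v
        return out

    @property
    def primary_allele(self) -> int:
        totals = self.allele_totals
        best = max(totals.values())
        # ties broken toward the smaller bp allele
        return min(a for a, v in totals.items() if v >= best - _TOL)

    @property
    def primary_tied(self) -> bool:
        totals = self.allele_totals
        best = max(totals.values())
        return sum(1 for v in totals.values() if v >= best - _TOL) > 1

    @property
    def primary_fraction(self) -> float:
        totals = self.allele_totals
        return max(totals.values()) / self.total_count

    @property
    def n_breeds(self) -> int:
        return sum(1 for d in self.counts.values() if sum(d.values()) > _TOL)

    def classify(self, min_count: float, concordance: float) -> str:
        total = self.total_count
        if total < min_count - _TOL:
            return CLASS_RARE
        pf = self.primary_fraction
        if pf >= 1.0 - _TOL:
            return CLASS_UNIQUE
        if pf >= concordance - _TOL:
            return CLASS_CONCORDANT
        return CLASS_AMBIGUOUS


@dataclass
class AssociationTable:
    """Haplotype string -> per-breed MS-allele counts for one marker."""

    marker: str
    hap_length: int
    entries: dict[str, TableEntry] = field(default_factory=dict)
    min_count: float = 4
    concordance: float = 0.90
    window: WindowSpec | None = None

    def add_observation(
        self, haplotype: str, breed: str, allele: int, weight: float = 1.0
    ) -> None:
        if len(haplotype) != self.hap_length:
            raise ValueError(
                f"haplotype length {len(haplotype)} != table length {self.hap_length}"
            )
        self.entries.setdefault(haplotype, TableEntry()).add(breed, allele, weight)

    def classify(self, haplotype: str) -> str:
        return self.entries[haplotype].classify(self.min_count, self.concordance)

    @property
    def total_observations(self) -> float:
        return sum(e.total_count for e in self.entries.values())

    def tallied_haplotypes(self) -> list[str]:
        return [
            h
            for h, e in self.entries.items()
            if e.classify(self.min_count, self.concordance)
            in (CLASS_UNIQUE, CLASS_CONCORDANT)
        ]

    def to_frame(self) -> pd.DataFrame:
        """One row per (haplotype, breed, allele) with the derived class."""
        rows = []
        for hap in sorted(self.entries):
            e = self.entries[hap]
            cls = e.classify(self.min_count, self.concordance)
            for breed in sorted(e.counts):
                for allele in sorted(e.counts[breed]):
                    rows.append(
                        {
                            "haplotype": hap,
                            "breed": breed,
                            "allele": allele,
                            "count": e.counts[breed][allele],
                            "total_count": e.total_count,
                            "primary_allele": e.primary_allele,
                            "primary_fraction": e.primary_fraction,
                            "n_breeds": e.n_breeds,
                            "class": cls,
                        }
                    )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(
        cls,
        df: pd.DataFrame,
        marker: str,
        min_count: float = 4,
        concordance: float = 0.90,
    ) -> "AssociationTable":
        if df.empty:
            raise ValueError("empty association frame")
        length = len(str(df["haplotype"].iloc[0]))
        table = cls(marker=marker, hap_length=length, min_count=min_count,
                    concordance=concordance)
        for _, r in df.iterrows():
            table.add_observation(
                str(r["haplotype"]), str(r["breed"]), int(r["allele"]),
                float(r["count"]),
            )
        return table


def build_table(
    haps: HaplotypeSet,
    breeds: dict[str, str] | None = None,
    min_count: float = 4,
    concordance: float = 0.90,
) -> AssociationTable:
    """Build the association table from jointly phased haplotypes.

    Every animal in ``haps`` must carry an MS linkage (``ms_links``); an
    animal with an ambiguous MS phase contributes weight 0.5 to each
    orientation.  Animals without a breed label are assigned breed
    ``unknown`` with a warning, not dropped.
    """
    breeds = breeds or {}
    table = AssociationTable(
        marker=haps.window.marker_name,
        hap_length=haps.window.size,
        min_count=min_count,
        concordance=concordance,
        window=haps.window,
    )
    missing_breed = []
    for animal in sorted(haps.pairs):
        links = haps.ms_links.get(animal)
        if links is None:
            raise ValueError(f"animal {animal} has no linked MS allele; "
                             "build the table from a joint MS+SNP phasing")
        breed = breeds.get(animal)
        if breed is None:
            missing_breed.append(animal)
            breed = "unknown"
        h1, h2 = haps.pairs[animal]
        for a1, a2, w in links:
            table.add_observation(h1.allele_string, breed, a1, w)
            table.add_observation(h2.allele_string, breed, a2, w)
    if missing_breed:
        warnings.warn(
            f"{len(missing_breed)} animals without breed label assigned "
            "'unknown'",
            stacklevel=2,
        )
    return table


def merge_tables(a: AssociationTable, b: AssociationTable) -> AssociationTable:
    """Cell-wise sum of two tables for the same marker and window length."""
    if a.marker != b.marker:
        raise ValueError(f"marker mismatch: {a.marker} vs {b.marker}")
    if a.hap_length != b.hap_length:
        raise ValueError("window mismatch: association tables are window-specific")
    out = AssociationTable(
        marker=a.marker,
        hap_length=a.hap_length,
        min_count=a.min_count,
        concordance=a.concordance,
        window=a.window or b.window,
    )
    for src in (a, b):
        for hap, entry in src.entries.items():
            for breed, d in entry.counts.items():
                for allele, w in d.items():
                    out.add_observation(hap, breed, allele, w)
    return out


def aggregate_trim(
    table: AssociationTable, trim_left: int, trim_right: int
) -> AssociationTable:
    """Re-aggregate the table at a shorter window by trimming haplotype ends.

    Used by imputation back-off: entries whose trimmed cores coincide are
    pooled and reclassified at the shorter length.
    """
    new_len = table.hap_length - trim_left - trim_right
    if new_len < 1:
        raise ValueError("trim exceeds haplotype length")
    out = AssociationTable(
        marker=table.marker,
        hap_length=new_len,
        min_count=table.min_count,
        concordance=table.concordance,
    )
    stop = table.hap_length - trim_right
    for hap, entry in table.entries.items():
        core = hap[trim_left:stop]
        for breed, d in entry.counts.items():
            for allele, w in d.items():
                out.add_observation(core, breed, allele, w)
    return out


@dataclass
class PanelSummary:
    """Per-marker panel statistics plus the breed-sharing histogram."""

    per_marker: pd.DataFrame
    breed_sharing: dict[int, int]

    @property
    def multi_breed_fraction(self) -> float:
        """Fraction of non-rare haplotypes observed in two or more breeds."""
        total = sum(self.breed_sharing.values())
        if total == 0:
            return float("nan")
        return sum(v for k, v in self.breed_sharing.items() if k >= 2) / total


def summarize_panel(tables: list[AssociationTable]) -> PanelSummary:
    """Panel-level statistics: one row per marker, plus the histogram of
    how many breeds each (non-rare) haplotype is observed in."""
    rows = []
    sharing: dict[int, int] = {}
    for table in tables:
        n_unique = len(table.entries)
        tallied = table.tallied_haplotypes()
        tallied_obs = sum(table.entries[h].total_count for h in tallied)
        total_obs = table.total_observations
        unique_breeds = []
        concordant_breeds = []
        alleles = set()
        for hap, e in table.entries.items():
            alleles.update(e.allele_totals)
            cls = e.classify(table.min_count, table.concordance)
            if cls == CLASS_UNIQUE:
                unique_breeds.append(e.n_breeds)
            elif cls == CLASS_CONCORDANT:
                concordant_breeds.append(e.n_breeds)
            if cls != CLASS_RARE:
                k = e.n_breeds
                sharing[k] = sharing.get(k, 0) + 1
        span = None
        if table.window is not None:
            by_id = {s.snp_id: s for s in table.window.region.snps}
            pos = [by_id[s].position for s in table.window.snp_ids]
            span = max(pos) - min(pos)
        rows.append(
            {
                "marker": table.marker,
                "n_alleles": len(alleles),
                "n_observations": total_obs,
                "window_size": table.hap_length,
                "span_bp": span,
                "n_unique_haplotypes": n_unique,
                "n_tallied": len(tallied),
                "pct_tallied": len(tallied) / n_unique if n_unique else 0.0,
                "pct_population": tallied_obs / total_obs if total_obs else 0.0,
                "breeds_unique_mean": (
                    sum(unique_breeds) / len(unique_breeds) if unique_breeds else float("nan")
                ),
                "breeds_unique_max": max(unique_breeds, default=0),
                "breeds_concordant_mean": (
                    sum(concordant_breeds) / len(concordant_breeds)
                    if concordant_breeds
                    else float("nan")
                ),
                "breeds_concordant_max": max(concordant_breeds, default=0),
            }
        )
    return PanelSummary(per_marker=pd.DataFrame(rows), breed_sharing=dict(sorted(sharing.items())))


def apply_taxon_filter(
    breeds: dict[str, str],
    taxon_of_breed: dict[str, str],
    taxon: str = "BT",
) -> set[str]:
    """Animals whose breed belongs to the requested reference taxon.

    ``taxon`` is ``"BT"`` (Bos taurus plus taurine crossbreds) or
    ``"BT+BI"`` (taurine plus indicine).  Breeds absent from the mapping
    default to BT with a warning.
    """
    if taxon not in ("BT", "BT+BI"):
        raise ValueError(f"unknown taxon filter: {taxon!r}")
    unknown = sorted({b for b in breeds.values() if b not in taxon_of_breed})
    if unknown:
        warnings.warn(
            f"breeds without taxon mapping default to BT: {unknown}", stacklevel=2
        )
    keep = {"BT"} if taxon == "BT" else {"BT", "BI"}
    return {
        a
        for a, b in breeds.items()
        if taxon_of_breed.get(b, "BT") in keep
    }
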