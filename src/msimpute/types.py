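"""Core domain types for MS-SNP haplotype imputation.

Microsatellite (MS) alleles are identified by PCR fragment size in base
pairs.  SNP genotypes are carried in Illumina-style AB coding: each diploid
call is one of ``AA``, ``AB``, ``BB`` or missing.  Coordinates are 1-based
inclusive throughout (VCF convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np

# Diploid genotype codes used in SnpGenotypeMatrix.calls
GT_AA = 0
GT_AB = 1
GT_BB = 2
GT_MISSING = -1

GT_TOKENS = {GT_AA: "AA", GT_AB: "AB", GT_BB: "BB", GT_MISSING: "--"}
TOKEN_TO_GT = {v: k for k, v in GT_TOKENS.items()}
# Common aliases accepted on input
TOKEN_TO_GT.update({"BA": GT_AB, "NN": GT_MISSING, "..": GT_MISSING})

#: sentinel for a missing MS allele
MISSING_ALLELE = 0


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; message names the line."""


class EmptyRegionError(ValueError):
    """Raised when no SNP falls within the flank of an MS marker."""


@dataclass(frozen=True)
class SnpMapEntry:
    """One SNP on the map: identifier, chromosome and 1-based bp position."""

    snp_id: str
    chromosome: str
    position: int
    alleles: tuple[str, str] = ("A", "B")

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive")


@dataclass(frozen=True)
class MsMarker:
    """A microsatellite locus: name, chromosome and 1-based bp position."""

    name: str
    chromosome: str
    position: int = 0


#: The 12 ISAG-recommended bovine parentage microsatellites and their
#: chromosomes.  Positions are assembly-dependent and supplied by the user's
#: marker map; the bundled defaults carry name and chromosome only.
ISAG_MARKER_CHROMOSOMES = {
    "BM1824": "1",
    "BM2113": "2",
    "INRA023": "3",
    "ETH10": "5",
    "ETH225": "9",
    "SPS115": "15",
    "TGLA53": "16",
    "TGLA227": "18",
    "ETH3": "19",
    "TGLA126": "20",
    "TGLA122": "21",
    "BM1818": "23",
}


def default_ms_markers() -> list[MsMarker]:
    """Return the bundled ISAG panel (12 markers, positions unset)."""
    text = (
        resources.files("msimpute").joinpath("data/isag_markers.tsv").read_text()
    )
    markers = []
    for line in text.splitlines()[1:]:
        if not line.strip():
            continue
        name, chrom = line.split("\t")[:2]
        markers.append(MsMarker(name=name, chromosome=chrom))
    return markers


@dataclass(frozen=True)
class MsSnpRegion:
    """A microsatellite plus its flanking SNP map (within ``flank_bp``)."""

    marker: MsMarker
    snps: tuple[SnpMapEntry, ...]
    flank_bp: int = 500_000

    def __post_init__(self) -> None:
        for s in self.snps:
            if s.chromosome != self.marker.chromosome:
                raise ValueError(
                    f"SNP {s.snp_id} on chr{s.chromosome}, marker on "
                    f"chr{self.marker.chromosome}"
                )
            if abs(s.position - self.marker.position) > self.flank_bp:
                raise ValueError(f"SNP {s.snp_id} outside {self.flank_bp} bp flank")
        positions = [s.position for s in self.snps]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise ValueError("region SNPs must be strictly position-sorted")

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def build_region(
    ms: MsMarker, snp_map: list[SnpMapEntry], flank_bp: int = 500_000
) -> MsSnpRegion:
    """Select the SNPs within ``flank_bp`` of the marker (boundary inclusive).

    Raises :class:`EmptyRegionError` if no SNP qualifies.
    """
    if not snp_map:
        raise ValueError("SNP map is empty")
    chosen = sorted(
        (
            s
            for s in snp_map
            if s.chromosome == ms.chromosome
            and abs(s.position - ms.position) <= flank_bp
        ),
        key=lambda s: s.position,
    )
    if not chosen:
        raise EmptyRegionError(
            f"no SNP within {flank_bp} bp of {ms.name} on chr{ms.chromosome}"
        )
    return MsSnpRegion(marker=ms, snps=tuple(chosen), flank_bp=flank_bp)


@dataclass(frozen=True)
class MsGenotype:
    """An unordered diploid MS genotype in bp; both alleles present or both
    missing (a fragment-size caller reports both or neither)."""

    animal_id: str
    marker: str
    allele_a: int
    allele_b: int

    def __post_init__(self) -> None:
        if (self.allele_a == MISSING_ALLELE) != (self.allele_b == MISSING_ALLELE):
            raise ValueError(
                f"{self.animal_id}/{self.marker}: half-missing MS genotype"
            )
        if self.allele_a > self.allele_b:
            a, b = self.allele_a, self.allele_b
            object.__setattr__(self, "allele_a", b)
            object.__setattr__(self, "allele_b", a)

    @staticmethod
    def make(animal_id: str, marker: str, a: int, b: int) -> "MsGenotype":
        lo, hi = sorted((a, b))
        return MsGenotype(animal_id, marker, lo, hi)

    @property
    def missing(self) -> bool:
        return self.allele_a == MISSING_ALLELE

    @property
    def alleles(self) -> tuple[int, int]:
        return (self.allele_a, self.allele_b)


@dataclass
class SnpGenotypeMatrix:
    """Diploid SNP calls for a cohort, animals x SNPs, AB-coded.

    ``calls`` is an int8 array with entries GT_AA/GT_AB/GT_BB/GT_MISSING.
    ``phased`` marks animals whose source genotypes carried phase (the phased
    haplotypes themselves travel separately, via :mod:`msimpute.phasing`).
    """

    animal_ids: list[str]
    snp_ids: list[str]
    calls: np.ndarray
    phased: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.animal_ids), len(self.snp_ids)):
            raise ValueError("calls shape inconsistent with id lists")
        self._animal_index = {a: i for i, a in enumerate(self.animal_ids)}
        self._snp_index = {s: j for j, s in enumerate(self.snp_ids)}

    def animal_row(self, animal_id: str) -> np.ndarray:
        return self.calls[self._animal_index[animal_id]]

    def snp_columns(self, snp_ids: list[str]) -> np.ndarray:
        idx = [self._snp_index[s] for s in snp_ids]
        return self.calls[:, idx]

    def missing_rate(self, animal_id: str) -> float:
        row = self.animal_row(animal_id)
        return float(np.mean(row == GT_MISSING))

    def subset(self, animal_ids: list[str]) -> "SnpGenotypeMatrix":
        idx = [self._animal_index[a] for a in animal_ids]
        return SnpGenotypeMatrix(
            animal_ids=list(animal_ids),
            snp_ids=list(self.snp_ids),
            calls=self.calls[idx].copy(),
            phased={a: self.phased.get(a, False) for a in animal_ids},
        )


@dataclass(frozen=True)
class PedigreeRecord:
    """One pedigree row; '.' / empty parent means unknown."""

    animal_id: str
    sire_id: str | None = None
    dam_id: str | None = None
    breed: str = "unknown"


def check_pedigree_cycles(records: list[PedigreeRecord]) -> None:
    """Reject pedigrees in which an animal is its own ancestor."""
    parents = {
        r.animal_id: [p for p in (r.sire_id, r.dam_id) if p]
        for r in records
    }
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {a: WHITE for a in parents}
    for start in parents:
        if colour[start] != WHITE:
            continue
        stack = [(start, iter(parents[start]))]
        colour[start] = GREY
        while stack:
            node, it = stack[-1]
            advanced = False
            for nxt in it:
                if nxt not in parents:
                    continue
                if colour[nxt] == GREY:
                    raise ValueError(f"pedigree cycle involving {nxt}")
                if colour[nxt] == WHITE:
                    colour[nxt] = GREY
                    stack.append((nxt, iter(parents[nxt])))
                    advanced = True
                    break
            if not advanced:
                colour[node] = BLACK
                stack.pop()


@dataclass(frozen=True)
class Haplotype:
    """A phased SNP haplotype over a window: fixed-length string over {A,B}."""

    allele_string: str

    def __post_init__(self) -> None:
        if set(self.allele_string) - {"A", "B"}:
            raise ValueError("haplotype alleles must be A or B")

    def __len__(self) -> int:
        return len(self.allele_string)

    def __str__(self) -> str:
        return self.allele_string
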