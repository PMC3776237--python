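"""Readers and writers for SNP genotypes, MS genotypes, pedigrees and maps.

Formats
-------
* SNP genotypes: VCF 4.x (GT only; read through cyvcf2) or a tab-separated
  AB matrix (rows = animals, columns = SNPs, tokens AA/AB/BB/--).
* MS genotypes: TSV with header ``animal  marker  allele1  allele2``;
  missing alleles written as ``.`` (or ``0``).
* Pedigree: TSV ``animal_id  sire_id  dam_id  breed`` with ``.`` for unknown.
* Marker maps: TSV ``snp_id  chromosome  position`` (same for MS markers
  with ``marker`` instead of ``snp_id``).

AB coding from VCF is deterministic: REF maps to A and ALT to B.  No strand
resolution is attempted.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    GT_AA,
    GT_AB,
    GT_BB,
    GT_MISSING,
    GT_TOKENS,
    TOKEN_TO_GT,
    MISSING_ALLELE,
    MsGenotype,
    MsMarker,
    MsSnpRegion,
    ParseError,
    PedigreeRecord,
    SnpGenotypeMatrix,
    SnpMapEntry,
    check_pedigree_cycles,
)

_MISSING_TOKENS = {".", "0", "", "NA", "-"}


def read_snp_genotypes(path: str | os.PathLike, format: str = "vcf") -> SnpGenotypeMatrix:
    """Read diploid SNP genotypes from a VCF or an AB-coded matrix.

    VCF sites with more than one ALT allele are rejected.  The per-animal
    phase flag is set when every GT on that sample uses the phased ``|``
    separator.
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "ab-matrix":
        return _read_ab_matrix(path)
    raise ValueError(f"unknown SNP genotype format: {format!r}")


def _read_vcf(path: str | os.PathLike) -> SnpGenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    animals = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    all_phased = np.ones(len(animals), dtype=bool)
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise ParseError(
                f"{path}: multiallelic site {variant.ID or variant.POS} not supported"
            )
        snp_ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        gts = variant.genotypes  # [allele0, allele1, phased] per sample
        calls = np.empty(len(animals), dtype=np.int8)
        for i, gt in enumerate(gts):
            a0, a1 = gt[0], gt[1]
            if a0 < 0 or a1 < 0:
                calls[i] = GT_MISSING
            else:
                calls[i] = a0 + a1  # 0/0->AA, 0/1->AB, 1/1->BB
            all_phased[i] &= bool(gt[2])
        rows.append(calls)
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(animals), 0), dtype=np.int8)
    )
    phased = {a: bool(all_phased[i]) for i, a in enumerate(animals)}
    return SnpGenotypeMatrix(animals, snp_ids, calls, phased)


def _read_ab_matrix(path: str | os.PathLike) -> SnpGenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    animals = [str(a) for a in df.index]
    snp_ids = [str(s) for s in df.columns]
    calls = np.empty(df.shape, dtype=np.int8)
    for i, (_, row) in enumerate(df.iterrows()):
        for j, token in enumerate(row):
            token = str(token).strip()
            try:
                calls[i, j] = TOKEN_TO_GT[token]
            except KeyError:
                raise ParseError(
                    f"{path}: bad genotype token {token!r} at row "
                    f"{animals[i]}, column {snp_ids[j]}"
                ) from None
    return SnpGenotypeMatrix(animals, snp_ids, calls, {a: False for a in animals})


def write_ab_matrix(matrix: SnpGenotypeMatrix, path: str | os.PathLike) -> None:
    """Write the matrix in the tab-separated AB dialect (AA/AB/BB/--)."""
    with open(path, "w") as fh:
        fh.write("animal\t" + "\t".join(matrix.snp_ids) + "\n")
        for i, animal in enumerate(matrix.animal_ids):
            tokens = [GT_TOKENS[int(c)] for c in matrix.calls[i]]
            fh.write(animal + "\t" + "\t".join(tokens) + "\n")


def write_vcf(
    matrix: SnpGenotypeMatrix,
    snp_map: list[SnpMapEntry],
    path: str | os.PathLike,
) -> None:
    """Write an unphased GT-only VCF 4.2 (REF=A, ALT=B) for the mapped SNPs."""
    by_id = {s.snp_id: s for s in snp_map}
    gt_token = {GT_AA: "0/0", GT_AB: "0/1", GT_BB: "1/1", GT_MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.animal_ids)
            + "\n"
        )
        order = sorted(
            range(len(matrix.snp_ids)),
            key=lambda j: (
                by_id[matrix.snp_ids[j]].chromosome,
                by_id[matrix.snp_ids[j]].position,
            ),
        )
        for j in order:
            entry = by_id[matrix.snp_ids[j]]
            gts = "\t".join(gt_token[int(c)] for c in matrix.calls[:, j])
            fh.write(
                f"{entry.chromosome}\t{entry.position}\t{entry.snp_id}"
                f"\tA\tB\t.\t.\t.\tGT\t{gts}\n"
            )


@dataclass
class MsReadResult:
    """MS genotype records plus per-record issues (nothing silently dropped)."""

    records: list[MsGenotype] = field(default_factory=list)
    unknown_marker: list[MsGenotype] = field(default_factory=list)
    errors: list[str] = field(default_factory=list)


def read_ms_genotypes(
    path: str | os.PathLike, known_markers: set[str] | None = None
) -> MsReadResult:
    """Read MS genotypes; normalize allele order; collect record errors.

    A record with one allele missing and the other present is an error (a
    fragment-size caller reports both alleles or neither).  Records whose
    marker is not in ``known_markers`` are returned separately, not dropped.
    """
    result = MsReadResult()
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if len(header) < 4:
            raise ParseError(f"{path}: expected 4 tab-separated columns")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                result.errors.append(f"line {lineno}: expected 4 columns")
                continue
            animal, marker, raw_a, raw_b = parts[:4]
            try:
                a = _parse_allele(raw_a)
                b = _parse_allele(raw_b)
            except ValueError as exc:
                result.errors.append(f"line {lineno}: {exc}")
                continue
            if (a == MISSING_ALLELE) != (b == MISSING_ALLELE):
                result.errors.append(
                    f"line {lineno}: half-missing genotype {raw_a}/{raw_b}"
                )
                continue
            record = MsGenotype.make(animal, marker, a, b)
            if known_markers is not None and marker not in known_markers:
                result.unknown_marker.append(record)
            else:
                result.records.append(record)
    return result


def _parse_allele(token: str) -> int:
    token = token.strip()
    if token in _MISSING_TOKENS:
        return MISSING_ALLELE
    try:
        value = int(token)
    except ValueError:
        raise ValueError(f"allele {token!r} is not an integer bp size") from None
    if value < 0:
        raise ValueError(f"allele size {value} is negative")
    return value


def write_ms_genotypes(records: list[MsGenotype], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal\tmarker\tallele1\tallele2\n")
        for r in records:
            a = "." if r.missing else str(r.allele_a)
            b = "." if r.missing else str(r.allele_b)
            fh.write(f"{r.animal_id}\t{r.marker}\t{a}\t{b}\n")


def read_pedigree(path: str | os.PathLike) -> list[PedigreeRecord]:
    """Read ``animal_id  sire_id  dam_id  breed`` with '.' for unknown."""
    records = []
    with open(path) as fh:
        fh.readline()  # header
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 4:
                raise ParseError(f"{path}: line {lineno}: expected 4 columns")
            animal, sire, dam, breed = parts[:4]
            records.append(
                PedigreeRecord(
                    animal_id=animal,
                    sire_id=None if sire in _MISSING_TOKENS else sire,
                    dam_id=None if dam in _MISSING_TOKENS else dam,
                    breed=breed or "unknown",
                )
            )
    check_pedigree_cycles(records)
    return records


def write_pedigree(records: list[PedigreeRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal_id\tsire_id\tdam_id\tbreed\n")
        for r in records:
            fh.write(
                f"{r.animal_id}\t{r.sire_id or '.'}\t{r.dam_id or '.'}\t{r.breed}\n"
            )


def read_snp_map(path: str | os.PathLike) -> list[SnpMapEntry]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    entries = [
        SnpMapEntry(snp_id=str(r.iloc[0]), chromosome=str(r.iloc[1]), position=int(r.iloc[2]))
        for _, r in df.iterrows()
    ]
    seen: set[str] = set()
    for e in entries:
        if e.snp_id in seen:
            raise ParseError(f"{path}: duplicate snp_id {e.snp_id}")
        seen.add(e.snp_id)
    return entries


def write_snp_map(entries: list[SnpMapEntry], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("snp_id\tchromosome\tposition\n")
        for e in entries:
            fh.write(f"{e.snp_id}\t{e.chromosome}\t{e.position}\n")


def read_ms_map(path: str | os.PathLike) -> list[MsMarker]:
    df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
    return [
        MsMarker(name=str(r.iloc[0]), chromosome=str(r.iloc[1]), position=int(r.iloc[2]))
        for _, r in df.iterrows()
    ]


def export_beagle_inputs(
    region: MsSnpRegion,
    snp_matrix: SnpGenotypeMatrix,
    ms_genotypes: list[MsGenotype],
    out_dir: str | os.PathLike,
) -> Path:
    """Write a BEAGLE-style unphased genotype file for one MS region.

    Only animals with an MS genotype for this marker are exported.  Layout
    (tab-separated, deterministic):

    * row 1: ``I id`` then each animal id twice (two allele columns);
    * one ``M <name>`` row per locus, markers ordered by bp position with the
      MS inserted at its own position; SNP alleles are A/B (``?`` missing),
    * MS alleles are fragment sizes in bp (``?`` missing).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = region.marker.name
    with_ms = sorted(
        {g.animal_id for g in ms_genotypes if g.marker == marker and not g.missing}
    )
    animals = [a for a in snp_matrix.animal_ids if a in set(with_ms)]
    ms_by_animal = {
        g.animal_id: g for g in ms_genotypes if g.marker == marker and not g.missing
    }

    loci: list[tuple[int, str, list[str]]] = []
    snp_allele = {GT_AA: ("A", "A"), GT_AB: ("A", "B"), GT_BB: ("B", "B"),
                  GT_MISSING: ("?", "?")}
    window_cols = snp_matrix.snp_columns(region.snp_ids) if region.snps else None
    row_index = {a: i for i, a in enumerate(snp_matrix.animal_ids)}
    for j, snp in enumerate(region.snps):
        tokens = []
        for a in animals:
            g = int(window_cols[row_index[a], j])
            tokens.extend(snp_allele[g])
        loci.append((snp.position, snp.snp_id, tokens))
    ms_tokens = []
    for a in animals:
        g = ms_by_animal[a]
        ms_tokens.extend([str(g.allele_a), str(g.allele_b)])
    loci.append((region.marker.position, marker, ms_tokens))
    loci.sort(key=lambda t: (t[0], t[1]))

    path = out_dir / f"{marker}.bgl"
    with open(path, "w") as fh:
        header = ["I", "id"]
        for a in animals:
            header.extend([a, a])
        fh.write("\t".join(header) + "\n")
        for _, name, tokens in loci:
            fh.write("\t".join(["M", name] + tokens) + "\n")
    return path
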