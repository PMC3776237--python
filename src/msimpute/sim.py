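"""Synthetic multi-breed SNP + MS genotype generator with known truth.

The generator emulates the population structure the imputation method
relies on: a pool of ancestral SNP haplotypes per MS region, each carrying
one MS allele in cis; a configurable fraction of those haplotypes segregate
in two or more breeds (identical by descent from ancestors predating breed
formation), the rest are breed specific.  Each breed draws its haplotype
frequencies from a Dirichlet perturbation of a uniform base (one-step
drift), founders are sampled from those frequencies, and trios are bred
with region-level recombination and stepwise MS mutation.  Observed MS
calls are corrupted by three error modes seen in fragment-size genotyping:
random mis-calls, +/-2 bp size rounding, and allele dropout (a false
homozygote).  MS alleles are spaced 2 bp apart (dinucleotide repeats), so
rounding errors collide with real alleles.

Every corruption is logged exactly once in the :class:`TruthSet`, and the
true haplotypes and genotypes stay recoverable independent of the observed
data.  The same seed reproduces the full dataset byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import (
    MISSING_ALLELE,
    MsGenotype,
    MsMarker,
    PedigreeRecord,
    SnpGenotypeMatrix,
    SnpMapEntry,
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset.

    Defaults follow reported fragment-genotyping behaviour (1-5% MS error
    per called genotype; 2 bp rounding slips) and desk-scale population
    sizes; rates are per meiosis (recombination, mutation) or per called
    genotype (errors).
    """

    n_breeds: int = 6
    n_ancestral_haplotypes: int = 12
    fraction_shared: float = 0.25
    region_snps: int = 60
    window_snps: int = 30
    ms_alleles: tuple[int, ...] = tuple(range(111, 135, 2))
    recomb_rate: float = 0.01
    ms_mutation_rate: float = 0.001
    ms_error_rate: float = 0.01
    rounding_error_rate: float = 0.005
    dropout_rate: float = 0.0
    n_founders: int = 100  # per breed
    n_trios: int = 50  # per breed
    markers: tuple[str, ...] = ("MS1",)
    drift_concentration: float = 5.0
    flank_bp: int = 500_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fraction_shared", "recomb_rate", "ms_mutation_rate",
                     "ms_error_rate", "rounding_error_rate", "dropout_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        sizes = sorted(self.ms_alleles)
        if any(s <= 0 for s in sizes):
            raise ValueError("MS allele sizes must be positive")
        steps = {b - a for a, b in zip(sizes, sizes[1:])}
        if steps and steps != {2}:
            raise ValueError("MS allele sizes must be evenly spaced 2 bp apart")
        if self.fraction_shared > 0 and self.n_breeds < 2:
            raise ValueError("shared haplotypes require at least 2 breeds")
        if round(self.fraction_shared * self.n_ancestral_haplotypes) > self.n_ancestral_haplotypes:
            raise ValueError("more shared haplotypes requested than exist")


@dataclass
class AncestralHaplotype:
    """Ground-truth ancestral haplotype for one region."""

    snp_string: str
    ms_allele: int
    breeds: tuple[str, ...]


@dataclass
class TruthSet:
    """Ground truth and the exact error-injection log."""

    # (animal, marker) -> ordered pair of SNP haplotype strings
    haplotypes: dict[tuple[str, str], tuple[str, str]] = field(default_factory=dict)
    # (animal, marker) -> true unordered MS genotype (bp, bp)
    ms_genotypes: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    # (animal, marker) -> MS alleles in cis with haplotypes 1 and 2 (ordered)
    cis_alleles: dict[tuple[str, str], tuple[int, int]] = field(default_factory=dict)
    # (animal, marker, kind, detail); each corrupted call appears once
    error_log: list[tuple[str, str, str, str]] = field(default_factory=list)
    ancestral: dict[str, list[AncestralHaplotype]] = field(default_factory=dict)

    def true_ms_records(self) -> list[MsGenotype]:
        return [
            MsGenotype.make(a, m, g[0], g[1])
            for (a, m), g in sorted(self.ms_genotypes.items())
        ]


@dataclass
class SimResult:
    """One simulated dataset: observed data, metadata, and truth."""

    config: SimConfig
    matrix: SnpGenotypeMatrix
    ms_records: list[MsGenotype]
    pedigree: list[PedigreeRecord]
    snp_map: list[SnpMapEntry]
    ms_map: list[MsMarker]
    truth: TruthSet

    @property
    def breeds(self) -> dict[str, str]:
        return {p.animal_id: p.breed for p in self.pedigree}


def _assign_breeds(
    cfg: SimConfig, rng: np.random.Generator, breed_names: list[str]
) -> list[tuple[str, ...]]:
    """Breed assignment per ancestral haplotype: shared ones to >=2 breeds."""
    n = cfg.n_ancestral_haplotypes
    n_shared = round(cfg.fraction_shared * n)
    if n_shared > n:
        raise ValueError("more shared haplotypes requested than exist")
    assignments: list[tuple[str, ...]] = []
    for i in range(n):
        if i < n_shared:
            k = 2 + int(rng.binomial(cfg.n_breeds - 2, 0.25)) if cfg.n_breeds > 2 else 2
            chosen = rng.choice(cfg.n_breeds, size=k, replace=False)
            assignments.append(tuple(breed_names[j] for j in sorted(chosen)))
        else:
            assignments.append((breed_names[i % cfg.n_breeds],))
    return assignments


def simulate_panel(cfg: SimConfig) -> SimResult:
    """Generate the full dataset described by ``cfg`` (deterministic per seed)."""
    rng = np.random.default_rng(cfg.seed)
    breed_names = [f"breed{b+1}" for b in range(cfg.n_breeds)]
    truth = TruthSet()
    snp_map: list[SnpMapEntry] = []
    ms_map: list[MsMarker] = []

    animals: list[str] = []
    pedigree: list[PedigreeRecord] = []
    animal_breed: dict[str, str] = {}
    parents: dict[str, tuple[str | None, str | None]] = {}
    for b in breed_names:
        for i in range(cfg.n_founders):
            a = f"{b}_f{i+1}"
            animals.append(a)
            animal_breed[a] = b
            parents[a] = (None, None)
            pedigree.append(PedigreeRecord(a, None, None, b))
    # trios: each child gets two distinct founder parents of its breed
    for b in breed_names:
        founders = [f"{b}_f{i+1}" for i in range(cfg.n_founders)]
        for i in range(cfg.n_trios):
            sire, dam = rng.choice(cfg.n_founders, size=2, replace=False)
            a = f"{b}_c{i+1}"
            animals.append(a)
            animal_breed[a] = b
            parents[a] = (founders[sire], founders[dam])
            pedigree.append(PedigreeRecord(a, founders[sire], founders[dam], b))

    all_snp_ids: list[str] = []
    all_calls: list[np.ndarray] = []
    ms_records: list[MsGenotype] = []
    for r, marker in enumerate(cfg.markers):
        chrom = str(r + 1)
        ms_pos = 50_000_000
        ms_map.append(MsMarker(marker, chrom, ms_pos))
        offsets = np.sort(
            rng.choice(
                np.arange(-cfg.flank_bp + 1, cfg.flank_bp),
                size=cfg.region_snps,
                replace=False,
            )
        )
        snp_ids = [f"{marker}_snp{j+1}" for j in range(cfg.region_snps)]
        for sid, off in zip(snp_ids, offsets):
            snp_map.append(SnpMapEntry(sid, chrom, int(ms_pos + off)))
        all_snp_ids.extend(snp_ids)
        # MS slot inserted into the ordered site list at its position
        ms_site = int(np.searchsorted(offsets, 0))

        anc = _draw_ancestral(cfg, rng)
        assignments = _assign_breeds(cfg, rng, breed_names)
        truth.ancestral[marker] = [
            AncestralHaplotype(
                snp_string="".join("AB"[x] for x in anc_row),
                ms_allele=int(allele),
                breeds=assignments[i],
            )
            for i, (anc_row, allele) in enumerate(anc)
        ]

        breed_pool: dict[str, list[int]] = {b: [] for b in breed_names}
        for i, bs in enumerate(assignments):
            for b in bs:
                breed_pool[b].append(i)
        for b in breed_names:
            if not breed_pool[b]:  # give every breed at least one haplotype
                breed_pool[b].append(int(rng.integers(cfg.n_ancestral_haplotypes)))
        breed_freq = {
            b: rng.dirichlet(
                np.full(len(breed_pool[b]), cfg.drift_concentration)
            )
            for b in breed_names
        }

        # founder haplotypes: (snp vector, ms allele)
        hap_of: dict[str, list[tuple[np.ndarray, int]]] = {}
        for a in animals:
            b = animal_breed[a]
            s, d = parents[a]
            if s is None:
                picks = rng.choice(
                    len(breed_pool[b]), size=2, replace=True, p=breed_freq[b]
                )
                hap_of[a] = [
                    (anc[breed_pool[b][k]][0].copy(), int(anc[breed_pool[b][k]][1]))
                    for k in picks
                ]
            else:
                hap_of[a] = [
                    _gamete(hap_of[s], cfg, rng, ms_site),
                    _gamete(hap_of[d], cfg, rng, ms_site),
                ]
            (h1, m1), (h2, m2) = hap_of[a]
            truth.haplotypes[(a, marker)] = (
                "".join("AB"[x] for x in h1),
                "".join("AB"[x] for x in h2),
            )
            truth.ms_genotypes[(a, marker)] = tuple(sorted((m1, m2)))
            truth.cis_alleles[(a, marker)] = (m1, m2)

        # observed SNP matrix (SNP calls taken as error-free)
        calls = np.empty((len(animals), cfg.region_snps), dtype=np.int8)
        for i, a in enumerate(animals):
            (h1, _), (h2, _) = hap_of[a]
            calls[i] = h1 + h2
        all_calls.append(calls)

        # observed MS genotypes with error injection
        allele_list = sorted(cfg.ms_alleles)
        for a in animals:
            m1, m2 = truth.ms_genotypes[(a, marker)]
            obs = [m1, m2]
            if rng.random() < cfg.ms_error_rate:
                slot = int(rng.integers(2))
                old = obs[slot]
                new = old
                while new == old:
                    new = int(allele_list[rng.integers(len(allele_list))])
                obs[slot] = new
                truth.error_log.append((a, marker, "miscall", f"{old}->{new}"))
            if rng.random() < cfg.rounding_error_rate:
                slot = int(rng.integers(2))
                shift = 2 if rng.random() < 0.5 else -2
                old = obs[slot]
                obs[slot] = old + shift
                truth.error_log.append((a, marker, "rounding", f"{old}->{obs[slot]}"))
            if cfg.dropout_rate and obs[0] != obs[1] and rng.random() < cfg.dropout_rate:
                keep = int(obs[rng.integers(2)])
                truth.error_log.append(
                    (a, marker, "dropout", f"{obs[0]}/{obs[1]}->{keep}/{keep}")
                )
                obs = [keep, keep]
            ms_records.append(MsGenotype.make(a, marker, obs[0], obs[1]))

    matrix = SnpGenotypeMatrix(
        animal_ids=list(animals),
        snp_ids=all_snp_ids,
        calls=np.concatenate(all_calls, axis=1),
        phased={a: False for a in animals},
    )
    return SimResult(
        config=cfg,
        matrix=matrix,
        ms_records=ms_records,
        pedigree=pedigree,
        snp_map=snp_map,
        ms_map=ms_map,
        truth=truth,
    )


def _draw_ancestral(
    cfg: SimConfig, rng: np.random.Generator
) -> list[tuple[np.ndarray, int]]:
    """Distinct random ancestral SNP haplotypes, each with one cis MS allele."""
    seen: set[bytes] = set()
    out: list[tuple[np.ndarray, int]] = []
    allele_list = sorted(cfg.ms_alleles)
    while len(out) < cfg.n_ancestral_haplotypes:
        h = rng.integers(0, 2, size=cfg.region_snps, dtype=np.int8)
        key = h.tobytes()
        if key in seen:
            continue
        seen.add(key)
        out.append((h, int(allele_list[rng.integers(len(allele_list))])))
    return out


def _gamete(
    hap_pair: list[tuple[np.ndarray, int]],
    cfg: SimConfig,
    rng: np.random.Generator,
    ms_site: int,
) -> tuple[np.ndarray, int]:
    """One meiotic product: optional single crossover, stepwise MS mutation."""
    first = int(rng.integers(2))
    (ha, ma) = hap_pair[first]
    (hb, mb) = hap_pair[1 - first]
    n_sites = cfg.region_snps + 1  # SNPs plus the MS slot
    if rng.random() < cfg.recomb_rate:
        bp = int(rng.integers(1, n_sites))  # breakpoint between ordered sites
        snp = np.empty(cfg.region_snps, dtype=np.int8)
        for j in range(cfg.region_snps):
            site = j if j < ms_site else j + 1
            snp[j] = ha[j] if site < bp else hb[j]
        ms = ma if ms_site < bp else mb
    else:
        snp, ms = ha.copy(), ma
    if rng.random() < cfg.ms_mutation_rate:
        step = 2 if rng.random() < 0.5 else -2
        ms = ms + step
    return snp, int(ms)


def truth_haplotype_set(data: SimResult, window, animal_ids=None) -> "HaplotypeSet":
    """A :class:`~msimpute.phasing.HaplotypeSet` built from simulator truth.

    Serves as externally phased input with exact MS linkage (the simulator
    plays the role of an outside phasing run with known answers).
    """
    from .phasing import SOURCE_EXTERNAL, HaplotypeSet
    from .types import Haplotype

    marker = window.marker_name
    region_ids = window.region.snp_ids
    idx = [region_ids.index(s) for s in window.snp_ids]
    pairs = {}
    ms_links = {}
    animal_ids = animal_ids if animal_ids is not None else data.matrix.animal_ids
    for a in animal_ids:
        h1, h2 = data.truth.haplotypes[(a, marker)]
        pairs[a] = (
            Haplotype("".join(h1[i] for i in idx)),
            Haplotype("".join(h2[i] for i in idx)),
        )
        # truth stores ms genotype sorted; recover per-haplotype cis alleles
        ms_links[a] = ((data.truth.cis_alleles[(a, marker)][0],
                        data.truth.cis_alleles[(a, marker)][1], 1.0),)
    return HaplotypeSet(
        window=window, pairs=pairs, source=SOURCE_EXTERNAL, ms_links=ms_links
    )


@dataclass
class HoldoutSplit:
    """Reference/validation partition with validation MS withheld."""

    reference_ids: list[str]
    validation_ids: list[str]
    reference_ms: list[MsGenotype]
    withheld_ms: list[MsGenotype]


def holdout_split(
    data: SimResult,
    scheme: str = "random",
    fraction: float = 0.5,
    holdout_breed: str | None = None,
    seed: int = 0,
) -> HoldoutSplit:
    """Partition animals into reference and validation sets.

    ``random`` splits animals by the given fraction; ``leave-breed-out``
    places one entire breed in validation, mimicking imputation into a breed
    unrepresented in the reference.  Validation animals' observed MS
    genotypes move to the withheld (scoring) side.
    """
    breeds = data.breeds
    all_ids = list(data.matrix.animal_ids)
    if scheme == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(len(all_ids))
        n_ref = int(round(fraction * len(all_ids)))
        ref = sorted(all_ids[i] for i in perm[:n_ref])
        val = sorted(all_ids[i] for i in perm[n_ref:])
    elif scheme == "leave-breed-out":
        present = sorted(set(breeds.values()))
        if len(present) < 2:
            raise ValueError("leave-breed-out needs at least 2 breeds")
        if holdout_breed is None:
            holdout_breed = present[-1]
        if holdout_breed not in present:
            raise ValueError(f"breed {holdout_breed!r} not in dataset")
        ref = [a for a in all_ids if breeds[a] != holdout_breed]
        val = [a for a in all_ids if breeds[a] == holdout_breed]
    else:
        raise ValueError(f"unknown holdout scheme: {scheme!r}")
    ref_set, val_set = set(ref), set(val)
    return HoldoutSplit(
        reference_ids=ref,
        validation_ids=val,
        reference_ms=[g for g in data.ms_records if g.animal_id in ref_set],
        withheld_ms=[g for g in data.ms_records if g.animal_id in val_set],
    )
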