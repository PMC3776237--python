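"""Window construction and haplotype phasing.

The reference panel needs, for every animal, the pair of phased SNP
haplotypes over a window centered on the microsatellite — and, for reference
animals, which MS allele rides in cis with each haplotype.  Phasing proceeds
in three layers:

1. **Pedigree transmission.**  For animals with genotyped parents, every
   heterozygous site whose origin is forced by a parent's genotype is
   phase-resolved before any statistical machinery runs (paternal haplotype
   in slot 0).
2. **EM over haplotype frequencies.**  Remaining ambiguity is resolved with
   an Excoffier–Slatkin-style EM: candidate haplotype pairs are enumerated
   per animal (the MS locus, when supplied, is treated as one extra
   multi-allelic site), haplotype frequencies are estimated by EM with
   random restarts, and each animal is hard-assigned its
   maximum-posterior pair.  Animals with too many unresolved sites to
   enumerate are phased by conditioning on the haplotypes already inferred
   from the rest of the cohort (Clark-style), not by full enumeration.
3. **External phase.**  Phased VCF or a two-line-per-animal haplotype table
   can be loaded directly, bypassing 1–2.

Missing SNP calls inside the window are filled from the assigned haplotype
pair.  Phasing never alters an observed genotype: the returned pair is
checked against the input genotype at every site, for every animal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np

from .types import (
    GT_AB,
    GT_MISSING,
    Haplotype,
    MISSING_ALLELE,
    MsGenotype,
    MsSnpRegion,
    PedigreeRecord,
    SnpGenotypeMatrix,
)

SOURCE_EM = "internal-em"
SOURCE_PEDIGREE = "pedigree-resolved"
SOURCE_EXTERNAL = "external-phased"


@dataclass(frozen=True)
class WindowSpec:
    """A contiguous window of ``size`` SNPs nearest the MS position.

    The window is split as evenly as possible across the two flanks, with
    the extra SNP (odd sizes) going to the flank that has more SNPs
    available.
    """

    region: MsSnpRegion
    size: int
    snp_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.size < 2:
            raise ValueError("window size must be >= 2")
        if len(self.snp_ids) != self.size:
            raise ValueError("snp_ids length must equal size")

    @property
    def marker_name(self) -> str:
        return self.region.marker.name


def make_window(region: MsSnpRegion, size: int) -> WindowSpec:
    """Build the centered window of ``size`` SNPs (capped at availability)."""
    ms_pos = region.marker.position
    left = [s for s in region.snps if s.position <= ms_pos]
    right = [s for s in region.snps if s.position > ms_pos]
    size = min(size, len(region.snps))
    if size < 2:
        raise ValueError(f"region {region.marker.name} has <2 SNPs")
    big, small = (left, right) if len(left) >= len(right) else (right, left)
    n_big = min(ceil(size / 2), len(big))
    n_small = min(size - n_big, len(small))
    n_big = size - n_small  # spill back if the small flank ran out
    take_left = n_big if big is left else n_small
    take_right = size - take_left
    chosen = left[len(left) - take_left:] + right[:take_right]
    chosen.sort(key=lambda s: s.position)
    return WindowSpec(region=region, size=size, snp_ids=tuple(s.snp_id for s in chosen))


@dataclass
class HaplotypeSet:
    """Phased haplotype pairs per animal over one window.

    ``ms_links[animal]`` is a tuple of ``(allele_on_hap1, allele_on_hap2,
    weight)`` triples summing to weight 1; two triples with weight 0.5 encode
    an MS phase that stayed ambiguous after pedigree and EM resolution.
    """

    window: WindowSpec
    pairs: dict[str, tuple[Haplotype, Haplotype]]
    source: str = SOURCE_EM
    ms_links: dict[str, tuple[tuple[int, int, float], ...]] = field(default_factory=dict)
    excluded: dict[str, str] = field(default_factory=dict)
    converged: bool = True
    loglike: float = float("nan")

    def check_consistency(self, matrix: SnpGenotypeMatrix) -> None:
        """Assert every pair agrees with the observed genotypes."""
        cols = matrix.snp_columns(list(self.window.snp_ids))
        idx = {a: i for i, a in enumerate(matrix.animal_ids)}
        for animal, (h1, h2) in self.pairs.items():
            g = cols[idx[animal]]
            a1 = np.frombuffer(h1.allele_string.encode(), dtype="S1") == b"B"
            a2 = np.frombuffer(h2.allele_string.encode(), dtype="S1") == b"B"
            implied = a1.astype(int) + a2.astype(int)
            observed = g != GT_MISSING
            if not np.array_equal(implied[observed], g[observed]):
                raise AssertionError(f"phase inconsistent with genotype: {animal}")


def _transmitted(child: tuple[int, int], parent: tuple[int, int]) -> int | None:
    """Allele the parent must have transmitted, or None if unforced."""
    a, b = child
    in_parent = [x for x in (a, b) if x in parent]
    distinct = set(in_parent)
    if len(distinct) == 1 and a != b:
        return distinct.pop()
    return None


class _SiteData:
    """Per-animal window genotypes as allele-pair tuples per site.

    SNP sites use alleles {0, 1}; the optional trailing MS site uses integer
    codes into ``ms_alleles``.  Missing is (-1, -1).
    """

    def __init__(
        self,
        matrix: SnpGenotypeMatrix,
        window: WindowSpec,
        ms: dict[str, tuple[int, int]] | None,
    ) -> None:
        self.window = window
        self.has_ms = ms is not None
        self.snp_cols = matrix.snp_columns(list(window.snp_ids))
        self.row = {a: i for i, a in enumerate(matrix.animal_ids)}
        self.n_snps = window.size
        self.n_sites = self.n_snps + (1 if self.has_ms else 0)
        if self.has_ms:
            sizes = sorted({x for g in ms.values() for x in g if x != MISSING_ALLELE})
            self.ms_alleles = sizes
            self.ms_code = {bp: i for i, bp in enumerate(sizes)}
            self.ms = ms
        else:
            self.ms_alleles = []
            self.ms_code = {}
            self.ms = {}

    def genotype(self, animal: str) -> list[tuple[int, int]]:
        g = self.snp_cols[self.row[animal]]
        sites: list[tuple[int, int]] = []
        for call in g:
            call = int(call)
            if call == GT_MISSING:
                sites.append((-1, -1))
            elif call == GT_AB:
                sites.append((0, 1))
            else:
                sites.append((call // 2, call // 2))
        if self.has_ms:
            a, b = self.ms.get(animal, (MISSING_ALLELE, MISSING_ALLELE))
            if a == MISSING_ALLELE:
                sites.append((-1, -1))
            else:
                sites.append((self.ms_code[a], self.ms_code[b]))
        return sites


def _pedigree_template(
    sites: list[tuple[int, int]],
    sire: list[tuple[int, int]] | None,
    dam: list[tuple[int, int]] | None,
) -> np.ndarray:
    """Ordered (paternal, maternal) template; -1 where phase is unresolved."""
    n = len(sites)
    t = -np.ones((2, n), dtype=np.int16)
    for s, (a, b) in enumerate(sites):
        if a == -1:
            continue
        if a == b:
            t[0, s] = t[1, s] = a
            continue
        from_sire = _transmitted((a, b), sire[s]) if sire and sire[s][0] != -1 else None
        from_dam = _transmitted((a, b), dam[s]) if dam and dam[s][0] != -1 else None
        if from_sire is not None and from_dam is not None:
            if {from_sire, from_dam} != {a, b}:
                continue  # parental genotypes contradict; leave unresolved
            t[0, s], t[1, s] = from_sire, from_dam
        elif from_sire is not None:
            t[0, s] = from_sire
            t[1, s] = b if from_sire == a else a
        elif from_dam is not None:
            t[1, s] = from_dam
            t[0, s] = b if from_dam == a else a
    return t


def _enumerate_pairs(
    sites: list[tuple[int, int]], template: np.ndarray, max_combos: int
) -> tuple[np.ndarray, np.ndarray] | None:
    """All ordered haplotype pairs consistent with genotype and template.

    Returns (H0, H1) arrays of shape (n_combos, n_sites), or None if the
    number of combinations exceeds ``max_combos``.
    """
    free_het: list[int] = []
    free_miss: list[int] = []
    for s, (a, b) in enumerate(sites):
        if template[0, s] != -1:
            continue
        if a == -1:
            free_miss.append(s)
        elif a != b:
            free_het.append(s)
    bits = len(free_het) + 2 * len(free_miss)
    if 2**bits > max_combos:
        return None
    n = 2**bits
    h0 = np.tile(template[0], (n, 1))
    h1 = np.tile(template[1], (n, 1))
    if bits:
        c = ((np.arange(n)[:, None] >> np.arange(bits)) & 1).astype(np.int16)
        b = 0
        for s in free_het:
            lo, hi = sites[s]
            h0[:, s] = np.where(c[:, b] == 0, lo, hi)
            h1[:, s] = np.where(c[:, b] == 0, hi, lo)
            b += 1
        for s in free_miss:
            # SNP sites only can be missing (MS-missing animals are excluded
            # from joint runs), so alleles are binary
            h0[:, s] = c[:, b]
            h1[:, s] = c[:, b + 1]
            b += 2
    return h0, h1


class _Registry:
    """Haplotype (site-vector) interning: bytes key <-> integer index."""

    def __init__(self, n_sites: int) -> None:
        self.n_sites = n_sites
        self.index: dict[bytes, int] = {}
        self.rows: list[np.ndarray] = []

    def add_rows(self, h: np.ndarray) -> np.ndarray:
        nbytes = self.n_sites * 2  # int16
        raw = np.ascontiguousarray(h, dtype=np.int16).tobytes()
        out = np.empty(h.shape[0], dtype=np.int32)
        for i in range(h.shape[0]):
            key = raw[i * nbytes : (i + 1) * nbytes]
            idx = self.index.get(key)
            if idx is None:
                idx = len(self.rows)
                self.index[key] = idx
                self.rows.append(np.frombuffer(key, dtype=np.int16).copy())
            out[i] = idx
        return out

    def key(self, idx: int) -> bytes:
        return self.rows[idx].tobytes()

    def __len__(self) -> int:
        return len(self.rows)


def _run_em(
    ai: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    mult: np.ndarray,
    gw: np.ndarray,
    n_haps: int,
    freqs0: np.ndarray,
    max_iter: int,
    tol: float = 1e-8,
) -> tuple[np.ndarray, float, bool]:
    """EM over haplotype frequencies.

    ``ai`` indexes genotype groups (animals with identical genotypes and
    pedigree constraints share one group); ``gw`` holds the group sizes, so
    the E-step runs once per distinct genotype rather than once per animal.
    """
    n_groups = len(gw)
    total_animals = float(gw.sum())
    freqs = freqs0.copy()
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        w = freqs[pi] * freqs[pj] * mult
        denom = np.bincount(ai, weights=w, minlength=n_groups)
        denom = np.where(denom <= 0, 1e-300, denom)
        loglike = float(np.sum(gw * np.log(denom)))
        post = w / denom[ai] * gw[ai]
        counts = np.bincount(pi, weights=post, minlength=n_haps) + np.bincount(
            pj, weights=post, minlength=n_haps
        )
        freqs = counts / (2 * total_animals)
        if abs(loglike - prev) < tol:
            converged = True
            break
        prev = loglike
    w = freqs[pi] * freqs[pj] * mult
    denom = np.bincount(ai, weights=w, minlength=n_groups)
    loglike = float(np.sum(gw * np.log(np.where(denom <= 0, 1e-300, denom))))
    return freqs, loglike, converged


def phase_window(
    matrix: SnpGenotypeMatrix,
    window: WindowSpec,
    pedigree: list[PedigreeRecord] | None = None,
    seed: int = 0,
    max_iter: int = 20,
    restarts: int = 5,
    ms: dict[str, tuple[int, int]] | list[MsGenotype] | None = None,
    enum_cap: int = 16,
    max_missing: float = 0.20,
) -> HaplotypeSet:
    """Phase every animal over the window; optionally joint with the MS locus.

    Parameters
    ----------
    ms
        MS genotypes for the window's marker, either as a mapping
        ``animal -> (bp, bp)`` or a list of :class:`MsGenotype`.  When given,
        the MS is phased jointly as one extra multi-allelic site and the
        resulting cis-linkage is reported in ``ms_links``; animals without an
        MS genotype are excluded (the reference panel is built from
        MS-genotyped animals only).
    enum_cap
        Animals with more than this many unresolved heterozygous/missing
        "bits" are phased by conditioning on already-inferred haplotypes.
    """
    if isinstance(ms, list):
        ms = {
            g.animal_id: (g.allele_a, g.allele_b)
            for g in ms
            if g.marker == window.marker_name
        }
    data = _SiteData(matrix, window, ms)
    ped_by_id = {p.animal_id: p for p in pedigree} if pedigree else {}
    in_matrix = set(matrix.animal_ids)

    excluded: dict[str, str] = {}
    animals: list[str] = []
    for a in matrix.animal_ids:
        if ms is not None and (a not in ms or ms[a][0] == MISSING_ALLELE):
            excluded[a] = "no MS genotype"
            continue
        g = data.snp_cols[data.row[a]]
        if float(np.mean(g == GT_MISSING)) > max_missing:
            excluded[a] = f"> {max_missing:.0%} missing SNP calls in window"
            continue
        animals.append(a)
    if not animals:
        raise ValueError("no animals eligible for phasing in this window")

    genos = {a: data.genotype(a) for a in animals}

    def parent_sites(pid: str | None) -> list[tuple[int, int]] | None:
        if pid is None or pid not in in_matrix:
            return None
        if pid in genos:
            return genos[pid]
        return data.genotype(pid)

    templates: dict[str, np.ndarray] = {}
    pedigree_resolved = False
    for a in animals:
        rec = ped_by_id.get(a)
        sire = parent_sites(rec.sire_id) if rec else None
        dam = parent_sites(rec.dam_id) if rec else None
        templates[a] = _pedigree_template(genos[a], sire, dam)
        if sire is not None or dam is not None:
            pedigree_resolved = True

    # Animals sharing genotype and pedigree constraints share one EM group.
    group_key: dict[bytes, int] = {}
    group_animals: list[list[str]] = []
    group_rep: list[str] = []
    for a in animals:
        key = repr(genos[a]).encode() + templates[a].tobytes()
        k = group_key.get(key)
        if k is None:
            k = len(group_animals)
            group_key[key] = k
            group_animals.append([])
            group_rep.append(a)
        group_animals[k].append(a)

    registry = _Registry(data.n_sites)
    max_combos = 2**enum_cap
    seg_ai: list[np.ndarray] = []
    seg_pi: list[np.ndarray] = []
    seg_pj: list[np.ndarray] = []
    deferred: list[int] = []
    enum_groups: list[int] = []
    group_pos: dict[int, int] = {}  # group id -> EM index
    for g, rep in enumerate(group_rep):
        pairs_enum = _enumerate_pairs(genos[rep], templates[rep], max_combos)
        if pairs_enum is None:
            deferred.append(g)
            continue
        h0, h1 = pairs_enum
        i0 = registry.add_rows(h0)
        i1 = registry.add_rows(h1)
        k = len(enum_groups)
        group_pos[g] = k
        enum_groups.append(g)
        seg_ai.append(np.full(len(i0), k, dtype=np.int32))
        seg_pi.append(i0)
        seg_pj.append(i1)

    rng_master = np.random.default_rng(seed)
    if enum_groups:
        ai = np.concatenate(seg_ai)
        pi = np.concatenate(seg_pi)
        pj = np.concatenate(seg_pj)
        mult = np.ones(len(ai))
        gw = np.array([len(group_animals[g]) for g in enum_groups], dtype=float)
        n_h = len(registry)
        best = None
        for r in range(max(1, restarts)):
            if r == 0:
                f0 = np.full(n_h, 1.0 / n_h)
            else:
                f0 = rng_master.dirichlet(np.ones(n_h))
            freqs, ll, conv = _run_em(ai, pi, pj, mult, gw, n_h, f0, max_iter)
            if best is None or ll > best[1] + 1e-9:
                best = (freqs, ll, conv)
        freqs, loglike, converged = best
    else:
        freqs = np.array([])
        loglike, converged = 0.0, True
        ai = pi = pj = np.empty(0, dtype=np.int32)
        mult = np.empty(0)
        gw = np.empty(0)

    if deferred:
        site_mode = _site_mode(genos, data.n_sites)
        extra_ai, extra_pi, extra_pj, extra_mult, extra_gw = [], [], [], [], []
        known = list(range(len(registry)))
        known_rows = [registry.rows[i] for i in known]
        for g in deferred:
            rep = group_rep[g]
            k = len(enum_groups) + len(extra_gw)
            group_pos[g] = k
            extra_gw.append(float(len(group_animals[g])))
            cand = _conditioned_pairs(
                genos[rep], templates[rep], known_rows, known, registry, site_mode
            )
            for i0, i1 in cand:
                extra_ai.append(k)
                extra_pi.append(i0)
                extra_pj.append(i1)
                extra_mult.append(2.0 if i0 != i1 else 1.0)
        ai = np.concatenate([ai, np.array(extra_ai, dtype=np.int32)])
        pi = np.concatenate([pi, np.array(extra_pi, dtype=np.int32)])
        pj = np.concatenate([pj, np.array(extra_pj, dtype=np.int32)])
        mult = np.concatenate([mult, np.array(extra_mult)])
        gw = np.concatenate([gw, np.array(extra_gw)])
        n_h = len(registry)
        f0 = np.full(n_h, 1e-6)
        f0[: len(freqs)] += freqs
        f0 /= f0.sum()
        freqs, loglike, converged2 = _run_em(ai, pi, pj, mult, gw, n_h, f0, max_iter)
        converged = converged and converged2

    if not converged:
        warnings.warn(
            f"EM did not converge within {max_iter} iterations for "
            f"{window.marker_name}; returning best-likelihood state",
            stacklevel=2,
        )

    pairs, ms_links = _assign_pairs(
        group_animals, group_rep, group_pos, ai, pi, pj, mult, freqs,
        registry, data, templates,
    )
    source = SOURCE_PEDIGREE if pedigree_resolved else SOURCE_EM
    haps = HaplotypeSet(
        window=window,
        pairs=pairs,
        source=source,
        ms_links=ms_links,
        excluded=excluded,
        converged=converged,
        loglike=loglike,
    )
    haps.check_consistency(matrix)
    return haps


def _site_mode(genos: dict[str, list[tuple[int, int]]], n_sites: int) -> list[int]:
    """Most common allele per site (used to fill deferred animals' gaps)."""
    modes = []
    for s in range(n_sites):
        counts: dict[int, int] = {}
        for g in genos.values():
            for x in g[s]:
                if x != -1:
                    counts[x] = counts.get(x, 0) + 1
        modes.append(max(sorted(counts), key=lambda k: counts[k]) if counts else 0)
    return modes


def _compatible(hap: np.ndarray, sites: list[tuple[int, int]]) -> bool:
    for s, (a, b) in enumerate(sites):
        if a == -1:
            continue
        if a == b and hap[s] != a:
            return False
        if a != b and hap[s] not in (a, b):
            return False
    return True


def _conditioned_pairs(
    sites: list[tuple[int, int]],
    template: np.ndarray,
    known_rows: list[np.ndarray],
    known_idx: list[int],
    registry: "_Registry",
    site_mode: list[int],
) -> list[tuple[int, int]]:
    """Candidate pairs (h, complement-of-h) for each compatible known h."""
    out: set[tuple[int, int]] = set()
    for h, idx in zip(known_rows, known_idx):
        if not _compatible(h, sites):
            continue
        comp = np.empty(len(sites), dtype=np.int16)
        ok = True
        for s, (a, b) in enumerate(sites):
            if template[0, s] != -1 and template[1, s] != -1:
                if h[s] == template[0, s]:
                    comp[s] = template[1, s]
                elif h[s] == template[1, s]:
                    comp[s] = template[0, s]
                else:
                    ok = False
                    break
                continue
            if a == -1:
                comp[s] = site_mode[s]
            elif a == b:
                comp[s] = a
            else:
                comp[s] = b if h[s] == a else a
        if not ok:
            continue
        cidx = registry.add_rows(comp[None, :])[0]
        out.add((min(idx, int(cidx)), max(idx, int(cidx))))
    if not out:
        # greedy fallback: deterministic single pair
        h0 = np.empty(len(sites), dtype=np.int16)
        h1 = np.empty(len(sites), dtype=np.int16)
        for s, (a, b) in enumerate(sites):
            if template[0, s] != -1:
                h0[s], h1[s] = template[0, s], template[1, s]
            elif a == -1:
                h0[s] = h1[s] = site_mode[s]
            else:
                h0[s], h1[s] = a, b
        i0 = registry.add_rows(h0[None, :])[0]
        i1 = registry.add_rows(h1[None, :])[0]
        out.add((min(int(i0), int(i1)), max(int(i0), int(i1))))
    return sorted(out)


def _assign_pairs(
    group_animals: list[list[str]],
    group_rep: list[str],
    group_pos: dict[int, int],
    ai: np.ndarray,
    pi: np.ndarray,
    pj: np.ndarray,
    mult: np.ndarray,
    freqs: np.ndarray,
    registry: "_Registry",
    data: "_SiteData",
    templates: dict[str, np.ndarray],
) -> tuple[dict[str, tuple[Haplotype, Haplotype]], dict[str, tuple[tuple[int, int, float], ...]]]:
    w = freqs[pi] * freqs[pj] * mult
    order = np.argsort(ai, kind="stable")
    ai_s, pi_s, pj_s, w_s = ai[order], pi[order], pj[order], w[order]
    bounds = np.searchsorted(ai_s, np.arange(len(group_pos) + 1))

    pairs: dict[str, tuple[Haplotype, Haplotype]] = {}
    ms_links: dict[str, tuple[tuple[int, int, float], ...]] = {}
    n_snps = data.n_snps
    for g, members in enumerate(group_animals):
        a = group_rep[g]
        k = group_pos[g]
        lo, hi = bounds[k], bounds[k + 1]
        cand_i, cand_j, cand_w = pi_s[lo:hi], pj_s[lo:hi], w_s[lo:hi]
        wmax = float(cand_w.max())
        tied = np.nonzero(cand_w >= wmax * (1 - 1e-9))[0]
        # deterministic pick among ties: smallest canonical byte key pair
        best = min(
            tied,
            key=lambda t: tuple(
                sorted((registry.key(int(cand_i[t])), registry.key(int(cand_j[t]))))
            ),
        )
        i0, j0 = int(cand_i[best]), int(cand_j[best])
        r0, r1 = registry.rows[i0], registry.rows[j0]
        t = templates[a]
        constrained = bool(((t[0] != -1) & (t[1] != -1) & (t[0] != t[1])).any())
        if not constrained and r1.tobytes() < r0.tobytes():
            r0, r1 = r1, r0
        h1 = Haplotype("".join("AB"[x] for x in r0[:n_snps]))
        h2 = Haplotype("".join("AB"[x] for x in r1[:n_snps]))
        link: tuple[tuple[int, int, float], ...] | None = None
        if data.has_ms:
            m0 = data.ms_alleles[int(r0[n_snps])]
            m1 = data.ms_alleles[int(r1[n_snps])]
            if m0 == m1:
                link = ((m0, m1, 1.0),)
            else:
                # posterior mass for each MS orientation given the SNP pair
                snp0, snp1 = r0[:n_snps].tobytes(), r1[:n_snps].tobytes()
                w_same = w_other = 0.0
                for q in range(len(cand_w)):
                    ri = registry.rows[int(cand_i[q])]
                    rj = registry.rows[int(cand_j[q])]
                    key = {ri[:n_snps].tobytes(), rj[:n_snps].tobytes()}
                    if key != {snp0, snp1}:
                        continue
                    for rr in (ri, rj):
                        if rr[:n_snps].tobytes() == snp0:
                            ma = data.ms_alleles[int(rr[n_snps])]
                            if ma == m0:
                                w_same += float(cand_w[q])
                            else:
                                w_other += float(cand_w[q])
                            break
                if snp0 == snp1 or abs(w_same - w_other) <= 1e-9 * max(w_same + w_other, 1e-300):
                    link = ((m0, m1, 0.5), (m1, m0, 0.5))
                else:
                    link = ((m0, m1, 1.0),)
        for member in members:
            pairs[member] = (h1, h2)
            if link is not None:
                ms_links[member] = link
    return pairs, ms_links


# ---------------------------------------------------------------------------
# External phase I/O


def write_phased(haps: HaplotypeSet, path) -> None:
    """Internal phased TSV: animal_id, hap_index in {1,2}, allele_string
    (plus the cis MS allele when known)."""
    with open(path, "w") as fh:
        fh.write("animal_id\thap_index\tallele_string\tms_allele\n")
        for animal in sorted(haps.pairs):
            h1, h2 = haps.pairs[animal]
            links = haps.ms_links.get(animal)
            m1 = m2 = "."
            if links and len(links) == 1:
                m1, m2 = str(links[0][0]), str(links[0][1])
            fh.write(f"{animal}\t1\t{h1.allele_string}\t{m1}\n")
            fh.write(f"{animal}\t2\t{h2.allele_string}\t{m2}\n")


def load_phased(
    path, window: WindowSpec, matrix: SnpGenotypeMatrix | None = None
) -> HaplotypeSet:
    """Load externally phased haplotypes (phased VCF or phased TSV).

    A VCF with any unphased GT among the window SNPs is rejected.  When a
    genotype matrix is supplied, each loaded pair is checked against the
    animal's unphased genotypes and the whole file is rejected on violation.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        haps = _load_phased_vcf(path, window)
    else:
        haps = _load_phased_tsv(path, window)
    if matrix is not None:
        haps.check_consistency(matrix)
    return haps


def _load_phased_vcf(path: str, window: WindowSpec) -> HaplotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(path)
    animals = list(vcf.samples)
    wanted = set(window.snp_ids)
    cols: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for variant in vcf:
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        if vid not in wanted:
            continue
        a0 = np.empty(len(animals), dtype=np.int16)
        a1 = np.empty(len(animals), dtype=np.int16)
        for i, gt in enumerate(variant.genotypes):
            if not gt[2]:
                raise ValueError(f"{path}: unphased GT at {vid}; refusing phased load")
            if gt[0] < 0 or gt[1] < 0:
                raise ValueError(f"{path}: missing GT at {vid} in phased file")
            a0[i], a1[i] = gt[0], gt[1]
        cols[vid] = (a0, a1)
    missing = [s for s in window.snp_ids if s not in cols]
    if missing:
        raise ValueError(f"{path}: window SNPs absent from file: {missing[:5]}")
    pairs = {}
    for i, animal in enumerate(animals):
        s0 = "".join("AB"[int(cols[s][0][i])] for s in window.snp_ids)
        s1 = "".join("AB"[int(cols[s][1][i])] for s in window.snp_ids)
        pairs[animal] = (Haplotype(s0), Haplotype(s1))
    return HaplotypeSet(window=window, pairs=pairs, source=SOURCE_EXTERNAL)


def _load_phased_tsv(path: str, window: WindowSpec) -> HaplotypeSet:
    rows: dict[str, dict[int, tuple[str, str]]] = {}
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            animal, idx, allele_string = parts[0], int(parts[1]), parts[2]
            ms = parts[3] if len(parts) > 3 else "."
            rows.setdefault(animal, {})[idx] = (allele_string, ms)
    pairs = {}
    ms_links: dict[str, tuple[tuple[int, int, float], ...]] = {}
    for animal, d in rows.items():
        if set(d) != {1, 2}:
            raise ValueError(f"{path}: animal {animal} lacks two haplotype rows")
        s1, m1 = d[1]
        s2, m2 = d[2]
        if len(s1) != window.size or len(s2) != window.size:
            raise ValueError(f"{path}: haplotype length mismatch for {animal}")
        pairs[animal] = (Haplotype(s1), Haplotype(s2))
        if m1 != "." and m2 != ".":
            ms_links[animal] = ((int(m1), int(m2), 1.0),)
    return HaplotypeSet(window=window, pairs=pairs, source=SOURCE_EXTERNAL, ms_links=ms_links)
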