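"""Domain types, marker-region arithmetic, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msimpute import io as msio
from msimpute.types import (
    GT_AB,
    GT_MISSING,
    EmptyRegionError,
    MsGenotype,
    MsMarker,
    SnpMapEntry,
    build_region,
    check_pedigree_cycles,
    default_ms_markers,
    PedigreeRecord,
)


def _map(positions, chrom="1"):
    return [SnpMapEntry(f"snp{i}", chrom, p) for i, p in enumerate(positions)]


class TestBuildRegion:
    def test_flank_boundary_inclusive(self):
        ms = MsMarker("MS1", "1", 1_000_000)
        snps = _map([400_000, 600_000, 1_500_000, 1_600_000])
        region = build_region(ms, snps, flank_bp=500_000)
        assert [s.position for s in region.snps] == [600_000, 1_500_000]

    def test_zero_flank_keeps_only_colocated(self):
        ms = MsMarker("MS1", "1", 1_000_000)
        region = build_region(ms, _map([1_000_000, 1_000_001]), flank_bp=0)
        assert [s.position for s in region.snps] == [1_000_000]

    def test_empty_region_raises(self):
        ms = MsMarker("MS1", "1", 1_000_000)
        with pytest.raises(EmptyRegionError):
            build_region(ms, _map([10_000_000]), flank_bp=500_000)

    def test_other_chromosome_excluded(self):
        ms = MsMarker("MS1", "1", 1_000_000)
        snps = _map([1_000_000], chrom="2") + _map([999_000])
        region = build_region(ms, snps)
        assert region.snp_ids == ["snp0"]

    @given(flanks=st.lists(st.integers(0, 2_000_000), min_size=2, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_snp_count_monotone_in_flank(self, flanks):
        ms = MsMarker("MS1", "1", 1_000_000)
        snps = _map(list(range(100_000, 2_100_000, 100_000)))
        counts = []
        for f in sorted(flanks):
            try:
                counts.append(len(build_region(ms, snps, f).snps))
            except EmptyRegionError:
                counts.append(0)
        assert counts == sorted(counts)

    def test_idempotent(self):
        ms = MsMarker("MS1", "1", 1_000_000)
        snps = _map([600_000, 900_000, 1_400_000])
        r1 = build_region(ms, snps)
        r2 = build_region(ms, list(r1.snps))
        assert r1.snp_ids == r2.snp_ids


class TestMsGenotype:
    def test_normalization_unordered(self):
        g = MsGenotype.make("X", "TGLA126", 123, 117)
        assert g.alleles == (117, 123)

    @given(a=st.integers(100, 300), b=st.integers(100, 300))
    @settings(max_examples=100, deadline=None)
    def test_normalization_involution(self, a, b):
        g = MsGenotype.make("X", "M", a, b)
        again = MsGenotype.make(g.animal_id, g.marker, g.allele_a, g.allele_b)
        assert again.alleles == g.alleles

    def test_half_missing_rejected(self):
        with pytest.raises(ValueError):
            MsGenotype("X", "M", 0, 123)


class TestMsGenotypeFile:
    def test_read_normalizes_and_flags(self, tmp_path):
        p = tmp_path / "ms.tsv"
        p.write_text(
            "animal\tmarker\tallele1\tallele2\n"
            "X\tTGLA126\t123\t117\n"
            "Y\tFOO\t100\t102\n"
            "Z\tBM1818\t266\t266\n"
            "W\tBM1818\t.\t123\n"
        )
        known = {m.name for m in default_ms_markers()}
        result = msio.read_ms_genotypes(p, known_markers=known)
        assert [(g.animal_id, g.alleles) for g in result.records] == [
            ("X", (117, 123)),
            ("Z", (266, 266)),
        ]
        assert [g.animal_id for g in result.unknown_marker] == ["Y"]
        assert len(result.errors) == 1 and "half-missing" in result.errors[0]

    def test_write_read_round_trip(self, tmp_path):
        records = [
            MsGenotype.make("A", "M1", 111, 115),
            MsGenotype.make("B", "M1", 0, 0),
        ]
        p = tmp_path / "ms.tsv"
        msio.write_ms_genotypes(records, p)
        back = msio.read_ms_genotypes(p)
        assert [g.alleles for g in back.records] == [g.alleles for g in records]


class TestSnpGenotypeIO:
    def test_ab_matrix_round_trip(self, clean_sim, tmp_path):
        p = tmp_path / "m.tsv"
        sub = clean_sim.matrix.subset(clean_sim.matrix.animal_ids[:10])
        msio.write_ab_matrix(sub, p)
        back = msio.read_snp_genotypes(p, "ab-matrix")
        assert back.animal_ids == sub.animal_ids
        assert back.snp_ids == sub.snp_ids
        assert np.array_equal(back.calls, sub.calls)

    def test_ab_matrix_missing_token(self, tmp_path):
        p = tmp_path / "m.tsv"
        p.write_text("animal\ts1\ts2\nA\tAA\t--\n")
        m = msio.read_snp_genotypes(p, "ab-matrix")
        assert m.calls[0, 1] == GT_MISSING

    def test_vcf_round_trip(self, clean_sim, tmp_path):
        sub = clean_sim.matrix.subset(clean_sim.matrix.animal_ids[:8])
        p = tmp_path / "g.vcf"
        msio.write_vcf(sub, clean_sim.snp_map, p)
        back = msio.read_snp_genotypes(p, "vcf")
        assert set(back.snp_ids) == set(sub.snp_ids)
        col = {s: j for j, s in enumerate(back.snp_ids)}
        reordered = back.calls[:, [col[s] for s in sub.snp_ids]]
        assert np.array_equal(reordered, sub.calls)
        assert not any(back.phased.values())  # written unphased

    def test_vcf_phased_single_sample(self, tmp_path):
        p = tmp_path / "p.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trs1\tA\tB\t.\t.\t.\tGT\t0|1\n"
        )
        m = msio.read_snp_genotypes(p, "vcf")
        assert m.calls[0, 0] == GT_AB
        assert m.phased["S1"] is True

    def test_vcf_multiallelic_rejected(self, tmp_path):
        p = tmp_path / "m.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\n"
            "1\t100\trs1\tA\tC,G\t.\t.\t.\tGT\t1/2\n"
        )
        with pytest.raises(msio.ParseError, match="multiallelic"):
            msio.read_snp_genotypes(p, "vcf")


class TestPedigree:
    def test_cycle_detected(self):
        records = [
            PedigreeRecord("A", "B", None),
            PedigreeRecord("B", "C", None),
            PedigreeRecord("C", "A", None),
        ]
        with pytest.raises(ValueError, match="cycle"):
            check_pedigree_cycles(records)

    def test_round_trip(self, tmp_path):
        records = [
            PedigreeRecord("A", None, None, "angus"),
            PedigreeRecord("B", "A", None, "angus"),
        ]
        p = tmp_path / "ped.tsv"
        msio.write_pedigree(records, p)
        assert msio.read_pedigree(p) == records


class TestBeagleExport:
    def _setup(self, clean_sim, tmp_path, n=3, n_ms=2):
        animals = clean_sim.matrix.animal_ids[:n]
        sub = clean_sim.matrix.subset(animals)
        ms = [g for g in clean_sim.ms_records if g.animal_id in animals[:n_ms]]
        region = build_region(clean_sim.ms_map[0], clean_sim.snp_map)
        return region, sub, ms

    def test_only_ms_genotyped_animals_exported(self, clean_sim, tmp_path):
        region, sub, ms = self._setup(clean_sim, tmp_path)
        path = msio.export_beagle_inputs(region, sub, ms, tmp_path)
        header = path.read_text().splitlines()[0].split("\t")
        exported = sorted(set(header[2:]))
        assert exported == sorted({g.animal_id for g in ms})

    def test_empty_ms_table_header_only(self, clean_sim, tmp_path):
        region, sub, _ = self._setup(clean_sim, tmp_path)
        path = msio.export_beagle_inputs(region, sub, [], tmp_path)
        first = path.read_text().splitlines()[0]
        assert first == "I\tid"

    def test_re_export_byte_identical(self, clean_sim, tmp_path):
        region, sub, ms = self._setup(clean_sim, tmp_path)
        p1 = msio.export_beagle_inputs(region, sub, ms, tmp_path / "a")
        p2 = msio.export_beagle_inputs(region, sub, ms, tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_ms_row_present_with_sizes(self, clean_sim, tmp_path):
        region, sub, ms = self._setup(clean_sim, tmp_path)
        lines = msio.export_beagle_inputs(region, sub, ms, tmp_path).read_text().splitlines()
        ms_rows = [l for l in lines if l.split("\t")[1] == region.marker.name]
        assert len(ms_rows) == 1
        sizes = {int(x) for x in ms_rows[0].split("\t")[2:]}
        truth = {a for g in ms for a in g.alleles}
        assert sizes == truth


def test_default_marker_panel_bundled():
    markers = default_ms_markers()
    assert len(markers) == 12
    by_name = {m.name: m.chromosome for m in markers}
    assert by_name["TGLA126"] == "20"
    assert by_name["BM1818"] == "23"
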