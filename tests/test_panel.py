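"""Association-table classification, merging, and panel summaries."""

import numpy as np
import pytest

from msimpute.panel import (
    CLASS_AMBIGUOUS,
    CLASS_CONCORDANT,
    CLASS_RARE,
    CLASS_UNIQUE,
    AssociationTable,
    build_table,
    merge_tables,
    summarize_panel,
)
from msimpute.phasing import make_window, phase_window
from msimpute.sim import SimConfig, simulate_panel, truth_haplotype_set
from msimpute.types import build_region


def _table(entries, length=6, **kw):
    t = AssociationTable("M", length, **kw)
    for hap, (breed, alleles) in entries.items():
        for allele, count in alleles.items():
            t.add_observation(hap, breed, allele, count)
    return t


class TestClassification:
    @pytest.mark.parametrize(
        "alleles, expected",
        [
            ({123: 937, 117: 1, 121: 2}, CLASS_CONCORDANT),
            ({200: 4}, CLASS_UNIQUE),
            ({200: 1}, CLASS_RARE),
            ({200: 3}, CLASS_RARE),
            ({123: 5, 117: 5}, CLASS_AMBIGUOUS),
            ({123: 9, 117: 1}, CLASS_CONCORDANT),  # exactly 90%
            ({123: 8, 117: 2}, CLASS_AMBIGUOUS),  # 80% < 90%
        ],
    )
    def test_class_rules(self, alleles, expected):
        t = _table({"AAAAAA": ("b", alleles)})
        assert t.classify("AAAAAA") == expected

    def test_worked_example_fractions(self):
        t = _table({"AAAAAA": ("b", {123: 937, 117: 1, 121: 2})})
        e = t.entries["AAAAAA"]
        assert e.primary_allele == 123
        assert round(100 * e.primary_fraction, 2) == 99.68
        assert round(100 * e.allele_totals[117] / e.total_count, 2) == 0.11

    def test_partition_exactly_one_class(self):
        rng = np.random.default_rng(0)
        t = AssociationTable("M", 4)
        for _ in range(200):
            hap = "".join(rng.choice(["A", "B"], size=4))
            t.add_observation(hap, "b", int(rng.choice([111, 113])), 1.0)
        classes = {CLASS_UNIQUE, CLASS_CONCORDANT, CLASS_AMBIGUOUS, CLASS_RARE}
        for hap in t.entries:
            assert t.classify(hap) in classes

    def test_primary_tie_broken_to_smaller_bp(self):
        t = _table({"AAAAAA": ("b", {123: 5, 117: 5})})
        assert t.entries["AAAAAA"].primary_allele == 117
        assert t.entries["AAAAAA"].primary_tied


class TestMerge:
    def test_identity(self):
        t = _table({"AAAAAA": ("b", {123: 5})})
        empty = AssociationTable("M", 6)
        merged = merge_tables(t, empty)
        assert merged.entries["AAAAAA"].total_count == 5

    def test_self_merge_doubles_counts_preserves_fractions(self):
        t = _table({"AAAAAA": ("b", {123: 9, 117: 1})})
        m = merge_tables(t, t)
        e = m.entries["AAAAAA"]
        assert e.total_count == 20
        assert e.primary_fraction == t.entries["AAAAAA"].primary_fraction

    def test_single_observations_give_half_fraction(self):
        a = _table({"AAAAAA": ("b1", {123: 1})})
        b = _table({"AAAAAA": ("b2", {117: 1})})
        m = merge_tables(a, b)
        e = m.entries["AAAAAA"]
        assert e.primary_fraction == 0.5
        assert e.n_breeds == 2

    def test_commutative_and_associative(self):
        rng = np.random.default_rng(3)

        def random_table():
            t = AssociationTable("M", 4)
            for _ in range(30):
                hap = "".join(rng.choice(["A", "B"], size=4))
                t.add_observation(hap, str(rng.integers(3)), int(rng.choice([111, 113])))
            return t

        a, b, c = random_table(), random_table(), random_table()

        def flat(t):
            return {
                (h, br, al): round(w, 9)
                for h, e in t.entries.items()
                for br, d in e.counts.items()
                for al, w in d.items()
            }

        assert flat(merge_tables(a, b)) == flat(merge_tables(b, a))
        assert flat(merge_tables(merge_tables(a, b), c)) == flat(
            merge_tables(a, merge_tables(b, c))
        )

    def test_window_mismatch_rejected(self):
        with pytest.raises(ValueError, match="window"):
            merge_tables(AssociationTable("M", 4), AssociationTable("M", 6))


class TestBuildTable:
    def test_total_is_twice_animal_count(self, clean_sim, clean_window):
        haps = phase_window(
            clean_sim.matrix, clean_window, pedigree=clean_sim.pedigree,
            seed=5, ms=clean_sim.ms_records,
        )
        table = build_table(haps, clean_sim.breeds)
        assert table.total_observations == pytest.approx(2 * len(haps.pairs))

    def test_missing_breed_warns_not_drops(self, clean_sim, clean_window):
        haps = phase_window(
            clean_sim.matrix, clean_window, seed=5, ms=clean_sim.ms_records
        )
        with pytest.warns(UserWarning, match="unknown"):
            table = build_table(haps, breeds={})
        assert table.total_observations == pytest.approx(2 * len(haps.pairs))

    def test_round_trip_via_frame(self, clean_sim, clean_window):
        haps = phase_window(
            clean_sim.matrix, clean_window, seed=5, ms=clean_sim.ms_records
        )
        table = build_table(haps, clean_sim.breeds)
        back = AssociationTable.from_frame(table.to_frame(), table.marker)
        assert set(back.entries) == set(table.entries)
        for h in table.entries:
            assert back.entries[h].total_count == pytest.approx(
                table.entries[h].total_count
            )
            assert back.classify(h) == table.classify(h)


class TestSummarize:
    def test_single_breed_histogram(self):
        t = _table({"AAAAAA": ("b", {123: 5}), "BBBBBB": ("b", {117: 6})})
        s = summarize_panel([t])
        assert s.breed_sharing == {1: 2}
        row = s.per_marker.iloc[0]
        assert row["breeds_unique_mean"] == 1.0

    def test_histogram_sums_to_non_rare(self):
        t = _table(
            {
                "AAAAAA": ("b1", {123: 5}),
                "BBBBBB": ("b2", {117: 1}),  # rare, excluded
                "ABABAB": ("b1", {111: 3, 113: 3}),  # ambiguous but non-rare
            }
        )
        t.add_observation("AAAAAA", "b2", 123, 2.0)
        s = summarize_panel([t])
        non_rare = sum(
            1 for h in t.entries if t.classify(h) != CLASS_RARE
        )
        assert sum(s.breed_sharing.values()) == non_rare

    def test_merge_then_summarize_equals_pooled(self):
        rng = np.random.default_rng(9)

        def obs():
            return (
                "".join(rng.choice(["A", "B"], size=4)),
                str(rng.integers(2)),
                int(rng.choice([111, 113])),
            )

        obs_a = [obs() for _ in range(40)]
        obs_b = [obs() for _ in range(40)]
        ta, tb, pooled = (AssociationTable("M", 4) for _ in range(3))
        for h, b, al in obs_a:
            ta.add_observation(h, b, al)
            pooled.add_observation(h, b, al)
        for h, b, al in obs_b:
            tb.add_observation(h, b, al)
            pooled.add_observation(h, b, al)
        s1 = summarize_panel([merge_tables(ta, tb)])
        s2 = summarize_panel([pooled])
        assert s1.breed_sharing == s2.breed_sharing
        assert s1.per_marker.drop(columns=["span_bp"]).equals(
            s2.per_marker.drop(columns=["span_bp"])
        )

    def test_shared_fraction_recovered(self):
        cfg = SimConfig(
            n_breeds=8, n_ancestral_haplotypes=100, fraction_shared=0.25,
            region_snps=30, n_founders=200, n_trios=0, markers=("MS1",),
            ms_error_rate=0.0, ms_mutation_rate=0.0, recomb_rate=0.0,
            rounding_error_rate=0.0, seed=11,
        )
        data = simulate_panel(cfg)
        region = build_region(data.ms_map[0], data.snp_map)
        window = make_window(region, 30)
        table = build_table(truth_haplotype_set(data, window), data.breeds)
        s = summarize_panel([table])
        assert s.multi_breed_fraction == pytest.approx(0.25, abs=0.06)

    def test_identical_inputs_identical_rows(self):
        t1 = _table({"AAAAAA": ("b", {123: 5})})
        t2 = _table({"AAAAAA": ("b", {123: 5})})
        t2.marker = "M"
        s = summarize_panel([t1, t2])
        rows = s.per_marker.drop(columns=["marker"])
        assert rows.iloc[0].equals(rows.iloc[1])
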