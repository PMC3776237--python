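"""Mendelian conflict counting, exclusion rules, and the update workflow."""

from itertools import product

import pytest

from msimpute.impute import impute_animal
from msimpute.panel import AssociationTable, build_table
from msimpute.parentage import (
    VERDICT_EXCLUDED,
    VERDICT_PASS,
    VERDICT_VERIFIED,
    WorkflowState,
    brute_force_trio_conflict,
    haplotype_assisted_review,
    marker_conflict,
    prob_at_least_one_error,
    trio_conflict,
    verify_cohort,
    workflow_step,
)
from msimpute.phasing import HaplotypeSet, make_window, phase_window
from msimpute.sim import SimConfig, simulate_panel
from msimpute.types import Haplotype, MsGenotype, PedigreeRecord, build_region


def _g(animal, a, b, marker="M"):
    return MsGenotype.make(animal, marker, a, b)


class TestErrorAlgebra:
    def test_error_probability_compounds_across_markers(self):
        # at 1% per marker, 11 markers already exceed a 10% chance of >=1 error
        assert prob_at_least_one_error(0.01, 11) > 0.10
        assert prob_at_least_one_error(0.01, 1) == pytest.approx(0.01)
        assert prob_at_least_one_error(0.0, 12) == 0.0


class TestMarkerConflict:
    def test_no_shared_allele_conflicts(self):
        assert marker_conflict(_g("o", 123, 115), _g("p", 117, 117))

    def test_shared_allele_no_conflict(self):
        assert not marker_conflict(_g("o", 117, 123), _g("p", 117, 117))

    def test_tolerance_2bp(self):
        off, par = _g("o", 121, 121), _g("p", 123, 119)
        assert marker_conflict(off, par, tolerance_bp=0)
        assert not marker_conflict(off, par, tolerance_bp=2)

    def test_missing_rejected(self):
        with pytest.raises(ValueError):
            marker_conflict(_g("o", 0, 0), _g("p", 117, 117))


class TestTrioConflict:
    def test_parents_explain_child(self):
        assert not trio_conflict(_g("o", 1, 2), _g("s", 1, 1), _g("d", 2, 2))

    def test_sire_cannot_contribute(self):
        assert trio_conflict(_g("o", 1, 1), _g("s", 2, 2), _g("d", 1, 1))

    def test_single_parent_falls_back_to_duo(self):
        assert not trio_conflict(_g("o", 1, 2), _g("s", 1, 1), None)
        assert trio_conflict(_g("o", 2, 2), _g("s", 1, 1), None)

    def test_exhaustive_three_allele_system_matches_oracle(self):
        alleles = [111, 113, 115]
        genos = [tuple(sorted(p)) for p in product(alleles, repeat=2)]
        genos = sorted(set(genos))
        n = 0
        for o, s, d in product(genos, repeat=3):
            got = trio_conflict(
                _g("o", *o), _g("s", *s), _g("d", *d)
            )
            want = brute_force_trio_conflict(o, s, d)
            assert got == want, (o, s, d)
            n += 1
        assert n == 216

    def test_oracle_agreement_with_tolerance(self):
        alleles = [111, 113, 115]
        genos = sorted({tuple(sorted(p)) for p in product(alleles, repeat=2)})
        for o, s, d in product(genos, repeat=3):
            assert trio_conflict(
                _g("o", *o), _g("s", *s), _g("d", *d), tolerance_bp=2
            ) == brute_force_trio_conflict(o, s, d, tolerance_bp=2)


class TestVerifyCohort:
    def test_true_transmission_zero_conflicts(self, clean_sim):
        truth_records = clean_sim.truth.true_ms_records()
        reports, dist = verify_cohort(truth_records, clean_sim.pedigree)
        assert dist.fraction_0 == 1.0
        assert all(r.verdict == VERDICT_VERIFIED for r in reports
                   if r.verdict != "unverifiable")

    def test_verdict_thresholds(self):
        ped = [PedigreeRecord("c", "s", None, "x")]
        markers = [f"M{i}" for i in range(3)]
        # two conflicting markers -> excluded
        genos = [_g("c", 1, 1, m) for m in markers]
        parents = [_g("s", 2, 2, markers[0]), _g("s", 2, 2, markers[1]),
                   _g("s", 1, 1, markers[2])]
        reports, _ = verify_cohort(genos, ped, parents)
        assert reports[0].n_conflicts == 2
        assert reports[0].verdict == VERDICT_EXCLUDED
        # one conflict -> pass
        parents[1] = _g("s", 1, 1, markers[1])
        reports, _ = verify_cohort(genos, ped, parents)
        assert reports[0].verdict == VERDICT_PASS

    def test_missing_marker_not_in_denominator(self):
        ped = [PedigreeRecord("c", "s", None, "x")]
        genos = [_g("c", 1, 1, "M1"), _g("c", 0, 0, "M2")]
        parents = [_g("s", 1, 2, "M1")]
        reports, _ = verify_cohort(genos, ped, parents)
        assert reports[0].n_compared == 1
        assert reports[0].n_not_compared == 1

    def test_no_genotyped_parent_unverifiable(self):
        ped = [PedigreeRecord("c", "s", None, "x")]
        reports, dist = verify_cohort([_g("c", 1, 1)], ped, [])
        assert reports[0].verdict == "unverifiable"
        assert dist.n_unverifiable == 1

    def test_order_invariance(self, noisy_sim):
        records = list(noisy_sim.ms_records)
        r1, _ = verify_cohort(records, noisy_sim.pedigree)
        r2, _ = verify_cohort(records[::-1], noisy_sim.pedigree[::-1])
        c1 = {r.animal_id: r.n_conflicts for r in r1}
        c2 = {r.animal_id: r.n_conflicts for r in r2}
        assert c1 == c2

    def test_parent_error_rate_propagates(self):
        # 1% per-marker error on each of two parents' genotypes, 12 markers:
        # P(child has >=1 conflict-prone parental error) <= 1 - 0.99^24;
        # measured conflict fraction stays near the closed form because an
        # error rarely leaves the genotype compatible by chance
        cfg = SimConfig(
            n_breeds=1, fraction_shared=0.0, n_founders=400, n_trios=200,
            region_snps=8, markers=tuple(f"M{i}" for i in range(12)),
            ms_error_rate=0.01, ms_mutation_rate=0.0, recomb_rate=0.0,
            rounding_error_rate=0.0, seed=23,
        )
        data = simulate_panel(cfg)
        reports, dist = verify_cohort(data.ms_records, data.pedigree)
        children = [r for r in reports if r.animal_id.split("_")[1].startswith("c")]
        frac_ge1 = sum(r.n_conflicts >= 1 for r in children) / len(children)
        upper = 1 - 0.99**36  # child's own calls can also be miscalled
        assert 0.0 < frac_ge1 < upper + 0.05


class TestReview:
    def _setup(self):
        window_len = 8
        shared = "ABABABAB"
        other = "BABABABA"
        table = AssociationTable("M", window_len)
        table.add_observation(shared, "b", 123, 937.0)
        table.add_observation(shared, "b", 117, 1.0)
        table.add_observation(shared, "b", 121, 2.0)
        hs = HaplotypeSet(
            window=None, pairs={
                "child": (Haplotype(shared), Haplotype(other)),
                "sire": (Haplotype(shared), Haplotype("A" * 8)),
            },
        )
        return table, hs

    def test_shared_haplotype_flags_parent_misscore(self):
        table, hs = self._setup()
        recs = haplotype_assisted_review(
            "child", "sire", ["M"], {"M": hs}, {"M": table},
            parent_ms={"M": MsGenotype.make("sire", "M", 117, 117)},
        )
        assert recs[0].shared_haplotype == "ABABABAB"
        assert recs[0].diagnosis == "probable-parent-misscore"
        assert recs[0].allele_distribution[123] == 937.0

    def test_no_shared_haplotype_corroborates(self):
        table, hs = self._setup()
        hs.pairs["sire"] = (Haplotype("B" * 8), Haplotype("A" * 8))
        recs = haplotype_assisted_review(
            "child", "sire", ["M"], {"M": hs}, {"M": table},
            parent_ms={"M": MsGenotype.make("sire", "M", 117, 117)},
        )
        assert recs[0].diagnosis == "corroborated"

    def test_unphased_parent_skipped(self):
        table, hs = self._setup()
        del hs.pairs["sire"]
        recs = haplotype_assisted_review(
            "child", "sire", ["M"], {"M": hs}, {"M": table}
        )
        assert recs[0].diagnosis.startswith("skipped")


class TestWorkflow:
    def _state(self):
        hap = "ABABABAB"
        table = AssociationTable("M", 8)
        table.add_observation(hap, "b", 123, 10.0)
        return WorkflowState(tables={"M": table}), hap

    def _haps(self, hap, animal="X"):
        return HaplotypeSet(
            window=None,
            pairs={animal: (Haplotype(hap), Haplotype(hap))},
            ms_links={animal: ((117, 117, 1.0),)},
        )

    def test_pass_leaves_state_unchanged(self):
        state, _ = self._state()
        v0 = state.version
        out = workflow_step(state, "X", verification_passed=True)
        assert out.version == v0 and not out.pending

    def test_fail_without_confirmation_queues(self):
        state, _ = self._state()
        out = workflow_step(state, "X", verification_passed=False)
        assert out.pending == ["X"]
        assert out.version == 1

    def test_confirmation_matching_imputation_flags_parent(self):
        state, hap = self._state()
        imputed = {"M": impute_animal((hap, hap), state.tables["M"],
                                      "X", backoff_floor=8)}
        confirmed = {"M": MsGenotype.make("X", "M", 123, 123)}
        out = workflow_step(
            state, "X", False, imputed=imputed, confirmed_ms=confirmed,
            phased={"M": self._haps(hap)},
        )
        assert out.version == 1
        assert any("re-test" in line for line in out.audit_log)

    def test_mismatch_updates_panel_and_self_corrects(self):
        state, hap = self._state()
        novel = "BBBBBBBB"
        # before any confirmation the novel haplotype cannot be imputed
        r0 = impute_animal((novel, novel), state.tables["M"], "Y", backoff_floor=8)
        assert not r0.complete
        # each confirmed homozygous animal adds 2 observations, so the
        # min_count=4 threshold is crossed after two ingested animals
        for i in range(2):
            imputed = {
                "M": impute_animal((novel, novel), state.tables["M"],
                                   f"X{i}", backoff_floor=8)
            }
            v0 = state.version
            state = workflow_step(
                state, f"X{i}", False, imputed=imputed,
                confirmed_ms={"M": MsGenotype.make(f"X{i}", "M", 117, 117)},
                phased={"M": self._haps(novel, f"X{i}")},
            )
            assert state.version == v0 + 1
        entry = state.tables["M"].entries[novel]
        assert entry.total_count == 4
        r = impute_animal((novel, novel), state.tables["M"], "Y", backoff_floor=8)
        assert r.alleles == (117, 117)
        # a further failure now confirms the imputation instead of updating
        imputed = {"M": r}
        state = workflow_step(
            state, "X9", False, imputed=imputed,
            confirmed_ms={"M": MsGenotype.make("X9", "M", 117, 117)},
            phased={"M": self._haps(novel, "X9")},
        )
        assert any("re-test" in line for line in state.audit_log)

    def test_confirmed_ms_without_phase_rejected(self):
        state, hap = self._state()
        imputed = {"M": impute_animal((hap, hap), state.tables["M"],
                                      "X", backoff_floor=8)}
        with pytest.raises(ValueError, match="phased"):
            workflow_step(
                state, "X", False, imputed=imputed,
                confirmed_ms={"M": MsGenotype.make("X", "M", 117, 117)},
            )
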