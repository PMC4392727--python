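"""Audit categorization, closed membership, overlap counts, ablation."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings, strategies as st

from epcaudit import (
    audit_kb,
    categorize_class,
    categorize_drug,
    closed_members,
    relation_overlap,
    run_ablation,
    summarize,
)
from epcaudit.classifier import EpcHierarchy
from epcaudit.comparison import CLASS_CATEGORIES, DRUG_CATEGORIES, DrugComparison
from epcaudit.kb import Hierarchy, Membership


def _hier(*edges: tuple[str, str]) -> EpcHierarchy:
    return EpcHierarchy(Hierarchy(frozenset(edges)))


FS = frozenset


class TestCategorizeDrug:
    @pytest.mark.parametrize(
        "A, I, edges, expected",
        [
            # same single class on both sides (the imatinib situation)
            (FS({"kinase"}), FS({"kinase"}), (), "identical"),
            # asserted class, nothing inferred (losartan)
            (FS({"arb"}), FS(), (), "asserted_only"),
            # extra unrelated inferred class (bupropion)
            (FS({"aminoketone"}), FS({"aminoketone", "nri"}), (),
             "additional_inferred"),
            # inference with no asserted class (isosorbide)
            (FS(), FS({"antianginal"}), (), "inferred_only"),
            # asserted more specific than inferred (amikacin)
            (FS({"ag_antibacterial"}), FS({"aminoglycoside"}),
             (("ag_antibacterial", "aminoglycoside"),), "compatible"),
            # unrelated classes on both sides
            (FS({"a", "x"}), FS({"a", "y"}), (), "additional_both"),
            # extra asserted only
            (FS({"a", "b"}), FS({"a"}), (), "additional_asserted"),
        ],
    )
    def test_decision_tree(self, A, I, edges, expected):
        assert categorize_drug(A, I, _hier(*edges)) == expected

    def test_one_directional_flag(self):
        """Under the looser reading, matched asserted classes suffice even
        with extra inferred ones."""
        h = _hier(("spec", "gen"))
        A, I = FS({"spec"}), FS({"gen", "other"})
        assert categorize_drug(A, I, h) == "additional_inferred"
        assert categorize_drug(A, I, h, bidirectional=False) == "compatible"

    def test_empty_both_rejected(self):
        with pytest.raises(ValueError):
            categorize_drug(FS(), FS(), _hier())

    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_partition_property(self, data):
        """Every non-empty (A, I) pair receives exactly one category."""
        universe = [f"e{i}" for i in range(6)]
        A = FS(data.draw(st.sets(st.sampled_from(universe), max_size=4)))
        I = FS(data.draw(st.sets(st.sampled_from(universe), max_size=4)))
        edges = data.draw(
            st.sets(
                st.tuples(st.sampled_from(universe), st.sampled_from(universe))
                .filter(lambda e: e[0] < e[1]),  # acyclic by ordering
                max_size=5,
            )
        )
        if not A and not I:
            return
        cat = categorize_drug(A, I, _hier(*edges))
        assert cat in DRUG_CATEGORIES


class TestCategorizeClass:
    @pytest.mark.parametrize(
        "Ac, Ic, expected",
        [
            (FS({"d1", "d2", "d3", "d4", "d5"}), FS({"d1", "d2", "d3", "d4", "d5"}),
             "identical"),
            (FS({"ofloxacin", "levofloxacin"}), FS(), "asserted_only"),
            (FS({"d1"}), FS({"d2"}), "additional_both"),
            (FS({"d1", "d2"}), FS({"d1"}), "additional_asserted"),
            (FS({"d1"}), FS({"d1", "d2"}), "additional_inferred"),
            (FS(), FS({"d1"}), "inferred_only"),
        ],
    )
    def test_decision_tree(self, Ac, Ic, expected):
        assert categorize_class(Ac, Ic) == expected

    def test_total_on_random_pairs(self):
        rng = random.Random(29)
        drugs = [f"d{i}" for i in range(6)]
        for _ in range(500):
            Ac = FS(d for d in drugs if rng.random() < 0.4)
            Ic = FS(d for d in drugs if rng.random() < 0.4)
            if not Ac and not Ic:
                continue
            assert categorize_class(Ac, Ic) in CLASS_CATEGORIES


class TestClosedMembers:
    def test_member_through_subclass(self):
        h = _hier(("beta2", "beta"))
        mem = [Membership("albuterol", "beta2", "asserted", "direct")]
        assert closed_members("beta", mem, h) == {"albuterol"}
        assert closed_members("beta2", mem, h) == {"albuterol"}

    def test_leaf_class_direct_only(self):
        h = _hier(("beta2", "beta"))
        mem = [Membership("d", "beta", "asserted", "direct")]
        assert closed_members("beta2", mem, h) == frozenset()

    def test_matches_bruteforce_union_on_random_dag(self):
        rng = random.Random(31)
        epcs = [f"e{i}" for i in range(10)]
        edges = frozenset(
            (epcs[i], epcs[j])
            for i in range(10) for j in range(i)
            if rng.random() < 0.25
        )
        h = _hier(*edges)
        mem = [
            Membership(f"d{k}", rng.choice(epcs), "asserted", "direct")
            for k in range(20)
        ]
        for e in epcs:
            brute = {
                m.drug for m in mem
                if m.epc == e or h.reach.is_descendant(m.epc, e)
            }
            assert closed_members(e, mem, h) == brute


class TestRelationOverlap:
    def test_identical_sets(self):
        mem = [Membership(f"d{i}", "e", "asserted", "direct") for i in range(3)]
        inf = [Membership(f"d{i}", "e", "inferred", "direct") for i in range(3)]
        o = relation_overlap(mem, inf, "direct")
        assert (o.n_common, o.n_asserted_only, o.n_inferred_only) == (3, 0, 0)

    def test_closed_mode_expands_through_hierarchy(self):
        h = _hier(("beta2", "beta"))
        asserted = [Membership("albuterol", "beta2", "asserted", "direct")]
        inferred = [Membership("albuterol", "beta2", "inferred", "direct")]
        o = relation_overlap(asserted, inferred, "closed", h)
        assert (o.n_asserted, o.n_inferred, o.n_common) == (2, 2, 2)

    def test_closed_counts_at_least_direct(self):
        rng = random.Random(37)
        epcs = [f"e{i}" for i in range(8)]
        edges = frozenset(
            (epcs[i], epcs[j]) for i in range(8) for j in range(i)
            if rng.random() < 0.3
        )
        h = _hier(*edges)
        asserted = [
            Membership(f"d{k}", rng.choice(epcs), "asserted", "direct")
            for k in range(15)
        ]
        inferred = [
            Membership(f"d{k}", rng.choice(epcs), "inferred", "direct")
            for k in range(15)
        ]
        d = relation_overlap(asserted, inferred, "direct")
        c = relation_overlap(asserted, inferred, "closed", h)
        assert c.n_asserted >= d.n_asserted
        assert c.n_inferred >= d.n_inferred
        assert c.n_common <= min(c.n_asserted, c.n_inferred)


class TestSummarize:
    def test_single_identical_drug(self):
        rows = [DrugComparison("d", FS({"e"}), FS({"e"}), "identical")]
        s = summarize(rows)
        assert s.counts["identical"] == 1 and s.total == 1
        assert s.percentages()["identical"] == 100.00

    def test_empty_input(self):
        s = summarize([], perspective="drug")
        assert s.total == 0 and all(v == 0 for v in s.counts.values())
        assert all(v == 0.0 for v in s.percentages().values())

    def test_percentages_sum_to_100(self):
        rng = random.Random(41)
        rows = [
            DrugComparison(f"d{i}", FS({"e"}), FS({"e"}),
                           rng.choice(DRUG_CATEGORIES))
            for i in range(97)
        ]
        s = summarize(rows)
        assert abs(sum(s.percentages().values()) - 100.0) < 0.05


class TestAblation:
    def test_citalopram_category_flip(self, examples):
        """With therapeutic intent the drug gains an inferred mood-stabilizer
        class beyond the asserted reuptake-inhibitor class."""
        result = run_ablation(examples["citalopram"].kb)
        assert result.baseline.drugs.counts["identical"] == 1
        assert result.enhanced.drugs.counts["additional_inferred"] == 1
        assert result.drug_deltas["identical"] == -1
        assert result.drug_deltas["additional_inferred"] == 1

    def test_no_therapeutic_definitions_zero_deltas(self, examples):
        result = run_ablation(examples["bupropion"].kb)
        assert all(v == 0 for v in result.drug_deltas.values())
        assert all(v == 0 for v in result.class_deltas.values())

    def test_removing_roles_never_adds_inferences_strict(self, examples):
        """Ablation monotonicity under strict folding: keeping the full
        conjunct set in the baseline means dropping the therapeutic-intent
        families can only remove inferences, never add them."""
        for name, case in examples.items():
            base = audit_kb(case.kb, use_therapeutic_intent=False,
                            strict_fold=True)
            enh = audit_kb(case.kb, use_therapeutic_intent=True,
                           strict_fold=True)
            base_pairs = {(m.drug, m.epc) for m in base.inferred}
            enh_pairs = {(m.drug, m.epc) for m in enh.inferred}
            assert base_pairs <= enh_pairs, name

    def test_drop_conjunct_baseline_can_overgeneralize(self, examples):
        """Under the default drop-conjunct folding the baseline *weakens*
        definitions that mix structural and therapeutic conjuncts, so it
        may infer pairs the enhanced run rejects — the granularity-mismatch
        class is inferred for the aminoglycoside drug only in the
        baseline. This is why strict mode exists."""
        case = examples["amikacin"]
        base = audit_kb(case.kb, use_therapeutic_intent=False)
        enh = audit_kb(case.kb, use_therapeutic_intent=True)
        base_pairs = {(m.drug, m.epc) for m in base.inferred}
        enh_pairs = {(m.drug, m.epc) for m in enh.inferred}
        assert ("amikacin", "EPC_ag_antibacterial") in base_pairs
        assert ("amikacin", "EPC_ag_antibacterial") not in enh_pairs

    def test_drug_totals_may_differ(self, examples):
        """A drug classifiable only through may_treat drops out of the
        baseline drug table entirely."""
        result = run_ablation(examples["isosorbide"].kb)
        assert result.baseline.drugs.total == 0
        assert result.enhanced.drugs.total == 1
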