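"""Structural subsumption: restriction entailment, drug classification,
class-hierarchy inference, diagnoses, and the brute-force oracle check."""

from __future__ import annotations

import random

import pytest

from epcaudit import (
    classify_all,
    classify_drug,
    diagnose,
    enrich,
    entails_restriction,
    infer_epc_hierarchy,
    make_kb,
)
from epcaudit.classifier import REASON_FILLER, REASON_NO_ROLE
from epcaudit.kb import PropertyAssertion, Restriction

from _oracle import brute_classify_all, random_kb


class TestEntailsRestriction:
    def test_equivalent_role_exact_filler(self, albuterol_enriched):
        ok, reason, witness = entails_restriction(
            "N0000147099", Restriction("has_MoA_FMTSME", "MoA_beta2"),
            albuterol_enriched,
        )
        assert ok
        assert witness == PropertyAssertion(
            "N0000147099", "has_MoA_FDASPL", "MoA_beta2"
        )

    def test_filler_subsumption(self):
        """A venous-dilation property satisfies a vasodilation restriction
        because the fillers are hierarchically related."""
        kb = enrich(make_kb(
            concepts=[
                ("ROOT", "r", "root"),
                ("alprostadil", "Alprostadil", "drug"),
                ("PE_venous", "Venous dilation", "filler"),
                ("PE_vaso", "Vasodilation", "filler"),
            ],
            edges=[("PE_venous", "PE_vaso")],
            roles=[("has_PE_FDASPL", "PE", "FDASPL"),
                   ("has_PE_FMTSME", "PE", "FMTSME")],
            assertions=[("alprostadil", "has_PE_FDASPL", "PE_venous")],
        ))
        ok, _, witness = entails_restriction(
            "alprostadil", Restriction("has_PE_FMTSME", "PE_vaso"), kb
        )
        assert ok and witness.filler == "PE_venous"

    def test_missing_role_reason(self, examples):
        kb = enrich(examples["ofloxacin"].kb)
        ok, reason, witness = entails_restriction(
            "ofloxacin", Restriction("may_prevent_FMTSME", "DIS_infectious"), kb
        )
        assert not ok and reason == REASON_NO_ROLE and witness is None

    def test_filler_mismatch_reason(self):
        kb = enrich(make_kb(
            concepts=[("ROOT", "r", "root"), ("d", "d", "drug"),
                      ("f1", "f1", "filler"), ("f2", "f2", "filler")],
            roles=[("has_MoA_FDASPL", "MoA", "FDASPL"),
                   ("has_MoA_FMTSME", "MoA", "FMTSME")],
            assertions=[("d", "has_MoA_FDASPL", "f1")],
        ))
        ok, reason, _ = entails_restriction(
            "d", Restriction("has_MoA_FMTSME", "f2"), kb
        )
        assert not ok and reason == REASON_FILLER

    def test_drug_without_assertions_fails(self, examples):
        kb = enrich(examples["lurasidone"].kb)
        ok, reason, _ = entails_restriction(
            "lurasidone", Restriction("may_treat_FMTSME", "DIS_schizo"), kb
        )
        assert not ok and reason == REASON_NO_ROLE


class TestClassHierarchy:
    def test_more_specific_filler_gives_subclass(self, albuterol_enriched):
        h = infer_epc_hierarchy(albuterol_enriched)
        assert ("N0000175779", "N0000175555") in h.hierarchy.edges
        assert h.related("N0000175779", "N0000175555")

    def test_conjunct_superset_gives_subclass(self):
        """A class requiring ingredient+indication is subsumed by one
        requiring the indication alone (penicillin antibacterial under
        antiseptic)."""
        kb = enrich(make_kb(
            concepts=[
                ("ROOT", "r", "root"),
                ("E_pen", "Penicillin antibacterial", "epc"),
                ("E_anti", "Antiseptic", "epc"),
                ("F_pen", "Penicillin", "filler"),
                ("F_bact", "Bacterial infection", "filler"),
            ],
            roles=[("has_Chemical_Structure_FMTSME", "ChemStructure", "FMTSME"),
                   ("may_treat_FMTSME", "may_treat", "FMTSME")],
            definitions=[
                ("E_pen", "ROOT",
                 [("has_Chemical_Structure_FMTSME", "F_pen"),
                  ("may_treat_FMTSME", "F_bact")], "primitive"),
                ("E_anti", "ROOT", [("may_treat_FMTSME", "F_bact")], "primitive"),
            ],
        ))
        h = infer_epc_hierarchy(kb)
        assert ("E_pen", "E_anti") in h.hierarchy.edges
        assert ("E_anti", "E_pen") not in h.hierarchy.edges

    def test_identical_definitions_form_equivalence_group(self):
        kb = enrich(make_kb(
            concepts=[("ROOT", "r", "root"), ("E1", "e1", "epc"),
                      ("E2", "e2", "epc"), ("f", "f", "filler")],
            roles=[("has_MoA_FMTSME", "MoA", "FMTSME")],
            definitions=[
                ("E1", "ROOT", [("has_MoA_FMTSME", "f")], "primitive"),
                ("E2", "ROOT", [("has_MoA_FMTSME", "f")], "primitive"),
            ],
        ))
        h = infer_epc_hierarchy(kb)
        assert h.equivalence_groups == (frozenset({"E1", "E2"}),)
        assert h.hierarchy.edges == frozenset()  # no strict edge
        assert h.related("E1", "E2")


class TestClassifyDrug:
    def test_albuterol_direct_and_indirect(self, albuterol_enriched):
        all_epcs, direct = classify_drug("N0000147099", albuterol_enriched)
        assert all_epcs == {"N0000175779", "N0000175555"}
        assert direct == {"N0000175779"}

    def test_drug_without_assertions_empty(self, examples):
        kb = enrich(examples["lurasidone"].kb)
        assert classify_drug("lurasidone", kb) == (frozenset(), frozenset())

    def test_classify_all_rows(self, albuterol_enriched):
        rows = classify_all(albuterol_enriched)
        assert [(m.epc, m.directness) for m in rows] == [
            ("N0000175555", "indirect"), ("N0000175779", "direct"),
        ]

    def test_rerun_identical(self, albuterol_enriched):
        assert classify_all(albuterol_enriched) == classify_all(albuterol_enriched)

    @pytest.mark.parametrize("seed", range(40))
    def test_matches_bruteforce_oracle(self, seed):
        """Full classification equals exhaustive enumeration on random
        KBs with random role blocks and filler DAGs."""
        kb = random_kb(random.Random(seed))
        assert classify_all(kb) == brute_classify_all(kb)


class TestInvariants:
    def test_monotone_under_assertion_addition(self):
        rng = random.Random(11)
        for _ in range(20):
            kb = random_kb(rng)
            before = set(classify_all(kb))
            drug = rng.choice(kb.drugs())
            role = rng.choice(sorted(kb.roles))
            filler = rng.choice(
                sorted(c.id for c in kb.concepts.values() if c.kind == "filler")
            )
            bigger = kb.replace(
                assertions=kb.assertions | {PropertyAssertion(drug, role, filler)}
            )
            after = set(classify_all(bigger))
            # memberships never disappear (directness may shift)
            assert {(m.drug, m.epc) for m in before} <= {(m.drug, m.epc) for m in after}

    def test_monotone_under_assertion_removal(self):
        rng = random.Random(13)
        for _ in range(20):
            kb = random_kb(rng)
            if not kb.assertions:
                continue
            before = {(m.drug, m.epc) for m in classify_all(kb)}
            victim = rng.choice(sorted(kb.assertions))
            smaller = kb.replace(assertions=kb.assertions - {victim})
            after = {(m.drug, m.epc) for m in classify_all(smaller)}
            assert after <= before

    def test_hierarchy_coherence_and_direct_expansion(self):
        """If a drug is in C and C ⊑ D then the drug is in D; expanding the
        direct memberships through the class hierarchy recovers all."""
        rng = random.Random(17)
        for _ in range(25):
            kb = random_kb(rng)
            h = infer_epc_hierarchy(kb)
            rows = classify_all(kb, h)
            all_pairs = {(m.drug, m.epc) for m in rows}
            for m in rows:
                for up in h.ancestors(m.epc):
                    assert (m.drug, up) in all_pairs
            expanded = set()
            for m in rows:
                if m.directness == "direct":
                    expanded.add((m.drug, m.epc))
                    expanded.update((m.drug, up) for up in h.ancestors(m.epc))
            assert expanded == all_pairs


class TestDiagnose:
    def test_ofloxacin_names_missing_prevention(self, examples):
        kb = enrich(examples["ofloxacin"].kb)
        diag = diagnose("ofloxacin", "EPC_quinolone", kb)
        assert not diag.entailed
        by_role = {r.restriction.role: r for r in diag.records}
        assert by_role["may_treat_FMTSME"].status == "matched"
        assert by_role["may_treat_FMTSME"].witness.filler == "DIS_klebsiella"
        assert by_role["may_prevent_FMTSME"].status == "unmatched"
        assert by_role["may_prevent_FMTSME"].reason == REASON_NO_ROLE

    def test_ipilimumab_partial_match(self, examples):
        kb = enrich(examples["ipilimumab"].kb)
        diag = diagnose("ipilimumab", "EPC_ctla4", kb)
        assert not diag.entailed
        matched = [r for r in diag.records if r.status == "matched"]
        unmatched = [r for r in diag.records if r.status == "unmatched"]
        assert {r.restriction.role for r in matched} == {"has_MoA_FMTSME"}
        assert len(unmatched) == 2
        assert all(r.restriction.role == "has_PE_FMTSME" for r in unmatched)

    def test_lurasidone_all_unmatched(self, examples):
        kb = enrich(examples["lurasidone"].kb)
        diag = diagnose("lurasidone", "EPC_atypical", kb)
        assert not diag.entailed
        assert all(
            r.status == "unmatched" and r.reason == REASON_NO_ROLE
            for r in diag.records
        )

    def test_primitive_class_marker(self, examples):
        diag = diagnose("lurasidone", "EPC_atypical", examples["lurasidone"].kb)
        assert diag.primitive and diag.records == ()

    def test_consistent_with_classification(self):
        rng = random.Random(23)
        for _ in range(15):
            kb = random_kb(rng)
            inferred = {(m.drug, m.epc) for m in classify_all(kb)}
            for drug in kb.drugs():
                for epc in kb.defined_epcs():
                    assert diagnose(drug, epc, kb).entailed == (
                        (drug, epc) in inferred
                    )
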