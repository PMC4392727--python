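"""Hand-encoded worked examples, one tiny KB per classic audit situation.

Each case encodes a well-known drug/class configuration from the NDF-RT
world — the beta2-agonist albuterol, the quinolone ofloxacin whose
description lacks a may_prevent property, the under-described lurasidone
and ipilimumab, the granularity mismatch around amikacin, and so on —
together with the outcome the audit is expected to produce. The KBs are
un-enriched (primitive class definitions, no role equivalences): run
them through the enrichment/classification pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .kb import KnowledgeBase, make_kb

__all__ = ["ExampleCase", "worked_examples"]

_ROOT = ("N_ROOT", "Pharmaceutical Preparations", "root")

_ROLES = {
    "moa": [("has_MoA_FMTSME", "MoA", "FMTSME"), ("has_MoA_FDASPL", "MoA", "FDASPL")],
    "pe": [("has_PE_FMTSME", "PE", "FMTSME"), ("has_PE_FDASPL", "PE", "FDASPL")],
    "chem": [
        ("has_Chemical_Structure_FMTSME", "ChemStructure", "FMTSME"),
        ("has_Chemical_Structure_FDASPL", "ChemStructure", "FDASPL"),
    ],
    "treat": [("may_treat_FMTSME", "may_treat", "FMTSME"), ("may_treat_NDFRT", "may_treat", "NDFRT")],
    "prevent": [("may_prevent_FMTSME", "may_prevent", "FMTSME"), ("may_prevent_NDFRT", "may_prevent", "NDFRT")],
}


def _roles(*keys: str) -> list[tuple[str, str, str]]:
    out: list[tuple[str, str, str]] = []
    for k in keys:
        out.extend(_ROLES[k])
    return out


@dataclass(frozen=True)
class ExampleCase:
    name: str
    kb: KnowledgeBase
    expected: dict[str, Any] = field(default_factory=dict)
    description: str = ""


def worked_examples() -> dict[str, ExampleCase]:
    """All named example KBs, keyed by drug name."""
    cases = [
        _albuterol(),
        _ofloxacin(),
        _lurasidone(),
        _ipilimumab(),
        _imatinib(),
        _losartan(),
        _bupropion(),
        _isosorbide(),
        _amikacin(),
        _citalopram(),
    ]
    return {c.name: c for c in cases}


def _albuterol() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("N0000147099", "albuterol", "drug"),
            ("N0000175779", "beta2-Adrenergic Agonist [EPC]", "epc"),
            ("N0000175555", "beta-Adrenergic Agonist [EPC]", "epc"),
            ("MoA_beta2", "Adrenergic beta2-Agonists [MoA]", "filler"),
            ("MoA_beta", "Adrenergic beta-Agonists [MoA]", "filler"),
        ],
        edges=[("MoA_beta2", "MoA_beta")],
        roles=_roles("moa"),
        assertions=[("N0000147099", "has_MoA_FDASPL", "MoA_beta2")],
        definitions=[
            ("N0000175779", "N_ROOT", [("has_MoA_FMTSME", "MoA_beta2")], "primitive"),
            ("N0000175555", "N_ROOT", [("has_MoA_FMTSME", "MoA_beta")], "primitive"),
        ],
        memberships=[("N0000147099", "N0000175779")],
    )
    return ExampleCase(
        "albuterol", kb,
        expected={
            "drug": "N0000147099",
            "all": {"N0000175779", "N0000175555"},
            "direct": {"N0000175779"},
            "epc_edges": {("N0000175779", "N0000175555")},
            "category": "identical",
        },
        description="beta2-agonist: direct member of the beta2 class, "
                    "indirect member of the beta class via the inferred "
                    "class-hierarchy edge",
    )


def _ofloxacin() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("ofloxacin", "ofloxacin", "drug"),
            ("EPC_quinolone", "Quinolone Antimicrobial [EPC]", "epc"),
            ("DIS_infectious", "Infectious Diseases", "filler"),
            ("DIS_klebsiella", "Klebsiella Infections", "filler"),
        ],
        edges=[("DIS_klebsiella", "DIS_infectious")],
        roles=_roles("treat", "prevent"),
        assertions=[("ofloxacin", "may_treat_NDFRT", "DIS_klebsiella")],
        definitions=[
            ("EPC_quinolone", "N_ROOT",
             [("may_treat_FMTSME", "DIS_infectious"),
              ("may_prevent_FMTSME", "DIS_infectious")], "primitive"),
        ],
        memberships=[("ofloxacin", "EPC_quinolone")],
    )
    return ExampleCase(
        "ofloxacin", kb,
        expected={
            "drug": "ofloxacin",
            "epc": "EPC_quinolone",
            "all": set(),
            "category": "asserted_only",
            "matched_roles": {"may_treat_FMTSME"},
            "unmatched_roles": {"may_prevent_FMTSME"},
            "witness_filler": "DIS_klebsiella",
        },
        description="the drug description covers treatment but not "
                    "prevention, so the two-conjunct class is not inferred",
    )


def _lurasidone() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("lurasidone", "lurasidone", "drug"),
            ("EPC_atypical", "Atypical Antipsychotic [EPC]", "epc"),
            ("DIS_schizo", "Schizophrenia and Disorders with Psychotic Features", "filler"),
        ],
        roles=_roles("treat"),
        definitions=[
            ("EPC_atypical", "N_ROOT",
             [("may_treat_FMTSME", "DIS_schizo")], "primitive"),
        ],
        memberships=[("lurasidone", "EPC_atypical")],
    )
    return ExampleCase(
        "lurasidone", kb,
        expected={
            "drug": "lurasidone",
            "epc": "EPC_atypical",
            "all": set(),
            "category": "asserted_only",
            "unmatched_roles": {"may_treat_FMTSME"},
        },
        description="no drug property asserted at all: every conjunct "
                    "fails with no equivalent-role property",
    )


def _ipilimumab() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("ipilimumab", "ipilimumab", "drug"),
            ("EPC_ctla4", "CTLA-4-directed Blocking Antibody [EPC]", "epc"),
            ("MoA_ctla4", "CTLA-4-directed Antibody Interactions", "filler"),
            ("PE_immuno", "Increased Immunologic Activity", "filler"),
            ("PE_tcell", "Increased T Lymphocyte Activation", "filler"),
        ],
        roles=_roles("moa", "pe"),
        assertions=[("ipilimumab", "has_MoA_FDASPL", "MoA_ctla4")],
        definitions=[
            ("EPC_ctla4", "N_ROOT",
             [("has_MoA_FMTSME", "MoA_ctla4"),
              ("has_PE_FMTSME", "PE_immuno"),
              ("has_PE_FMTSME", "PE_tcell")], "primitive"),
        ],
        memberships=[("ipilimumab", "EPC_ctla4")],
    )
    return ExampleCase(
        "ipilimumab", kb,
        expected={
            "drug": "ipilimumab",
            "epc": "EPC_ctla4",
            "all": set(),
            "category": "asserted_only",
            "matched_roles": {"has_MoA_FMTSME"},
            "unmatched_roles": {"has_PE_FMTSME"},
            "n_unmatched": 2,
        },
        description="under-specified drug: mechanism of action matches but "
                    "the two physiologic-effect conjuncts do not",
    )


def _imatinib() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("imatinib", "imatinib", "drug"),
            ("EPC_kinase", "Kinase Inhibitor [EPC]", "epc"),
            ("MoA_pki", "Protein Kinase Inhibitors [MoA]", "filler"),
        ],
        roles=_roles("moa"),
        assertions=[("imatinib", "has_MoA_FDASPL", "MoA_pki")],
        definitions=[
            ("EPC_kinase", "N_ROOT", [("has_MoA_FMTSME", "MoA_pki")], "primitive"),
        ],
        memberships=[("imatinib", "EPC_kinase")],
    )
    return ExampleCase(
        "imatinib", kb,
        expected={"drug": "imatinib", "direct": {"EPC_kinase"}, "category": "identical"},
        description="same single class asserted and inferred",
    )


def _losartan() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("losartan", "losartan", "drug"),
            ("EPC_arb", "Angiotensin 2 Receptor Blocker [EPC]", "epc"),
            ("MoA_at2", "Angiotensin 2 Receptor Antagonists [MoA]", "filler"),
        ],
        roles=_roles("moa"),
        definitions=[
            ("EPC_arb", "N_ROOT", [("has_MoA_FMTSME", "MoA_at2")], "primitive"),
        ],
        memberships=[("losartan", "EPC_arb")],
    )
    return ExampleCase(
        "losartan", kb,
        expected={"drug": "losartan", "all": set(), "category": "asserted_only"},
        description="asserted class with no inferable counterpart",
    )


def _bupropion() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("bupropion", "bupropion", "drug"),
            ("EPC_aminoketone", "Aminoketone [EPC]", "epc"),
            ("EPC_nri", "Norepinephrine Reuptake Inhibitor [EPC]", "epc"),
            ("CHEM_aminoketone", "Aminoketones [Chemical/Ingredient]", "filler"),
            ("MoA_ne_uptake", "Norepinephrine Uptake Inhibitors [MoA]", "filler"),
        ],
        roles=_roles("moa", "chem"),
        assertions=[
            ("bupropion", "has_Chemical_Structure_FDASPL", "CHEM_aminoketone"),
            ("bupropion", "has_MoA_FDASPL", "MoA_ne_uptake"),
        ],
        definitions=[
            ("EPC_aminoketone", "N_ROOT",
             [("has_Chemical_Structure_FMTSME", "CHEM_aminoketone")], "primitive"),
            ("EPC_nri", "N_ROOT",
             [("has_MoA_FMTSME", "MoA_ne_uptake")], "primitive"),
        ],
        memberships=[("bupropion", "EPC_aminoketone")],
    )
    return ExampleCase(
        "bupropion", kb,
        expected={
            "drug": "bupropion",
            "direct": {"EPC_aminoketone", "EPC_nri"},
            "category": "additional_inferred",
        },
        description="mechanism of action yields an inferred class the "
                    "asserted set lacks — a candidate missing assertion",
    )


def _isosorbide() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("isosorbide", "isosorbide", "drug"),
            ("EPC_antianginal", "Anti-anginal [EPC]", "epc"),
            ("DIS_angina", "Angina Pectoris", "filler"),
        ],
        roles=_roles("treat"),
        assertions=[("isosorbide", "may_treat_NDFRT", "DIS_angina")],
        definitions=[
            ("EPC_antianginal", "N_ROOT",
             [("may_treat_FMTSME", "DIS_angina")], "primitive"),
        ],
        memberships=[],
    )
    return ExampleCase(
        "isosorbide", kb,
        expected={
            "drug": "isosorbide",
            "direct": {"EPC_antianginal"},
            "category": "inferred_only",
        },
        description="correct inference with no asserted class at all",
    )


def _amikacin() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("amikacin", "amikacin", "drug"),
            ("EPC_ag_antibacterial", "Aminoglycoside Antibacterial [EPC]", "epc"),
            ("EPC_aminoglycoside", "Aminoglycoside [EPC]", "epc"),
            ("CHEM_ag", "Aminoglycosides [Chemical/Ingredient]", "filler"),
            ("DIS_bacterial", "Bacterial Infections", "filler"),
        ],
        roles=_roles("chem", "treat", "prevent"),
        assertions=[
            ("amikacin", "has_Chemical_Structure_FDASPL", "CHEM_ag"),
            ("amikacin", "may_treat_NDFRT", "DIS_bacterial"),
        ],
        definitions=[
            ("EPC_ag_antibacterial", "N_ROOT",
             [("has_Chemical_Structure_FMTSME", "CHEM_ag"),
              ("may_treat_FMTSME", "DIS_bacterial"),
              ("may_prevent_FMTSME", "DIS_bacterial")], "primitive"),
            ("EPC_aminoglycoside", "N_ROOT",
             [("has_Chemical_Structure_FMTSME", "CHEM_ag"),
              ("may_treat_FMTSME", "DIS_bacterial")], "primitive"),
        ],
        memberships=[("amikacin", "EPC_ag_antibacterial")],
    )
    return ExampleCase(
        "amikacin", kb,
        expected={
            "drug": "amikacin",
            "direct": {"EPC_aminoglycoside"},
            "epc_edges": {("EPC_ag_antibacterial", "EPC_aminoglycoside")},
            "category": "compatible",
        },
        description="granularity mismatch: asserted class is a strict "
                    "subclass of the inferred one (asserted more specific)",
    )


def _citalopram() -> ExampleCase:
    kb = make_kb(
        concepts=[
            _ROOT,
            ("citalopram", "citalopram", "drug"),
            ("EPC_ssri", "Serotonin Reuptake Inhibitor [EPC]", "epc"),
            ("EPC_moodstab", "Mood Stabilizer [EPC]", "epc"),
            ("MoA_serotonin", "Serotonin Uptake Inhibitors [MoA]", "filler"),
            ("DIS_bipolar", "Bipolar Disorder", "filler"),
        ],
        roles=_roles("moa", "treat"),
        assertions=[
            ("citalopram", "has_MoA_FDASPL", "MoA_serotonin"),
            ("citalopram", "may_treat_NDFRT", "DIS_bipolar"),
        ],
        definitions=[
            ("EPC_ssri", "N_ROOT", [("has_MoA_FMTSME", "MoA_serotonin")], "primitive"),
            ("EPC_moodstab", "N_ROOT",
             [("may_treat_FMTSME", "DIS_bipolar")], "primitive"),
        ],
        memberships=[("citalopram", "EPC_ssri")],
    )
    return ExampleCase(
        "citalopram", kb,
        expected={
            "drug": "citalopram",
            "baseline_category": "identical",
            "enhanced_category": "additional_inferred",
        },
        description="therapeutic intent flips the category: without "
                    "may_treat the inferred set equals the asserted set; "
                    "with it, an extra class is inferred",
    )
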