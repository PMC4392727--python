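"""Synthetic NDF-RT-like knowledge bases with known ground truth.

The generator emulates the structure of a drug terminology: one filler
vocabulary tree per role family (mechanism of action, physiologic
effect, chemical structure, may_treat, may_prevent), pharmacologic
classes described by 1–3 existential restrictions over those trees using
class-side FMTSME roles, and drugs whose drug-side (FDASPL/NDFRT)
assertions exactly satisfy one class, with the matching membership
asserted. Controlled discrepancies of each kind the audit must detect
are then injected per drug:

* ``drop_property`` — delete a needed drug property, so the asserted
  class can no longer be inferred (an under-described drug);
* ``prevent_asymmetry`` — delete only the drug's may_prevent property
  while the class definition requires both therapeutic-intent conjuncts
  (the quinolone pattern: treatment described, prevention not);
* ``drop_asserted`` — delete the asserted membership while the inference
  still succeeds (a missing authoritative relation);
* ``coarsen_definition`` — move the asserted membership to a newly
  created, more specific subclass while the drug's properties match the
  broader class (granularity mismatch: asserted more specific than
  inferred);
* ``extra_property`` — add properties satisfying a second, unrelated
  class (an inferred relation with no asserted counterpart).

With ``ensure_independent_injections`` each class owns disjoint filler
subtrees and each drug receives at most one injection, so the audit
category of every drug is exactly predictable.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .comparison import (
    AuditSummary,
    CLASS_CATEGORIES,
    DRUG_CATEGORIES,
    OverlapCounts,
    PerspectiveSummary,
)
from .kb import (
    KnowledgeBase,
    Membership,
    PropertyAssertion,
    ROLE_FAMILIES,
    Restriction,
    make_kb,
)

__all__ = [
    "INJECTION_TYPES",
    "SyntheticSpec",
    "DrugTruth",
    "GroundTruth",
    "InfeasibleSpecError",
    "generate_kb",
    "expected_summary",
]

ROOT_ID = "N_ROOT"
ROOT_LABEL = "Pharmaceutical Preparations"

#: class-side and drug-side role ids per family, NDF-RT naming
CLASS_ROLE = {
    "MoA": "has_MoA_FMTSME",
    "PE": "has_PE_FMTSME",
    "ChemStructure": "has_Chemical_Structure_FMTSME",
    "may_treat": "may_treat_FMTSME",
    "may_prevent": "may_prevent_FMTSME",
}
DRUG_ROLE = {
    "MoA": ("has_MoA_FDASPL", "FDASPL"),
    "PE": ("has_PE_FDASPL", "FDASPL"),
    "ChemStructure": ("has_Chemical_Structure_FDASPL", "FDASPL"),
    "may_treat": ("may_treat_NDFRT", "NDFRT"),
    "may_prevent": ("may_prevent_NDFRT", "NDFRT"),
}

INJECTION_TYPES = (
    "drop_property",
    "prevent_asymmetry",
    "drop_asserted",
    "coarsen_definition",
    "extra_property",
)


class InfeasibleSpecError(ValueError):
    """The requested shape cannot be generated (e.g. more classes than
    disjoint filler subtrees, or an injection with no eligible class)."""


@dataclass(frozen=True)
class SyntheticSpec:
    """Shape and injection rates for one generated KB.

    ``tree_depth`` levels below each family root with ``tree_branching``
    children per node; the root's children are the subtree anchors
    handed out to classes. Injection rates are per drug; with
    ``ensure_independent_injections`` they are drawn as one categorical
    (their sum must be ≤ 1) and filler subtrees are disjoint across
    classes.
    """

    seed: int = 0
    tree_depth: int = 2
    tree_branching: int = 4
    n_epcs: int = 6
    min_restrictions: int = 1
    max_restrictions: int = 3
    n_drugs: int = 30
    p_drop_property: float = 0.0
    p_prevent_asymmetry: float = 0.0
    p_drop_asserted: float = 0.0
    p_coarsen_definition: float = 0.0
    p_extra_property: float = 0.0
    ensure_independent_injections: bool = True

    def rates(self) -> dict[str, float]:
        return {
            "drop_property": self.p_drop_property,
            "prevent_asymmetry": self.p_prevent_asymmetry,
            "drop_asserted": self.p_drop_asserted,
            "coarsen_definition": self.p_coarsen_definition,
            "extra_property": self.p_extra_property,
        }

    def __post_init__(self) -> None:
        for name, p in self.rates().items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"rate {name}={p} outside [0, 1]")
        if self.ensure_independent_injections and sum(self.rates().values()) > 1.0 + 1e-12:
            raise ValueError("injection rates must sum to <= 1 for independent injections")
        if self.tree_depth < 2:
            raise ValueError("tree_depth must be >= 2 so anchors have children")
        if not 1 <= self.min_restrictions <= self.max_restrictions <= len(ROLE_FAMILIES):
            raise ValueError("invalid restrictions-per-class range")


@dataclass(frozen=True)
class DrugTruth:
    drug: str
    injection: str  # "none" or one of INJECTION_TYPES
    category: str | None  # None when the drug relates to no class at all
    asserted: frozenset[str]
    inferred_direct: frozenset[str]


@dataclass(frozen=True)
class GroundTruth:
    """Per-drug intended outcomes plus the intended class hierarchy, from
    which the expected audit tables are derived independently of the
    classifier."""

    drugs: dict[str, DrugTruth]
    epc_edges: frozenset[tuple[str, str]]  # (subclass, superclass)
    epcs: frozenset[str]

    def asserted_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (t.drug, e) for t in self.drugs.values() for e in t.asserted
        )

    def inferred_pairs(self) -> frozenset[tuple[str, str]]:
        return frozenset(
            (t.drug, e) for t in self.drugs.values() for e in t.inferred_direct
        )


def _categorize(
    A: frozenset[str], I: frozenset[str], edges: frozenset[tuple[str, str]]
) -> str | None:
    """Minimal re-statement of the drug decision tree over the intended
    one-level class hierarchy (oracle bookkeeping)."""
    def related(x: str, y: str) -> bool:
        return (x, y) in edges or (y, x) in edges

    if not A and not I:
        return None
    if not I:
        return "asserted_only"
    if not A:
        return "inferred_only"
    if A == I:
        return "identical"
    um_a = {a for a in A if not any(a == b or related(a, b) for b in I)}
    um_i = {i for i in I if not any(i == b or related(i, b) for b in A)}
    if not um_a and not um_i:
        return "compatible"
    if um_a and not um_i:
        return "additional_asserted"
    if um_i and not um_a:
        return "additional_inferred"
    return "additional_both"


def generate_kb(spec: SyntheticSpec) -> tuple[KnowledgeBase, GroundTruth]:
    """Build one KB and its ground truth; deterministic given the seed."""
    rng = random.Random(spec.seed)

    concepts: list[tuple[str, str, str]] = [(ROOT_ID, ROOT_LABEL, "root")]
    edges: list[tuple[str, str]] = []
    roles = [(CLASS_ROLE[f], f, "FMTSME") for f in ROLE_FAMILIES]
    roles += [(DRUG_ROLE[f][0], f, DRUG_ROLE[f][1]) for f in ROLE_FAMILIES]

    # one filler tree per family; anchors are the root's children
    anchors: dict[str, list[str]] = {}
    children_of: dict[str, list[str]] = {}
    for fam in ROLE_FAMILIES:
        froot = f"F:{fam}"
        concepts.append((froot, f"{fam} vocabulary", "filler"))
        level = [froot]
        for depth in range(1, spec.tree_depth + 1):
            nxt = []
            for node in level:
                for i in range(spec.tree_branching):
                    child = f"{node}.{i}"
                    concepts.append((child, child, "filler"))
                    edges.append((child, node))
                    children_of.setdefault(node, []).append(child)
                    nxt.append(child)
            level = nxt
        anchors[fam] = list(children_of[froot])

    free_anchors = {f: list(a) for f, a in anchors.items()}

    def take_anchor(fam: str) -> str:
        pool = free_anchors[fam] if spec.ensure_independent_injections else anchors[fam]
        if not pool:
            raise InfeasibleSpecError(
                f"no disjoint filler subtree left in family {fam}; "
                "increase tree_branching or reduce n_epcs/restrictions"
            )
        pick = rng.choice(sorted(pool))
        if spec.ensure_independent_injections:
            free_anchors[fam].remove(pick)
        return pick

    if spec.p_extra_property > 0 and spec.n_epcs < 2:
        raise InfeasibleSpecError("extra_property injection needs >= 2 classes")

    epc_defs: dict[str, list[Restriction]] = {}
    definitions: list[tuple[str, str, list[tuple[str, str]], str]] = []
    for i in range(spec.n_epcs):
        epc = f"EPC{i:04d}"
        k = rng.randint(spec.min_restrictions, spec.max_restrictions)
        if i == 0 and spec.p_prevent_asymmetry > 0:
            fams = ["may_treat", "may_prevent"]
            others = [f for f in ROLE_FAMILIES if f not in fams]
            extra_n = max(k - 2, 0)
            fams += rng.sample(others, min(extra_n, len(others)))
        else:
            avail = [
                f for f in ROLE_FAMILIES
                if not spec.ensure_independent_injections or free_anchors[f]
            ]
            if len(avail) < k:
                raise InfeasibleSpecError(
                    f"class {epc} needs {k} families but only {len(avail)} "
                    "have free filler subtrees"
                )
            fams = rng.sample(sorted(avail), k)
        restrictions = [
            Restriction(CLASS_ROLE[f], take_anchor(f)) for f in sorted(fams)
        ]
        concepts.append((epc, f"class {i}", "epc"))
        epc_defs[epc] = restrictions
        definitions.append(
            (epc, ROOT_ID, [(r.role, r.filler) for r in restrictions], "primitive")
        )
    base_epcs = sorted(epc_defs)

    prevent_epcs = sorted(
        e for e, rs in epc_defs.items()
        if any(r.role == CLASS_ROLE["may_prevent"] for r in rs)
    )
    if spec.p_prevent_asymmetry > 0 and not prevent_epcs:
        raise InfeasibleSpecError("prevent_asymmetry needs a class using may_prevent")

    # specialized subclasses are created lazily, once per base class
    child_epc_of: dict[str, str] = {}
    epc_edges: set[tuple[str, str]] = set()

    def specialized_child(epc: str) -> str:
        if epc in child_epc_of:
            return child_epc_of[epc]
        child = f"{epc}.spec"
        restrictions = [
            Restriction(r.role, rng.choice(sorted(children_of[r.filler])))
            for r in sorted(epc_defs[epc])
        ]
        concepts.append((child, f"specialized {epc}", "epc"))
        epc_defs[child] = restrictions
        definitions.append(
            (child, ROOT_ID, [(r.role, r.filler) for r in restrictions], "primitive")
        )
        child_epc_of[epc] = child
        epc_edges.add((child, epc))
        return child

    def draw_injection() -> list[str]:
        rates = spec.rates()
        if spec.ensure_independent_injections:
            u = rng.random()
            cum = 0.0
            for t in INJECTION_TYPES:
                cum += rates[t]
                if u < cum:
                    return [t]
            return []
        return [t for t in INJECTION_TYPES if rng.random() < rates[t]]

    assertions: set[tuple[str, str, str]] = set()
    memberships: set[tuple[str, str]] = set()
    truths: dict[str, DrugTruth] = {}

    for j in range(spec.n_drugs):
        drug = f"D{j:05d}"
        concepts.append((drug, f"drug {j}", "drug"))
        injections = draw_injection()
        if "prevent_asymmetry" in injections:
            epc = rng.choice(prevent_epcs)
        else:
            epc = rng.choice(base_epcs)

        drug_assertions: set[PropertyAssertion] = set()
        for r in sorted(epc_defs[epc]):
            fam = next(f for f, cr in CLASS_ROLE.items() if cr == r.role)
            filler = r.filler
            if not spec.ensure_independent_injections:
                # occasionally use a more specific filler to exercise
                # filler subsumption
                pool = [filler] + sorted(children_of.get(filler, []))
                filler = rng.choice(pool)
            drug_assertions.add(PropertyAssertion(drug, DRUG_ROLE[fam][0], filler))
        asserted: set[str] = {epc}
        satisfies_own = True

        for inj in injections:
            if inj == "drop_property":
                victim = rng.choice(sorted(drug_assertions))
                drug_assertions.remove(victim)
                satisfies_own = False
            elif inj == "prevent_asymmetry":
                for a in sorted(drug_assertions):
                    if a.role == DRUG_ROLE["may_prevent"][0]:
                        drug_assertions.remove(a)
                satisfies_own = False
            elif inj == "drop_asserted":
                asserted.discard(epc)
            elif inj == "coarsen_definition":
                child = specialized_child(epc)
                asserted.discard(epc)
                asserted.add(child)
            elif inj == "extra_property":
                other = rng.choice([e for e in base_epcs if e != epc])
                for r in sorted(epc_defs[other]):
                    fam = next(f for f, cr in CLASS_ROLE.items() if cr == r.role)
                    drug_assertions.add(
                        PropertyAssertion(drug, DRUG_ROLE[fam][0], r.filler)
                    )

        inferred: set[str] = {epc} if satisfies_own else set()
        for inj in injections:
            if inj == "extra_property":
                inferred = {
                    e for e in epc_defs
                    if _satisfies(drug_assertions, epc_defs[e], children_of)
                }
        if not spec.ensure_independent_injections:
            inferred = {
                e for e in epc_defs
                if _satisfies(drug_assertions, epc_defs[e], children_of)
            }
            # reduce to most specific within the one-level intended hierarchy
            inferred -= {
                parent for (child, parent) in epc_edges if child in inferred
            }

        assertions.update((a.drug, a.role, a.filler) for a in drug_assertions)
        memberships.update((drug, e) for e in sorted(asserted))
        truths[drug] = DrugTruth(
            drug=drug,
            injection=injections[0] if len(injections) == 1 else
            ("none" if not injections else "+".join(injections)),
            category=_categorize(
                frozenset(asserted), frozenset(inferred), frozenset(epc_edges)
            ),
            asserted=frozenset(asserted),
            inferred_direct=frozenset(inferred),
        )

    kb = make_kb(
        concepts=concepts,
        edges=edges,
        roles=roles,
        blocks=None,  # un-harmonized; enrichment installs the blocks
        assertions=sorted(assertions),
        definitions=definitions,
        memberships=sorted(memberships),
    )
    gt = GroundTruth(
        drugs=truths,
        epc_edges=frozenset(epc_edges),
        epcs=frozenset(epc_defs),
    )
    return kb, gt


def _satisfies(
    drug_assertions: set[PropertyAssertion],
    restrictions: list[Restriction],
    children_of: dict[str, list[str]],
) -> bool:
    """Does the assertion set satisfy every restriction? Fillers match
    exactly or one level down (the only depth the generator uses)."""
    fam_of_class_role = {v: k for k, v in CLASS_ROLE.items()}
    for r in restrictions:
        fam = fam_of_class_role[r.role]
        ok_fillers = {r.filler} | set(children_of.get(r.filler, []))
        if not any(
            a.role == DRUG_ROLE[fam][0] and a.filler in ok_fillers
            for a in drug_assertions
        ):
            return False
    return True


def expected_summary(gt: GroundTruth) -> AuditSummary:
    """Audit tables implied by the ground truth alone.

    Drug perspective counts come straight from the per-drug labels; the
    class perspective and overlap counts are recomputed from the intended
    membership pairs and the intended (one-level) class hierarchy.
    """
    drug_counts = {c: 0 for c in DRUG_CATEGORIES}
    n_drugs = 0
    for t in gt.drugs.values():
        if t.category is None:
            continue
        drug_counts[t.category] += 1
        n_drugs += 1

    a_pairs = gt.asserted_pairs()
    i_pairs = gt.inferred_pairs()
    kids: dict[str, set[str]] = {}
    for child, parent in gt.epc_edges:
        kids.setdefault(parent, set()).add(child)

    class_counts = {c: 0 for c in CLASS_CATEGORIES}
    n_classes = 0
    for epc in sorted(gt.epcs):
        scope = {epc} | kids.get(epc, set())
        Ac = frozenset(d for d, e in a_pairs if e in scope)
        Ic = frozenset(d for d, e in i_pairs if e in scope)
        if not Ac and not Ic:
            continue
        n_classes += 1
        if not Ic:
            cat = "asserted_only"
        elif not Ac:
            cat = "inferred_only"
        elif Ac == Ic:
            cat = "identical"
        elif Ic < Ac:
            cat = "additional_asserted"
        elif Ac < Ic:
            cat = "additional_inferred"
        else:
            cat = "additional_both"
        class_counts[cat] += 1

    def expand(pairs: frozenset[tuple[str, str]]) -> frozenset[tuple[str, str]]:
        out = set(pairs)
        parent_of = {c: p for c, p in gt.epc_edges}
        for d, e in pairs:
            if e in parent_of:
                out.add((d, parent_of[e]))
        return frozenset(out)

    ac, ic = expand(a_pairs), expand(i_pairs)
    return AuditSummary(
        drugs=PerspectiveSummary(drug_counts, n_drugs),
        classes=PerspectiveSummary(class_counts, n_classes),
        overlap_direct=OverlapCounts(
            len(a_pairs), len(i_pairs), len(a_pairs & i_pairs)
        ),
        overlap_closed=OverlapCounts(len(ac), len(ic), len(ac & ic)),
    )
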