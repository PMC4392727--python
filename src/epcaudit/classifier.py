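"""Structural subsumption over the EL fragment used by drug terminologies.

The classifier decides drug ⊑ class and class ⊑ class by syntactic
matching of conjuncts: a restriction ∃r.f in a definition is satisfied
by an assertion ∃r'.f' when r' is role-equivalent to r (optionally a
declared sub-role) and f' equals f or is a strict descendant of f in the
filler hierarchy. This is sound and complete for the fragment in play —
conjunctions of existential restrictions over an acyclic filler
hierarchy with role equivalences — without invoking a tableau reasoner.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import networkx as nx

from .kb import (
    Hierarchy,
    KnowledgeBase,
    Membership,
    PropertyAssertion,
    Reachability,
    ReferentialError,
    Restriction,
    minimal_elements,
    transitive_closure,
)

__all__ = [
    "RestrictionRecord",
    "Diagnosis",
    "EpcHierarchy",
    "entails_restriction",
    "infer_epc_hierarchy",
    "classify_drug",
    "classify_all",
    "diagnose",
]

REASON_NONE = "none"
REASON_NO_ROLE = "no_property_with_equivalent_role"
REASON_FILLER = "filler_not_subsumed"


@dataclass(frozen=True, order=True)
class RestrictionRecord:
    restriction: Restriction
    status: str  # "matched" | "unmatched"
    reason: str  # REASON_NONE | REASON_NO_ROLE | REASON_FILLER
    witness: PropertyAssertion | None = None


@dataclass(frozen=True)
class Diagnosis:
    """Restriction-by-restriction account of why a drug is (not) a member.

    For a primitive class no restriction records exist and ``primitive``
    is set: primitive classes admit no inferred members by construction.
    """

    drug: str
    epc: str
    entailed: bool
    records: tuple[RestrictionRecord, ...]
    primitive: bool = False


@dataclass(frozen=True)
class EpcHierarchy:
    """Inferred hierarchy over pharmacologic classes.

    ``hierarchy`` holds strict-subsumption edges (child, parent);
    classes with mutually subsuming (logically equivalent) definitions
    are reported in ``equivalence_groups`` and never merged. Primitive
    classes appear as isolated nodes.
    """

    hierarchy: Hierarchy
    equivalence_groups: tuple[frozenset[str], ...] = ()

    @cached_property
    def reach(self) -> Reachability:
        return transitive_closure(self.hierarchy)

    def group_of(self, epc: str) -> frozenset[str]:
        for g in self.equivalence_groups:
            if epc in g:
                return g
        return frozenset({epc})

    def related(self, a: str, b: str) -> bool:
        """Hierarchically related: reachable in either direction, or in the
        same equivalence group; a class is never related to itself."""
        if a == b:
            return False
        return (
            self.reach.is_descendant(a, b)
            or self.reach.is_descendant(b, a)
            or b in self.group_of(a)
        )

    def ancestors(self, epc: str) -> frozenset[str]:
        """Strict ancestors, including equivalent peers of the class and of
        each ancestor (equivalent definitions subsume one another)."""
        out = set(self.group_of(epc)) - {epc}
        for anc in self.reach.ancestors(epc):
            out |= self.group_of(anc)
        return frozenset(out)

    def descendants(self, epc: str) -> frozenset[str]:
        out = set(self.group_of(epc)) - {epc}
        for d in self.reach.descendants(epc):
            out |= self.group_of(d)
        return frozenset(out)


def _role_matches(
    kb: KnowledgeBase,
    asserted_role: str,
    wanted_role: str,
    subroles: Reachability | None,
) -> bool:
    if kb.role_partition.equivalent(asserted_role, wanted_role):
        return True
    if subroles is not None:
        # declared sub-role reading: the drug's role may be a sub-role of
        # any role equivalent to the one in the definition
        for target in kb.role_partition.block_of(wanted_role):
            if subroles.is_descendant(asserted_role, target):
                return True
    return False


def entails_restriction(
    drug: str,
    r: Restriction,
    kb: KnowledgeBase,
    reach: Reachability | None = None,
    subroles: Reachability | None = None,
) -> tuple[bool, str, PropertyAssertion | None]:
    """Does the drug's description satisfy ∃r.f?

    Returns (entailed, reason, witness). The reason distinguishes a drug
    with no property in the right role block (`no_property_with_equivalent_role`,
    the lurasidone/ofloxacin pattern) from one whose filler is not
    subsumed by the definition's filler (`filler_not_subsumed`).
    """
    if r.role not in kb.roles:
        raise ReferentialError(f"unknown role {r.role}")
    if r.filler not in kb.concepts:
        raise ReferentialError(f"unknown filler {r.filler}")
    if reach is None:
        reach = transitive_closure(kb.hierarchy)
    role_hits = [
        a for a in sorted(kb.assertions)
        if a.drug == drug and _role_matches(kb, a.role, r.role, subroles)
    ]
    if not role_hits:
        return False, REASON_NO_ROLE, None
    for a in role_hits:
        if a.filler == r.filler or reach.is_descendant(a.filler, r.filler):
            return True, REASON_NONE, a
    return False, REASON_FILLER, None


def _definition_subsumes(
    kb: KnowledgeBase,
    sub: frozenset[Restriction],
    sup: frozenset[Restriction],
    reach: Reachability,
    subroles: Reachability | None,
) -> bool:
    """sub ⊑ sup: every conjunct of the broader definition is matched by a
    conjunct of the narrower one (roles up to equivalence, fillers up to
    hierarchy descent)."""
    for want in sup:
        ok = any(
            _role_matches(kb, have.role, want.role, subroles)
            and (
                have.filler == want.filler
                or reach.is_descendant(have.filler, want.filler)
            )
            for have in sub
        )
        if not ok:
            return False
    return True


def infer_epc_hierarchy(
    kb: KnowledgeBase, subroles: Reachability | None = None
) -> EpcHierarchy:
    """Classify the defined pharmacologic classes against one another.

    A class with the more specific definition becomes a subclass of the
    more general one (e.g. a beta2-agonist class under a beta-agonist
    class once the agonist fillers are hierarchically related). Mutually
    subsuming definitions form equivalence groups; the strict edges are
    acyclic by construction.
    """
    reach = transitive_closure(kb.hierarchy)
    defined = kb.defined_epcs()
    defs = {e: kb.definitions[e].restrictions for e in defined}
    g = nx.DiGraph()
    g.add_nodes_from(defined)
    for c in defined:
        for d in defined:
            if c != d and _definition_subsumes(kb, defs[c], defs[d], reach, subroles):
                g.add_edge(c, d)
    groups = tuple(
        frozenset(scc)
        for scc in sorted(map(sorted, nx.strongly_connected_components(g)))
        if len(scc) > 1
    )
    edges = frozenset(
        (c, d) for c, d in g.edges if not g.has_edge(d, c)
    )
    return EpcHierarchy(Hierarchy(edges), groups)


def _root_satisfied(
    kb: KnowledgeBase, drug: str, root: str,
    reach: Reachability, strict_root: bool,
) -> bool:
    if not strict_root:
        return kb.concepts[drug].kind == "drug"
    return reach.is_descendant(drug, root)


def classify_drug(
    drug: str,
    kb: KnowledgeBase,
    epc_hier: EpcHierarchy | None = None,
    reach: Reachability | None = None,
    subroles: Reachability | None = None,
    strict_root: bool = False,
) -> tuple[frozenset[str], frozenset[str]]:
    """All and direct inferred classes for one drug.

    A drug belongs to every defined class whose full conjunct set its
    assertions satisfy; the direct classes are the most specific ones
    under the inferred class hierarchy.
    """
    if reach is None:
        reach = transitive_closure(kb.hierarchy)
    if epc_hier is None:
        epc_hier = infer_epc_hierarchy(kb, subroles)
    all_epcs = set()
    for epc in kb.defined_epcs():
        d = kb.definitions[epc]
        if not _root_satisfied(kb, drug, d.root, reach, strict_root):
            continue
        if all(
            entails_restriction(drug, r, kb, reach, subroles)[0]
            for r in d.restrictions
        ):
            all_epcs.add(epc)
    direct = minimal_elements(all_epcs, epc_hier.reach)
    return frozenset(all_epcs), direct


def classify_all(
    kb: KnowledgeBase,
    epc_hier: EpcHierarchy | None = None,
    subroles: Reachability | None = None,
    strict_root: bool = False,
) -> tuple[Membership, ...]:
    """Inferred memberships for every drug, direct rows plus indirect ones,
    deterministically sorted by (drug, class)."""
    reach = transitive_closure(kb.hierarchy)
    if epc_hier is None:
        epc_hier = infer_epc_hierarchy(kb, subroles)
    rows: list[Membership] = []
    for drug in kb.drugs():
        all_epcs, direct = classify_drug(
            drug, kb, epc_hier, reach, subroles, strict_root
        )
        for epc in all_epcs:
            rows.append(
                Membership(
                    drug, epc, "inferred",
                    "direct" if epc in direct else "indirect",
                )
            )
    return tuple(sorted(rows))


def diagnose(
    drug: str,
    epc: str,
    kb: KnowledgeBase,
    reach: Reachability | None = None,
    subroles: Reachability | None = None,
    strict_root: bool = False,
) -> Diagnosis:
    """Explain, restriction by restriction, whether the drug satisfies the
    class definition — the audit's tool for pinpointing which conjunct
    blocks an inference (e.g. a missing may_prevent property)."""
    if reach is None:
        reach = transitive_closure(kb.hierarchy)
    d = kb.definitions.get(epc)
    if d is None or d.status != "defined":
        return Diagnosis(drug, epc, entailed=False, records=(), primitive=True)
    records = []
    for r in sorted(d.restrictions):
        ok, reason, witness = entails_restriction(drug, r, kb, reach, subroles)
        records.append(
            RestrictionRecord(r, "matched" if ok else "unmatched", reason, witness)
        )
    entailed = all(rec.status == "matched" for rec in records) and _root_satisfied(
        kb, drug, d.root, reach, strict_root
    )
    return Diagnosis(drug, epc, entailed, tuple(records))
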