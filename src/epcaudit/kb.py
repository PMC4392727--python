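"""Core knowledge-base model for drug/class ontology auditing.

The model mirrors the EL-style fragment used by NDF-RT-like drug
terminologies: a concept table (drugs, pharmacologic classes, filler
vocabularies), an is-a hierarchy, roles partitioned into equivalence
blocks, existential property assertions on drugs, class definitions as
conjunctions of existential restrictions, and asserted drug-class
memberships.

Everything is immutable; operations elsewhere in the package return new
:class:`KnowledgeBase` instances rather than mutating in place.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "CONCEPT_KINDS",
    "ROLE_FAMILIES",
    "THERAPEUTIC_INTENT_FAMILIES",
    "ROLE_SOURCES",
    "Concept",
    "Hierarchy",
    "Role",
    "RolePartition",
    "PropertyAssertion",
    "Restriction",
    "ClassDefinition",
    "Membership",
    "KnowledgeBase",
    "Finding",
    "HierarchyCycleError",
    "ReferentialError",
    "Reachability",
    "transitive_closure",
    "minimal_elements",
    "validate_kb",
    "make_kb",
]

CONCEPT_KINDS = ("drug", "epc", "filler", "root")

#: Role families used in drug descriptions and class definitions.
#: MoA = mechanism of action, PE = physiologic effect; may_treat and
#: may_prevent are the therapeutic-intent families linking to diseases.
ROLE_FAMILIES = ("MoA", "PE", "ChemStructure", "may_treat", "may_prevent")
THERAPEUTIC_INTENT_FAMILIES = frozenset({"may_treat", "may_prevent"})

#: Provenance tags: FMTSME roles carry class definitions, FDASPL roles
#: carry drug descriptions from product-label indexing, NDFRT roles carry
#: legacy drug relations (therapeutic intent).
ROLE_SOURCES = ("FMTSME", "FDASPL", "NDFRT", "other")


class HierarchyCycleError(ValueError):
    """The is-a hierarchy contains a cycle and is not a valid DAG."""


class ReferentialError(KeyError):
    """An axiom references a concept or role absent from the KB."""


@dataclass(frozen=True, order=True)
class Concept:
    id: str
    label: str
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in CONCEPT_KINDS:
            raise ValueError(f"unknown concept kind {self.kind!r} for {self.id}")


@dataclass(frozen=True)
class Hierarchy:
    """A set of (child, parent) is-a edges; expected to be acyclic."""

    edges: frozenset[tuple[str, str]] = frozenset()

    @staticmethod
    def from_edges(edges: Iterable[tuple[str, str]]) -> "Hierarchy":
        return Hierarchy(frozenset((str(c), str(p)) for c, p in edges))

    def nodes(self) -> frozenset[str]:
        return frozenset(n for e in self.edges for n in e)

    def parents(self, node: str) -> frozenset[str]:
        return frozenset(p for c, p in self.edges if c == node)

    def children(self, node: str) -> frozenset[str]:
        return frozenset(c for c, p in self.edges if p == node)


@dataclass(frozen=True, order=True)
class Role:
    id: str
    family: str
    source: str

    def __post_init__(self) -> None:
        if self.family not in ROLE_FAMILIES and self.family != "other":
            raise ValueError(f"unknown role family {self.family!r} for {self.id}")
        if self.source not in ROLE_SOURCES:
            raise ValueError(f"unknown role source {self.source!r} for {self.id}")


@dataclass(frozen=True)
class RolePartition:
    """Disjoint equivalence blocks covering every role id.

    Roles in the same block are interchangeable when matching a drug's
    property assertions against a restriction in a class definition
    (the owl:equivalentProperty construct).
    """

    blocks: frozenset[frozenset[str]] = frozenset()

    @staticmethod
    def from_blocks(blocks: Iterable[Iterable[str]]) -> "RolePartition":
        fblocks = frozenset(frozenset(str(r) for r in b) for b in blocks if b)
        seen: set[str] = set()
        for b in fblocks:
            dup = seen & b
            if dup:
                raise ValueError(f"role(s) {sorted(dup)} appear in two blocks")
            seen |= b
        return RolePartition(fblocks)

    @staticmethod
    def discrete(role_ids: Iterable[str]) -> "RolePartition":
        return RolePartition(frozenset(frozenset({r}) for r in role_ids))

    def block_of(self, role_id: str) -> frozenset[str]:
        for b in self.blocks:
            if role_id in b:
                return b
        return frozenset({role_id})

    def equivalent(self, a: str, b: str) -> bool:
        return a == b or b in self.block_of(a)

    def covered_roles(self) -> frozenset[str]:
        return frozenset(r for b in self.blocks for r in b)


@dataclass(frozen=True, order=True)
class PropertyAssertion:
    """drug ⊑ ∃role.filler — an existential property of a drug."""

    drug: str
    role: str
    filler: str


@dataclass(frozen=True, order=True)
class Restriction:
    """∃role.filler conjunct inside a class definition."""

    role: str
    filler: str


@dataclass(frozen=True)
class ClassDefinition:
    """A pharmacologic class: root conjunct plus existential restrictions.

    ``status`` distinguishes primitive classes (necessary conditions
    only; no members can be inferred) from defined classes
    (necessary-and-sufficient, the owl:equivalentClass form).
    """

    epc: str
    root: str
    restrictions: frozenset[Restriction] = frozenset()
    status: str = "primitive"

    def __post_init__(self) -> None:
        if self.status not in ("primitive", "defined"):
            raise ValueError(f"unknown definition status {self.status!r}")
        if self.status == "defined" and not self.restrictions:
            raise ValueError(f"defined class {self.epc} requires >=1 restriction")


@dataclass(frozen=True, order=True)
class Membership:
    drug: str
    epc: str
    provenance: str = "asserted"
    directness: str = "direct"

    def __post_init__(self) -> None:
        if self.provenance not in ("asserted", "inferred"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.directness not in ("direct", "indirect"):
            raise ValueError(f"unknown directness {self.directness!r}")


@dataclass(frozen=True)
class KnowledgeBase:
    concepts: Mapping[str, Concept] = field(default_factory=dict)
    hierarchy: Hierarchy = field(default_factory=Hierarchy)
    roles: Mapping[str, Role] = field(default_factory=dict)
    role_partition: RolePartition = field(default_factory=RolePartition)
    assertions: frozenset[PropertyAssertion] = frozenset()
    definitions: Mapping[str, ClassDefinition] = field(default_factory=dict)
    memberships: frozenset[Membership] = frozenset()

    def drugs(self) -> list[str]:
        return sorted(c.id for c in self.concepts.values() if c.kind == "drug")

    def epcs(self) -> list[str]:
        return sorted(c.id for c in self.concepts.values() if c.kind == "epc")

    def defined_epcs(self) -> list[str]:
        return sorted(
            e for e, d in self.definitions.items() if d.status == "defined"
        )

    def assertions_of(self, drug: str) -> list[PropertyAssertion]:
        return sorted(a for a in self.assertions if a.drug == drug)

    def asserted_epcs(self, drug: str) -> frozenset[str]:
        return frozenset(
            m.epc for m in self.memberships
            if m.drug == drug and m.provenance == "asserted"
        )

    def replace(self, **kwargs) -> "KnowledgeBase":
        return replace(self, **kwargs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, KnowledgeBase):
            return NotImplemented
        return (
            dict(self.concepts) == dict(other.concepts)
            and self.hierarchy == other.hierarchy
            and dict(self.roles) == dict(other.roles)
            and self.role_partition == other.role_partition
            and self.assertions == other.assertions
            and dict(self.definitions) == dict(other.definitions)
            and self.memberships == other.memberships
        )

    __hash__ = None  # type: ignore[assignment]


@dataclass(frozen=True, order=True)
class Finding:
    severity: str  # "error" | "warning"
    code: str
    message: str


class Reachability:
    """Precomputed transitive closure over a DAG of is-a edges.

    ``is_descendant(a, b)`` answers whether ``a`` reaches ``b`` through
    one or more child→parent edges (or ``a == b`` when the closure was
    built reflexive). Ancestor/descendant sets are strict.
    """

    def __init__(
        self,
        ancestors: Mapping[str, frozenset[str]],
        descendants: Mapping[str, frozenset[str]],
        reflexive: bool = False,
    ) -> None:
        self._anc = dict(ancestors)
        self._desc = dict(descendants)
        self.reflexive = reflexive

    def is_descendant(self, a: str, b: str) -> bool:
        if a == b:
            return self.reflexive
        return b in self._anc.get(a, frozenset())

    def ancestors(self, node: str) -> frozenset[str]:
        return self._anc.get(node, frozenset())

    def descendants(self, node: str) -> frozenset[str]:
        return self._desc.get(node, frozenset())


def transitive_closure(h: Hierarchy, reflexive: bool = False) -> Reachability:
    """Close the is-a relation; raises :class:`HierarchyCycleError` on cycles."""
    g = nx.DiGraph()
    g.add_edges_from(h.edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = nx.find_cycle(g)
        raise HierarchyCycleError(f"hierarchy contains a cycle: {cycle}")
    anc: dict[str, frozenset[str]] = {}
    for node in reversed(list(nx.topological_sort(g))):
        acc: set[str] = set()
        for parent in g.successors(node):
            acc.add(parent)
            acc |= anc[parent]
        anc[node] = frozenset(acc)
    desc: dict[str, set[str]] = {n: set() for n in g.nodes}
    for node, ups in anc.items():
        for up in ups:
            desc[up].add(node)
    return Reachability(anc, {n: frozenset(s) for n, s in desc.items()}, reflexive)


def minimal_elements(
    ids: Iterable[str], hierarchy: Hierarchy | Reachability
) -> frozenset[str]:
    """Most-specific reduction: drop every element that has a strict
    descendant also present in the input set."""
    ids = frozenset(ids)
    reach = (
        hierarchy
        if isinstance(hierarchy, Reachability)
        else transitive_closure(hierarchy)
    )
    return frozenset(
        x for x in ids if not any(reach.is_descendant(y, x) for y in ids if y != x)
    )


def validate_kb(kb: KnowledgeBase) -> list[Finding]:
    """Structural validation; returns findings instead of raising.

    Errors: hierarchy cycles, dangling concept/role references, kind
    mismatches, defined classes with no restrictions, partition
    violations. Warnings: classes sharing an identical definition.
    """
    findings: list[Finding] = []

    def err(code: str, msg: str) -> None:
        findings.append(Finding("error", code, msg))

    def warn(code: str, msg: str) -> None:
        findings.append(Finding("warning", code, msg))

    ids = set(kb.concepts)
    for cid, c in kb.concepts.items():
        if cid != c.id:
            err("concept_key_mismatch", f"concept keyed {cid} has id {c.id}")

    for child, parent in sorted(kb.hierarchy.edges):
        if child == parent:
            err("cycle", f"self-loop {child} ⊑ {child}")
        for n in (child, parent):
            if n not in ids:
                err("dangling_reference", f"hierarchy edge references unknown concept {n}")
    try:
        transitive_closure(kb.hierarchy)
    except HierarchyCycleError as exc:
        err("cycle", str(exc))

    covered = kb.role_partition.covered_roles()
    for rid in covered - set(kb.roles):
        err("dangling_reference", f"role partition references unknown role {rid}")
    counts: dict[str, int] = {}
    for b in kb.role_partition.blocks:
        for r in b:
            counts[r] = counts.get(r, 0) + 1
    for rid, n in sorted(counts.items()):
        if n > 1:
            err("partition_violation", f"role {rid} appears in {n} blocks")

    for a in sorted(kb.assertions):
        if a.drug not in ids:
            err("dangling_reference", f"assertion references unknown drug {a.drug}")
        elif kb.concepts[a.drug].kind != "drug":
            err("kind_mismatch", f"assertion subject {a.drug} is not kind=drug")
        if a.role not in kb.roles:
            err("dangling_reference", f"assertion references unknown role {a.role}")
        if a.filler not in ids:
            err("dangling_reference", f"assertion references unknown filler {a.filler}")

    for epc, d in sorted(kb.definitions.items()):
        if epc != d.epc:
            err("concept_key_mismatch", f"definition keyed {epc} has epc {d.epc}")
        if d.epc not in ids:
            err("dangling_reference", f"definition references unknown class {d.epc}")
        elif kb.concepts[d.epc].kind != "epc":
            err("kind_mismatch", f"defined class {d.epc} is not kind=epc")
        if d.root not in ids:
            err("dangling_reference", f"definition of {d.epc} references unknown root {d.root}")
        if d.status == "defined" and not d.restrictions:
            err("empty_definition", f"defined class {d.epc} has zero restrictions")
        for r in sorted(d.restrictions):
            if r.role not in kb.roles:
                err("dangling_reference", f"definition of {d.epc} uses unknown role {r.role}")
            if r.filler not in ids:
                err("dangling_reference", f"definition of {d.epc} uses unknown filler {r.filler}")

    for m in sorted(kb.memberships):
        for cid, kind in ((m.drug, "drug"), (m.epc, "epc")):
            if cid not in ids:
                err("dangling_reference", f"membership references unknown concept {cid}")
            elif kb.concepts[cid].kind != kind:
                err("kind_mismatch", f"membership {m.drug}->{m.epc}: {cid} is not kind={kind}")

    by_def: dict[tuple, list[str]] = {}
    for epc, d in kb.definitions.items():
        if d.status == "defined" or d.restrictions:
            by_def.setdefault(tuple(sorted(d.restrictions)), []).append(epc)
    for key, epcs in sorted(by_def.items()):
        if len(epcs) > 1 and key:
            warn("duplicate_definition",
                 f"classes {sorted(epcs)} share an identical definition")

    return findings


def make_kb(
    concepts: Iterable[tuple[str, str, str]] = (),
    edges: Iterable[tuple[str, str]] = (),
    roles: Iterable[tuple[str, str, str]] = (),
    blocks: Iterable[Iterable[str]] | None = None,
    assertions: Iterable[tuple[str, str, str]] = (),
    definitions: Iterable[tuple[str, str, Iterable[tuple[str, str]], str]] = (),
    memberships: Iterable[tuple[str, str]] = (),
) -> KnowledgeBase:
    """Convenience constructor from plain tuples (fixtures, tests, generators).

    ``definitions`` rows are (epc, root, [(role, filler), ...], status);
    ``memberships`` rows are asserted direct (drug, epc) pairs. When
    ``blocks`` is None every role gets a singleton block.
    """
    concept_map = {c[0]: Concept(*c) for c in concepts}
    role_map = {r[0]: Role(*r) for r in roles}
    if blocks is None:
        partition = RolePartition.discrete(role_map)
    else:
        declared = [list(b) for b in blocks]
        in_declared = {r for b in declared for r in b}
        declared += [[r] for r in role_map if r not in in_declared]
        partition = RolePartition.from_blocks(declared)
    return KnowledgeBase(
        concepts=concept_map,
        hierarchy=Hierarchy.from_edges(edges),
        roles=role_map,
        role_partition=partition,
        assertions=frozenset(PropertyAssertion(*a) for a in assertions),
        definitions={
            epc: ClassDefinition(
                epc, root, frozenset(Restriction(*r) for r in rs), status
            )
            for epc, root, rs, status in definitions
        },
        memberships=frozenset(
            Membership(d, e, "asserted", "direct") for d, e in memberships
        ),
    )
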