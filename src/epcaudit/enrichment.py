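"""Enrichment of primitive pharmacologic classes with sufficient conditions.

NDF-RT-style terminologies describe pharmacologic classes with necessary
conditions only ("primitive" classes), so a reasoner can never place a
drug under a class. Enrichment folds the necessary conditions of each
class into an equivalence (necessary-and-sufficient) definition and
declares the class-side/drug-side role pairs equivalent, after which
structural subsumption can infer memberships.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable
from urllib.parse import quote

from rdflib import BNode, Graph, Literal, Namespace, RDF, RDFS, OWL, URIRef

from .kb import (
    ClassDefinition,
    KnowledgeBase,
    ROLE_FAMILIES,
    RolePartition,
)

__all__ = [
    "fold_definitions",
    "harmonize_roles",
    "enrich",
    "export_owl",
    "expected_triple_count",
    "DEFAULT_FAMILIES",
]

logger = logging.getLogger(__name__)

#: All role families participating in definitions by default: mechanism
#: of action, physiologic effect, chemical structure, and the two
#: therapeutic-intent families.
DEFAULT_FAMILIES = frozenset(ROLE_FAMILIES)

#: Drug-side source expected to pair with the class-side FMTSME role of
#: each family. MoA/PE/ChemStructure descriptions come from product-label
#: indexing (FDASPL); therapeutic intent comes from legacy relations.
_DRUG_SIDE_SOURCE = {
    "MoA": "FDASPL",
    "PE": "FDASPL",
    "ChemStructure": "FDASPL",
    "may_treat": "NDFRT",
    "may_prevent": "NDFRT",
}


def fold_definitions(
    kb: KnowledgeBase,
    families: Iterable[str] = DEFAULT_FAMILIES,
    strict: bool = False,
) -> KnowledgeBase:
    """Turn primitive classes with in-scope restrictions into defined ones.

    A class becomes ``defined`` when at least one of its necessary
    restrictions uses a role whose family is in ``families``. By default
    the definition keeps exactly the in-scope restrictions (out-of-scope
    conjuncts are dropped); with ``strict=True`` the full conjunct set is
    kept, so a class citing an excluded family retains conjuncts that
    drugs may be unable to satisfy. Classes with no in-scope restriction
    stay primitive and are logged.

    Assertions, memberships and the hierarchy are untouched.
    """
    families = frozenset(families)
    new_defs = {}
    for epc, d in kb.definitions.items():
        in_scope = frozenset(
            r for r in d.restrictions if kb.roles[r.role].family in families
        )
        if in_scope:
            kept = d.restrictions if strict else in_scope
            new_defs[epc] = ClassDefinition(d.epc, d.root, kept, "defined")
        else:
            if d.restrictions:
                logger.warning(
                    "class %s has no restriction in families %s; left primitive",
                    epc, sorted(families),
                )
            new_defs[epc] = ClassDefinition(d.epc, d.root, d.restrictions, "primitive")
    return kb.replace(definitions=new_defs)


def harmonize_roles(kb: KnowledgeBase) -> KnowledgeBase:
    """Install the canonical role-equivalence blocks.

    For each role family, the class-side FMTSME role and the matching
    drug-side role (FDASPL for mechanism of action / physiologic effect /
    chemical structure; legacy NDFRT for may_treat / may_prevent) are
    placed in one equivalence block. Every other role becomes a singleton
    block. Idempotent.
    """
    blocks: list[list[str]] = []
    grouped: set[str] = set()
    for family in ROLE_FAMILIES:
        drug_side = _DRUG_SIDE_SOURCE[family]
        block = sorted(
            r.id for r in kb.roles.values()
            if r.family == family and r.source in ("FMTSME", drug_side)
        )
        if len(block) >= 2:
            blocks.append(block)
            grouped.update(block)
    blocks.extend([r] for r in sorted(kb.roles) if r not in grouped)
    return kb.replace(role_partition=RolePartition.from_blocks(blocks))


def enrich(
    kb: KnowledgeBase,
    families: Iterable[str] = DEFAULT_FAMILIES,
    strict: bool = False,
) -> KnowledgeBase:
    """Full enrichment: role harmonization followed by definition folding."""
    return fold_definitions(harmonize_roles(kb), families, strict=strict)


KB_NS = Namespace("http://example.org/kb#")


def _uri(local: str) -> URIRef:
    return KB_NS[quote(local, safe="")]


def _some_values_node(g: Graph, node: BNode, role: str, filler: str) -> BNode:
    g.add((node, RDF.type, OWL.Restriction))
    g.add((node, OWL.onProperty, _uri(role)))
    g.add((node, OWL.someValuesFrom, _uri(filler)))
    return node


def export_owl(kb: KnowledgeBase, path: str | Path) -> Path:
    """Serialize the KB to Turtle for interoperability with OWL toolchains.

    Concepts become owl:Class, is-a edges rdfs:subClassOf, defined
    classes an owl:equivalentClass of the intersection of the root class
    and owl:someValuesFrom restrictions, role blocks chains of
    owl:equivalentProperty, drug properties subclass-of-restriction
    axioms, and asserted memberships rdfs:subClassOf. Blank nodes carry
    stable labels so equal KBs serialize byte-identically.
    """
    g = Graph()
    g.bind("owl", OWL)
    g.bind("rdfs", RDFS)
    g.bind("rdf", RDF)
    g.bind("kb", KB_NS)

    for cid in sorted(kb.concepts):
        c = kb.concepts[cid]
        g.add((_uri(cid), RDF.type, OWL.Class))
        if c.label:
            g.add((_uri(cid), RDFS.label, Literal(c.label)))
    for rid in sorted(kb.roles):
        g.add((_uri(rid), RDF.type, OWL.ObjectProperty))
    for child, parent in sorted(kb.hierarchy.edges):
        g.add((_uri(child), RDFS.subClassOf, _uri(parent)))

    for epc in sorted(kb.definitions):
        d = kb.definitions[epc]
        if d.status != "defined":
            continue
        head = BNode(f"def_{quote(epc, safe='')}")
        g.add((_uri(epc), OWL.equivalentClass, head))
        g.add((head, RDF.type, OWL.Class))
        restrictions = sorted(d.restrictions)
        members: list = [_uri(d.root)]
        for i, r in enumerate(restrictions):
            members.append(
                _some_values_node(
                    g, BNode(f"def_{quote(epc, safe='')}_r{i}"), r.role, r.filler
                )
            )
        # explicit RDF list with stable node labels
        prev = None
        for i, member in enumerate(members):
            cell = BNode(f"def_{quote(epc, safe='')}_l{i}")
            if prev is None:
                g.add((head, OWL.intersectionOf, cell))
            else:
                g.add((prev, RDF.rest, cell))
            g.add((cell, RDF.first, member))
            prev = cell
        g.add((prev, RDF.rest, RDF.nil))

    for block in sorted(map(sorted, kb.role_partition.blocks)):
        for a, b in zip(block, block[1:]):
            g.add((_uri(a), OWL.equivalentProperty, _uri(b)))

    for i, a in enumerate(sorted(kb.assertions)):
        node = BNode(f"prop_{i}")
        _some_values_node(g, node, a.role, a.filler)
        g.add((_uri(a.drug), RDFS.subClassOf, node))

    for m in sorted(kb.memberships):
        if m.provenance == "asserted":
            g.add((_uri(m.drug), RDFS.subClassOf, _uri(m.epc)))

    path = Path(path)
    path.write_text(g.serialize(format="turtle"), encoding="utf-8")
    return path


def expected_triple_count(kb: KnowledgeBase) -> int:
    """Independent tally of the triples :func:`export_owl` should emit,
    computed from the KB tables rather than from a graph."""
    n = len(kb.concepts)  # rdf:type owl:Class
    n += sum(1 for c in kb.concepts.values() if c.label)  # rdfs:label
    n += len(kb.roles)  # rdf:type owl:ObjectProperty
    n += len(kb.hierarchy.edges)
    for d in kb.definitions.values():
        if d.status != "defined":
            continue
        k = len(d.restrictions)
        # equivalentClass + rdf:type + 3 per restriction + list cells:
        # (k + 1) members, each with rdf:first and rdf:rest, plus the
        # owl:intersectionOf link on the head
        n += 2 + 3 * k + 2 * (k + 1) + 1
    n += sum(len(b) - 1 for b in kb.role_partition.blocks)  # equivalentProperty
    n += 4 * len(kb.assertions)  # restriction bnode (3) + subClassOf
    n += sum(1 for m in kb.memberships if m.provenance == "asserted")
    return n
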