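"""Independent brute-force oracle for the structural classifier.

Deliberately naive and separate from the package implementation: role
equivalence is checked by scanning the partition blocks, filler
subsumption by breadth-first search over the raw edge set for every
query, class subsumption by exhaustive pairwise conjunct matching, and
drug classification by enumerating all (drug, class) pairs.
"""

from __future__ import annotations

import random

from epcaudit.kb import KnowledgeBase, Membership, make_kb


def bfs_reaches(edges: frozenset[tuple[str, str]], a: str, b: str) -> bool:
    """Is b a strict ancestor of a (>=1 edge)?"""
    frontier = [a]
    seen = set()
    while frontier:
        node = frontier.pop()
        for child, parent in edges:
            if child == node and parent not in seen:
                if parent == b:
                    return True
                seen.add(parent)
                frontier.append(parent)
    return False


def same_block(kb: KnowledgeBase, r1: str, r2: str) -> bool:
    if r1 == r2:
        return True
    for block in kb.role_partition.blocks:
        if r1 in block and r2 in block:
            return True
    return False


def filler_ok(kb: KnowledgeBase, have: str, want: str) -> bool:
    return have == want or bfs_reaches(kb.hierarchy.edges, have, want)


def drug_satisfies(kb: KnowledgeBase, drug: str, epc: str) -> bool:
    d = kb.definitions[epc]
    if d.status != "defined":
        return False
    for r in d.restrictions:
        if not any(
            a.drug == drug
            and same_block(kb, a.role, r.role)
            and filler_ok(kb, a.filler, r.filler)
            for a in kb.assertions
        ):
            return False
    return True


def def_subsumes(kb: KnowledgeBase, sub: str, sup: str) -> bool:
    """Every conjunct of sup's definition matched by one of sub's."""
    for want in kb.definitions[sup].restrictions:
        if not any(
            same_block(kb, have.role, want.role)
            and filler_ok(kb, have.filler, want.filler)
            for have in kb.definitions[sub].restrictions
        ):
            return False
    return True


def brute_classify_all(kb: KnowledgeBase) -> tuple[Membership, ...]:
    defined = [e for e, d in kb.definitions.items() if d.status == "defined"]
    rows = []
    for drug in kb.drugs():
        hits = [e for e in defined if drug_satisfies(kb, drug, e)]
        for epc in hits:
            strictly_below = any(
                o != epc and def_subsumes(kb, o, epc) and not def_subsumes(kb, epc, o)
                for o in hits
            )
            rows.append(
                Membership(drug, epc, "inferred",
                           "indirect" if strictly_below else "direct")
            )
    return tuple(sorted(rows))


def random_kb(rng: random.Random) -> KnowledgeBase:
    """A small random KB: random filler DAG, random role blocks, random
    definitions and assertions. Pre-enriched (defined statuses set)."""
    n_fillers = rng.randint(2, 15)
    fillers = [f"F{i}" for i in range(n_fillers)]
    edges = []
    for i, f in enumerate(fillers):
        if i and rng.random() < 0.6:
            for p in rng.sample(fillers[:i], rng.randint(1, min(2, i))):
                edges.append((f, p))

    n_roles = rng.randint(2, 6)
    role_ids = [f"r{i}" for i in range(n_roles)]
    roles = [
        (r, rng.choice(["MoA", "PE", "ChemStructure", "may_treat", "may_prevent"]),
         rng.choice(["FMTSME", "FDASPL", "NDFRT", "other"]))
        for r in role_ids
    ]
    shuffled = role_ids[:]
    rng.shuffle(shuffled)
    blocks, i = [], 0
    while i < len(shuffled):
        size = rng.randint(1, min(3, len(shuffled) - i))
        blocks.append(shuffled[i:i + size])
        i += size

    n_epcs = rng.randint(1, 6)
    epcs = [f"E{i}" for i in range(n_epcs)]
    definitions = []
    for e in epcs:
        if rng.random() < 0.15:
            definitions.append((e, "ROOT", [], "primitive"))
        else:
            k = rng.randint(1, 3)
            rs = [
                (rng.choice(role_ids), rng.choice(fillers)) for _ in range(k)
            ]
            definitions.append((e, "ROOT", rs, "defined"))

    n_drugs = rng.randint(1, 8)
    drugs = [f"D{i}" for i in range(n_drugs)]
    assertions = []
    for d in drugs:
        for _ in range(rng.randint(0, 4)):
            assertions.append((d, rng.choice(role_ids), rng.choice(fillers)))

    concepts = (
        [("ROOT", "Pharmaceutical Preparations", "root")]
        + [(f, f, "filler") for f in fillers]
        + [(e, e, "epc") for e in epcs]
        + [(d, d, "drug") for d in drugs]
    )
    return make_kb(
        concepts=concepts, edges=edges, roles=roles, blocks=blocks,
        assertions=assertions, definitions=definitions,
    )
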