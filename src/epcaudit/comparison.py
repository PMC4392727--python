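"""Asserted-vs-inferred audit: categorization, overlap, and ablation.

Given a terminology whose drug-class memberships exist both as
authoritative assertions and as inferences from drug/class property
descriptions, this module quantifies their agreement from the drug
perspective (per drug, comparing direct class sets), the class
perspective (per class, comparing direct-plus-indirect member sets),
and the relation level (overlap counts), and measures the specific
contribution of the therapeutic-intent (may_treat/may_prevent) roles
by ablating them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .classifier import EpcHierarchy, classify_all, infer_epc_hierarchy
from .enrichment import DEFAULT_FAMILIES, enrich
from .kb import (
    KnowledgeBase,
    Membership,
    Reachability,
    THERAPEUTIC_INTENT_FAMILIES,
)

__all__ = [
    "DRUG_CATEGORIES",
    "CLASS_CATEGORIES",
    "DrugComparison",
    "ClassComparison",
    "PerspectiveSummary",
    "OverlapCounts",
    "AuditSummary",
    "AuditResult",
    "AblationResult",
    "categorize_drug",
    "categorize_class",
    "closed_members",
    "relation_overlap",
    "summarize",
    "compare_drugs",
    "compare_classes",
    "audit_kb",
    "run_ablation",
]

DRUG_CATEGORIES = (
    "identical",
    "compatible",
    "additional_asserted",
    "additional_inferred",
    "additional_both",
    "asserted_only",
    "inferred_only",
)

CLASS_CATEGORIES = (
    "identical",
    "additional_asserted",
    "additional_inferred",
    "additional_both",
    "asserted_only",
    "inferred_only",
)


@dataclass(frozen=True)
class DrugComparison:
    drug: str
    asserted: frozenset[str]
    inferred: frozenset[str]
    category: str


@dataclass(frozen=True)
class ClassComparison:
    epc: str
    asserted: frozenset[str]
    inferred: frozenset[str]
    category: str


@dataclass(frozen=True)
class PerspectiveSummary:
    """Category counts for one perspective; percentages are derived."""

    counts: dict[str, int]
    total: int

    def percentages(self) -> dict[str, float]:
        if self.total == 0:
            return {c: 0.0 for c in self.counts}
        return {
            c: round(100.0 * n / self.total, 2) for c, n in self.counts.items()
        }


@dataclass(frozen=True)
class OverlapCounts:
    n_asserted: int
    n_inferred: int
    n_common: int

    @property
    def n_asserted_only(self) -> int:
        return self.n_asserted - self.n_common

    @property
    def n_inferred_only(self) -> int:
        return self.n_inferred - self.n_common


@dataclass(frozen=True)
class AuditSummary:
    drugs: PerspectiveSummary
    classes: PerspectiveSummary
    overlap_direct: OverlapCounts
    overlap_closed: OverlapCounts


@dataclass(frozen=True)
class AuditResult:
    """Full audit output: the enriched KB, inferred artifacts, per-item
    comparisons, and the roll-up summary."""

    kb: KnowledgeBase
    epc_hierarchy: EpcHierarchy
    inferred: tuple[Membership, ...]
    drug_comparisons: tuple[DrugComparison, ...]
    class_comparisons: tuple[ClassComparison, ...]
    summary: AuditSummary


@dataclass(frozen=True)
class AblationResult:
    baseline: AuditSummary
    enhanced: AuditSummary
    drug_deltas: dict[str, int] = field(default_factory=dict)
    class_deltas: dict[str, int] = field(default_factory=dict)


def _matched(x: str, others: frozenset[str], h: EpcHierarchy) -> bool:
    return any(x == y or h.related(x, y) for y in others)


def categorize_drug(
    A: frozenset[str],
    I: frozenset[str],
    h: EpcHierarchy,
    bidirectional: bool = True,
) -> str:
    """Categorize one drug from its asserted (A) and inferred (I) direct
    class sets. First matching rule wins:

    no inferred classes → asserted_only; no asserted → inferred_only;
    equal sets → identical; every class on each side identical to or
    hierarchically related to one on the other side → compatible;
    otherwise the side(s) carrying unmatched classes name the category.

    With ``bidirectional=False``, compatible only requires every asserted
    class to be matched in the inferred set (the looser one-directional
    reading), at the price of overlapping with additional_inferred.
    """
    if not A and not I:
        raise ValueError("drug with neither asserted nor inferred classes")
    if not I:
        return "asserted_only"
    if not A:
        return "inferred_only"
    if A == I:
        return "identical"
    unmatched_a = {a for a in A if not _matched(a, I, h)}
    unmatched_i = {i for i in I if not _matched(i, A, h)}
    if bidirectional:
        if not unmatched_a and not unmatched_i:
            return "compatible"
    elif not unmatched_a:
        return "compatible"
    if unmatched_a and not unmatched_i:
        return "additional_asserted"
    if unmatched_i and not unmatched_a:
        return "additional_inferred"
    return "additional_both"


def categorize_class(Ac: frozenset[str], Ic: frozenset[str]) -> str:
    """Categorize one class from its closed (direct+indirect) asserted and
    inferred member sets."""
    if not Ac and not Ic:
        raise ValueError("class with neither asserted nor inferred members")
    if not Ic:
        return "asserted_only"
    if not Ac:
        return "inferred_only"
    if Ac == Ic:
        return "identical"
    if Ic < Ac:
        return "additional_asserted"
    if Ac < Ic:
        return "additional_inferred"
    return "additional_both"


def closed_members(
    epc: str,
    memberships: Iterable[Membership],
    epc_hierarchy: EpcHierarchy,
) -> frozenset[str]:
    """Direct and indirect members: drugs directly in the class or in any
    of its descendants in the inferred class hierarchy."""
    scope = {epc} | set(epc_hierarchy.descendants(epc))
    return frozenset(
        m.drug for m in memberships
        if m.directness == "direct" and m.epc in scope
    )


def _expand(
    pairs: frozenset[tuple[str, str]], h: EpcHierarchy
) -> frozenset[tuple[str, str]]:
    out = set(pairs)
    for drug, epc in pairs:
        out.update((drug, anc) for anc in h.ancestors(epc))
    return frozenset(out)


def relation_overlap(
    asserted: Iterable[Membership],
    inferred: Iterable[Membership],
    mode: str = "direct",
    epc_hierarchy: EpcHierarchy | None = None,
) -> OverlapCounts:
    """Count (drug, class) pairs on each side and in common.

    ``direct`` compares direct relations only; ``closed`` first expands
    each relation through the class-hierarchy ancestors (the transitive
    closure of subclass-of), so members of a subclass count for every
    superclass too.
    """
    a_pairs = frozenset(
        (m.drug, m.epc) for m in asserted if m.directness == "direct"
    )
    i_pairs = frozenset(
        (m.drug, m.epc) for m in inferred if m.directness == "direct"
    )
    if mode == "closed":
        if epc_hierarchy is None:
            raise ValueError("closed mode requires the inferred class hierarchy")
        a_pairs = _expand(a_pairs, epc_hierarchy)
        i_pairs = _expand(i_pairs, epc_hierarchy)
    elif mode != "direct":
        raise ValueError(f"unknown overlap mode {mode!r}")
    return OverlapCounts(
        n_asserted=len(a_pairs),
        n_inferred=len(i_pairs),
        n_common=len(a_pairs & i_pairs),
    )


def summarize(
    comparisons: Sequence[DrugComparison] | Sequence[ClassComparison],
    perspective: str | None = None,
) -> PerspectiveSummary:
    """Roll per-item categories into counts; percentages to 2 decimals."""
    if perspective is None:
        if comparisons and isinstance(comparisons[0], ClassComparison):
            perspective = "class"
        else:
            perspective = "drug"
    cats = DRUG_CATEGORIES if perspective == "drug" else CLASS_CATEGORIES
    counts = {c: 0 for c in cats}
    for cmp_ in comparisons:
        counts[cmp_.category] += 1
    return PerspectiveSummary(counts=counts, total=len(comparisons))


def compare_drugs(
    kb: KnowledgeBase,
    inferred: Iterable[Membership],
    epc_hierarchy: EpcHierarchy,
    bidirectional: bool = True,
) -> tuple[DrugComparison, ...]:
    """Per-drug comparison of asserted vs inferred direct class sets;
    drugs related to no class on either side are excluded."""
    direct_inferred: dict[str, set[str]] = {}
    for m in inferred:
        if m.directness == "direct":
            direct_inferred.setdefault(m.drug, set()).add(m.epc)
    out = []
    for drug in kb.drugs():
        A = kb.asserted_epcs(drug)
        I = frozenset(direct_inferred.get(drug, ()))
        if not A and not I:
            continue
        out.append(
            DrugComparison(drug, A, I, categorize_drug(A, I, epc_hierarchy, bidirectional))
        )
    return tuple(out)


def compare_classes(
    kb: KnowledgeBase,
    inferred: Iterable[Membership],
    epc_hierarchy: EpcHierarchy,
) -> tuple[ClassComparison, ...]:
    """Per-class comparison of closed member sets; classes with no member
    on either side are excluded."""
    inferred = tuple(inferred)
    asserted = tuple(m for m in kb.memberships if m.provenance == "asserted")
    out = []
    for epc in kb.epcs():
        Ac = closed_members(epc, asserted, epc_hierarchy)
        Ic = closed_members(epc, inferred, epc_hierarchy)
        if not Ac and not Ic:
            continue
        out.append(ClassComparison(epc, Ac, Ic, categorize_class(Ac, Ic)))
    return tuple(out)


def audit_kb(
    kb: KnowledgeBase,
    use_therapeutic_intent: bool = True,
    strict_fold: bool = False,
    bidirectional: bool = True,
    subroles: Reachability | None = None,
    strict_root: bool = False,
) -> AuditResult:
    """Run the full pipeline on an un-enriched KB: harmonize roles, fold
    definitions, classify every drug, and compare against the asserted
    memberships from both perspectives."""
    families = set(DEFAULT_FAMILIES)
    if not use_therapeutic_intent:
        families -= THERAPEUTIC_INTENT_FAMILIES
    enriched = enrich(kb, families, strict=strict_fold)
    epc_hier = infer_epc_hierarchy(enriched, subroles)
    inferred = classify_all(enriched, epc_hier, subroles, strict_root)
    drug_cmp = compare_drugs(enriched, inferred, epc_hier, bidirectional)
    class_cmp = compare_classes(enriched, inferred, epc_hier)
    asserted = tuple(m for m in enriched.memberships if m.provenance == "asserted")
    summary = AuditSummary(
        drugs=summarize(drug_cmp, "drug"),
        classes=summarize(class_cmp, "class"),
        overlap_direct=relation_overlap(asserted, inferred, "direct"),
        overlap_closed=relation_overlap(asserted, inferred, "closed", epc_hier),
    )
    return AuditResult(enriched, epc_hier, inferred, drug_cmp, class_cmp, summary)


def run_ablation(kb: KnowledgeBase, **options) -> AblationResult:
    """Audit twice — without and with the therapeutic-intent roles — and
    report per-category deltas (enhanced − baseline). Totals may differ
    between arms: a drug whose only inferred class comes through
    may_treat/may_prevent drops out of the baseline comparison."""
    baseline = audit_kb(kb, use_therapeutic_intent=False, **options).summary
    enhanced = audit_kb(kb, use_therapeutic_intent=True, **options).summary
    drug_deltas = {
        c: enhanced.drugs.counts[c] - baseline.drugs.counts[c]
        for c in DRUG_CATEGORIES
    }
    class_deltas = {
        c: enhanced.classes.counts[c] - baseline.classes.counts[c]
        for c in CLASS_CATEGORIES
    }
    return AblationResult(baseline, enhanced, drug_deltas, class_deltas)
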