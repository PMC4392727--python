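# Methods

## The model

The knowledge bases this package audits live in a small EL-style
description-logic fragment: named concepts (drugs, pharmacologic
classes, filler vocabulary terms, and a root class standing for
pharmaceutical preparations), an acyclic is-a hierarchy over fillers,
object roles in five families (mechanism of action, physiologic effect,
chemical structure, may_treat, may_prevent), existential property
assertions on drugs (`drug ⊑ ∃r.f`), and class definitions that are
conjunctions of the root class and existential restrictions. There is
no negation, disjunction, cardinality, or role composition — exactly
the constructs NDF-RT-style terminologies use.

Classes arrive *primitive*: their restrictions are necessary conditions
only, so no membership is derivable. Enrichment makes them *defined*
(`owl:equivalentClass` semantics) by folding the necessary conditions
into a sufficient definition, and installs role-equivalence blocks that
bridge the class-side vocabulary (`*_FMTSME`) and the drug-side
vocabularies (`*_FDASPL` for the three descriptive families, `*_NDFRT`
legacy relations for therapeutic intent).

## Structural subsumption

For this fragment, subsumption is decidable by syntactic conjunct
matching, which is what the classifier implements instead of calling a
tableau reasoner:

* `drug ⊑ EPC` iff for every conjunct `∃r.f` of the definition there is
  an assertion `∃r'.f'` of the drug with `r'` in the same
  role-equivalence block as `r` and `f' = f` or `f'` a strict descendant
  of `f` in the transitive closure of the filler hierarchy.
* `EPC C ⊑ EPC D` iff every conjunct of `D` is matched, in the same
  sense, by a conjunct of `C` (a more specific definition is subsumed by
  a more general one). Mutually subsuming definitions are reported as
  equivalence groups, never merged: duplicate definitions are precisely
  the kind of anomaly an audit must surface.

Soundness and completeness of this check against model-theoretic
entailment is standard for conjunctions of existentials over a concept
hierarchy; the test suite cross-checks the implementation against an
independent brute-force enumerator on hundreds of random KBs rather
than against an external reasoner (none is available as a library
dependency here).

Two deliberately open readings are settled by flags, off by default:

* **Root conjunct.** Every concept of kind `drug` is taken to satisfy
  the root conjunct; `strict_root=True` instead demands hierarchy
  placement under the definition's root. Drug terminologies keep drugs
  in a separate branch (DRUG_KIND), so hierarchy placement would
  vacuously kill every inference on real-shaped data.
* **Role subsumption.** The matching of a drug's role against a
  definition's role uses equivalence blocks only; a declared sub-role
  table (a `Reachability` over role ids) can be supplied to extend the
  match. Filler subsumption is always on.

## The audit

**Drug perspective** compares, per drug, the asserted direct class set
`A` against the inferred *direct* class set `I` (the most specific
inferred classes, i.e. the minimal elements of the full inferred set
under the inferred class hierarchy). The decision tree, first match
wins: `I=∅` → asserted only; `A=∅` → inferred only; `A=I` → identical;
all classes on both sides matched (identical or hierarchically related
in the inferred hierarchy) → compatible; otherwise the side(s) with
unmatched classes name the category. "Hierarchically related" means
reachable in either direction, or co-membership in an equivalence
group; a class is never related to itself (equality is its own
category). Compatibility is required in both directions so that the
seven categories partition; the looser one-directional reading — every
asserted class matched, extra inferred classes tolerated — is available
as `bidirectional=False`.

**Class perspective** compares closed (direct plus indirect) member
sets: the members of a class are the direct members of the class and of
all its descendants in the inferred class hierarchy. Set comparison
here is plain inclusion (six categories; no "compatible", since closure
already absorbs hierarchy effects).

**Relation overlap** counts (drug, class) pairs on each side and in
common, either on direct relations or after expanding every relation
through the class-hierarchy ancestors.

**Ablation.** The pipeline runs twice — definitions folded without and
with the therapeutic-intent families — and per-category deltas are
reported. Folding has two modes. Default (*drop-conjunct*): a class
keeps exactly its in-scope restrictions, so a class mixing structural
and therapeutic conjuncts gets a *weaker* baseline definition; this
mode answers "what could be inferred from the descriptive families
alone". Strict mode keeps the full conjunct set whenever at least one
conjunct is in scope; baseline definitions are then identical to
enhanced ones and the set of defined classes only grows, which makes
the ablation monotone (the baseline never infers a relation the
enhanced run lacks). The drop-conjunct baseline is *not* monotone in
general — weakened mixed definitions can acquire members — which is
observable on the granularity worked example and is intended behavior,
not a defect. Classes with no in-scope conjunct stay primitive in both
modes.

## Ingredient normalization

Audits should run on clinically meaningful ingredients. The ingredient
map (a TSV emulating an RxNorm export) sends each precise ingredient
(salt, ester, complex) to its base ingredient; drugs flagged
multi-ingredient or not linked to clinical drugs are removed outright,
and memberships/assertions of merged ingredients are unioned. The live
RxNorm service and its term-type traversal are out of scope by design —
the flags encode their outcome.

## Synthetic data

The generator emulates the *structure* of an NDF-RT release, not its
marginal statistics. Per role family it grows a filler tree of depth 2
(default branching 4): the root's children are "anchors", each anchor
owning a disjoint subtree. Each class draws 1–3 distinct families and
one anchor per family for its definition; each drug is assigned one
class, given drug-side assertions that exactly satisfy it, and its
membership is asserted. Five injection kinds then create the
discrepancy categories the audit must recover:

| injection | emulates | expected category |
|---|---|---|
| drop_property | under-described drug (no inferable class) | asserted only |
| prevent_asymmetry | drug lists treatment but not prevention | asserted only |
| drop_asserted | missing authoritative relation | inferred only |
| coarsen_definition | asserted class more specific than inferred | compatible |
| extra_property | property satisfying a second class | additional inferred |

With `ensure_independent_injections` (default), anchors are handed out
without replacement (definitions cannot interact), drug fillers equal
the definition fillers exactly, and each drug receives at most one
injection drawn from a single categorical — so the audited category of
every drug is exactly predictable, and `expected_summary` reproduces
both audit tables and the overlap counts from the ground truth alone.
The coarsening injection lazily creates one specialized subclass per
base class (same roles, child fillers) and moves the asserted
membership there; when the asymmetry injection is requested the first
class is forced to include both therapeutic-intent conjuncts so an
eligible class always exists. Relaxing the independence flag allows
overlapping subtrees, descendant fillers (exercising filler
subsumption) and multiple injections per drug; ground truth then
remains a best-effort intent, not a guarantee.

What passing the recovery test shows: the pipeline inverts exactly the
discrepancy classes it was built to detect, under non-interacting
injections. What it does not show: behavior under correlated defects,
realistic class-size distributions, or the lexical-mapping noise of a
real release — those require real terminology data.

Default study conditions used by the acceptance script: 500 drugs, 25
classes, branching 25, injection rates 0.2 / 0.1 / 0.1 / 0.1 / 0.1 for
the five kinds above, everything driven by one seeded `random.Random`
stream with draws in a fixed documented order, so equal seeds produce
byte-identical interchange files.

## Numerical and formatting choices

Percentages are `100·count/total` rounded to two decimals. All outputs
(memberships, comparisons, tables, Turtle statements, interchange
files) are deterministically sorted by identifier, so equal inputs give
byte-identical outputs. Hierarchy cycles are hard errors everywhere —
an is-a cycle in a terminology of this shape is data corruption, and
collapsing it silently would hide exactly what an audit exists to find.
Duplicate assertions and duplicate class definitions are tolerated with
warnings (deduplicated and reported, respectively). The Turtle export
uses labeled blank nodes so serialization is reproducible; the
interchange writer adds an optional `status` column to
`class_definitions.tsv` so enriched KBs round-trip (readers without the
column default every class to primitive).

## Known limitations

* Only the EL fragment above; no general OWL reasoning, no ABox
  individuals (drugs are classes, as in the source terminology).
* The inferred class hierarchy is the only hierarchy used for
  relatedness and closure; an independently curated class hierarchy, if
  one existed, is ignored.
* The drug-branch hierarchy (under DRUG_KIND) is carried but takes no
  part in filler subsumption.
* Ingredient normalization is table-driven; it cannot detect mapping
  errors in the supplied table.
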