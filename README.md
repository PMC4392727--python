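# epcaudit

Quality-assurance auditing of drug-class membership relations in
NDF-RT-style drug terminologies.

Drug terminologies such as NDF-RT describe both active ingredients and
pharmacologic classes (EPCs, Established Pharmacologic Classes) in terms
of the same property families — mechanism of action (MoA), physiologic
effect (PE), chemical structure, and therapeutic intent (may_treat /
may_prevent) — yet the classes carry only *necessary* conditions. A
description-logic reasoner therefore cannot place any drug under any
class, and the authoritative drug-class memberships asserted from FDA
Structured Product Labels float free of the logical definitions. Since
those two sources are independent, they can disagree — and every
disagreement is a potential terminology defect: an under-described drug,
an over-constrained class definition, a missing authoritative relation,
or a granularity mismatch.

`epcaudit` makes the disagreements visible. It is aimed at terminology
maintainers and ontology QA researchers. The pipeline:

1. **Enrichment** — fold each class's necessary conditions into a
   necessary-and-sufficient definition,
   `EPC ≡ PharmaceuticalPreparation ⊓ ∃r₁.f₁ ⊓ … ⊓ ∃rₖ.fₖ`
   (the `owl:equivalentClass` construct), and declare the class-side /
   drug-side role pairs equivalent (`has_MoA_FMTSME ≡ has_MoA_FDASPL`,
   …, `may_prevent_FMTSME ≡ may_prevent_NDFRT`).
2. **Classification** — a structural subsumption classifier for this EL
   fragment: a drug with assertions `{∃rᵢ'.fᵢ'}` is a member of a defined
   class iff every conjunct `∃r.f` of the definition is matched by some
   assertion with `r'` role-equivalent to `r` and `f' ⊑ f` in the filler
   hierarchy. The same test applied between definitions yields the
   inferred class hierarchy (e.g. *beta2-Adrenergic Agonist* ⊑
   *beta-Adrenergic Agonist* once the agonist fillers are related).
3. **Audit** — compare inferred against asserted memberships per drug
   (direct class sets, seven categories: identical / compatible /
   additional on either or both sides / one side only), per class
   (direct-plus-indirect member sets, six categories), and at the
   relation level (overlap counts, direct and hierarchy-closed); measure
   the specific contribution of the therapeutic-intent roles by ablating
   them; and explain any non-inference conjunct by conjunct.

A synthetic-KB generator produces NDF-RT-like inputs with controlled
discrepancy injections and exact ground truth, so the whole audit is
testable without any external terminology release.

## Worked example

The amikacin granularity case: the drug's chemical-structure and
may_treat properties satisfy the broad *Aminoglycoside* class, while the
asserted membership points at the narrower *Aminoglycoside
Antibacterial*, whose definition additionally demands a may_prevent
property the drug lacks.

```python
from epcaudit import audit_kb, render_tables, worked_examples

case = worked_examples()["amikacin"]
result = audit_kb(case.kb)
print(render_tables(result.summary, "tsv"))
```

prints

```
# Drug perspective (direct relations)
category	description	count	percent
identical	Drugs with identical sets of classes	0	0.00
compatible	Drugs with compatible sets of classes	1	100.00
...
total	Total	1	100.00

# Class perspective (direct and indirect relations)
category	description	count	percent
identical	Classes with identical sets of drugs	1	50.00
...
asserted_only	Classes with asserted relations only (no inferred)	1	50.00
total	Total	2	100.00

# Relation overlap
mode	n_asserted	n_inferred	n_common	n_asserted_only	n_inferred_only
direct	1	1	0	1	1
closed	2	1	1	1	0
```

Reading it: the drug lands in the **compatible** row — its asserted and
inferred classes differ but are hierarchically related (the classifier
inferred *Aminoglycoside Antibacterial* ⊑ *Aminoglycoside* from the
definitions alone). From the class perspective the broad class has
identical closed member sets while the narrow one has asserted members
only. The direct relations disagree (0 common), but after expanding
through the inferred class hierarchy the asserted pair subsumes the
inferred one (1 common).

The same pipeline runs from the shell on a TSV interchange directory:

```sh
epcaudit audit --kb KB_DIR --out OUT_DIR --ablation --diagnoses
epcaudit diagnose --kb KB_DIR --drug ofloxacin --epc EPC_quinolone
epcaudit simulate --seed 7 --drugs 100 --p-drop-property 0.2 --out OUT
epcaudit export-owl --kb KB_DIR --out kb.ttl
```

See `docs/methods.md` for the model, parameters, and design choices.

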