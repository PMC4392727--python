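"""Rendering audit outputs and writing the tabular interchange format.

Tables mirror the canonical audit layouts: a seven-row drug-perspective
table, a six-row class-perspective table, and a baseline/+disease/delta
ablation table. Renderers never recompute: every number comes from the
summary object handed in.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import pandas as pd

from .classifier import Diagnosis
from .comparison import (
    AblationResult,
    AuditSummary,
    CLASS_CATEGORIES,
    ClassComparison,
    DRUG_CATEGORIES,
    DrugComparison,
    OverlapCounts,
    PerspectiveSummary,
)
from .kb import KnowledgeBase, Membership

__all__ = [
    "render_tables",
    "write_kb",
    "write_memberships",
    "write_drug_comparisons",
    "write_class_comparisons",
    "write_diagnoses",
]

DRUG_ROW_LABELS = {
    "identical": "Drugs with identical sets of classes",
    "compatible": "Drugs with compatible sets of classes",
    "additional_asserted": "Drugs with additional relations in the asserted set only",
    "additional_inferred": "Drugs with additional relations in the inferred set only",
    "additional_both": "Drugs with additional relations in both sets",
    "asserted_only": "Drugs with asserted relations only (no inferred)",
    "inferred_only": "Drugs with inferred relations only (no asserted)",
}

CLASS_ROW_LABELS = {
    "identical": "Classes with identical sets of drugs",
    "additional_asserted": "Classes with additional relations in the asserted set only",
    "additional_inferred": "Classes with additional relations in the inferred set only",
    "additional_both": "Classes with additional relations in both sets",
    "asserted_only": "Classes with asserted relations only (no inferred)",
    "inferred_only": "Classes with inferred relations only (no asserted)",
}

FORMATS = ("tsv", "json", "markdown")


def _fmt_pct(x: float) -> str:
    return f"{x:.2f}"


def _perspective_rows(
    summary: PerspectiveSummary, labels: dict[str, str]
) -> list[tuple[str, str, str, str]]:
    pct = summary.percentages()
    rows = [
        (cat, labels[cat], str(summary.counts[cat]), _fmt_pct(pct[cat]))
        for cat in labels
    ]
    total_pct = "100.00" if summary.total else "0.00"
    rows.append(("total", "Total", str(summary.total), total_pct))
    return rows


def _table_text(
    rows: list[tuple[str, ...]], header: tuple[str, ...], fmt: str
) -> str:
    if fmt == "tsv":
        lines = ["\t".join(header)] + ["\t".join(r) for r in rows]
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        widths = [
            max(len(str(x)) for x in [h] + [r[i] for r in rows])
            for i, h in enumerate(header)
        ]
        def line(cells):
            return "| " + " | ".join(str(c).ljust(w) for c, w in zip(cells, widths)) + " |"
        sep = "|" + "|".join("-" * (w + 2) for w in widths) + "|"
        return "\n".join([line(header), sep] + [line(r) for r in rows]) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def _summary_dict(summary: AuditSummary) -> dict:
    def overlap(o: OverlapCounts) -> dict:
        return {
            "n_asserted": o.n_asserted,
            "n_inferred": o.n_inferred,
            "n_common": o.n_common,
            "n_asserted_only": o.n_asserted_only,
            "n_inferred_only": o.n_inferred_only,
        }

    return {
        "drug_perspective": {
            "counts": dict(summary.drugs.counts),
            "percentages": summary.drugs.percentages(),
            "total": summary.drugs.total,
        },
        "class_perspective": {
            "counts": dict(summary.classes.counts),
            "percentages": summary.classes.percentages(),
            "total": summary.classes.total,
        },
        "overlap_direct": overlap(summary.overlap_direct),
        "overlap_closed": overlap(summary.overlap_closed),
    }


def _render_summary(summary: AuditSummary, fmt: str) -> str:
    if fmt == "json":
        return json.dumps(_summary_dict(summary), indent=2, sort_keys=True) + "\n"
    header = ("category", "description", "count", "percent")
    parts = [
        "# Drug perspective (direct relations)",
        _table_text(_perspective_rows(summary.drugs, DRUG_ROW_LABELS), header, fmt),
        "# Class perspective (direct and indirect relations)",
        _table_text(_perspective_rows(summary.classes, CLASS_ROW_LABELS), header, fmt),
        "# Relation overlap",
        _table_text(
            [
                (mode, str(o.n_asserted), str(o.n_inferred), str(o.n_common),
                 str(o.n_asserted_only), str(o.n_inferred_only))
                for mode, o in (
                    ("direct", summary.overlap_direct),
                    ("closed", summary.overlap_closed),
                )
            ],
            ("mode", "n_asserted", "n_inferred", "n_common",
             "n_asserted_only", "n_inferred_only"),
            fmt,
        ),
    ]
    return "\n".join(parts)


def _render_ablation(result: AblationResult, fmt: str) -> str:
    if fmt == "json":
        payload = {
            "baseline": _summary_dict(result.baseline),
            "enhanced": _summary_dict(result.enhanced),
            "drug_deltas": result.drug_deltas,
            "class_deltas": result.class_deltas,
        }
        return json.dumps(payload, indent=2, sort_keys=True) + "\n"

    def arm_rows(cats, base: PerspectiveSummary, enh: PerspectiveSummary, deltas):
        bp, ep = base.percentages(), enh.percentages()
        rows = [
            (c, str(base.counts[c]), _fmt_pct(bp[c]),
             str(enh.counts[c]), _fmt_pct(ep[c]), str(deltas[c]))
            for c in cats
        ]
        rows.append(
            ("total", str(base.total), "100.00" if base.total else "0.00",
             str(enh.total), "100.00" if enh.total else "0.00",
             str(enh.total - base.total))
        )
        return rows

    header = ("category", "baseline_n", "baseline_pct",
              "enhanced_n", "enhanced_pct", "delta")
    parts = [
        "# Drug perspective: contribution of therapeutic intent",
        _table_text(
            arm_rows(DRUG_CATEGORIES, result.baseline.drugs,
                     result.enhanced.drugs, result.drug_deltas),
            header, fmt,
        ),
        "# Class perspective: contribution of therapeutic intent",
        _table_text(
            arm_rows(CLASS_CATEGORIES, result.baseline.classes,
                     result.enhanced.classes, result.class_deltas),
            header, fmt,
        ),
    ]
    return "\n".join(parts)


def render_tables(summary: AuditSummary | AblationResult, fmt: str = "tsv") -> str:
    """Render an audit summary or ablation result as tsv/json/markdown."""
    if fmt not in FORMATS:
        raise ValueError(f"unknown format {fmt!r}; choose from {FORMATS}")
    if isinstance(summary, AblationResult):
        return _render_ablation(summary, fmt)
    if isinstance(summary, AuditSummary):
        return _render_summary(summary, fmt)
    raise TypeError(f"cannot render {type(summary).__name__}")


def _df_to_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, encoding="utf-8", lineterminator="\n")


def write_kb(kb: KnowledgeBase, directory: str | Path) -> Path:
    """Write a KB back to the interchange directory, deterministically
    sorted so equal KBs produce byte-identical files."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)

    _df_to_tsv(
        pd.DataFrame(
            [(c.id, c.label, c.kind) for c in sorted(kb.concepts.values())],
            columns=["id", "label", "kind"],
        ),
        d / "concepts.tsv",
    )
    _df_to_tsv(
        pd.DataFrame(sorted(kb.hierarchy.edges), columns=["child_id", "parent_id"]),
        d / "hierarchy.tsv",
    )
    _df_to_tsv(
        pd.DataFrame(
            [(r.id, r.family, r.source) for r in sorted(kb.roles.values())],
            columns=["role_id", "family", "source"],
        ),
        d / "roles.tsv",
    )
    blocks = sorted(
        [sorted(b) for b in kb.role_partition.blocks if len(b) > 1]
    )
    _df_to_tsv(
        pd.DataFrame(
            [(f"B{i:04d}", r) for i, b in enumerate(blocks) for r in b],
            columns=["block_id", "role_id"],
        ),
        d / "role_equiv.tsv",
    )
    _df_to_tsv(
        pd.DataFrame(
            [(a.drug, a.role, a.filler) for a in sorted(kb.assertions)],
            columns=["drug_id", "role_id", "filler_id"],
        ),
        d / "drug_properties.tsv",
    )
    def_rows = []
    for epc in sorted(kb.definitions):
        dd = kb.definitions[epc]
        if dd.restrictions:
            for r in sorted(dd.restrictions):
                def_rows.append((epc, dd.root, r.role, r.filler, dd.status))
        else:
            def_rows.append((epc, dd.root, "", "", dd.status))
    _df_to_tsv(
        pd.DataFrame(
            def_rows, columns=["epc_id", "root_id", "role_id", "filler_id", "status"]
        ),
        d / "class_definitions.tsv",
    )
    _df_to_tsv(
        pd.DataFrame(
            sorted((m.drug, m.epc) for m in kb.memberships if m.provenance == "asserted"),
            columns=["drug_id", "epc_id"],
        ),
        d / "asserted_memberships.tsv",
    )
    return d


def write_memberships(rows: Iterable[Membership], path: str | Path) -> Path:
    path = Path(path)
    _df_to_tsv(
        pd.DataFrame(
            [(m.drug, m.epc, m.provenance, m.directness) for m in sorted(rows)],
            columns=["drug_id", "epc_id", "provenance", "directness"],
        ),
        path,
    )
    return path


def write_drug_comparisons(
    rows: Iterable[DrugComparison], path: str | Path
) -> Path:
    path = Path(path)
    _df_to_tsv(
        pd.DataFrame(
            [
                (r.drug, "|".join(sorted(r.asserted)),
                 "|".join(sorted(r.inferred)), r.category)
                for r in rows
            ],
            columns=["drug_id", "asserted_epcs", "inferred_epcs", "category"],
        ),
        path,
    )
    return path


def write_class_comparisons(
    rows: Iterable[ClassComparison], path: str | Path
) -> Path:
    path = Path(path)
    _df_to_tsv(
        pd.DataFrame(
            [
                (r.epc, "|".join(sorted(r.asserted)),
                 "|".join(sorted(r.inferred)), r.category)
                for r in rows
            ],
            columns=["epc_id", "asserted_drugs", "inferred_drugs", "category"],
        ),
        path,
    )
    return path


def write_diagnoses(diagnoses: Iterable[Diagnosis], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for diag in diagnoses:
        if diag.primitive:
            rows.append(
                (diag.drug, diag.epc, "0", "", "", "primitive_class", "", "", "")
            )
            continue
        for rec in diag.records:
            rows.append(
                (
                    diag.drug,
                    diag.epc,
                    "1" if diag.entailed else "0",
                    rec.restriction.role,
                    rec.restriction.filler,
                    rec.status,
                    rec.reason,
                    rec.witness.role if rec.witness else "",
                    rec.witness.filler if rec.witness else "",
                )
            )
    _df_to_tsv(
        pd.DataFrame(
            rows,
            columns=[
                "drug_id", "epc_id", "entailed", "restriction_role",
                "restriction_filler", "status", "reason",
                "witness_role", "witness_filler",
            ],
        ),
        path,
    )
    return path
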