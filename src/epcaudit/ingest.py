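"""Loading the tabular KB interchange format and ingredient normalization.

The interchange is a directory of UTF-8, tab-delimited files with fixed
headers (``concepts.tsv``, ``hierarchy.tsv``, ``roles.tsv``,
``role_equiv.tsv``, ``drug_properties.tsv``, ``class_definitions.tsv``,
``asserted_memberships.tsv``, plus a free-standing
``ingredient_map.tsv``). Missing optional files load as empty tables.

Ingredient normalization emulates the RxNorm step of restricting an
audit to clinically significant drugs: precise ingredients (salts,
esters, complexes) are rewritten onto their base ingredient, drugs not
linked to clinical drugs are dropped, and multi-ingredient drugs are
ignored because their classification is too variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .kb import (
    ClassDefinition,
    Concept,
    Hierarchy,
    KnowledgeBase,
    Membership,
    PropertyAssertion,
    Restriction,
    Role,
    RolePartition,
    validate_kb,
)

__all__ = [
    "InterchangeError",
    "IngredientMap",
    "load_kb",
    "load_ingredient_map",
    "normalize_ingredients",
    "FILE_COLUMNS",
]

logger = logging.getLogger(__name__)


class InterchangeError(ValueError):
    """A file violates the interchange contract (named file/line/column)."""


FILE_COLUMNS: dict[str, list[str]] = {
    "concepts.tsv": ["id", "label", "kind"],
    "hierarchy.tsv": ["child_id", "parent_id"],
    "roles.tsv": ["role_id", "family", "source"],
    "role_equiv.tsv": ["block_id", "role_id"],
    "drug_properties.tsv": ["drug_id", "role_id", "filler_id"],
    # one row per restriction; a definition-less or restriction-less class
    # uses empty role/filler cells; the optional status column round-trips
    # enriched KBs and defaults to primitive
    "class_definitions.tsv": ["epc_id", "root_id", "role_id", "filler_id"],
    "asserted_memberships.tsv": ["drug_id", "epc_id"],
    "ingredient_map.tsv": ["source_id", "base_id", "multi_ingredient", "clinically_linked"],
}

_OPTIONAL_COLUMNS = {"class_definitions.tsv": ["status"]}


def _read_table(path: Path, name: str) -> pd.DataFrame:
    cols = FILE_COLUMNS[name]
    if not path.exists():
        return pd.DataFrame(columns=cols)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise InterchangeError(f"{path}: missing column(s) {missing}")
    allowed = set(cols) | set(_OPTIONAL_COLUMNS.get(name, []))
    extra = [c for c in df.columns if c not in allowed]
    if extra:
        raise InterchangeError(f"{path}: unexpected column(s) {extra}")
    return df


def _require(df: pd.DataFrame, path: Path, columns: list[str]) -> None:
    for col in columns:
        bad = df.index[df[col] == ""]
        if len(bad):
            line = int(bad[0]) + 2  # header + 1-based
            raise InterchangeError(f"{path}, line {line}: empty value in column {col!r}")


def load_kb(directory: str | Path) -> KnowledgeBase:
    """Load a KB from an interchange directory; the result is validated and
    an :class:`InterchangeError` is raised on any error-level finding.
    Row order never affects the loaded KB."""
    d = Path(directory)
    if not d.is_dir():
        raise InterchangeError(f"{d} is not a directory")

    cdf = _read_table(d / "concepts.tsv", "concepts.tsv")
    _require(cdf, d / "concepts.tsv", ["id", "kind"])
    concepts: dict[str, Concept] = {}
    for i, row in cdf.iterrows():
        if row["id"] in concepts:
            raise InterchangeError(
                f"{d / 'concepts.tsv'}, line {int(i) + 2}: duplicate concept id {row['id']}"
            )
        try:
            concepts[row["id"]] = Concept(row["id"], row["label"], row["kind"])
        except ValueError as exc:
            raise InterchangeError(
                f"{d / 'concepts.tsv'}, line {int(i) + 2}: {exc}"
            ) from exc

    hdf = _read_table(d / "hierarchy.tsv", "hierarchy.tsv")
    _require(hdf, d / "hierarchy.tsv", ["child_id", "parent_id"])
    hierarchy = Hierarchy.from_edges(
        zip(hdf["child_id"], hdf["parent_id"])
    )

    rdf = _read_table(d / "roles.tsv", "roles.tsv")
    _require(rdf, d / "roles.tsv", ["role_id", "family", "source"])
    roles: dict[str, Role] = {}
    for i, row in rdf.iterrows():
        try:
            roles[row["role_id"]] = Role(row["role_id"], row["family"], row["source"])
        except ValueError as exc:
            raise InterchangeError(
                f"{d / 'roles.tsv'}, line {int(i) + 2}: {exc}"
            ) from exc

    edf = _read_table(d / "role_equiv.tsv", "role_equiv.tsv")
    _require(edf, d / "role_equiv.tsv", ["block_id", "role_id"])
    declared: dict[str, list[str]] = {}
    for _, row in edf.iterrows():
        declared.setdefault(row["block_id"], []).append(row["role_id"])
    in_blocks = {r for b in declared.values() for r in b}
    blocks = [sorted(set(b)) for _, b in sorted(declared.items())]
    blocks += [[r] for r in sorted(roles) if r not in in_blocks]
    try:
        partition = RolePartition.from_blocks(blocks)
    except ValueError as exc:
        raise InterchangeError(f"{d / 'role_equiv.tsv'}: {exc}") from exc

    pdf = _read_table(d / "drug_properties.tsv", "drug_properties.tsv")
    _require(pdf, d / "drug_properties.tsv", ["drug_id", "role_id", "filler_id"])
    raw = list(zip(pdf["drug_id"], pdf["role_id"], pdf["filler_id"]))
    assertions = frozenset(PropertyAssertion(*t) for t in raw)
    if len(raw) != len(assertions):
        logger.warning(
            "%s: %d duplicate assertion row(s) collapsed",
            d / "drug_properties.tsv", len(raw) - len(assertions),
        )

    ddf = _read_table(d / "class_definitions.tsv", "class_definitions.tsv")
    _require(ddf, d / "class_definitions.tsv", ["epc_id", "root_id"])
    defs: dict[str, dict] = {}
    for i, row in ddf.iterrows():
        entry = defs.setdefault(
            row["epc_id"],
            {"root": row["root_id"], "restrictions": set(), "status": "primitive"},
        )
        if entry["root"] != row["root_id"]:
            raise InterchangeError(
                f"{d / 'class_definitions.tsv'}, line {int(i) + 2}: "
                f"class {row['epc_id']} repeated with a different root"
            )
        if (row["role_id"] == "") != (row["filler_id"] == ""):
            raise InterchangeError(
                f"{d / 'class_definitions.tsv'}, line {int(i) + 2}: "
                "role_id and filler_id must be both present or both empty"
            )
        if row["role_id"]:
            entry["restrictions"].add(Restriction(row["role_id"], row["filler_id"]))
        if "status" in ddf.columns and row["status"]:
            entry["status"] = row["status"]
    definitions = {
        epc: ClassDefinition(epc, e["root"], frozenset(e["restrictions"]), e["status"])
        for epc, e in defs.items()
    }

    mdf = _read_table(d / "asserted_memberships.tsv", "asserted_memberships.tsv")
    _require(mdf, d / "asserted_memberships.tsv", ["drug_id", "epc_id"])
    memberships = frozenset(
        Membership(dr, ep, "asserted", "direct")
        for dr, ep in zip(mdf["drug_id"], mdf["epc_id"])
    )

    kb = KnowledgeBase(
        concepts=concepts,
        hierarchy=hierarchy,
        roles=roles,
        role_partition=partition,
        assertions=assertions,
        definitions=definitions,
        memberships=memberships,
    )
    errors = [f for f in validate_kb(kb) if f.severity == "error"]
    if errors:
        detail = "; ".join(f"{f.code}: {f.message}" for f in errors[:10])
        raise InterchangeError(f"{d}: KB fails validation — {detail}")
    return kb


@dataclass(frozen=True)
class MapRow:
    source: str
    base: str
    multi_ingredient: bool
    clinically_linked: bool


@dataclass(frozen=True)
class IngredientMap:
    """Functional map from precise/source ingredients to base ingredients,
    with inclusion flags. Base ingredients map to themselves."""

    rows: Mapping[str, MapRow]

    def __post_init__(self) -> None:
        for src, row in self.rows.items():
            if src != row.source:
                raise ValueError(f"map keyed {src} holds row for {row.source}")
            base = row.base
            if base in self.rows and self.rows[base].base != base:
                raise ValueError(
                    f"base ingredient {base} does not map to itself"
                )

    @staticmethod
    def identity(drug_ids, clinically_linked: bool = True) -> "IngredientMap":
        return IngredientMap(
            {d: MapRow(d, d, False, clinically_linked) for d in drug_ids}
        )


def load_ingredient_map(path: str | Path) -> IngredientMap:
    path = Path(path)
    df = _read_table(path, "ingredient_map.tsv")
    _require(df, path, FILE_COLUMNS["ingredient_map.tsv"])
    rows: dict[str, MapRow] = {}
    for i, row in df.iterrows():
        for flag_col in ("multi_ingredient", "clinically_linked"):
            if row[flag_col] not in ("0", "1"):
                raise InterchangeError(
                    f"{path}, line {int(i) + 2}: {flag_col} must be 0 or 1"
                )
        src = row["source_id"]
        if src in rows:
            raise InterchangeError(
                f"{path}, line {int(i) + 2}: duplicate source ingredient {src}"
            )
        rows[src] = MapRow(
            src,
            row["base_id"],
            row["multi_ingredient"] == "1",
            row["clinically_linked"] == "1",
        )
    try:
        return IngredientMap(rows)
    except ValueError as exc:
        raise InterchangeError(f"{path}: {exc}") from exc


def normalize_ingredients(kb: KnowledgeBase, m: IngredientMap) -> KnowledgeBase:
    """Rewrite every drug onto its base ingredient.

    Multi-ingredient drugs and drugs not linked to clinical drugs are
    removed outright, together with their assertions, memberships and
    hierarchy edges. When several precise ingredients collapse onto one
    base, their assertions and memberships are unioned. Raises
    ``ValueError`` listing drugs absent from the map.
    """
    drugs = kb.drugs()
    unmapped = sorted(d for d in drugs if d not in m.rows)
    if unmapped:
        raise ValueError(f"drugs absent from ingredient map: {unmapped}")

    keep: dict[str, str] = {}  # old drug id -> base id
    removed: set[str] = set()
    for d in drugs:
        row = m.rows[d]
        if row.multi_ingredient or not row.clinically_linked:
            removed.add(d)
        else:
            keep[d] = row.base

    concepts: dict[str, Concept] = {
        cid: c for cid, c in kb.concepts.items() if c.kind != "drug"
    }
    for old in sorted(keep):
        base = keep[old]
        if base not in concepts:
            # keep the base concept's own label when the KB already has one
            label = kb.concepts[base].label if base in kb.concepts else kb.concepts[old].label
            concepts[base] = Concept(base, label, "drug")

    def rewrite(cid: str) -> str | None:
        if cid in removed:
            return None
        return keep.get(cid, cid)

    edges = set()
    for child, parent in kb.hierarchy.edges:
        c, p = rewrite(child), rewrite(parent)
        if c is None or p is None or c == p:
            continue
        edges.add((c, p))

    assertions = frozenset(
        PropertyAssertion(keep[a.drug], a.role, a.filler)
        for a in kb.assertions
        if a.drug in keep
    )
    memberships = frozenset(
        Membership(keep[mm.drug], mm.epc, mm.provenance, mm.directness)
        for mm in kb.memberships
        if mm.drug in keep
    )
    return kb.replace(
        concepts=concepts,
        hierarchy=Hierarchy(frozenset(edges)),
        assertions=assertions,
        memberships=memberships,
    )
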