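"""Semi-automatic harvesting of curated disease-phenotype associations.

Pipeline: curated source tables (direct ICD-10-phenotype links, plus
OMIM-keyed annotations bridged to ICD-10 through cross-terminology mapping
tables) are merged with per-record provenance, generic low-information
phenotypes are filtered out, annotations are propagated down the ICD-10
hierarchy (a phenotype of a 3-character class also annotates its dotted
subcodes) and, for diseases left unannotated, inherited from a phenotype
class whose label is lexically contained in the disease label.  The released
set can be restricted to a common-disease id list and adjusted by an expert
curation override file.

Every record carries exactly one provenance tag so that released datasets
can be accounted for source by source.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import MappingParseError
from .ontology import OntologyGraph, TermLexicon, normalize_term

__all__ = [
    "PROVENANCES",
    "PROVENANCE_PRECEDENCE",
    "DEFAULT_GENERIC_PHENOTYPES",
    "AssociationRecord",
    "MappingTable",
    "GenericPhenotypeFilter",
    "bridge_associations",
    "BridgeResult",
    "dedup_records",
    "filter_generic",
    "propagate_icd",
    "propagate_lexical",
    "select_common",
    "apply_curation",
    "CurationResult",
    "provenance_summary",
    "read_associations",
    "write_associations",
]

PROVENANCES = (
    "wikidata",
    "hpo_via_wikidata",
    "hpo_via_umls",
    "umls_direct",
    "expert",
    "prop_icd",
    "prop_lexical",
)

# When one (disease, phenotype) pair arrives from several sources, a single
# provenance is kept for accounting.  Direct terminology mappings are the
# most reliable pathway, bridged mappings next, propagation last.
PROVENANCE_PRECEDENCE = (
    "umls_direct",
    "hpo_via_umls",
    "hpo_via_wikidata",
    "wikidata",
    "expert",
    "prop_icd",
    "prop_lexical",
)

# Generic, low-information phenotype classes excluded from released sets.
# The shipped default holds the five canonical examples (mode of inheritance,
# autosomal dominant inheritance, severity, aggravated-by, right); block
# lists are user-extensible through GenericPhenotypeFilter / --block-list.
DEFAULT_GENERIC_PHENOTYPES = frozenset(
    {"HP:0000005", "HP:0000006", "HP:0012824", "HP:0025285", "HP:0012834"}
)


@dataclass(frozen=True)
class AssociationRecord:
    """One disease-phenotype edge with its source pathway."""

    disease_id: str
    phenotype_id: str
    provenance: str
    curation_status: str = "accepted"  # accepted | removed_fp | added_fn

    def __post_init__(self) -> None:
        if self.provenance not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.disease_id, self.phenotype_id)


@dataclass
class MappingTable:
    """Cross-terminology identifier mapping (e.g. OMIM -> ICD-10).

    One source id may map to several targets; rows are deduplicated.
    """

    rows: list[tuple[str, str, str]] = field(default_factory=list)  # (source, target, resource)
    direction: str = ""

    @classmethod
    def from_tsv(cls, path: str | Path, direction: str = "") -> "MappingTable":
        rows: list[tuple[str, str, str]] = []
        for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not raw.strip() or raw.startswith("#") or raw.startswith("source_id\t"):
                continue
            parts = raw.rstrip("\n").split("\t")
            if len(parts) != 3 or not all(p.strip() for p in parts):
                raise MappingParseError(f"{path}:{lineno}: expected source_id<TAB>target_id<TAB>resource")
            rows.append((parts[0], parts[1], parts[2]))
        return cls(rows=sorted(set(rows)), direction=direction)

    def targets(self, source_id: str) -> list[tuple[str, str]]:
        return [(t, res) for s, t, res in self.rows if s == source_id]

    def as_dict(self) -> dict[str, list[tuple[str, str]]]:
        out: dict[str, list[tuple[str, str]]] = {}
        for s, t, res in sorted(set(self.rows)):
            out.setdefault(s, []).append((t, res))
        return out


@dataclass
class GenericPhenotypeFilter:
    blocked_ids: frozenset[str] = DEFAULT_GENERIC_PHENOTYPES

    @classmethod
    def from_file(cls, path: str | Path) -> "GenericPhenotypeFilter":
        ids = {
            line.strip().split("\t")[0]
            for line in Path(path).read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        }
        return cls(blocked_ids=frozenset(ids))


@dataclass
class BridgeResult:
    records: list[AssociationRecord]
    unmapped: list[str]  # source disease ids with no bridge row


# resource tag in the bridge table -> provenance of the bridged association
_RESOURCE_PROVENANCE = {"umls": "hpo_via_umls", "wikidata": "hpo_via_wikidata"}


def bridge_associations(
    assoc: Iterable[tuple[str, str]],
    bridge: MappingTable,
    resource_provenance: Mapping[str, str] | None = None,
) -> BridgeResult:
    """Re-key source-terminology associations to ICD-10 through a mapping bridge.

    ``assoc`` holds (source_disease_id, phenotype_id) pairs (e.g. OMIM-keyed
    annotations).  Every pair fans out to one record per mapped target code;
    the record's provenance comes from the bridge row's resource tag.
    Diseases with no bridge row are dropped and reported.
    """
    prov_map = dict(_RESOURCE_PROVENANCE if resource_provenance is None else resource_provenance)
    mapping = bridge.as_dict()
    records: list[AssociationRecord] = []
    unmapped: set[str] = set()
    for source_id, phenotype_id in assoc:
        targets = mapping.get(source_id)
        if not targets:
            unmapped.add(source_id)
            continue
        for target_id, resource in targets:
            try:
                provenance = prov_map[resource]
            except KeyError:
                raise MappingParseError(f"no provenance rule for bridge resource {resource!r}")
            records.append(AssociationRecord(target_id, phenotype_id, provenance))
    return BridgeResult(records=records, unmapped=sorted(unmapped))


def dedup_records(records: Iterable[AssociationRecord]) -> list[AssociationRecord]:
    """Collapse duplicate pairs, keeping the highest-precedence provenance."""
    rank = {p: i for i, p in enumerate(PROVENANCE_PRECEDENCE)}
    best: dict[tuple[str, str], AssociationRecord] = {}
    for rec in records:
        cur = best.get(rec.pair)
        if cur is None or rank[rec.provenance] < rank[cur.provenance]:
            best[rec.pair] = rec
    return sorted(best.values(), key=lambda r: r.pair)


def filter_generic(
    records: Iterable[AssociationRecord],
    generic: GenericPhenotypeFilter | None = None,
) -> tuple[list[AssociationRecord], list[AssociationRecord]]:
    """Drop records whose phenotype is on the block list.

    Returns (kept, removed) so no record is silently lost.
    """
    blocked = (generic or GenericPhenotypeFilter()).blocked_ids
    kept, removed = [], []
    for rec in records:
        (removed if rec.phenotype_id in blocked else kept).append(rec)
    return kept, removed


_DOTTED_CODE_RE = re.compile(r"^([A-Z]\d{2})\.\d+$")


def code_parent(disease_id: str) -> str | None:
    """Syntactic ICD-10 parent of a dotted code (G30.0 -> G30), else None."""
    m = _DOTTED_CODE_RE.match(disease_id)
    return m.group(1) if m else None


def propagate_icd(
    records: Sequence[AssociationRecord],
    g_icd: OntologyGraph | None = None,
) -> list[AssociationRecord]:
    """Propagate annotations down the ICD-10 hierarchy.

    For each record on class P, emits one ``prop_icd`` record per proper
    descendant of P whose (descendant, phenotype) pair is not already present
    in the input (so a second application adds nothing).  Parent links come
    from ``g_icd`` when given; otherwise dotted-code syntax (G30.0 under G30)
    is used.  Disease ids absent from the hierarchy are skipped: harvested
    codes may exceed the loaded ontology.
    """
    existing = {rec.pair for rec in records}
    if g_icd is None:
        children_of: dict[str, set[str]] = {}
        for rec in records:
            parent = code_parent(rec.disease_id)
            if parent is not None:
                children_of.setdefault(parent, set()).add(rec.disease_id)
        # syntax-only fallback can only see codes present in the input
        def proper_descendants(cid: str) -> set[str]:
            return children_of.get(cid, set())
    else:
        def proper_descendants(cid: str) -> set[str]:
            if cid not in g_icd:
                return set()
            return g_icd.descendants(cid, include_self=False)

    new: list[AssociationRecord] = []
    emitted: set[tuple[str, str]] = set()
    for rec in records:
        if rec.provenance in ("prop_icd", "prop_lexical"):
            continue  # propagate only asserted annotations
        for child in sorted(proper_descendants(rec.disease_id)):
            pair = (child, rec.phenotype_id)
            if pair in existing or pair in emitted:
                continue
            emitted.add(pair)
            new.append(AssociationRecord(child, rec.phenotype_id, "prop_icd"))
    return new


def propagate_lexical(
    diseases: Iterable[tuple[str, str]],
    phenotype_lexicon: TermLexicon,
    existing: Iterable[AssociationRecord],
) -> list[AssociationRecord]:
    """Annotate still-unannotated diseases by lexical superclass match.

    A disease whose normalized label contains a phenotype-class label as a
    token-boundary substring inherits that class (e.g. "external hemorrhoids
    with complications" contains "hemorrhoids").  The longest matching label
    wins; only diseases with no record from any other provenance are
    eligible.
    """
    annotated = {rec.disease_id for rec in existing}
    out: list[AssociationRecord] = []
    for disease_id, label in sorted(set(diseases)):
        if disease_id in annotated:
            continue
        tokens = normalize_term(label).split()
        best_len = 0
        best_classes: set[str] = set()
        for i in range(len(tokens)):
            for j in range(i + 1, len(tokens) + 1):
                gram = " ".join(tokens[i:j])
                classes = phenotype_lexicon.terms.get(gram)
                if classes:
                    if j - i > best_len:
                        best_len, best_classes = j - i, set(classes)
                    elif j - i == best_len:
                        best_classes |= classes
        for cid in sorted(best_classes):
            out.append(AssociationRecord(disease_id, cid, "prop_lexical"))
    return out


def select_common(
    records: Iterable[AssociationRecord], common_ids: Iterable[str]
) -> list[AssociationRecord]:
    """Restrict a dataset to a supplied common-disease id list.

    The list is an input (e.g. ICD-10 codes with >= 100 patients in a
    biobank); it is never computed here.
    """
    ids = set(common_ids)
    return [rec for rec in records if rec.disease_id in ids]


@dataclass
class CurationResult:
    released: list[AssociationRecord]
    removed: list[AssociationRecord]  # curation_status == removed_fp
    missing_removals: list[tuple[str, str]]  # remove actions that matched nothing


def apply_curation(
    records: Sequence[AssociationRecord],
    overrides: Iterable[tuple[str, str, str]],
) -> CurationResult:
    """Apply expert curation overrides: (disease_id, phenotype_id, remove|add).

    Removals mark the record ``removed_fp`` and drop it from the released
    set; additions enter with provenance ``expert`` and status ``added_fn``.
    A removal targeting an absent pair is reported, not an error.
    """
    to_remove: set[tuple[str, str]] = set()
    to_add: list[tuple[str, str]] = []
    for disease_id, phenotype_id, action in overrides:
        if action == "remove":
            to_remove.add((disease_id, phenotype_id))
        elif action == "add":
            to_add.append((disease_id, phenotype_id))
        else:
            raise ValueError(f"unknown curation action {action!r}")

    released: list[AssociationRecord] = []
    removed: list[AssociationRecord] = []
    for rec in records:
        if rec.pair in to_remove:
            removed.append(replace(rec, curation_status="removed_fp"))
        else:
            released.append(rec)
    present = {rec.pair for rec in records}
    missing = sorted(to_remove - present)
    existing_released = {rec.pair for rec in released}
    for pair in to_add:
        if pair not in existing_released:
            released.append(AssociationRecord(pair[0], pair[1], "expert", "added_fn"))
            existing_released.add(pair)
    return CurationResult(released=released, removed=removed, missing_removals=missing)


def provenance_summary(records: Iterable[AssociationRecord]) -> dict[str, int]:
    """Per-provenance counts plus TOTAL; the provenances partition the dataset."""
    counts = Counter(rec.provenance for rec in records)
    summary = {p: counts.get(p, 0) for p in PROVENANCES}
    summary["TOTAL"] = sum(counts.values())
    return summary


# -- I/O --------------------------------------------------------------------


def read_associations(path: str | Path) -> list[AssociationRecord]:
    out = []
    for lineno, raw in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip() or raw.startswith("#") or raw.startswith("disease_id\t"):
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) == 2:
            parts = [*parts, "expert", "accepted"]
        elif len(parts) == 3:
            parts = [*parts, "accepted"]
        elif len(parts) != 4:
            raise ValueError(f"{path}:{lineno}: expected 2-4 tab-separated fields")
        out.append(AssociationRecord(*parts))
    return out


def write_associations(records: Iterable[AssociationRecord], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("disease_id\tphenotype_id\tprovenance\tcuration_status\n")
        for rec in records:
            fh.write(f"{rec.disease_id}\t{rec.phenotype_id}\t{rec.provenance}\t{rec.curation_status}\n")
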