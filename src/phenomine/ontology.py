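"""Ontology model: labeled subclass DAGs and the term machinery built on them.

A terminology (ICD-10-like disease codes, HPO/MP-like phenotype classes) is
held as an :class:`OntologyGraph` — a directed acyclic graph of classes with
``child -> parent`` subclass edges.  On top of it sits the lexical layer:
``Labels(C)`` is the set of labels and synonyms of a class, and ``Terms(C)``
is the union of ``Labels(S)`` over every subclass ``S`` of ``C`` (reflexive).
Mentioning any member of ``Terms(C)`` in text counts as mentioning ``C``;
this is what lets corpus statistics be aggregated at every level of the
hierarchy.

Two on-disk dialects are supported: a minimal OBO-like stanza format
(``id:``, ``name:``, ``synonym:``, ``is_a:`` lines) and a two-file TSV edge
dialect (``child<TAB>parent`` plus a labels table).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx

from .errors import CyclicHierarchyError, UnknownClassError

__all__ = [
    "OntologyClass",
    "OntologyGraph",
    "TermLexicon",
    "normalize_term",
    "NORMALIZATION_POLICY",
    "load_ontology",
    "terms_of_class",
]

# Lowercase; any run of characters outside [a-z0-9'] becomes a single space;
# leading/trailing separators are trimmed.  Applying the same function to
# lexicon terms and to document text makes term lookup a pure string-equality
# test on token n-grams.
NORMALIZATION_POLICY = "lowercase; non-alphanumeric (apostrophe kept) -> single space; trim"

_SEPARATOR_RE = re.compile(r"[^a-z0-9']+")


def normalize_term(text: str) -> str:
    """Normalize a label or a piece of text to its canonical matching key."""
    return _SEPARATOR_RE.sub(" ", text.lower()).strip(" '")


@dataclass(frozen=True)
class OntologyClass:
    """A single ontology class with its lexical annotations."""

    class_id: str
    primary_label: str
    synonyms: frozenset[str] = frozenset()
    alt_labels: frozenset[str] = frozenset()
    obsolete: bool = False

    def labels(self) -> set[str]:
        """All strings that name this class (primary label, synonyms, alt labels)."""
        return {self.primary_label, *self.synonyms, *self.alt_labels}


class OntologyGraph:
    """A validated subclass DAG over :class:`OntologyClass` objects.

    Edges are stored child -> parent ("is a subclass of").  The graph may be
    a multi-parent DAG; all closure operations are over all parents.
    """

    def __init__(
        self,
        classes: Iterable[OntologyClass] = (),
        subclass_edges: Iterable[tuple[str, str]] = (),
    ) -> None:
        self.classes: dict[str, OntologyClass] = {}
        self._dag = nx.DiGraph()
        for cls in classes:
            self.add_class(cls)
        for child, parent in subclass_edges:
            self.add_edge(child, parent)
        self.validate()

    # -- construction -------------------------------------------------------

    def add_class(self, cls: OntologyClass) -> None:
        if cls.class_id in self.classes:
            raise ValueError(f"duplicate class id {cls.class_id!r}")
        self.classes[cls.class_id] = cls
        self._dag.add_node(cls.class_id)

    def add_edge(self, child: str, parent: str) -> None:
        """Assert ``child`` is a subclass of ``parent``."""
        for end in (child, parent):
            if end not in self.classes:
                raise UnknownClassError(f"edge endpoint {end!r} is not a known class")
        self._dag.add_edge(child, parent)

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self._dag):
            cycle = nx.find_cycle(self._dag)
            raise CyclicHierarchyError(f"subclass hierarchy contains a cycle: {cycle}")

    # -- structure ----------------------------------------------------------

    def __contains__(self, class_id: str) -> bool:
        return class_id in self.classes

    def __len__(self) -> int:
        return len(self.classes)

    @property
    def subclass_edges(self) -> set[tuple[str, str]]:
        return set(self._dag.edges())

    @property
    def roots(self) -> set[str]:
        """Classes with no parent."""
        return {n for n in self._dag.nodes if self._dag.out_degree(n) == 0}

    def parents(self, class_id: str) -> set[str]:
        self._require(class_id)
        return set(self._dag.successors(class_id))

    def children(self, class_id: str) -> set[str]:
        self._require(class_id)
        return set(self._dag.predecessors(class_id))

    def descendants(self, class_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure of subclass-of below ``class_id``."""
        self._require(class_id)
        out = nx.ancestors(self._dag, class_id)  # nodes that can reach class_id
        if include_self:
            out = out | {class_id}
        return out

    def ancestors(self, class_id: str, include_self: bool = False) -> set[str]:
        """Transitive closure of superclass-of above ``class_id``."""
        self._require(class_id)
        out = nx.descendants(self._dag, class_id)
        if include_self:
            out = out | {class_id}
        return out

    def _require(self, class_id: str) -> None:
        if class_id not in self.classes:
            raise UnknownClassError(f"unknown class {class_id!r}")


@dataclass
class TermLexicon:
    """Map from normalized term to the set of classes it may refer to.

    Built from the direct labels of every non-obsolete, labeled class; class
    hierarchy is *not* folded in here (that is what mention propagation and
    :func:`terms_of_class` are for).  A single surface form may name several
    classes; lookup returns all of them.
    """

    terms: dict[str, set[str]] = field(default_factory=dict)
    normalization_policy: str = NORMALIZATION_POLICY

    @classmethod
    def from_graph(cls, graph: OntologyGraph) -> "TermLexicon":
        lex = cls()
        for c in graph.classes.values():
            if c.obsolete:
                continue
            for label in c.labels():
                key = normalize_term(label)
                if key:
                    lex.terms.setdefault(key, set()).add(c.class_id)
        return lex

    def lookup(self, term: str) -> set[str]:
        return self.terms.get(normalize_term(term), set())

    def __contains__(self, normalized: str) -> bool:
        return normalized in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    @property
    def max_term_tokens(self) -> int:
        return max((t.count(" ") + 1 for t in self.terms), default=0)


def terms_of_class(graph: OntologyGraph, class_id: str, lexicon: TermLexicon | None = None) -> set[str]:
    """``Terms(C)``: normalized labels of ``C`` and of every subclass of ``C``.

    The optional lexicon only supplies the normalization policy; the label
    union itself is taken from the graph so the two representations can be
    cross-checked in tests.
    """
    out: set[str] = set()
    for sub in graph.descendants(class_id, include_self=True):
        cls = graph.classes[sub]
        if cls.obsolete:
            continue
        for label in cls.labels():
            key = normalize_term(label)
            if key:
                out.add(key)
    return out


# -- loading ----------------------------------------------------------------


def load_ontology(
    path: str | Path,
    dialect: str = "obo_like",
    labels_path: str | Path | None = None,
) -> OntologyGraph:
    """Load an ontology file and return a validated :class:`OntologyGraph`.

    ``obo_like``: stanza-per-class files with ``[Term]`` headers and ``id:``,
    ``name:``, ``synonym:``, ``alt_id``-style lines.  ``tsv_edges``: ``path``
    is a child<TAB>parent edge list and ``labels_path`` a 2-3 column table
    ``id<TAB>label[<TAB>type]`` with type in {primary, synonym, alt}.
    """
    path = Path(path)
    if dialect == "obo_like":
        classes, edges = _parse_obo_like(path.read_text(encoding="utf-8"))
    elif dialect == "tsv_edges":
        if labels_path is None:
            raise ValueError("tsv_edges dialect requires labels_path")
        classes, edges = _parse_tsv_edges(path, Path(labels_path))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    graph = OntologyGraph()
    for cls in classes:
        graph.add_class(cls)
    for child, parent in edges:
        graph.add_edge(child, parent)
    graph.validate()
    return graph


_SYNONYM_QUOTED_RE = re.compile(r'^"(?P<text>(?:[^"\\]|\\.)*)"')


def _parse_obo_like(text: str) -> tuple[list[OntologyClass], list[tuple[str, str]]]:
    classes: list[OntologyClass] = []
    edges: list[tuple[str, str]] = []
    current: dict | None = None

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        cid = current.get("id")
        if cid is None:
            raise ValueError("stanza without an id: line")
        classes.append(
            OntologyClass(
                class_id=cid,
                primary_label=current.get("name", ""),
                synonyms=frozenset(current["synonyms"]),
                alt_labels=frozenset(current["alt_labels"]),
                obsolete=current["obsolete"],
            )
        )
        edges.extend((cid, parent) for parent in current["is_a"])
        current = None

    for raw in text.splitlines():
        line = raw.split("!")[0].strip() if not raw.lstrip().startswith("!") else ""
        if not line:
            continue
        if line.startswith("["):
            flush()
            current = (
                {"synonyms": set(), "alt_labels": set(), "is_a": [], "obsolete": False}
                if line == "[Term]"
                else None
            )
            continue
        if current is None or ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        if tag == "id":
            current["id"] = value
        elif tag == "name":
            current["name"] = value
        elif tag == "synonym":
            m = _SYNONYM_QUOTED_RE.match(value)
            current["synonyms"].add(m.group("text") if m else value)
        elif tag == "alt_label":
            current["alt_labels"].add(value)
        elif tag == "is_a":
            current["is_a"].append(value.split()[0])
        elif tag == "is_obsolete" and value.lower() == "true":
            current["obsolete"] = True
    flush()
    return classes, edges


def _parse_tsv_edges(edges_path: Path, labels_path: Path) -> tuple[list[OntologyClass], list[tuple[str, str]]]:
    labels: dict[str, dict[str, set[str]]] = {}
    for lineno, raw in enumerate(labels_path.read_text(encoding="utf-8").splitlines(), 1):
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) < 2:
            raise ValueError(f"{labels_path}:{lineno}: expected id<TAB>label[<TAB>type]")
        cid, label = parts[0], parts[1]
        kind = parts[2] if len(parts) > 2 else "primary"
        slot = labels.setdefault(cid, {"primary": set(), "synonym": set(), "alt": set()})
        if kind not in slot:
            raise ValueError(f"{labels_path}:{lineno}: unknown label type {kind!r}")
        slot[kind].add(label)

    edges: list[tuple[str, str]] = []
    ids: set[str] = set(labels)
    for raw in edges_path.read_text(encoding="utf-8").splitlines():
        if not raw.strip():
            continue
        parts = raw.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise ValueError(f"{edges_path}: expected child<TAB>parent rows")
        edges.append((parts[0], parts[1]))
        ids.update(parts)

    classes = []
    for cid in sorted(ids):
        slot = labels.get(cid, {"primary": set(), "synonym": set(), "alt": set()})
        primary = min(slot["primary"]) if slot["primary"] else cid
        classes.append(
            OntologyClass(
                class_id=cid,
                primary_label=primary,
                synonyms=frozenset(slot["synonym"] | (slot["primary"] - {primary})),
                alt_labels=frozenset(slot["alt"]),
            )
        )
    return classes, edges
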