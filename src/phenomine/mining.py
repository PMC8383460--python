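"""Corpus indexing, dictionary-based mention detection and co-occurrence counting.

Documents are title+abstract records.  Mentions of disease and phenotype
classes are found with a longest-match, non-overlapping dictionary matcher
over normalized token n-grams, then closed upward over the subclass
hierarchy (a mention of a class is also a mention of every superclass).
Counting is at abstract level and boolean: a class either occurs in an
abstract or it does not.

The corpus universe for all counts is the *restricted corpus* — abstracts in
which at least one disease and at least one phenotype mention occur.  This
makes the co-occurrence tallies internally consistent for NPMI:
``n_CD <= min(n_C, n_D) <= n_tot``.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .errors import EmptyCorpusError, UnknownClassError
from .ontology import OntologyGraph, TermLexicon, normalize_term

__all__ = [
    "AbstractDoc",
    "CooccurrenceCounts",
    "match_mentions",
    "propagate_mentions",
    "count_cooccurrence",
    "read_corpus",
    "write_corpus",
]

DISEASE = "disease"
PHENOTYPE = "phenotype"


@dataclass(frozen=True)
class AbstractDoc:
    """One title+abstract record."""

    doc_id: str
    title: str
    body: str

    @property
    def text(self) -> str:
        return f"{self.title} {self.body}"


@dataclass
class CooccurrenceCounts:
    """Abstract-level occurrence and co-occurrence tallies over the restricted corpus."""

    n_tot: int = 0
    n_disease: Counter = field(default_factory=Counter)
    n_phenotype: Counter = field(default_factory=Counter)
    n_pair: Counter = field(default_factory=Counter)  # (disease_id, phenotype_id) -> count

    def validate(self) -> None:
        for (c, d), joint in self.n_pair.items():
            if not (0 <= joint <= min(self.n_disease[c], self.n_phenotype[d]) <= self.n_tot):
                raise ValueError(f"inconsistent counts for pair ({c!r}, {d!r})")


def _tokenize(text: str) -> list[str]:
    return normalize_term(text).split()


def match_mentions(
    doc: AbstractDoc,
    lex_disease: TermLexicon,
    lex_phenotype: TermLexicon,
) -> set[tuple[str, str]]:
    """Direct (unpropagated) class mentions in a document.

    Scans the normalized token stream left to right; at each position the
    longest n-gram present in either lexicon wins and consumes its tokens
    (non-overlapping).  A term naming several classes yields all of them.
    Returns ``(class_id, tag)`` pairs with tag disease/phenotype.
    """
    tokens = _tokenize(doc.text)
    max_len = max(lex_disease.max_term_tokens, lex_phenotype.max_term_tokens)
    hits: set[tuple[str, str]] = set()
    i = 0
    while i < len(tokens):
        matched = 0
        for length in range(min(max_len, len(tokens) - i), 0, -1):
            gram = " ".join(tokens[i : i + length])
            found = False
            for lex, tag in ((lex_disease, DISEASE), (lex_phenotype, PHENOTYPE)):
                for cid in lex.terms.get(gram, ()):
                    hits.add((cid, tag))
                    found = True
            if found:
                matched = length
                break
        i += matched or 1
    return hits


def propagate_mentions(
    hits: Iterable[tuple[str, str]],
    g_disease: OntologyGraph,
    g_phenotype: OntologyGraph,
    propagate_disease: bool = True,
) -> set[tuple[str, str]]:
    """Close a mention set under superclass addition within each ontology.

    Phenotype-side propagation is always applied; the disease side mirrors it
    by default and can be switched off to count diseases only at the
    mentioned class.
    """
    graphs = {DISEASE: g_disease, PHENOTYPE: g_phenotype}
    out: set[tuple[str, str]] = set()
    for cid, tag in hits:
        g = graphs[tag]
        if cid not in g:
            raise UnknownClassError(f"mention of unknown {tag} class {cid!r}")
        out.add((cid, tag))
        if tag == PHENOTYPE or propagate_disease:
            out.update((a, tag) for a in g.ancestors(cid))
    return out


def count_cooccurrence(
    corpus: Iterable[AbstractDoc],
    lex_disease: TermLexicon,
    lex_phenotype: TermLexicon,
    g_disease: OntologyGraph,
    g_phenotype: OntologyGraph,
    propagate_disease: bool = True,
) -> CooccurrenceCounts:
    """Stream a corpus once and tally propagated occurrence/co-occurrence counts.

    Only abstracts mentioning at least one disease *and* one phenotype enter
    the restricted corpus; all four tallies are over that restriction.
    """
    counts = CooccurrenceCounts()
    for doc in corpus:
        direct = match_mentions(doc, lex_disease, lex_phenotype)
        closed = propagate_mentions(direct, g_disease, g_phenotype, propagate_disease)
        diseases = {cid for cid, tag in closed if tag == DISEASE}
        phenotypes = {cid for cid, tag in closed if tag == PHENOTYPE}
        if not diseases or not phenotypes:
            continue
        counts.n_tot += 1
        counts.n_disease.update(diseases)
        counts.n_phenotype.update(phenotypes)
        counts.n_pair.update((c, d) for c in diseases for d in phenotypes)
    if counts.n_tot == 0:
        raise EmptyCorpusError("no abstract contains both a disease and a phenotype mention")
    counts.validate()
    return counts


# -- corpus I/O -------------------------------------------------------------


def read_corpus(path: str | Path) -> Iterator[AbstractDoc]:
    """Read a line-delimited corpus; ``.jsonl`` records or 3-column TSV."""
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if path.suffix == ".jsonl":
                rec = json.loads(line)
                yield AbstractDoc(str(rec["doc_id"]), rec.get("title", ""), rec.get("body", ""))
            else:
                parts = line.split("\t")
                if len(parts) != 3:
                    raise ValueError(f"{path}:{lineno}: expected doc_id<TAB>title<TAB>body")
                yield AbstractDoc(*parts)


def write_corpus(docs: Iterable[AbstractDoc], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            if path.suffix == ".jsonl":
                fh.write(json.dumps({"doc_id": doc.doc_id, "title": doc.title, "body": doc.body}) + "\n")
            else:
                fh.write(f"{doc.doc_id}\t{doc.title}\t{doc.body}\n")
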