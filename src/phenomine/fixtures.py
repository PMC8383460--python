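"""Seeded synthetic fixtures: toy ontologies, corpora with planted
co-occurrence structure, mapping bridges, gold standards and gene profiles.

These generators stand in for the real-world inputs of a disease-phenotype
association study (a PubMed-scale abstract corpus, UMLS/Wikidata mapping
tables, curated annotation databases) at desk scale.  Everything is a pure
function of a :class:`FixtureSpec` and its seed.

The corpus generator plants a set of disease-phenotype pairs that co-occur
in documents at rate ``p_planted`` against a background co-mention rate
``p_background`` for all other leaf pairs; recovering the planted set by
NPMI ranking is the headline recovery benchmark.  Labels are multi-token
adjective-noun strings, child labels sometimes extend their parent's label,
so token-boundary matching, longest-match resolution and lexical superclass
containment are all exercised by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from .embedding import EntityProfile
from .harvest import MappingTable
from .mining import AbstractDoc
from .ontology import OntologyClass, OntologyGraph, TermLexicon

__all__ = [
    "FixtureSpec",
    "GoldAndBridges",
    "gen_ontology",
    "gen_planted_pairs",
    "gen_corpus",
    "gen_gold_and_bridges",
    "write_fixture_dir",
]

_ADJECTIVES = (
    "azure", "crimson", "umber", "viridian", "ochre", "cobalt", "sable", "ivory",
    "amber", "teal", "scarlet", "indigo", "sepia", "pearl", "onyx", "coral",
    "fawn", "slate", "russet", "jade", "lilac", "maroon", "ebony", "saffron",
    "cerise", "tawny", "hazel", "mauve", "auburn", "beryl",
)
_MODIFIERS = ("chronic", "acute", "juvenile", "recurrent", "atypical", "familial", "transient", "severe")
_DISEASE_NOUNS = (
    "carditis", "nephrosis", "myopathy", "dermatosis", "colitis", "hepatitis",
    "neuritis", "arthrosis", "gastritis", "pneumonitis", "angiopathy", "keratosis",
    "cystitis", "myelosis", "adenitis", "fibromatosis", "osteitis", "vasculitis",
    "encephalosis", "pleuritis",
)
_PHENOTYPE_NOUNS = (
    "tremor", "pallor", "edema", "fibrosis", "atrophy", "cyanosis", "ataxia",
    "dysplasia", "sclerosis", "hypotonia", "macrocephaly", "anemia", "alopecia",
    "petechiae", "stenosis", "hyperplasia", "nystagmus", "erythema", "dystonia",
    "paresis",
)
_FILLERS = (
    "we", "report", "a", "series", "of", "patients", "presenting", "with",
    "findings", "consistent", "in", "this", "cohort", "study", "observed",
    "clinical", "features", "were", "assessed", "and", "the", "outcomes",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for every synthetic generator.

    ``hierarchy_depth``/``branching`` shape both toy ontologies (a complete
    tree plus a few seeded extra DAG parents); ``n_docs`` abstracts are
    generated with ``n_planted_pairs`` leaf-level disease-phenotype pairs
    co-mentioned at rate ``p_planted`` against ``p_background`` elsewhere.
    """

    hierarchy_depth: int = 3
    branching: int = 3
    n_disease_classes: int | None = None  # optional cap on class count
    n_phenotype_classes: int | None = None
    n_docs: int = 2000
    p_planted: float = 0.3
    p_background: float = 0.02
    n_planted_pairs: int = 20
    synonym_rate: float = 0.3
    lone_mention_rate: float = 0.2
    extra_parent_rate: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_background < self.p_planted <= 1.0:
            raise ValueError("need 0 <= p_background < p_planted <= 1")
        for name in ("hierarchy_depth", "branching", "n_docs", "n_planted_pairs"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")


def _unique_label(rng: np.random.Generator, nouns: tuple[str, ...], used: set[str]) -> str:
    while True:
        label = f"{_ADJECTIVES[rng.integers(len(_ADJECTIVES))]} {nouns[rng.integers(len(nouns))]}"
        if label not in used:
            used.add(label)
            return label


def gen_ontology(spec: FixtureSpec, kind: str) -> tuple[OntologyGraph, TermLexicon]:
    """Seeded random rooted DAG with generated labels and synonyms.

    ``disease`` kind uses ICD-style ids with dotted-code children (B00 ->
    B00.0) to exercise code-syntax parenting; ``phenotype`` kind uses
    HP-style ids.  With probability ``extra_parent_rate`` a node gains a
    second parent from a shallower level, so the graph is a true DAG.
    Child labels extend their parent's label with a modifier ~30% of the
    time, planting longest-match and lexical-containment cases.
    """
    if kind not in ("disease", "phenotype"):
        raise ValueError(f"kind must be disease or phenotype, got {kind!r}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 101 if kind == "disease" else 202]))
    nouns = _DISEASE_NOUNS if kind == "disease" else _PHENOTYPE_NOUNS
    cap = spec.n_disease_classes if kind == "disease" else spec.n_phenotype_classes

    used_labels: set[str] = set()
    classes: list[OntologyClass] = []
    edges: list[tuple[str, str]] = []
    labels: dict[str, str] = {}
    levels: list[list[str]] = []

    def next_id(level: int, ordinal: int, parent_id: str | None) -> str:
        if kind == "phenotype":
            return f"HP:{7000000 + len(classes):07d}"[:10]
        if level == 0:
            return "A00"
        if level == 1:
            return f"B{ordinal:02d}"
        if level == 2 and parent_id is not None and "." not in parent_id:
            return f"{parent_id}.{ordinal}"
        return f"{parent_id}x{ordinal}" if parent_id else f"Z{ordinal:02d}"

    def make_class(level: int, ordinal: int, parent_id: str | None) -> str:
        cid = next_id(level, ordinal, parent_id)
        if parent_id is not None and rng.random() < 0.3:
            base = labels[parent_id]
            label = f"{_MODIFIERS[rng.integers(len(_MODIFIERS))]} {base}"
            if label in used_labels:
                label = _unique_label(rng, nouns, used_labels)
            else:
                used_labels.add(label)
        else:
            label = _unique_label(rng, nouns, used_labels)
        synonyms: set[str] = set()
        if rng.random() < spec.synonym_rate:
            synonyms.add(_unique_label(rng, nouns, used_labels))
        labels[cid] = label
        classes.append(OntologyClass(cid, label, frozenset(synonyms)))
        return cid

    root = make_class(0, 0, None)
    levels.append([root])
    counter = {"lvl1": 0}
    for depth in range(1, spec.hierarchy_depth + 1):
        level_nodes: list[str] = []
        for parent in levels[depth - 1]:
            for b in range(spec.branching):
                if cap is not None and len(classes) >= cap:
                    break
                ordinal = counter["lvl1"] if depth == 1 else b
                if depth == 1:
                    counter["lvl1"] += 1
                cid = make_class(depth, ordinal, parent)
                edges.append((cid, parent))
                # occasional second parent from a shallower level keeps it a DAG
                if depth >= 2 and rng.random() < spec.extra_parent_rate:
                    pool = [n for n in levels[depth - 1] if n != parent]
                    if pool:
                        edges.append((cid, pool[rng.integers(len(pool))]))
                level_nodes.append(cid)
        levels.append(level_nodes)
    graph = OntologyGraph(classes, edges)
    return graph, TermLexicon.from_graph(graph)


def _leaves(g: OntologyGraph) -> list[str]:
    return sorted(c for c in g.classes if not g.children(c))


def gen_planted_pairs(spec: FixtureSpec, g_d: OntologyGraph, g_p: OntologyGraph) -> list[tuple[str, str]]:
    """Distinct leaf-level (disease, phenotype) pairs to plant in the corpus."""
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 303]))
    d_leaves, p_leaves = _leaves(g_d), _leaves(g_p)
    all_pairs = [(d, p) for d in d_leaves for p in p_leaves]
    if spec.n_planted_pairs > len(all_pairs):
        raise ValueError("more planted pairs requested than leaf pairs available")
    idx = rng.choice(len(all_pairs), size=spec.n_planted_pairs, replace=False)
    return sorted(all_pairs[i] for i in idx)


def _mention(rng: np.random.Generator, g: OntologyGraph, cid: str) -> str:
    cls = g.classes[cid]
    options = [cls.primary_label, *sorted(cls.synonyms)]
    return options[rng.integers(len(options))]


def gen_corpus(
    spec: FixtureSpec,
    g_d: OntologyGraph,
    g_p: OntologyGraph,
    planted: list[tuple[str, str]],
) -> tuple[list[AbstractDoc], set[tuple[str, str]]]:
    """Corpus with planted co-mentions; returns (docs, planted truth set).

    Per document, each planted pair co-occurs with probability ``p_planted``
    and every other leaf pair with ``p_background``; lone disease-only or
    phenotype-only mentions are added at ``lone_mention_rate`` to exercise
    the restricted-corpus rule.  Mentions use a random label or synonym,
    shuffled in with filler words.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 404]))
    planted_set = set(planted)
    d_leaves, p_leaves = _leaves(g_d), _leaves(g_p)
    background = [(d, p) for d in d_leaves for p in p_leaves if (d, p) not in planted_set]

    fire_planted = rng.random((spec.n_docs, len(planted))) < spec.p_planted
    fire_background = rng.random((spec.n_docs, len(background))) < spec.p_background

    docs: list[AbstractDoc] = []
    for i in range(spec.n_docs):
        diseases: set[str] = set()
        phenotypes: set[str] = set()
        for j in np.flatnonzero(fire_planted[i]):
            d, p = planted[j]
            diseases.add(d)
            phenotypes.add(p)
        for j in np.flatnonzero(fire_background[i]):
            d, p = background[j]
            diseases.add(d)
            phenotypes.add(p)
        if rng.random() < spec.lone_mention_rate:
            diseases.add(d_leaves[rng.integers(len(d_leaves))])
        if rng.random() < spec.lone_mention_rate:
            phenotypes.add(p_leaves[rng.integers(len(p_leaves))])

        phrases = [_mention(rng, g_d, d) for d in sorted(diseases)]
        phrases += [_mention(rng, g_p, p) for p in sorted(phenotypes)]
        rng.shuffle(phrases)
        words: list[str] = []
        for phrase in phrases:
            words.extend(_FILLERS[rng.integers(len(_FILLERS))] for _ in range(2))
            words.append(phrase)
        words.extend(_FILLERS[rng.integers(len(_FILLERS))] for _ in range(3))
        # split on a word boundary so no mention straddles title and body
        cut = max(1, len(words) // 4)
        docs.append(
            AbstractDoc(
                doc_id=f"PMID:{i + 1}",
                title=" ".join(words[:cut]),
                body=" ".join(words[cut:]),
            )
        )
    return docs, planted_set


@dataclass
class GoldAndBridges:
    """Planted evaluation artefacts derived from one corpus truth set."""

    gold: set[tuple[str, str]]  # expert-style gold standard (some ancestor-level)
    bridge: MappingTable  # OMIM-style -> ICD-style mapping with injected wrong links
    omim_associations: list[tuple[str, str]]  # (omim_id, phenotype_id)
    omim_of_disease: dict[str, str]
    gene_profiles: list[EntityProfile]
    gene_disease: list[tuple[str, str]]  # ground-truth gene -> disease links


def gen_gold_and_bridges(
    spec: FixtureSpec,
    g_d: OntologyGraph,
    g_p: OntologyGraph,
    planted: Iterable[tuple[str, str]],
    ancestor_rate: float = 0.25,
    wrong_link_rate: float = 0.0,
    gene_noise: float = 0.0,
) -> GoldAndBridges:
    """Gold standard, mapping bridge and gene-phenotype table from planted truth.

    ``ancestor_rate`` of gold pairs are lifted to a proper ancestor of the
    planted phenotype (strict-vs-soft divergence); ``wrong_link_rate`` of
    bridge rows point at the wrong disease code (emulating noisy
    cross-terminology mappings); genes carry noisy copies of their disease's
    phenotype profile.
    """
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 505]))
    planted = sorted(set(planted))
    p_leaves = _leaves(g_p)

    gold: set[tuple[str, str]] = set()
    for d, p in planted:
        if rng.random() < ancestor_rate:
            ancestors = sorted(g_p.ancestors(p))
            if ancestors:
                p = ancestors[rng.integers(len(ancestors))]
        gold.add((d, p))

    diseases = sorted({d for d, _ in planted})
    omim_of = {d: f"OMIM:{600000 + i}" for i, d in enumerate(diseases)}
    d_all = sorted(g_d.classes)
    rows = []
    for i, d in enumerate(diseases):
        target = d
        if rng.random() < wrong_link_rate:
            wrong = [c for c in d_all if c != d]
            target = wrong[rng.integers(len(wrong))]
        rows.append((omim_of[d], target, "umls" if i % 2 == 0 else "wikidata"))
    bridge = MappingTable(rows=rows, direction="OMIM->ICD-10")

    omim_assoc = sorted((omim_of[d], p) for d, p in planted)

    profile_of: dict[str, set[str]] = {}
    for d, p in planted:
        profile_of.setdefault(d, set()).add(p)
    gene_profiles: list[EntityProfile] = []
    gene_disease: list[tuple[str, str]] = []
    for i, d in enumerate(diseases):
        phens = set(profile_of[d])
        noisy = {
            p_leaves[rng.integers(len(p_leaves))] if rng.random() < gene_noise else p
            for p in phens
        }
        gene = f"GENE:{i + 1:04d}"
        gene_profiles.append(EntityProfile(gene, "gene", frozenset(noisy)))
        gene_disease.append((gene, d))
    return GoldAndBridges(gold, bridge, omim_assoc, omim_of, gene_profiles, gene_disease)


def write_ontology_obo(g: OntologyGraph, path: str | Path) -> None:
    """Serialize a graph in the OBO-like stanza dialect the loader reads."""
    with Path(path).open("w", encoding="utf-8") as fh:
        for cid in sorted(g.classes):
            cls = g.classes[cid]
            fh.write("[Term]\n")
            fh.write(f"id: {cid}\n")
            fh.write(f"name: {cls.primary_label}\n")
            for syn in sorted(cls.synonyms):
                fh.write(f'synonym: "{syn}" EXACT []\n')
            for parent in sorted(g.parents(cid)):
                fh.write(f"is_a: {parent}\n")
            fh.write("\n")


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, str]:
    """Generate the full fixture family and write it in the dialects the
    pipeline commands read; returns {artifact: path}."""
    from .harvest import DEFAULT_GENERIC_PHENOTYPES
    from .mining import write_corpus

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    g_d, _ = gen_ontology(spec, "disease")
    g_p, _ = gen_ontology(spec, "phenotype")
    planted = gen_planted_pairs(spec, g_d, g_p)
    docs, _ = gen_corpus(spec, g_d, g_p, planted)
    extras = gen_gold_and_bridges(spec, g_d, g_p, planted, wrong_link_rate=0.1, gene_noise=0.1)

    paths = {
        "disease_ontology": out / "disease.obo",
        "phenotype_ontology": out / "phenotype.obo",
        "corpus": out / "corpus.jsonl",
        "gold": out / "gold.tsv",
        "bridge": out / "bridge.tsv",
        "omim_associations": out / "omim_assoc.tsv",
        "gene_profiles": out / "gene_profiles.tsv",
        "common_ids": out / "common_ids.txt",
        "block_list": out / "block_list.txt",
    }
    write_ontology_obo(g_d, paths["disease_ontology"])
    write_ontology_obo(g_p, paths["phenotype_ontology"])
    write_corpus(docs, paths["corpus"])
    paths["gold"].write_text(
        "".join(f"{d}\t{p}\n" for d, p in sorted(extras.gold)), encoding="utf-8"
    )
    paths["bridge"].write_text(
        "".join(f"{s}\t{t}\t{r}\n" for s, t, r in extras.bridge.rows), encoding="utf-8"
    )
    paths["omim_associations"].write_text(
        "".join(f"{o}\t{p}\n" for o, p in extras.omim_associations), encoding="utf-8"
    )
    paths["gene_profiles"].write_text(
        "".join(
            f"{g.entity_id}\t{'|'.join(sorted(g.phenotypes))}\n" for g in extras.gene_profiles
        ),
        encoding="utf-8",
    )
    paths["common_ids"].write_text(
        "".join(f"{d}\n" for d in sorted({d for d, _ in planted})), encoding="utf-8"
    )
    paths["block_list"].write_text(
        "".join(f"{p}\n" for p in sorted(DEFAULT_GENERIC_PHENOTYPES)), encoding="utf-8"
    )
    return {k: str(v) for k, v in paths.items()}
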