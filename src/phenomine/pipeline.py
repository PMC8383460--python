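"""End-to-end pipeline orchestration with run manifests.

Two pipelines mirror the two association-generation strategies:

* ``run_textmine``: load ontologies -> match mentions -> count propagated
  co-occurrence -> NPMI score -> optional rank threshold -> scores TSV.
* ``run_harvest``: bridge curated source tables -> merge/dedup -> generic
  filter -> ICD-hierarchy propagation -> lexical superclass propagation ->
  optional common-disease restriction -> optional curation overrides ->
  released TSV + provenance summary.

Each run writes a JSON manifest recording the configuration, per-stage
counts and a sha256 of every output file, so a rerun can be checked for
byte-identical reproduction.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import harvest as hv
from .mining import count_cooccurrence, read_corpus
from .npmi import score_all, threshold_profile, write_scores
from .ontology import TermLexicon, load_ontology

__all__ = ["RunConfig", "run_textmine", "run_harvest"]


@dataclass
class RunConfig:
    """Paths and knobs for one pipeline run; serialized into the manifest."""

    out_dir: str
    disease_ontology: str | None = None
    phenotype_ontology: str | None = None
    corpus: str | None = None
    omim_associations: str | None = None
    bridge: str | None = None
    direct_associations: str | None = None
    block_list: str | None = None
    common_ids: str | None = None
    overrides: str | None = None
    min_npmi: float = 0.0
    top_k: int | None = None
    propagate_disease: bool = True
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"config field {name!r} is required for this pipeline")
            if not Path(value).exists():
                raise FileNotFoundError(f"{name}: no such file {value!r}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_manifest(out_dir: Path, pipeline: str, cfg: RunConfig, stages: dict, outputs: list[Path]) -> Path:
    manifest = {
        "pipeline": pipeline,
        "config": asdict(cfg),
        "stages": stages,
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    path = out_dir / f"{pipeline}_manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path


def run_textmine(cfg: RunConfig) -> dict:
    """Text-mining pipeline; returns the manifest dict."""
    cfg.require("disease_ontology", "phenotype_ontology", "corpus")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    g_d = load_ontology(cfg.disease_ontology)
    g_p = load_ontology(cfg.phenotype_ontology)
    lex_d = TermLexicon.from_graph(g_d)
    lex_p = TermLexicon.from_graph(g_p)
    stages = {"disease_classes": len(g_d), "phenotype_classes": len(g_p)}

    counts = count_cooccurrence(
        read_corpus(cfg.corpus), lex_d, lex_p, g_d, g_p, propagate_disease=cfg.propagate_disease
    )
    stages["restricted_corpus"] = counts.n_tot
    stages["observed_pairs"] = len(counts.n_pair)

    scores = [s for s in score_all(counts, positive_only=True) if s.npmi > cfg.min_npmi]
    stages["positive_associations"] = len(scores)
    if cfg.top_k is not None:
        profile = threshold_profile(scores, cfg.top_k)
        scores = [s for s in scores if s.phenotype_id in profile.get(s.disease_id, ())]
        stages["thresholded_associations"] = len(scores)

    scores_path = out_dir / "textmine_scores.tsv"
    write_scores(scores, scores_path)
    manifest_path = _write_manifest(out_dir, "textmine", cfg, stages, [scores_path])
    return json.loads(manifest_path.read_text(encoding="utf-8"))


def run_harvest(cfg: RunConfig) -> dict:
    """Semi-automatic harvesting pipeline; returns the manifest dict."""
    cfg.require("omim_associations", "bridge")
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stages: dict = {}

    omim_assoc = [
        tuple(line.split("\t")[:2])
        for line in Path(cfg.omim_associations).read_text(encoding="utf-8").splitlines()
        if line.strip() and not line.startswith("#")
    ]
    bridge = hv.MappingTable.from_tsv(cfg.bridge, direction="OMIM->ICD-10")
    bridged = hv.bridge_associations(omim_assoc, bridge)
    stages["bridged"] = len(bridged.records)
    stages["unmapped_source_diseases"] = len(bridged.unmapped)

    records = list(bridged.records)
    if cfg.direct_associations:
        records.extend(hv.read_associations(cfg.direct_associations))
    records = hv.dedup_records(records)
    stages["merged_unique_pairs"] = len(records)

    generic = (
        hv.GenericPhenotypeFilter.from_file(cfg.block_list)
        if cfg.block_list
        else hv.GenericPhenotypeFilter()
    )
    records, removed = hv.filter_generic(records, generic)
    stages["generic_filtered"] = len(removed)

    g_icd = load_ontology(cfg.disease_ontology) if cfg.disease_ontology else None
    prop = hv.propagate_icd(records, g_icd)
    stages["prop_icd"] = len(prop)
    records = records + prop

    if cfg.phenotype_ontology:
        g_p = load_ontology(cfg.phenotype_ontology)
        lex_p = TermLexicon.from_graph(g_p)
        if g_icd is not None:
            disease_labels = {
                (cid, g_icd.classes[cid].primary_label) for cid in g_icd.classes
            }
            lexical = hv.propagate_lexical(disease_labels, lex_p, records)
            # lexically inherited phenotypes are still subject to the block list
            lexical, removed_lex = hv.filter_generic(lexical, generic)
            stages["prop_lexical"] = len(lexical)
            records = records + lexical

    if cfg.common_ids:
        ids = {
            line.strip()
            for line in Path(cfg.common_ids).read_text(encoding="utf-8").splitlines()
            if line.strip()
        }
        records = hv.select_common(records, ids)
        stages["after_common_restriction"] = len(records)

    removed_fp: list = []
    if cfg.overrides:
        overrides = [
            tuple(line.split("\t")[:3])
            for line in Path(cfg.overrides).read_text(encoding="utf-8").splitlines()
            if line.strip() and not line.startswith("#")
        ]
        result = hv.apply_curation(records, overrides)
        records, removed_fp = result.released, result.removed
        stages["curation_removed"] = len(removed_fp)
        stages["curation_missing_removals"] = len(result.missing_removals)

    stages["released"] = len(records)
    summary = hv.provenance_summary(records)

    released_path = out_dir / "harvest_released.tsv"
    hv.write_associations(records, released_path)
    summary_path = out_dir / "harvest_provenance.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    manifest_path = _write_manifest(out_dir, "harvest", cfg, stages, [released_path, summary_path])
    return json.loads(manifest_path.read_text(encoding="utf-8"))
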