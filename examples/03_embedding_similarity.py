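"""Recover gene-disease links from phenotype-profile embedding similarity.

Diseases and genes are embedded from a shared annotation graph (ontology
subclass edges + entity-phenotype edges) via random walks and skip-gram;
cosine similarity between a gene and a disease vector ranks candidate links.
"""

from phenomine import FixtureSpec, cosine, embed_profiles, roc_auc
from phenomine.embedding import EntityProfile
from phenomine.fixtures import gen_gold_and_bridges, gen_ontology, gen_planted_pairs

spec = FixtureSpec(n_docs=50, seed=5)
g_d, _ = gen_ontology(spec, "disease")
g_p, _ = gen_ontology(spec, "phenotype")
planted = gen_planted_pairs(spec, g_d, g_p)
extras = gen_gold_and_bridges(spec, g_d, g_p, planted, gene_noise=0.1)

profile_of: dict[str, set] = {}
for d, p in planted:
    profile_of.setdefault(d, set()).add(p)
diseases = [EntityProfile(d, "disease", frozenset(ps)) for d, ps in sorted(profile_of.items())]

space = embed_profiles(g_p, diseases + extras.gene_profiles, dim=64, seed=1)
print(f"embedded {len(space.vectors)} nodes in {space.dim} dimensions")

links = set(extras.gene_disease)
pairs = [
    (cosine(space[g.entity_id], space[d.entity_id]),
     "pos" if (g.entity_id, d.entity_id) in links else "neg")
    for g in extras.gene_profiles
    for d in diseases
]
print(f"gene-disease ranking AUC over {len(pairs)} candidate pairs: "
      f"{roc_auc(pairs):.3f}")
# Genes carry noisy copies of their disease's phenotype profile, so the true
# gene-disease pairs should receive the highest cosine similarities.
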