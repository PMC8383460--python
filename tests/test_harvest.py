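"""Bridging, filtering, propagation and curation of curated associations."""

import pytest

from phenomine.errors import MappingParseError
from phenomine.harvest import (
    DEFAULT_GENERIC_PHENOTYPES,
    AssociationRecord,
    GenericPhenotypeFilter,
    MappingTable,
    apply_curation,
    bridge_associations,
    dedup_records,
    filter_generic,
    propagate_icd,
    propagate_lexical,
    provenance_summary,
    read_associations,
    select_common,
    write_associations,
)
from phenomine.ontology import TermLexicon

from conftest import make_graph


def rec(d, p, prov="umls_direct"):
    return AssociationRecord(d, p, prov)


class TestBridge:
    def test_one_disease_two_phenotypes(self):
        bridge = MappingTable(rows=[("OMIM:1", "A10", "umls")])
        out = bridge_associations([("OMIM:1", "HP:1"), ("OMIM:1", "HP:2")], bridge)
        assert {r.pair for r in out.records} == {("A10", "HP:1"), ("A10", "HP:2")}
        assert all(r.provenance == "hpo_via_umls" for r in out.records)

    def test_fan_out_to_two_codes(self):
        bridge = MappingTable(rows=[("OMIM:1", "A10", "umls"), ("OMIM:1", "B20", "wikidata")])
        out = bridge_associations([("OMIM:1", "HP:1")], bridge)
        got = {(r.disease_id, r.provenance) for r in out.records}
        assert got == {("A10", "hpo_via_umls"), ("B20", "hpo_via_wikidata")}

    def test_unmapped_reported(self):
        bridge = MappingTable(rows=[("OMIM:1", "A10", "umls")])
        out = bridge_associations([("OMIM:2", "HP:1")], bridge)
        assert out.records == [] and out.unmapped == ["OMIM:2"]

    def test_matches_nested_loop_join_oracle(self):
        rows = [(f"OMIM:{i}", f"C{i % 4}{j}", "umls" if j else "wikidata") for i in range(10) for j in range(2)]
        bridge = MappingTable(rows=rows)
        assoc = [(f"OMIM:{i}", f"HP:{k}") for i in range(12) for k in range(3)]
        out = bridge_associations(assoc, bridge)
        mapping = {}
        for s, t, r in rows:
            mapping.setdefault(s, []).append((t, r))
        expected = {
            (t, p, "hpo_via_umls" if r == "umls" else "hpo_via_wikidata")
            for s, p in assoc
            for t, r in mapping.get(s, [])
        }
        assert {(r.disease_id, r.phenotype_id, r.provenance) for r in out.records} == expected
        assert out.unmapped == ["OMIM:10", "OMIM:11"]

    def test_malformed_row_raises(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("OMIM:1\tA10\n")
        with pytest.raises(MappingParseError):
            MappingTable.from_tsv(path)


class TestFilterGeneric:
    def test_blocklisted_example_removed(self):
        records = [rec("A10", "HP:0000006"), rec("A10", "HP:0001250")]
        kept, removed = filter_generic(records)
        assert [r.phenotype_id for r in kept] == ["HP:0001250"]
        assert [r.phenotype_id for r in removed] == ["HP:0000006"]

    def test_default_blocklist_holds_the_five_examples(self):
        assert DEFAULT_GENERIC_PHENOTYPES == {
            "HP:0000005", "HP:0000006", "HP:0012824", "HP:0025285", "HP:0012834",
        }

    def test_empty_blocklist_is_identity(self):
        records = [rec("A10", "HP:0000006")]
        kept, removed = filter_generic(records, GenericPhenotypeFilter(frozenset()))
        assert kept == records and removed == []

    def test_matches_set_difference_oracle(self):
        blocked = frozenset({f"HP:{i}" for i in range(0, 50, 7)})
        records = [rec(f"D{i % 9}", f"HP:{i}") for i in range(100)]
        kept, removed = filter_generic(records, GenericPhenotypeFilter(blocked))
        assert {r.phenotype_id for r in kept} == {r.phenotype_id for r in records} - blocked
        assert len(kept) + len(removed) == len(records)


class TestPropagateIcd:
    def test_g30_fixture_emits_four(self, g30_graph):
        records = [rec("G30", "HP:0001")]
        new = propagate_icd(records, g30_graph)
        assert {r.disease_id for r in new} == {"G30.0", "G30.1", "G30.8", "G30.9"}
        assert all(r.provenance == "prop_icd" and r.phenotype_id == "HP:0001" for r in new)

    def test_leaf_disease_adds_nothing(self, g30_graph):
        assert propagate_icd([rec("G30.0", "HP:0001")], g30_graph) == []

    def test_existing_child_annotation_not_duplicated(self, g30_graph):
        records = [rec("G30", "HP:0001"), rec("G30.1", "HP:0001", "wikidata")]
        new = propagate_icd(records, g30_graph)
        assert {r.disease_id for r in new} == {"G30.0", "G30.8", "G30.9"}

    def test_idempotence(self, g30_graph):
        records = [rec("G30", "HP:0001"), rec("G30", "HP:0002")]
        first = propagate_icd(records, g30_graph)
        second = propagate_icd(records + first, g30_graph)
        assert second == []

    def test_unknown_disease_skipped(self, g30_graph):
        assert propagate_icd([rec("Z99", "HP:0001")], g30_graph) == []

    def test_code_syntax_fallback_without_graph(self):
        records = [rec("G30", "HP:0001"), rec("G30.0", "HP:0009", "wikidata")]
        new = propagate_icd(records, None)
        # fallback sees only codes present in the input
        assert {(r.disease_id, r.phenotype_id) for r in new} == {("G30.0", "HP:0001")}

    def test_matches_descendant_expansion_oracle(self, fixture_world):
        g_d = fixture_world["g_d"]
        some = sorted(g_d.classes)[:12]
        records = [rec(d, f"HP:{i:04d}") for i, d in enumerate(some)]
        new = propagate_icd(records, g_d)
        existing = {r.pair for r in records}
        expected = set()
        for r in records:
            for child in g_d.descendants(r.disease_id):
                if (child, r.phenotype_id) not in existing:
                    expected.add((child, r.phenotype_id))
        assert {r.pair for r in new} == expected

    def test_commutes_with_generic_filter(self, g30_graph):
        blocked = GenericPhenotypeFilter(frozenset({"HP:0000006"}))
        records = [rec("G30", "HP:0000006"), rec("G30", "HP:0001")]
        filter_then_prop = filter_generic(records, blocked)[0]
        filter_then_prop = filter_then_prop + propagate_icd(filter_then_prop, g30_graph)
        prop_first = records + propagate_icd(records, g30_graph)
        prop_then_filter = filter_generic(prop_first, blocked)[0]
        assert {r.pair for r in filter_then_prop} == {r.pair for r in prop_then_filter}


class TestPropagateLexical:
    @pytest.fixture(scope="class")
    @classmethod
    def hpo_lex(cls):
        g = make_graph({"HP:0032551": "hemorrhoids", "HP:0000010": "nocturia"}, [])
        return TermLexicon.from_graph(g)

    def test_hemorrhoids_example(self, hpo_lex):
        out = propagate_lexical(
            [("I84.4", "external hemorrhoids with complications")], hpo_lex, []
        )
        assert [(r.disease_id, r.phenotype_id) for r in out] == [("I84.4", "HP:0032551")]
        assert out[0].provenance == "prop_lexical"

    def test_no_shared_token_no_record(self, hpo_lex):
        assert propagate_lexical([("A10", "azure carditis")], hpo_lex, []) == []

    def test_already_annotated_disease_ineligible(self, hpo_lex):
        existing = [rec("I84.4", "HP:0000010", "wikidata")]
        assert propagate_lexical(
            [("I84.4", "external hemorrhoids with complications")], hpo_lex, existing
        ) == []

    def test_longest_label_wins(self):
        g = make_graph(
            {"HP:1": "glaucoma", "HP:2": "open angle glaucoma"}, []
        )
        lex = TermLexicon.from_graph(g)
        out = propagate_lexical([("H40.1", "primary open angle glaucoma")], lex, [])
        assert [(r.disease_id, r.phenotype_id) for r in out] == [("H40.1", "HP:2")]

    def test_matches_all_pairs_containment_oracle(self, fixture_world):
        g_p, lex_p = fixture_world["g_p"], fixture_world["lex_p"]
        g_d = fixture_world["g_d"]
        diseases = sorted((cid, g_d.classes[cid].primary_label) for cid in g_d.classes)[:30]
        out = propagate_lexical(diseases, lex_p, [])
        got = {(r.disease_id, r.phenotype_id) for r in out}
        from phenomine.ontology import normalize_term
        expected = set()
        for cid, label in diseases:
            tokens = normalize_term(label).split()
            matches = []
            for term, classes in lex_p.terms.items():
                t = term.split()
                for i in range(len(tokens) - len(t) + 1):
                    if tokens[i : i + len(t)] == t:
                        matches.append((len(t), classes))
                        break
            if matches:
                best = max(m[0] for m in matches)
                for n, classes in matches:
                    if n == best:
                        expected.update((cid, c) for c in classes)
        assert got == expected


class TestSelectCommonAndCuration:
    def test_empty_common_list(self):
        assert select_common([rec("A10", "HP:1")], set()) == []

    def test_full_common_list_is_identity(self):
        records = [rec("A10", "HP:1"), rec("B20", "HP:2")]
        assert select_common(records, {"A10", "B20"}) == records

    def test_membership_filter_oracle(self):
        records = [rec(f"D{i}", f"HP:{i}") for i in range(50)]
        ids = {f"D{i}" for i in range(0, 50, 3)}
        out = select_common(records, ids)
        assert {r.disease_id for r in out} == ids
        assert len(out) == len([r for r in records if r.disease_id in ids])

    def test_remove_and_add(self):
        records = [rec("A10", "HP:1"), rec("A10", "HP:2"), rec("B20", "HP:3")]
        result = apply_curation(records, [("A10", "HP:2", "remove"), ("C30", "HP:9", "add")])
        assert len(result.released) == 3
        assert sum(1 for r in result.released if r.provenance == "expert") == 1
        assert [r.pair for r in result.removed] == [("A10", "HP:2")]
        assert all(r.curation_status == "removed_fp" for r in result.removed)

    def test_empty_overrides_identity(self):
        records = [rec("A10", "HP:1")]
        result = apply_curation(records, [])
        assert result.released == records and result.removed == []

    def test_remove_absent_pair_reported(self):
        result = apply_curation([rec("A10", "HP:1")], [("A10", "HP:9", "remove")])
        assert result.missing_removals == [("A10", "HP:9")]
        assert len(result.released) == 1

    def test_matches_sequential_replay_oracle(self):
        import random

        rng = random.Random(13)
        records = [rec(f"D{i % 7}", f"HP:{i % 11}", "wikidata") for i in range(40)]
        records = dedup_records(records)
        overrides = []
        for _ in range(15):
            action = rng.choice(["remove", "add"])
            overrides.append((f"D{rng.randrange(9)}", f"HP:{rng.randrange(13)}", action))
        result = apply_curation(records, overrides)
        # replay: removals apply to the original set, additions append if new
        removed = {(d, p) for d, p, a in overrides if a == "remove"}
        surviving = [r.pair for r in records if r.pair not in removed]
        added = []
        for d, p, a in overrides:
            if a == "add" and (d, p) not in surviving and (d, p) not in added:
                added.append((d, p))
        assert [r.pair for r in result.released] == surviving + added


class TestProvenanceAccounting:
    def test_partition_sums_to_total(self, fixture_world):
        records = [
            rec("A1", "HP:1", "wikidata"),
            rec("A2", "HP:2", "hpo_via_umls"),
            rec("A3", "HP:3", "prop_icd"),
            rec("A4", "HP:4", "prop_lexical"),
            rec("A5", "HP:5", "expert"),
        ]
        summary = provenance_summary(records)
        assert summary["TOTAL"] == len(records)
        assert sum(v for k, v in summary.items() if k != "TOTAL") == summary["TOTAL"]

    def test_dedup_keeps_highest_precedence(self):
        records = [
            rec("A1", "HP:1", "prop_icd"),
            rec("A1", "HP:1", "hpo_via_wikidata"),
            rec("A1", "HP:1", "umls_direct"),
        ]
        out = dedup_records(records)
        assert len(out) == 1 and out[0].provenance == "umls_direct"

    def test_associations_roundtrip(self, tmp_path):
        records = [rec("A1", "HP:1", "wikidata"), rec("A2", "HP:2", "prop_icd")]
        path = tmp_path / "assoc.tsv"
        write_associations(records, path)
        assert read_associations(path) == records
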