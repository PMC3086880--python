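"""Domain-type invariants and TSV/SIF/GraphML round trips."""

import networkx as nx
import pytest

from signalog import (
    Dataset,
    Interaction,
    OrthologCluster,
    ParseError,
    PathwayAnnotation,
    PathwayVocabulary,
    ProteinAttributes,
    ProteinRef,
    ProteinRegistry,
    ValidationError,
    export_network,
    read_annotations,
    read_attributes,
    read_clusters,
    read_dataset,
    read_interactions,
    write_dataset,
)
from signalog.model import normalize_id, round1

from conftest import make_random_dataset


class TestNormalization:
    def test_ids_compare_case_insensitively_preserving_case(self):
        a = ProteinRef("CEL", "Crb-1")
        b = ProteinRef("CEL", " crb-1 ")
        assert a == b and hash(a) == hash(b)
        assert a.primary_id == "Crb-1"

    def test_synonym_resolution_is_idempotent(self):
        reg = ProteinRegistry()
        ref = reg.add(ProteinRef("HSA", "NOTCH2", frozenset({"N2", "notch-2"})))
        once = reg.resolve("HSA", "n2")
        assert once is reg.resolve("HSA", once.primary_id)
        assert once == ref

    def test_primary_id_always_among_synonyms(self):
        ref = ProteinRef("HSA", "NUMB")
        assert normalize_id("numb") in ref.synonyms


class TestClusterInvariants:
    def test_missing_seed_rejected(self):
        w, f = ProteinRef("CEL", "w"), ProteinRef("DME", "f")
        with pytest.raises(ValidationError, match="seed"):
            OrthologCluster("c", frozenset({"CEL", "DME"}), ((w, 0.5), (f, 1.0)))

    def test_two_seeds_per_species_rejected(self):
        w1, w2 = ProteinRef("CEL", "w1"), ProteinRef("CEL", "w2")
        f = ProteinRef("DME", "f")
        with pytest.raises(ValidationError, match="seed"):
            OrthologCluster(
                "c", frozenset({"CEL", "DME"}), ((w1, 1.0), (w2, 1.0), (f, 1.0))
            )

    def test_score_outside_unit_interval_rejected(self):
        w, f = ProteinRef("CEL", "w"), ProteinRef("DME", "f")
        with pytest.raises(ValidationError, match=r"\(0,1\]"):
            OrthologCluster("c", frozenset({"CEL", "DME"}), ((w, 1.0), (f, 1.5)))


class TestPathwayVocabulary:
    @pytest.mark.parametrize(
        "raw,canonical",
        [("ErbB", "EGF/MAPK"), ("JNK", "EGF/MAPK"), ("MAPK", "EGF/MAPK"),
         ("notch", "Notch"), ("TGF-β", "TGF-beta"), ("Wingless", "WNT")],
    )
    def test_synonyms_resolve(self, raw, canonical):
        assert PathwayVocabulary().resolve(raw) == canonical

    def test_unknown_pathway_is_an_error_naming_it(self):
        with pytest.raises(ValidationError, match="mTOR"):
            PathwayVocabulary().resolve("mTOR")


class TestClusterIO:
    def test_single_cluster_file(self, tmp_path):
        path = tmp_path / "clusters.tsv"
        path.write_text(
            "# a comment\n"
            "cluster_id\tspecies_pair\tspecies\tprotein_id\tinparalog_score\n"
            "c1\tCEL-HSA\tCEL\tcrb-1\t1.0\n"
            "c1\tCEL-HSA\tHSA\tNOTCH2\t1.0\n"
        )
        clusters = read_clusters(path)
        assert len(clusters) == 1 and len(clusters[0].members) == 2

    def test_header_only_file_is_empty_list(self, tmp_path):
        path = tmp_path / "clusters.tsv"
        path.write_text(
            "cluster_id\tspecies_pair\tspecies\tprotein_id\tinparalog_score\n"
        )
        assert read_clusters(path) == []

    def test_malformed_score_names_line(self, tmp_path):
        path = tmp_path / "clusters.tsv"
        path.write_text(
            "cluster_id\tspecies_pair\tspecies\tprotein_id\tinparalog_score\n"
            "c1\tCEL-HSA\tCEL\tcrb-1\tnot-a-number\n"
        )
        with pytest.raises(ParseError, match=":2"):
            read_clusters(path)

    def test_seed_violation_names_cluster(self, tmp_path):
        path = tmp_path / "clusters.tsv"
        path.write_text(
            "cluster_id\tspecies_pair\tspecies\tprotein_id\tinparalog_score\n"
            "bad\tCEL-HSA\tCEL\tcrb-1\t0.8\n"
            "bad\tCEL-HSA\tHSA\tNOTCH2\t1.0\n"
        )
        with pytest.raises(ValidationError, match="bad"):
            read_clusters(path)


class TestAnnotationIO:
    def test_single_row(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "species\tprotein_id\tpathway\trole\tpmids\n"
            "CEL\tlin-12\tNotch\treceptor\t\n"
        )
        anns = read_annotations(path)
        assert len(anns) == 1
        assert anns[0].pathway == "Notch" and anns[0].role == "receptor"

    def test_duplicate_rows_collapse_with_pmids_unioned(self, tmp_path):
        path = tmp_path / "ann.tsv"
        path.write_text(
            "species\tprotein_id\tpathway\trole\tpmids\n"
            "CEL\tlin-12\tNotch\treceptor\t111\n"
            "CEL\tlin-12\tNotch\treceptor\t222\n"
        )
        anns = read_annotations(path)
        assert len(anns) == 1 and set(anns[0].pmids) == {111, 222}


class TestInteractionIO:
    def test_enum_fields_parse(self, tmp_path):
        path = tmp_path / "int.tsv"
        path.write_text(
            "species\tsource_id\ttarget_id\tevidence\teffect\tpmids\n"
            "HSA\tNOTCH2\tNUMB\tdirect\tinhibition\t123\n"
        )
        (i,) = read_interactions(path)
        assert i.evidence == "direct" and i.effect == "inhibition"
        assert i.pmids == (123,)

    def test_cross_species_endpoints_rejected(self):
        with pytest.raises(ValidationError, match="belong"):
            Interaction("CEL", ProteinRef("CEL", "a"), ProteinRef("DME", "b"))


class TestAttributeIO:
    def test_booleans_and_lists(self, tmp_path):
        path = tmp_path / "attrs.tsv"
        path.write_text(
            "species\tprotein_id\tis_membrane\tis_enzyme\thas_kinase_domain\t"
            "is_disease_related\tknown_drugs\torthologs_known\tfunction_known\t"
            "disease_names\n"
            "HSA\tANPRA\t1\t1\t1\t1\tNesiritide;Nitroglycerin\t1\t1\t\n"
        )
        attrs = read_attributes(path)
        (a,) = attrs.values()
        assert a.is_membrane and a.is_disease_related
        assert a.known_drugs == ("Nesiritide", "Nitroglycerin")

    def test_missing_attribute_record_synthesized_with_warning(self):
        ds = Dataset()
        ref = ds.registry.add(ProteinRef("CEL", "orphan"))
        with pytest.warns(UserWarning, match="synthesizing"):
            attrs = ds.attributes_of(ref)
        assert not attrs.is_membrane and attrs.known_drugs == ()


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_dataset_tsv_round_trip_is_identity(tmp_path, seed):
    """Write -> read over every dialect reproduces the typed records."""
    ds = make_random_dataset(seed, n=25)
    write_dataset(ds, tmp_path)
    back = read_dataset(tmp_path)
    orig_clusters = {
        (c.cluster_id, c.species_pair, tuple((r.key, s) for r, s in c.members))
        for c in ds.clusters
    }
    back_clusters = {
        (c.cluster_id, c.species_pair, tuple((r.key, s) for r, s in c.members))
        for c in back.clusters
    }
    assert orig_clusters == back_clusters
    assert {(a.protein, a.pathway) for a in ds.annotations} == {
        (a.protein, a.pathway) for a in back.annotations
    }
    assert {(i.source, i.target, i.evidence, i.effect) for i in ds.interactions} \
        == {(i.source, i.target, i.evidence, i.effect) for i in back.interactions}
    assert len(back.attributes) == len(ds.attributes)
    for ref, a in ds.attributes.items():
        b = back.attributes[ref]
        assert (a.is_membrane, a.is_enzyme, a.has_kinase_domain,
                a.is_disease_related, a.known_drugs, a.orthologs_known,
                a.function_known, a.disease_names) == (
            b.is_membrane, b.is_enzyme, b.has_kinase_domain,
            b.is_disease_related, b.known_drugs, b.orthologs_known,
            b.function_known, b.disease_names)


class TestNetworkExport:
    def test_sif_has_one_line_per_edge_with_distinct_relations(
        self, tmp_path, tiny_dataset
    ):
        from signalog.interolog import Interolog

        w1 = tiny_dataset.registry.get("CEL", "w1")
        w2 = tiny_dataset.registry.get("CEL", "w2")
        il = Interolog("CEL", (w1, w2), frozenset({("DME", (w1, w2))}))
        out = tmp_path / "net.sif"
        export_network(tiny_dataset, (), [il], "sif", out)
        lines = out.read_text().splitlines()
        assert len(lines) == 2
        assert {line.split("\t")[1] for line in lines} == {"known", "interolog"}

    def test_empty_prediction_set_means_all_nodes_known(
        self, tmp_path, tiny_dataset
    ):
        out = tmp_path / "net.graphml"
        export_network(tiny_dataset, (), (), "graphml", out)
        g = nx.read_graphml(out)
        assert all(d["status"] == "known" for _, d in g.nodes(data=True))

    def test_graphml_round_trip_preserves_counts(self, tmp_path):
        from conftest import all_maps
        from signalog import derive_interologs, predict_signalogs
        from signalog.io import build_network

        ds = make_random_dataset(5, n=20)
        maps = all_maps(ds)
        preds = predict_signalogs(ds, maps, "CEL")
        ils = derive_interologs(ds, maps, "CEL")
        g = build_network(ds, preds, ils)
        out = tmp_path / "net.graphml"
        export_network(ds, preds, ils, "graphml", out)
        back = nx.read_graphml(out)
        assert back.number_of_nodes() == g.number_of_nodes()
        assert back.number_of_edges() == g.number_of_edges()

    def test_unsupported_format_rejected(self, tmp_path, tiny_dataset):
        with pytest.raises(ValidationError, match="format"):
            export_network(tiny_dataset, (), (), "xgmml", tmp_path / "x")


@pytest.mark.parametrize(
    "value,expected",
    [(77.7666, 77.8), (0.25, 0.2), (0.35, 0.4), (6.849, 6.8)],
)
def test_round1_is_half_even(value, expected):
    assert round1(value) == expected
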