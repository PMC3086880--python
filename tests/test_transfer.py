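"""Signalog prediction, summaries, and orthology-coverage statistics."""

import pytest

from signalog import (
    Dataset,
    OrthologCluster,
    PathwayAnnotation,
    ProteinRef,
    build_ortholog_map,
    coverage_stats,
    predict_signalogs,
    summarize_predictions,
)
from signalog.model import ConfigError, percent, round1

from conftest import SPECIES_PAIRS, all_maps, make_random_dataset


def brute_force_predictions(dataset, threshold, target):
    """Independent triple loop over (protein, ortholog, annotation)."""
    from test_orthology import brute_force_links

    known = {(a.protein.key, a.pathway) for a in dataset.annotations}
    refs = {r.key: r for r in dataset.registry}
    expected = set()
    for pair in SPECIES_PAIRS:
        if target not in pair:
            continue
        for a_key, b_key, _sa, _sb, _cid in brute_force_links(
            dataset.clusters, pair, threshold
        ):
            for my_key, other_key in ((a_key, b_key), (b_key, a_key)):
                if my_key[0] != target or other_key[0] == target:
                    continue
                other = refs[other_key]
                for ann in dataset.annotations:
                    if ann.protein == other and (my_key, ann.pathway) not in known:
                        expected.add((my_key, ann.pathway))
    return expected


class TestPredictOnFixture:
    def test_table1_yields_six_worm_notch_predictions(self, table1, table1_maps):
        preds = predict_signalogs(table1, table1_maps, "CEL")
        assert len(preds) == 6
        assert {p.pathway for p in preds} == {"Notch"}
        assert all(p.is_new_protein for p in preds)
        assert {p.protein.primary_id for p in preds} == {
            "aqp-6", "crb-1", "D1009.3", "F10D7.5", "nsh-1", "num-1",
        }

    def test_provenance_merged_across_source_species(self, table1, table1_maps):
        preds = {p.protein.primary_id: p for p in
                 predict_signalogs(table1, table1_maps, "CEL")}
        # crb-1 is supported both by fly crb and human NOTCH2
        sources = {sp for sp, _, _ in preds["crb-1"].provenance}
        assert sources == {"DME", "HSA"}
        # aqp-6 has no human ortholog: fly support only
        assert {sp for sp, _, _ in preds["aqp-6"].provenance} == {"DME"}

    def test_every_provenance_ortholog_is_annotated_to_the_pathway(
        self, table1, table1_maps
    ):
        known = table1.known_pairs()
        for p in predict_signalogs(table1, table1_maps, "CEL"):
            for _sp, ortholog, _score in p.provenance:
                assert (ortholog, p.pathway) in known

    def test_unknown_target_species_rejected(self, table1, table1_maps):
        with pytest.raises(Exception):
            predict_signalogs(table1, table1_maps, "MUS")


class TestPredictProperties:
    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_oracle(self, seed):
        ds = make_random_dataset(seed, n=30)
        for target in ("CEL", "DME", "HSA"):
            preds = predict_signalogs(ds, all_maps(ds), target)
            got = {(p.protein.key, p.pathway) for p in preds}
            assert got == brute_force_predictions(ds, 0.3, target)

    @pytest.mark.parametrize("seed", range(4))
    def test_novelty_guarantee(self, seed):
        ds = make_random_dataset(seed, n=40)
        known = ds.known_pairs()
        for target in ("CEL", "DME", "HSA"):
            for p in predict_signalogs(ds, all_maps(ds), target):
                assert (p.protein, p.pathway) not in known

    @pytest.mark.parametrize("seed", range(4))
    def test_threshold_monotonicity_of_predictions(self, seed):
        ds = make_random_dataset(seed, n=40)
        previous = None
        for thr in (0.0, 0.3, 0.6, 1.0):
            preds = {
                (p.protein.key, p.pathway)
                for p in predict_signalogs(ds, all_maps(ds, thr), "CEL")
            }
            if previous is not None:
                assert preds <= previous
            previous = preds

    def test_deterministic_sorted_output(self):
        ds = make_random_dataset(21, n=40)
        a = predict_signalogs(ds, all_maps(ds), "DME")
        b = predict_signalogs(ds, list(reversed(all_maps(ds))), "DME")
        assert a == b
        assert a == sorted(a, key=lambda p: p.sort_key())

    def test_already_annotated_protein_can_gain_other_pathway(self):
        # the least-novel case: a known WNT member predicted into Notch
        ds = Dataset()
        w = ds.registry.add(ProteinRef("CEL", "w"))
        f = ds.registry.add(ProteinRef("DME", "f"))
        ds.clusters = [
            OrthologCluster("c", frozenset({"CEL", "DME"}), ((w, 1.0), (f, 1.0)))
        ]
        ds.annotations = [
            PathwayAnnotation(w, "WNT"),
            PathwayAnnotation(f, "WNT"),
            PathwayAnnotation(f, "Notch"),
        ]
        ds.validate()
        maps = [build_ortholog_map(ds.clusters, ("CEL", "DME"))]
        (pred,) = predict_signalogs(ds, maps, "CEL")
        assert pred.pathway == "Notch"
        assert not pred.is_new_protein

    def test_source_without_annotations_predicts_nothing(self, table1):
        ds = Dataset()
        ds.registry = table1.registry
        ds.clusters = table1.clusters
        maps = all_maps(ds)
        assert predict_signalogs(ds, maps, "CEL") == []

    def test_require_no_interactions_excludes_interacting_proteins(self):
        from signalog import Interaction

        ds = Dataset()
        w1 = ds.registry.add(ProteinRef("CEL", "w1"))
        w2 = ds.registry.add(ProteinRef("CEL", "w2"))
        f1 = ds.registry.add(ProteinRef("DME", "f1"))
        f2 = ds.registry.add(ProteinRef("DME", "f2"))
        ds.clusters = [
            OrthologCluster("c1", frozenset({"CEL", "DME"}),
                            ((w1, 1.0), (f1, 1.0))),
            OrthologCluster("c2", frozenset({"CEL", "DME"}),
                            ((w2, 1.0), (f2, 1.0))),
        ]
        ds.annotations = [PathwayAnnotation(f1, "Notch"),
                          PathwayAnnotation(f2, "WNT")]
        ds.interactions = [Interaction("CEL", w1, w2)]
        ds.validate()
        maps = all_maps(ds)
        assert len(predict_signalogs(ds, maps, "CEL")) == 2
        assert predict_signalogs(ds, maps, "CEL",
                                 require_no_interactions=True) == []


class TestSummaries:
    def test_multi_pathway_arithmetic(self):
        from signalog.synth import synthetic_breakdown_predictions

        s = summarize_predictions(synthetic_breakdown_predictions())
        assert s["n_signalog_proteins"] == 253
        assert s["n_multi_pathway_proteins"] == 39
        assert s["n_annotations_of_multi"] == 87
        assert s["n_annotations"] == 301
        assert s["n_annotations"] == (
            s["n_signalog_proteins"] - s["n_multi_pathway_proteins"]
        ) + s["n_annotations_of_multi"]

    def test_empty_prediction_list_all_zero(self):
        s = summarize_predictions([])
        assert s["n_signalog_proteins"] == 0
        assert s["n_annotations"] == 0
        assert s["per_pathway_counts"] == {}

    @pytest.mark.parametrize("seed", range(4))
    def test_per_pathway_counts_sum_to_total(self, seed):
        ds = make_random_dataset(seed, n=40)
        preds = predict_signalogs(ds, all_maps(ds), "HSA")
        s = summarize_predictions(preds)
        assert sum(s["per_pathway_counts"].values()) == s["n_annotations"]
        assert s["n_annotations"] == (
            s["n_signalog_proteins"] - s["n_multi_pathway_proteins"]
        ) + s["n_annotations_of_multi"]


def brute_force_coverage(dataset, maps):
    partners = {}
    for m in maps:
        for link in m.links:
            partners.setdefault(link.protein_a, set()).add(link.protein_b)
            partners.setdefault(link.protein_b, set()).add(link.protein_a)
    paths = {}
    for a in dataset.annotations:
        paths.setdefault(a.protein, set()).add(a.pathway)
    out = {}
    for sp in dataset.species.codes:
        annotated = [p for p in paths if p.species == sp]
        if not annotated:
            out[sp] = None
            continue
        with_orth = [p for p in annotated if partners.get(p)]
        sig = [p for p in with_orth
               if any(o in paths for o in partners[p])]
        ident = [p for p in with_orth
                 if any(paths.get(o, set()) & paths[p] for o in partners[p])]
        out[sp] = (
            percent(len(with_orth), len(annotated)),
            percent(len(sig), len(with_orth)) if with_orth else 0.0,
            percent(len(ident), len(with_orth)) if with_orth else 0.0,
        )
    return out


class TestCoverage:
    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_recount(self, seed):
        ds = make_random_dataset(seed, n=35)
        maps = all_maps(ds)
        stats = coverage_stats(ds, maps)
        expected = brute_force_coverage(ds, maps)
        for sp, vals in expected.items():
            got = stats.per_species[sp]
            assert vals == (
                got["frac_with_ortholog"],
                got["frac_ortholog_signaling"],
                got["frac_identical_pathway"],
            )

    def test_perfect_transfer_fixture_is_all_hundred(self):
        ds = Dataset()
        refs = {}
        for sp in ("CEL", "DME", "HSA"):
            refs[sp] = ds.registry.add(ProteinRef(sp, f"{sp}-gene"))
            ds.annotations.append(PathwayAnnotation(refs[sp], "WNT"))
        ds.clusters = [
            OrthologCluster("c1", frozenset({"CEL", "DME"}),
                            ((refs["CEL"], 1.0), (refs["DME"], 1.0))),
            OrthologCluster("c2", frozenset({"CEL", "HSA"}),
                            ((refs["CEL"], 1.0), (refs["HSA"], 1.0))),
            OrthologCluster("c3", frozenset({"DME", "HSA"}),
                            ((refs["DME"], 1.0), (refs["HSA"], 1.0))),
        ]
        ds.validate()
        stats = coverage_stats(ds, all_maps(ds))
        for sp in ("CEL", "DME", "HSA"):
            assert stats.per_species[sp] == {
                "frac_with_ortholog": 100.0,
                "frac_ortholog_signaling": 100.0,
                "frac_identical_pathway": 100.0,
            }
        assert stats.mean_ortholog_signaling == 100.0

    def test_species_without_annotations_excluded_from_mean(self):
        ds = Dataset()
        w = ds.registry.add(ProteinRef("CEL", "w"))
        f = ds.registry.add(ProteinRef("DME", "f"))
        ds.clusters = [
            OrthologCluster("c", frozenset({"CEL", "DME"}), ((w, 1.0), (f, 1.0)))
        ]
        ds.annotations = [PathwayAnnotation(w, "WNT"), PathwayAnnotation(f, "WNT")]
        ds.validate()
        with pytest.warns(UserWarning, match="HSA"):
            stats = coverage_stats(ds, all_maps(ds))
        assert stats.per_species["HSA"]["frac_with_ortholog"] is None
        assert stats.mean_ortholog_signaling == 100.0

    def test_mean_reproduces_reported_average(self):
        from signalog import average_percent

        assert average_percent([83.2, 67.5, 82.6]) == 77.8
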