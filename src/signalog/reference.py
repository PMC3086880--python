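"""Overlap of signalog predictions with reference pathway resources.

Quantifies novelty by asking how many predicted signalogs already appear in
a KEGG/Reactome-like resource at all, and how many appear under the same
pathway once sub-pathway names (ErbB, JNK, MAPK, ...) are folded through
the synonym map.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .model import (
    PathwayVocabulary,
    ProteinRef,
    ValidationError,
    normalize_id,
    percent,
    round1,
)
from .transfer import SignalogPrediction

__all__ = ["compare_to_reference", "compare_to_prediction_set"]


def _reference_index(
    reference: Sequence[dict],
    vocabulary: PathwayVocabulary,
    species: str,
) -> dict[str, set[str | None]]:
    """Normalized protein id -> set of mapped pathway names ('None' = other)."""
    index: dict[str, set[str | None]] = {}
    for rec in reference:
        if rec["species"] != species:
            raise ValidationError(
                f"reference record for {rec['species']} in a {species} comparison"
            )
        pid = normalize_id(rec["protein_id"])
        index.setdefault(pid, set()).add(
            vocabulary.resolve_or_other(rec["pathway_name"])
        )
    return index


def compare_to_reference(
    predictions: Iterable[SignalogPrediction],
    reference: Sequence[dict],
    vocabulary: PathwayVocabulary | None = None,
) -> dict:
    """Overlap of one species' signalogs with a reference annotation table.

    A signalog counts as present when the reference lists it under *any*
    pathway (mapped or not), and as same-pathway when at least one of its
    predicted pathways matches a mapped reference pathway.  The novel
    fraction is protein-level: the share of reference-present signalogs
    whose predicted memberships are all absent from the reference.
    """
    vocabulary = vocabulary or PathwayVocabulary()
    predictions = list(predictions)
    species = {p.protein.species for p in predictions}
    if len(species) > 1:
        raise ValidationError("predictions must be restricted to one species")
    sp = species.pop() if species else None
    by_protein: dict[ProteinRef, set[str]] = {}
    for p in predictions:
        by_protein.setdefault(p.protein, set()).add(p.pathway)
    ref_index = (
        _reference_index(reference, vocabulary, sp) if sp is not None else {}
    )

    n_signalogs = len(by_protein)
    present = {
        protein for protein in by_protein
        if any(tok in ref_index for tok in protein.synonyms)
    }
    same_pathway = set()
    for protein in present:
        ref_pathways: set[str | None] = set()
        for tok in protein.synonyms:
            ref_pathways |= ref_index.get(tok, set())
        if by_protein[protein] & {pw for pw in ref_pathways if pw is not None}:
            same_pathway.add(protein)
    n_present = len(present)
    n_same = len(same_pathway)
    return {
        "n_signalogs": n_signalogs,
        "n_present_in_ref": n_present,
        "n_same_pathway": n_same,
        "pct_present": percent(n_present, n_signalogs) if n_signalogs else 0.0,
        "pct_novel_annotations": (
            round1(100.0 - 100.0 * n_same / n_present) if n_present else 100.0
        ),
    }


def compare_to_prediction_set(
    predictions_a: Iterable[SignalogPrediction],
    predictions_b: Iterable[tuple[str, str]] | Iterable[SignalogPrediction],
    vocabulary: PathwayVocabulary | None = None,
) -> dict:
    """Compare two prediction sets of one species.

    ``predictions_b`` may be another prediction list or raw
    ``(protein_id, pathway_name)`` pairs from an external study; pathway
    names are synonym-mapped before comparison.  Counts are over shared
    proteins: annotations of each set restricted to the shared proteins, and
    the identical (protein, pathway) pairs among them.
    """
    vocabulary = vocabulary or PathwayVocabulary()

    def to_pairs(items) -> set[tuple[str, str]]:
        pairs = set()
        for item in items:
            if isinstance(item, SignalogPrediction):
                pid = normalize_id(item.protein.primary_id)
                pw = item.pathway
            else:
                pid, raw = item
                pid = normalize_id(pid)
                pw = vocabulary.resolve_or_other(raw)
                if pw is None:
                    continue
            pairs.add((pid, pw))
        return pairs

    pairs_a = to_pairs(predictions_a)
    pairs_b = to_pairs(predictions_b)
    proteins_a = {pid for pid, _ in pairs_a}
    proteins_b = {pid for pid, _ in pairs_b}
    shared = proteins_a & proteins_b
    ann_a = {pair for pair in pairs_a if pair[0] in shared}
    ann_b = {pair for pair in pairs_b if pair[0] in shared}
    return {
        "n_shared_proteins": len(shared),
        "n_annotations_a": len(ann_a),
        "n_annotations_b": len(ann_b),
        "n_identical_annotations": len(ann_a & ann_b),
    }
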