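"""Orthology-based pathway-membership transfer ("signalog" prediction).

A protein of the target species is predicted to be a member of every
signaling pathway to which one of its orthologs in another species is
annotated, unless that membership is already curated in the target species.
Such predicted proteins are called signalogs.  The module also computes the
orthology-coverage statistics that motivate the transfer: how many known
signaling proteins have orthologs, how many of those orthologs are
themselves signaling proteins, and how many share the identical pathway.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import mean
from typing import Iterable, Sequence

from .model import ConfigError, Dataset, ProteinRef, round1, percent
from .orthology import OrthologMap

__all__ = [
    "SignalogPrediction",
    "CoverageStats",
    "predict_signalogs",
    "summarize_predictions",
    "coverage_stats",
    "average_percent",
]


@dataclass(frozen=True)
class SignalogPrediction:
    """A predicted novel (protein, pathway) membership with its provenance.

    Each provenance entry is one supporting ortholog:
    ``(source_species, ortholog, inparalog_score)``.  ``is_new_protein`` is
    true when the protein carried no pathway annotation at all before the
    transfer.
    """

    protein: ProteinRef
    pathway: str
    provenance: frozenset[tuple[str, ProteinRef, float]]
    is_new_protein: bool

    def sort_key(self) -> tuple:
        return (self.protein.key, self.pathway)


@dataclass(frozen=True)
class CoverageStats:
    """Per-species orthology coverage of known signaling proteins.

    All values are percentages rounded to one decimal (half-even).  The mean
    is the unweighted arithmetic mean of the per-species ortholog-signaling
    fractions; species without annotated proteins are reported as missing and
    excluded from the mean.
    """

    per_species: dict[str, dict[str, float | None]] = field(default_factory=dict)
    mean_ortholog_signaling: float | None = None


def _ortholog_index(
    maps: Sequence[OrthologMap],
) -> dict[ProteinRef, set[tuple[str, ProteinRef, float]]]:
    """protein -> {(other species, ortholog, ortholog's inparalog score)}."""
    index: dict[ProteinRef, set[tuple[str, ProteinRef, float]]] = {}
    for m in maps:
        for link in m.links:
            a, b = link.protein_a, link.protein_b
            index.setdefault(a, set()).add((b.species, b, link.score_b))
            index.setdefault(b, set()).add((a.species, a, link.score_a))
    return index


def predict_signalogs(
    dataset: Dataset,
    maps: Sequence[OrthologMap],
    target_species: str,
    require_no_interactions: bool = False,
) -> list[SignalogPrediction]:
    """Transfer pathway annotations onto the target species via orthology.

    The candidate universe is every target-species protein appearing in any
    ortholog cluster (proteins without orthology can never receive a
    transfer).  For each candidate ``p`` and each pathway ``P`` annotated to
    some ortholog of ``p`` in another species, ``(p, P)`` is emitted iff the
    membership is not already curated for ``p``.  Provenance aggregates all
    supporting orthologs across source species; output is sorted by
    (protein id, pathway).

    With ``require_no_interactions`` the candidate universe is additionally
    restricted to proteins that take part in no known interaction — the
    stricter reading of "no known signaling interactions".
    """
    dataset.species.validate(target_species)
    if not any(target_species in m.pair for m in maps):
        raise ConfigError(
            f"no ortholog map covers a pair containing {target_species}"
        )
    known = dataset.known_pairs()
    annotated = dataset.annotated_proteins()
    interacting: set[ProteinRef] = set()
    if require_no_interactions:
        for i in dataset.interactions:
            if i.species == target_species:
                interacting |= {i.source, i.target}

    annotations_by_protein: dict[ProteinRef, set[str]] = {}
    for a in dataset.annotations:
        annotations_by_protein.setdefault(a.protein, set()).add(a.pathway)

    index = _ortholog_index(maps)
    support: dict[tuple[ProteinRef, str], set[tuple[str, ProteinRef, float]]] = {}
    for protein, orthologs in index.items():
        if protein.species != target_species or protein in interacting:
            continue
        for sp, ortholog, score in orthologs:
            if sp == target_species:
                continue
            for pathway in annotations_by_protein.get(ortholog, ()):
                if (protein, pathway) in known:
                    continue
                support.setdefault((protein, pathway), set()).add(
                    (sp, ortholog, score)
                )

    predictions = [
        SignalogPrediction(
            protein=protein,
            pathway=pathway,
            provenance=frozenset(prov),
            is_new_protein=protein not in annotated,
        )
        for (protein, pathway), prov in support.items()
    ]
    predictions.sort(key=SignalogPrediction.sort_key)
    return predictions


def summarize_predictions(predictions: Iterable[SignalogPrediction]) -> dict:
    """Count signalog proteins, annotations, and multi-pathway proteins.

    ``per_pathway_percent`` uses the total annotation count as denominator;
    ``per_pathway_percent_of_proteins`` is also reported because the protein
    count is the other natural denominator for per-pathway breakdowns.
    """
    predictions = list(predictions)
    by_protein: dict[ProteinRef, list[str]] = {}
    per_pathway: dict[str, int] = {}
    for p in predictions:
        by_protein.setdefault(p.protein, []).append(p.pathway)
        per_pathway[p.pathway] = per_pathway.get(p.pathway, 0) + 1
    n_proteins = len(by_protein)
    n_annotations = len(predictions)
    multi = {ref: pws for ref, pws in by_protein.items() if len(pws) > 1}
    n_multi = len(multi)
    n_annotations_of_multi = sum(len(pws) for pws in multi.values())
    return {
        "n_signalog_proteins": n_proteins,
        "n_annotations": n_annotations,
        "n_multi_pathway_proteins": n_multi,
        "n_annotations_of_multi": n_annotations_of_multi,
        "per_pathway_counts": dict(sorted(per_pathway.items())),
        "per_pathway_percent": {
            pw: percent(n, n_annotations) for pw, n in sorted(per_pathway.items())
        } if n_annotations else {},
        "per_pathway_percent_of_proteins": {
            pw: percent(n, n_proteins) for pw, n in sorted(per_pathway.items())
        } if n_proteins else {},
    }


def average_percent(values: Sequence[float]) -> float:
    """Unweighted arithmetic mean of percentages, to one decimal
    (half-even)."""
    return round1(mean(values))


def coverage_stats(dataset: Dataset, maps: Sequence[OrthologMap]) -> CoverageStats:
    """Orthology coverage of each species' annotated signaling proteins.

    Per species: the fraction with at least one ortholog in the other
    species; of those, the fraction with at least one ortholog that is
    itself a known signaling protein; and the fraction with at least one
    ortholog sharing an identical pathway membership.  A species without
    annotated proteins is reported as missing and excluded from the mean.
    """
    index = _ortholog_index(maps)
    annotations_by_protein: dict[ProteinRef, set[str]] = {}
    for a in dataset.annotations:
        annotations_by_protein.setdefault(a.protein, set()).add(a.pathway)

    per_species: dict[str, dict[str, float | None]] = {}
    signaling_fracs: list[float] = []
    for sp in dataset.species.codes:
        annotated = sorted(dataset.annotated_proteins(sp))
        if not annotated:
            import warnings

            warnings.warn(
                f"species {sp} has no annotated proteins; coverage undefined",
                stacklevel=2,
            )
            per_species[sp] = {
                "frac_with_ortholog": None,
                "frac_ortholog_signaling": None,
                "frac_identical_pathway": None,
            }
            continue
        with_orth = [
            p for p in annotated
            if any(osp != sp for osp, _, _ in index.get(p, ()))
        ]
        orth_signaling = [
            p for p in with_orth
            if any(o in annotations_by_protein
                   for osp, o, _ in index.get(p, ()) if osp != sp)
        ]
        identical = [
            p for p in with_orth
            if any(
                annotations_by_protein.get(o, set()) & annotations_by_protein[p]
                for osp, o, _ in index.get(p, ()) if osp != sp
            )
        ]
        frac_with = percent(len(with_orth), len(annotated))
        frac_sig = percent(len(orth_signaling), len(with_orth)) if with_orth else 0.0
        frac_ident = percent(len(identical), len(with_orth)) if with_orth else 0.0
        per_species[sp] = {
            "frac_with_ortholog": frac_with,
            "frac_ortholog_signaling": frac_sig,
            "frac_identical_pathway": frac_ident,
        }
        signaling_fracs.append(frac_sig)
    return CoverageStats(
        per_species=per_species,
        mean_ortholog_signaling=(
            average_percent(signaling_fracs) if signaling_fracs else None
        ),
    )
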