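"""Novelty grading, drug-target relevance scoring, and candidate tables.

Novelty of a predicted signalog is graded 1-5 from what the literature
already documented about the protein: its orthology, its biochemical
function, and any prior pathway membership.  Drug-target relevance counts
how many of the four key target-like properties (membrane localization,
enzymatic activity, kinase domain, disease relatedness) a protein carries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .model import ConfigError, ProteinAttributes, ProteinRef
from .orthology import OrthologMap
from .transfer import SignalogPrediction, _ortholog_index

__all__ = [
    "NoveltyClass",
    "RelevanceScore",
    "classify_novelty",
    "relevance_score",
    "candidate_table",
    "orthodisease_report",
]


@dataclass(frozen=True)
class NoveltyClass:
    """One of five mutually exclusive novelty grades (1 = most novel)."""

    value: int

    def __post_init__(self) -> None:
        if self.value not in range(1, 6):
            raise ConfigError(f"novelty class {self.value} outside 1..5")


@dataclass(frozen=True)
class RelevanceScore:
    """Count of target-like key properties, with the contributing subset."""

    value: int
    components: frozenset[str]

    def __post_init__(self) -> None:
        if self.value != len(self.components):
            raise ConfigError("relevance score must equal its component count")


def classify_novelty(attrs: ProteinAttributes, pathway_known: bool) -> NoveltyClass:
    """Grade how much was previously known about a predicted signalog.

    Class 5: orthology, function, and some pathway membership all already
    documented; 4: orthology and function known, no pathway; 3: function
    known but orthology not; 2: orthology known but function not; 1: neither
    known.  Classes are evaluated most-specific-first so every flag
    combination lands in exactly one class.  "Known orthologs" means
    literature-documented orthology, not the cluster-derived orthology used
    for the transfer itself — a signalog's orthology may well have been
    unknown to the literature.
    """
    ortho, func = attrs.orthologs_known, attrs.function_known
    if ortho and func and pathway_known:
        return NoveltyClass(5)
    if ortho and func:
        return NoveltyClass(4)
    if not ortho and func:
        return NoveltyClass(3)
    if ortho and not func:
        return NoveltyClass(2)
    return NoveltyClass(1)


_KEY_PROPERTIES = (
    ("membrane", "is_membrane"),
    ("enzyme", "is_enzyme"),
    ("kinase_domain", "has_kinase_domain"),
    ("disease", "is_disease_related"),
)


def relevance_score(attrs: ProteinAttributes) -> RelevanceScore:
    """Drug-target relevance: how many of the four key properties hold."""
    components = frozenset(
        name for name, flag in _KEY_PROPERTIES if getattr(attrs, flag)
    )
    return RelevanceScore(len(components), components)


def candidate_table(
    predictions: Iterable[SignalogPrediction],
    attributes: Mapping[ProteinRef, ProteinAttributes],
    drug_target_ids: set[ProteinRef] | None = None,
    min_score: int = 0,
) -> list[dict]:
    """Rank signalog proteins of one species by drug-target relevance.

    One row per signalog protein, sorted by (score descending, protein id
    ascending).  ``is_current_target`` marks proteins in ``drug_target_ids``;
    novel candidates are the rows that are not current targets and reach
    ``min_score``.
    """
    predictions = list(predictions)
    species = {p.protein.species for p in predictions}
    if len(species) > 1:
        raise ConfigError(
            "candidate_table expects predictions of a single species"
        )
    drug_target_ids = drug_target_ids or set()
    by_protein: dict[ProteinRef, list[str]] = {}
    for p in predictions:
        by_protein.setdefault(p.protein, []).append(p.pathway)
    rows = []
    for protein, pathways in by_protein.items():
        attrs = attributes.get(protein, ProteinAttributes(protein))
        score = relevance_score(attrs)
        rows.append(
            {
                "protein": protein,
                "predicted_pathways": tuple(sorted(set(pathways))),
                "known_drugs": attrs.known_drugs,
                "score": score.value,
                "score_components": tuple(sorted(score.components)),
                "is_current_target": protein in drug_target_ids,
            }
        )
    rows.sort(key=lambda r: (-r["score"], r["protein"].key))
    for r in rows:
        r["is_novel_candidate"] = (
            not r["is_current_target"] and r["score"] >= min_score
        )
    return rows


def orthodisease_report(
    predictions: Iterable[SignalogPrediction],
    maps: Sequence[OrthologMap],
    attributes: Mapping[ProteinRef, ProteinAttributes],
    disease_species: str,
) -> list[dict]:
    """Signalogs whose orthologs in ``disease_species`` are disease-linked.

    One row per signalog protein with at least one disease-flagged ortholog
    in ``disease_species``; diseases are aggregated from the orthologs'
    disease names.  Such model-organism proteins ("orthodisease" proteins)
    point at human disease mechanisms testable in the model.
    """
    predictions = list(predictions)
    species = {p.protein.species for p in predictions}
    if disease_species in species:
        raise ConfigError(
            "disease species must differ from the predictions' species"
        )
    index = _ortholog_index(maps)
    by_protein: dict[ProteinRef, list[str]] = {}
    for p in predictions:
        by_protein.setdefault(p.protein, []).append(p.pathway)
    rows = []
    for protein in sorted(by_protein):
        disease_orthologs = []
        diseases: list[str] = []
        for sp, ortholog, _score in sorted(
            index.get(protein, ()), key=lambda t: t[1].key
        ):
            if sp != disease_species:
                continue
            attrs = attributes.get(ortholog)
            if attrs is not None and attrs.is_disease_related:
                disease_orthologs.append(ortholog)
                diseases.extend(attrs.disease_names)
        if disease_orthologs:
            rows.append(
                {
                    "signalog": protein,
                    "predicted_pathways": tuple(sorted(set(by_protein[protein]))),
                    "disease_orthologs": tuple(disease_orthologs),
                    "diseases": tuple(dict.fromkeys(diseases)),
                }
            )
    return rows
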