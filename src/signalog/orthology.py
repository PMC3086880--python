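"""Thresholded pairwise ortholog maps built from InParanoid-style clusters.

Within a cluster, every cross-species member pair is a candidate ortholog
link.  A counterpart is retained from a protein's perspective when it is the
protein's only counterpart in the cluster, when its inparalog score exceeds
the threshold (strictly), or when it is a seed ortholog (score 1.0).  A link
survives only if retained from both perspectives, which makes the map
symmetric by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

from .model import ConfigError, OrthologCluster, ProteinRef

__all__ = ["OrthologLink", "OrthologMap", "build_ortholog_map", "orthologs_of"]

DEFAULT_THRESHOLD = 0.3


class OrthologLink(NamedTuple):
    """One retained cross-species ortholog pair from one cluster.

    ``protein_a``/``protein_b`` are ordered by species code so that a link is
    a canonical, hashable record.
    """

    protein_a: ProteinRef
    protein_b: ProteinRef
    score_a: float
    score_b: float
    cluster_id: str


@dataclass
class OrthologMap:
    """All retained ortholog links of one species pair at one threshold."""

    pair: frozenset[str]
    links: set[OrthologLink] = field(default_factory=set)
    threshold: float = DEFAULT_THRESHOLD

    def covers(self, species_a: str, species_b: str) -> bool:
        return self.pair == frozenset({species_a, species_b})

    def partners(self, protein: ProteinRef) -> set[tuple[ProteinRef, float]]:
        """Counterparts of ``protein`` with their inparalog scores."""
        out: set[tuple[ProteinRef, float]] = set()
        for link in self.links:
            if link.protein_a == protein:
                out.add((link.protein_b, link.score_b))
            elif link.protein_b == protein:
                out.add((link.protein_a, link.score_a))
        return out


def _retained(
    n_counterparts: int, counterpart_score: float, threshold: float
) -> bool:
    if counterpart_score == 1.0:  # seed orthologs are always retained
        return True
    if n_counterparts == 1:  # a sole counterpart is kept regardless of score
        return True
    return counterpart_score > threshold


def build_ortholog_map(
    clusters: Iterable[OrthologCluster],
    pair: Sequence[str] | frozenset[str],
    threshold: float = DEFAULT_THRESHOLD,
) -> OrthologMap:
    """Build the ortholog map of one species pair.

    The threshold filter applies only to proteins with more than one
    counterpart in their cluster, and retention is required from both
    perspectives.  A pair not covered by any cluster yields an empty map.
    """
    pair = frozenset(pair)
    if len(pair) != 2:
        raise ConfigError("species pair must contain exactly 2 distinct species")
    if not (0.0 <= threshold <= 1.0):
        raise ConfigError(f"threshold {threshold} outside [0, 1]")
    sp_a, sp_b = sorted(pair)
    links: set[OrthologLink] = set()
    for cluster in clusters:
        if cluster.species_pair != pair:
            continue
        side_a = cluster.side(sp_a)
        side_b = cluster.side(sp_b)
        for ref_a, score_a in side_a:
            for ref_b, score_b in side_b:
                keep_from_a = _retained(len(side_b), score_b, threshold)
                keep_from_b = _retained(len(side_a), score_a, threshold)
                if keep_from_a and keep_from_b:
                    links.add(
                        OrthologLink(ref_a, ref_b, score_a, score_b,
                                     cluster.cluster_id)
                    )
    return OrthologMap(pair=pair, links=links, threshold=threshold)


def orthologs_of(
    maps: Iterable[OrthologMap],
    protein: ProteinRef,
    target_species: str,
) -> set[tuple[ProteinRef, float]]:
    """Orthologs of ``protein`` in ``target_species``, unioned over all maps
    covering that species pair.  Unknown proteins yield an empty set with a
    warning rather than an error."""
    if target_species == protein.species:
        raise ConfigError("target species must differ from the protein's species")
    out: set[tuple[ProteinRef, float]] = set()
    covered = False
    for m in maps:
        if not m.covers(protein.species, target_species):
            continue
        covered = True
        out |= m.partners(protein)
    if covered and not out:
        warnings.warn(
            f"protein {protein!r} has no retained ortholog in {target_species}",
            stacklevel=2,
        )
    return out
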