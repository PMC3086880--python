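"""Interolog derivation and comparison.

An interolog links two proteins of one species when their orthologs
interact in at least one other species.  Direction and effect of the source
interaction are dropped (external protein-protein interaction sets are
undirected) but kept in provenance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import Dataset, ProteinRef, ValidationError, percent
from .orthology import OrthologMap
from .transfer import SignalogPrediction, _ortholog_index

__all__ = [
    "Interolog",
    "derive_interologs",
    "filter_signalog_touching",
    "compare_interolog_sets",
]


def _canonical_pair(a: ProteinRef, b: ProteinRef) -> tuple[ProteinRef, ProteinRef]:
    return (a, b) if a.key <= b.key else (b, a)


@dataclass(frozen=True)
class Interolog:
    """A predicted undirected interaction with its cross-species provenance.

    Each provenance entry is ``(source_species, (source, target))`` — the
    known directed interaction whose endpoints are orthologs of the pair.
    """

    species: str
    pair: tuple[ProteinRef, ProteinRef]
    provenance: frozenset[tuple[str, tuple[ProteinRef, ProteinRef]]]

    def __post_init__(self) -> None:
        a, b = self.pair
        if a.species != self.species or b.species != self.species:
            raise ValidationError("interolog endpoints must belong to its species")
        object.__setattr__(self, "pair", _canonical_pair(a, b))

    def sort_key(self) -> tuple:
        return (self.pair[0].key, self.pair[1].key)


def derive_interologs(
    dataset: Dataset,
    maps: Sequence[OrthologMap],
    target_species: str,
) -> list[Interolog]:
    """Map every known interaction of the other species onto the target.

    For a known interaction a'->b' in species Y != target, every combination
    of target-species orthologs (a of a', b of b') yields the undirected
    interolog (a, b).  Self-pairs (a, a) are suppressed; a self-interaction
    a'=b' mapping to two distinct inparalogs is allowed.  Output is sorted
    and canonical: (a, b) and (b, a) never both appear.
    """
    dataset.species.validate(target_species)
    index = _ortholog_index(maps)

    def orthologs_in_target(p: ProteinRef) -> set[ProteinRef]:
        return {o for sp, o, _ in index.get(p, ()) if sp == target_species}

    support: dict[
        tuple[ProteinRef, ProteinRef],
        set[tuple[str, tuple[ProteinRef, ProteinRef]]],
    ] = {}
    for i in dataset.interactions:
        if i.species == target_species:
            continue
        for a in orthologs_in_target(i.source):
            for b in orthologs_in_target(i.target):
                if a == b:
                    continue
                support.setdefault(_canonical_pair(a, b), set()).add(
                    (i.species, (i.source, i.target))
                )
    out = [
        Interolog(target_species, pair, frozenset(prov))
        for pair, prov in support.items()
    ]
    out.sort(key=Interolog.sort_key)
    return out


def filter_signalog_touching(
    interologs: Iterable[Interolog],
    predictions: Iterable[SignalogPrediction],
) -> list[Interolog]:
    """Keep only interologs where at least one endpoint is a signalog."""
    signalogs = {p.protein for p in predictions}
    return [
        il for il in interologs
        if il.pair[0] in signalogs or il.pair[1] in signalogs
    ]


def _pair_keys(interologs: Iterable[Interolog]) -> tuple[str, set]:
    species = None
    keys = set()
    for il in interologs:
        if species is None:
            species = il.species
        elif il.species != species:
            raise ValidationError(
                "interolog set mixes species; comparison is per-species"
            )
        a, b = il.pair
        keys.add(frozenset({a.key, b.key}))
    return species, keys


def compare_interolog_sets(
    set_a: Iterable[Interolog], set_b: Iterable[Interolog]
) -> dict:
    """Set algebra over two interolog sets of the same species.

    Pairs are compared as unordered, synonym-normalized id pairs.  Because
    the natural denominator of an overlap is ambiguous, the shared fraction
    is reported relative to the union and to each input set.
    """
    sp_a, keys_a = _pair_keys(set_a)
    sp_b, keys_b = _pair_keys(set_b)
    if sp_a is not None and sp_b is not None and sp_a != sp_b:
        raise ValidationError(
            f"cannot compare interologs across species ({sp_a} vs {sp_b})"
        )
    shared = keys_a & keys_b
    union = keys_a | keys_b
    return {
        "n_a": len(keys_a),
        "n_b": len(keys_b),
        "n_shared": len(shared),
        "n_only_a": len(keys_a - keys_b),
        "n_only_b": len(keys_b - keys_a),
        "pct_shared_of_union": percent(len(shared), len(union)) if union else 0.0,
        "pct_shared_of_a": percent(len(shared), len(keys_a)) if keys_a else 0.0,
        "pct_shared_of_b": percent(len(shared), len(keys_b)) if keys_b else 0.0,
    }
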