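"""Domain types for orthology-based signaling-pathway annotation transfer.

The objects here mirror the inputs of a cross-species pathway-transfer
analysis: InParanoid-style ortholog clusters with inparalog scores,
curated pathway-membership annotations for a small set of canonical
signaling pathways, directed signaling interactions, and per-protein
attribute flags used for novelty grading and drug-target scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Mapping

__all__ = [
    "DEFAULT_SPECIES",
    "DEFAULT_PATHWAYS",
    "DEFAULT_PATHWAY_SYNONYMS",
    "ROLES",
    "EVIDENCE_TYPES",
    "EFFECT_TYPES",
    "SignalogError",
    "ParseError",
    "ValidationError",
    "ConfigError",
    "normalize_id",
    "round1",
    "percent",
    "SpeciesConfig",
    "PathwayVocabulary",
    "ProteinRef",
    "ProteinRegistry",
    "OrthologCluster",
    "PathwayAnnotation",
    "Interaction",
    "ProteinAttributes",
    "Dataset",
]

# ---------------------------------------------------------------------------
# Configuration defaults
# ---------------------------------------------------------------------------

#: Default species codes: C. elegans, D. melanogaster, H. sapiens.
DEFAULT_SPECIES: tuple[str, ...] = ("CEL", "DME", "HSA")

#: The eight canonical metazoan signaling pathways used throughout.
DEFAULT_PATHWAYS: tuple[str, ...] = (
    "EGF/MAPK",
    "TGF-beta",
    "IGF/insulin",
    "Notch",
    "WNT",
    "Hedgehog",
    "JAK/STAT",
    "NHR",
)

#: Pathway-name synonyms.  Sub-pathways that other resources list separately
#: (ErbB, JNK, MAPK) are folded into EGF/MAPK before any comparison.
DEFAULT_PATHWAY_SYNONYMS: dict[str, str] = {
    "erbb": "EGF/MAPK",
    "jnk": "EGF/MAPK",
    "mapk": "EGF/MAPK",
    "egf": "EGF/MAPK",
    "ras/mapk": "EGF/MAPK",
    "tgf": "TGF-beta",
    "tgf-b": "TGF-beta",
    "tgfb": "TGF-beta",
    "tgf-β": "TGF-beta",
    "tgfbeta": "TGF-beta",
    "insulin": "IGF/insulin",
    "igf": "IGF/insulin",
    "insulin/igf-1": "IGF/insulin",
    "igf/insulin": "IGF/insulin",
    "wnt/wingless": "WNT",
    "wingless": "WNT",
    "hh": "Hedgehog",
    "jak-stat": "JAK/STAT",
    "nuclear hormone receptor": "NHR",
}

ROLES: tuple[str, ...] = (
    "ligand",
    "receptor",
    "mediator",
    "co-factor",
    "transcription factor",
    "other",
)

EVIDENCE_TYPES: tuple[str, ...] = ("direct", "indirect")
EFFECT_TYPES: tuple[str, ...] = ("stimulation", "inhibition", "unknown")


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------


class SignalogError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(SignalogError):
    """A malformed input row; the message names the file and line."""


class ValidationError(SignalogError):
    """A structurally parsed record violating a domain invariant."""


class ConfigError(SignalogError):
    """An invalid configuration value."""


# ---------------------------------------------------------------------------
# Small numeric helpers
# ---------------------------------------------------------------------------


def normalize_id(token: str) -> str:
    """Normalize a protein identifier for comparison.

    Whitespace is trimmed and the token is case-folded.  Original casing is
    preserved everywhere else; worm (lower-case), fly (mixed) and human
    (upper-case) gene symbols only differ reliably after case-folding.
    """
    return token.strip().casefold()


def round1(x: float) -> float:
    """Round to one decimal using banker's (half-even) rounding."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), ROUND_HALF_EVEN))


def percent(numerator: float, denominator: float) -> float:
    """``100 * numerator / denominator`` rounded to one decimal (half-even)."""
    if denominator == 0:
        raise ZeroDivisionError("percent() with zero denominator")
    return round1(100.0 * numerator / denominator)


# ---------------------------------------------------------------------------
# Vocabulary / configuration objects
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpeciesConfig:
    """The configured species set (>= 2 codes)."""

    codes: tuple[str, ...] = DEFAULT_SPECIES

    def __post_init__(self) -> None:
        if len(self.codes) < 2:
            raise ConfigError("species set must contain at least 2 codes")
        if len(set(self.codes)) != len(self.codes):
            raise ConfigError("species codes must be unique")

    def validate(self, code: str) -> str:
        if code not in self.codes:
            raise ValidationError(
                f"unknown species code {code!r}; configured: {', '.join(self.codes)}"
            )
        return code


@dataclass(frozen=True)
class PathwayVocabulary:
    """Pathway vocabulary plus a user-editable synonym map.

    Resolution is case-insensitive, first against the vocabulary itself and
    then against the synonym map.
    """

    names: tuple[str, ...] = DEFAULT_PATHWAYS
    synonyms: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PATHWAY_SYNONYMS)
    )

    def resolve(self, name: str) -> str:
        """Return the canonical pathway name, raising on unknown names."""
        token = name.strip()
        lowered = token.casefold()
        for canonical in self.names:
            if canonical.casefold() == lowered:
                return canonical
        mapped = {k.casefold(): v for k, v in self.synonyms.items()}.get(lowered)
        if mapped is not None and mapped in self.names:
            return mapped
        raise ValidationError(
            f"unknown pathway name {name!r}; not in vocabulary and no synonym maps it"
        )

    def resolve_or_other(self, name: str) -> str | None:
        """Like :meth:`resolve` but returns ``None`` (with a warning) instead
        of raising; used when reference resources carry pathways outside the
        configured vocabulary."""
        try:
            return self.resolve(name)
        except ValidationError:
            warnings.warn(
                f"pathway name {name!r} is not resolvable; counted as 'other'",
                stacklevel=2,
            )
            return None


# ---------------------------------------------------------------------------
# Core records
# ---------------------------------------------------------------------------


@dataclass(frozen=True, eq=False)
class ProteinRef:
    """A protein of one species, identified case-insensitively.

    ``primary_id`` keeps its original casing for output; equality and
    hashing use the normalized ``key``.  ``synonyms`` always contains the
    normalized primary id.
    """

    species: str
    primary_id: str
    synonyms: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.primary_id.strip():
            raise ValidationError("protein primary_id must be non-empty")
        syn = {normalize_id(s) for s in self.synonyms}
        syn.add(normalize_id(self.primary_id))
        object.__setattr__(self, "synonyms", frozenset(syn))

    @property
    def key(self) -> tuple[str, str]:
        return (self.species, normalize_id(self.primary_id))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinRef):
            return NotImplemented
        return self.key == other.key

    def __hash__(self) -> int:
        return hash(self.key)

    def __lt__(self, other: "ProteinRef") -> bool:
        return self.key < other.key

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{self.species}:{self.primary_id}"


class ProteinRegistry:
    """Registry resolving (species, token) to a canonical :class:`ProteinRef`.

    Every synonym of a registered protein resolves to the same reference, so
    resolution is idempotent by construction.
    """

    def __init__(self) -> None:
        self._by_token: dict[tuple[str, str], ProteinRef] = {}
        self._all: dict[tuple[str, str], ProteinRef] = {}

    def add(self, ref: ProteinRef) -> ProteinRef:
        existing = self._all.get(ref.key)
        if existing is not None:
            if ref.synonyms - existing.synonyms:
                merged = ProteinRef(
                    existing.species,
                    existing.primary_id,
                    existing.synonyms | ref.synonyms,
                )
                self._all[merged.key] = merged
                existing = merged
            ref = existing
        else:
            self._all[ref.key] = ref
        for token in ref.synonyms:
            self._by_token[(ref.species, token)] = ref
        return ref

    def resolve(self, species: str, token: str) -> ProteinRef:
        """Return the registered protein for ``token``; registers a fresh
        reference when the token is unseen."""
        found = self._by_token.get((species, normalize_id(token)))
        if found is not None:
            return found
        return self.add(ProteinRef(species, token.strip()))

    def get(self, species: str, token: str) -> ProteinRef | None:
        return self._by_token.get((species, normalize_id(token)))

    def __iter__(self):
        return iter(self._all.values())

    def __len__(self) -> int:
        return len(self._all)


@dataclass(frozen=True)
class OrthologCluster:
    """One InParanoid-style cluster for a species pair.

    Each member carries an inparalog score in (0, 1]; the two seed orthologs
    (the reciprocal best match anchoring the cluster) score exactly 1.0, one
    per species.
    """

    cluster_id: str
    species_pair: frozenset[str]
    members: tuple[tuple[ProteinRef, float], ...]

    def __post_init__(self) -> None:
        pair = frozenset(self.species_pair)
        object.__setattr__(self, "species_pair", pair)
        object.__setattr__(self, "members", tuple(self.members))
        if len(pair) != 2:
            raise ValidationError(
                f"cluster {self.cluster_id!r}: species_pair must contain 2 species"
            )
        for ref, score in self.members:
            if ref.species not in pair:
                raise ValidationError(
                    f"cluster {self.cluster_id!r}: member {ref!r} outside species pair"
                )
            if not (0.0 < score <= 1.0):
                raise ValidationError(
                    f"cluster {self.cluster_id!r}: inparalog score {score} not in (0,1]"
                )
        for sp in pair:
            side = [s for r, s in self.members if r.species == sp]
            if not side:
                raise ValidationError(
                    f"cluster {self.cluster_id!r}: no member for species {sp}"
                )
            n_seed = sum(1 for s in side if s == 1.0)
            if n_seed != 1:
                raise ValidationError(
                    f"cluster {self.cluster_id!r}: species {sp} has {n_seed} "
                    "members with score 1.0 (expected exactly one seed ortholog)"
                )

    def side(self, species: str) -> list[tuple[ProteinRef, float]]:
        return [(r, s) for r, s in self.members if r.species == species]


@dataclass(frozen=True)
class PathwayAnnotation:
    """Curated membership of a protein in one signaling pathway."""

    protein: ProteinRef
    pathway: str
    role: str = "other"
    pmids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValidationError(
                f"unknown role {self.role!r}; expected one of {', '.join(ROLES)}"
            )
        object.__setattr__(self, "pmids", tuple(self.pmids))


@dataclass(frozen=True)
class Interaction:
    """A directed, species-internal signaling interaction."""

    species: str
    source: ProteinRef
    target: ProteinRef
    evidence: str = "direct"
    effect: str = "unknown"
    pmids: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.source.species != self.species or self.target.species != self.species:
            raise ValidationError(
                f"interaction endpoints {self.source!r}->{self.target!r} must both "
                f"belong to species {self.species}"
            )
        if self.evidence not in EVIDENCE_TYPES:
            raise ValidationError(f"unknown evidence type {self.evidence!r}")
        if self.effect not in EFFECT_TYPES:
            raise ValidationError(f"unknown effect type {self.effect!r}")
        object.__setattr__(self, "pmids", tuple(self.pmids))


@dataclass(frozen=True)
class ProteinAttributes:
    """Literature-derived per-protein flags.

    The four drug-target key properties are membrane localization, enzymatic
    activity, kinase domain content, and disease relatedness.
    ``orthologs_known`` / ``function_known`` record whether orthology and
    biochemical function were already documented in the literature; they
    drive the five-level novelty grading.
    """

    protein: ProteinRef
    is_membrane: bool = False
    is_enzyme: bool = False
    has_kinase_domain: bool = False
    is_disease_related: bool = False
    known_drugs: tuple[str, ...] = ()
    orthologs_known: bool = False
    function_known: bool = False
    disease_names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "known_drugs", tuple(self.known_drugs))
        object.__setattr__(self, "disease_names", tuple(self.disease_names))


@dataclass
class Dataset:
    """All inputs of one analysis run, cross-resolved through one registry."""

    registry: ProteinRegistry = field(default_factory=ProteinRegistry)
    clusters: list[OrthologCluster] = field(default_factory=list)
    annotations: list[PathwayAnnotation] = field(default_factory=list)
    interactions: list[Interaction] = field(default_factory=list)
    attributes: dict[ProteinRef, ProteinAttributes] = field(default_factory=dict)
    species: SpeciesConfig = field(default_factory=SpeciesConfig)
    pathways: PathwayVocabulary = field(default_factory=PathwayVocabulary)

    def known_pairs(self) -> set[tuple[ProteinRef, str]]:
        """Set of all known (protein, pathway) memberships."""
        return {(a.protein, a.pathway) for a in self.annotations}

    def annotations_of(self, protein: ProteinRef) -> list[PathwayAnnotation]:
        return [a for a in self.annotations if a.protein == protein]

    def annotated_proteins(self, species: str | None = None) -> set[ProteinRef]:
        refs = {a.protein for a in self.annotations}
        if species is not None:
            refs = {r for r in refs if r.species == species}
        return refs

    def attributes_of(self, protein: ProteinRef) -> ProteinAttributes:
        """Attributes for ``protein``; absent records resolve to all-false
        flags with a warning, so downstream scoring never crashes on the
        incompleteness of attribute sources."""
        found = self.attributes.get(protein)
        if found is None:
            warnings.warn(
                f"no attribute record for {protein!r}; synthesizing all-false flags",
                stacklevel=2,
            )
            found = ProteinAttributes(protein)
            self.attributes[protein] = found
        return found

    def validate(self) -> None:
        """Check that every referenced protein resolves in the registry."""
        def check(ref: ProteinRef, what: str) -> None:
            if self.registry.get(ref.species, ref.primary_id) is None:
                raise ValidationError(f"{what} references unregistered protein {ref!r}")

        for c in self.clusters:
            for ref, _ in c.members:
                check(ref, f"cluster {c.cluster_id!r}")
        for a in self.annotations:
            check(a.protein, "annotation")
        for i in self.interactions:
            check(i.source, "interaction")
            check(i.target, "interaction")
        seen: set[tuple[ProteinRef, str]] = set()
        for a in self.annotations:
            pair = (a.protein, a.pathway)
            if pair in seen:
                raise ValidationError(
                    f"duplicate annotation ({a.protein!r}, {a.pathway})"
                )
            seen.add(pair)


def register_all(dataset: Dataset, refs: Iterable[ProteinRef]) -> None:
    for ref in refs:
        dataset.registry.add(ref)
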