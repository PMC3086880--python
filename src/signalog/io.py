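"""TSV readers/writers for every input dialect, plus SIF/GraphML export.

All tables are UTF-8, tab-separated, with one header row; lines starting
with ``#`` are comments.  List-valued cells (pmids, drug names, disease
names) use ``;`` separators.  Booleans are written as ``0``/``1``.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .model import (
    EVIDENCE_TYPES,
    EFFECT_TYPES,
    Dataset,
    Interaction,
    OrthologCluster,
    ParseError,
    PathwayAnnotation,
    PathwayVocabulary,
    ProteinAttributes,
    ProteinRef,
    ProteinRegistry,
    SpeciesConfig,
    ValidationError,
)

__all__ = [
    "read_clusters",
    "write_clusters",
    "read_annotations",
    "write_annotations",
    "read_interactions",
    "write_interactions",
    "read_attributes",
    "write_attributes",
    "read_reference_annotations",
    "read_dataset",
    "write_dataset",
    "export_network",
]

CLUSTER_COLUMNS = ["cluster_id", "species_pair", "species", "protein_id", "inparalog_score"]
ANNOTATION_COLUMNS = ["species", "protein_id", "pathway", "role", "pmids"]
INTERACTION_COLUMNS = ["species", "source_id", "target_id", "evidence", "effect", "pmids"]
ATTRIBUTE_COLUMNS = [
    "species", "protein_id", "is_membrane", "is_enzyme", "has_kinase_domain",
    "is_disease_related", "known_drugs", "orthologs_known", "function_known",
    "disease_names",
]
REFERENCE_COLUMNS = ["resource", "species", "protein_id", "pathway_name"]


# ---------------------------------------------------------------------------
# Low-level row plumbing
# ---------------------------------------------------------------------------


def _iter_rows(path: str | Path, columns: Sequence[str]):
    """Yield (line_number, dict) for each data row, checking the header."""
    path = Path(path)
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header: list[str] | None = None
        for lineno, row in enumerate(reader, start=1):
            if not row or (row[0].startswith("#")):
                continue
            if header is None:
                header = [c.strip() for c in row]
                missing = [c for c in columns if c not in header]
                if missing:
                    raise ParseError(
                        f"{path}:{lineno}: missing column(s) {', '.join(missing)}"
                    )
                continue
            if len(row) < len(header):
                row = row + [""] * (len(header) - len(row))
            yield lineno, dict(zip(header, row))


def _split_list(cell: str) -> list[str]:
    return [tok.strip() for tok in cell.split(";") if tok.strip()]


def _parse_pmids(cell: str, path: Path, lineno: int) -> tuple[int, ...]:
    out = []
    for tok in _split_list(cell):
        try:
            out.append(int(tok))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: malformed pmid {tok!r}") from None
    return tuple(out)


def _parse_bool(cell: str, path: Path, lineno: int, column: str) -> bool:
    tok = cell.strip().lower()
    if tok in {"1", "true", "yes"}:
        return True
    if tok in {"0", "false", "no", ""}:
        return False
    raise ParseError(f"{path}:{lineno}: malformed boolean {cell!r} in {column}")


def _open_out(path: str | Path, header_lines: Sequence[str] = ()):
    path = Path(path)
    fh = path.open("w", encoding="utf-8", newline="")
    for line in header_lines:
        fh.write(f"# {line}\n")
    return fh


# ---------------------------------------------------------------------------
# Ortholog clusters
# ---------------------------------------------------------------------------


def read_clusters(
    path: str | Path,
    registry: ProteinRegistry | None = None,
    species: SpeciesConfig | None = None,
) -> list[OrthologCluster]:
    """Read InParanoid-style clusters from ``clusters.tsv``.

    Row order within a cluster is preserved.  A score outside (0, 1] is a
    parse error naming the line; a cluster without exactly one seed ortholog
    (score 1.0) per species is a validation error naming the cluster.
    """
    path = Path(path)
    registry = registry if registry is not None else ProteinRegistry()
    species = species or SpeciesConfig()
    grouped: dict[str, dict] = {}
    for lineno, row in _iter_rows(path, CLUSTER_COLUMNS):
        cid = row["cluster_id"].strip()
        pair = frozenset(p.strip() for p in row["species_pair"].split("-"))
        sp = species.validate(row["species"].strip())
        try:
            score = float(row["inparalog_score"])
        except ValueError:
            raise ParseError(
                f"{path}:{lineno}: malformed inparalog score "
                f"{row['inparalog_score']!r}"
            ) from None
        if not (0.0 < score <= 1.0):
            raise ParseError(
                f"{path}:{lineno}: inparalog score {score} not in (0,1]"
            )
        ref = registry.resolve(sp, row["protein_id"])
        entry = grouped.setdefault(cid, {"pair": pair, "members": []})
        if entry["pair"] != pair:
            raise ParseError(
                f"{path}:{lineno}: cluster {cid!r} rows disagree on species pair"
            )
        entry["members"].append((ref, score))
    clusters = []
    for cid, entry in grouped.items():
        clusters.append(
            OrthologCluster(cid, entry["pair"], tuple(entry["members"]))
        )
    return clusters


def write_clusters(
    clusters: Iterable[OrthologCluster],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with _open_out(path, header_lines) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(CLUSTER_COLUMNS)
        for c in clusters:
            pair = "-".join(sorted(c.species_pair))
            for ref, score in c.members:
                w.writerow([c.cluster_id, pair, ref.species, ref.primary_id,
                            format(score, "g")])


# ---------------------------------------------------------------------------
# Pathway annotations
# ---------------------------------------------------------------------------


def read_annotations(
    path: str | Path,
    registry: ProteinRegistry | None = None,
    species: SpeciesConfig | None = None,
    pathways: PathwayVocabulary | None = None,
) -> list[PathwayAnnotation]:
    """Read pathway-membership annotations.

    Duplicate (protein, pathway) rows are collapsed with their pmids
    unioned.  A pathway name outside the vocabulary and synonym map is an
    error listing the offending name.
    """
    path = Path(path)
    registry = registry if registry is not None else ProteinRegistry()
    species = species or SpeciesConfig()
    pathways = pathways or PathwayVocabulary()
    merged: dict[tuple[ProteinRef, str], dict] = {}
    for lineno, row in _iter_rows(path, ANNOTATION_COLUMNS):
        sp = species.validate(row["species"].strip())
        ref = registry.resolve(sp, row["protein_id"])
        pathway = pathways.resolve(row["pathway"])
        role = row["role"].strip() or "other"
        pmids = _parse_pmids(row.get("pmids", ""), path, lineno)
        key = (ref, pathway)
        entry = merged.setdefault(key, {"role": role, "pmids": []})
        entry["pmids"].extend(pmids)
    return [
        PathwayAnnotation(ref, pathway, entry["role"],
                          tuple(dict.fromkeys(entry["pmids"])))
        for (ref, pathway), entry in merged.items()
    ]


def write_annotations(
    annotations: Iterable[PathwayAnnotation],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with _open_out(path, header_lines) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ANNOTATION_COLUMNS)
        for a in annotations:
            w.writerow([a.protein.species, a.protein.primary_id, a.pathway,
                        a.role, ";".join(str(p) for p in a.pmids)])


# ---------------------------------------------------------------------------
# Interactions
# ---------------------------------------------------------------------------


def read_interactions(
    path: str | Path,
    registry: ProteinRegistry | None = None,
    species: SpeciesConfig | None = None,
) -> list[Interaction]:
    path = Path(path)
    registry = registry if registry is not None else ProteinRegistry()
    species = species or SpeciesConfig()
    out = []
    for lineno, row in _iter_rows(path, INTERACTION_COLUMNS):
        sp = species.validate(row["species"].strip())
        evidence = row["evidence"].strip() or "direct"
        effect = row["effect"].strip() or "unknown"
        if evidence not in EVIDENCE_TYPES:
            raise ParseError(f"{path}:{lineno}: unknown evidence {evidence!r}")
        if effect not in EFFECT_TYPES:
            raise ParseError(f"{path}:{lineno}: unknown effect {effect!r}")
        out.append(
            Interaction(
                sp,
                registry.resolve(sp, row["source_id"]),
                registry.resolve(sp, row["target_id"]),
                evidence,
                effect,
                _parse_pmids(row.get("pmids", ""), path, lineno),
            )
        )
    return out


def write_interactions(
    interactions: Iterable[Interaction],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    with _open_out(path, header_lines) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(INTERACTION_COLUMNS)
        for i in interactions:
            w.writerow([i.species, i.source.primary_id, i.target.primary_id,
                        i.evidence, i.effect, ";".join(str(p) for p in i.pmids)])


# ---------------------------------------------------------------------------
# Protein attributes
# ---------------------------------------------------------------------------


def read_attributes(
    path: str | Path,
    registry: ProteinRegistry | None = None,
    species: SpeciesConfig | None = None,
) -> dict[ProteinRef, ProteinAttributes]:
    path = Path(path)
    registry = registry if registry is not None else ProteinRegistry()
    species = species or SpeciesConfig()
    out: dict[ProteinRef, ProteinAttributes] = {}
    for lineno, row in _iter_rows(path, ATTRIBUTE_COLUMNS):
        sp = species.validate(row["species"].strip())
        ref = registry.resolve(sp, row["protein_id"])
        attrs = ProteinAttributes(
            ref,
            is_membrane=_parse_bool(row["is_membrane"], path, lineno, "is_membrane"),
            is_enzyme=_parse_bool(row["is_enzyme"], path, lineno, "is_enzyme"),
            has_kinase_domain=_parse_bool(
                row["has_kinase_domain"], path, lineno, "has_kinase_domain"),
            is_disease_related=_parse_bool(
                row["is_disease_related"], path, lineno, "is_disease_related"),
            known_drugs=tuple(_split_list(row.get("known_drugs", ""))),
            orthologs_known=_parse_bool(
                row["orthologs_known"], path, lineno, "orthologs_known"),
            function_known=_parse_bool(
                row["function_known"], path, lineno, "function_known"),
            disease_names=tuple(_split_list(row.get("disease_names", ""))),
        )
        out[ref] = attrs
    return out


def write_attributes(
    attributes: dict[ProteinRef, ProteinAttributes] | Iterable[ProteinAttributes],
    path: str | Path,
    header_lines: Sequence[str] = (),
) -> None:
    records = attributes.values() if isinstance(attributes, dict) else attributes
    with _open_out(path, header_lines) as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ATTRIBUTE_COLUMNS)
        for a in records:
            w.writerow([
                a.protein.species, a.protein.primary_id,
                int(a.is_membrane), int(a.is_enzyme), int(a.has_kinase_domain),
                int(a.is_disease_related), ";".join(a.known_drugs),
                int(a.orthologs_known), int(a.function_known),
                ";".join(a.disease_names),
            ])


# ---------------------------------------------------------------------------
# Reference pathway annotations (KEGG/Reactome-like)
# ---------------------------------------------------------------------------


def read_reference_annotations(
    path: str | Path,
    species: SpeciesConfig | None = None,
) -> list[dict]:
    """Read a reference resource table as raw records.

    Pathway names are *not* resolved here: the comparison layer maps them
    through the synonym map and counts unresolvable names as "other".
    """
    path = Path(path)
    species = species or SpeciesConfig()
    out = []
    for _lineno, row in _iter_rows(path, REFERENCE_COLUMNS):
        out.append(
            {
                "resource": row["resource"].strip(),
                "species": species.validate(row["species"].strip()),
                "protein_id": row["protein_id"].strip(),
                "pathway_name": row["pathway_name"].strip(),
            }
        )
    return out


# ---------------------------------------------------------------------------
# Whole-dataset convenience
# ---------------------------------------------------------------------------

_STANDARD_FILES = {
    "clusters": "clusters.tsv",
    "annotations": "annotations.tsv",
    "interactions": "interactions.tsv",
    "attributes": "attributes.tsv",
}


def read_dataset(directory: str | Path) -> Dataset:
    """Load the standard TSV set from ``directory``; missing files load as
    empty sections."""
    directory = Path(directory)
    ds = Dataset()
    p = directory / _STANDARD_FILES["clusters"]
    if p.exists():
        ds.clusters = read_clusters(p, ds.registry, ds.species)
    p = directory / _STANDARD_FILES["annotations"]
    if p.exists():
        ds.annotations = read_annotations(p, ds.registry, ds.species, ds.pathways)
    p = directory / _STANDARD_FILES["interactions"]
    if p.exists():
        ds.interactions = read_interactions(p, ds.registry, ds.species)
    p = directory / _STANDARD_FILES["attributes"]
    if p.exists():
        ds.attributes = read_attributes(p, ds.registry, ds.species)
    ds.validate()
    return ds


def write_dataset(
    dataset: Dataset, directory: str | Path, header_lines: Sequence[str] = ()
) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_clusters(dataset.clusters, directory / _STANDARD_FILES["clusters"],
                   header_lines)
    write_annotations(dataset.annotations,
                      directory / _STANDARD_FILES["annotations"], header_lines)
    write_interactions(dataset.interactions,
                       directory / _STANDARD_FILES["interactions"], header_lines)
    write_attributes(dataset.attributes,
                     directory / _STANDARD_FILES["attributes"], header_lines)


# ---------------------------------------------------------------------------
# Network export
# ---------------------------------------------------------------------------


def _node_id(ref: ProteinRef) -> str:
    return f"{ref.species}:{ref.primary_id}"


def build_network(dataset: Dataset, predictions=(), interologs=()) -> nx.Graph:
    """Assemble the annotated network exported as SIF or GraphML.

    Nodes carry species, known pathways, predicted pathways, and a status
    flag; known directed interactions and predicted undirected interologs
    become edges with their own status.
    """
    g = nx.Graph()
    known_paths: dict[ProteinRef, list[str]] = {}
    for a in dataset.annotations:
        known_paths.setdefault(a.protein, []).append(a.pathway)
    predicted_paths: dict[ProteinRef, list[str]] = {}
    for p in predictions:
        predicted_paths.setdefault(p.protein, []).append(p.pathway)

    def add_node(ref: ProteinRef) -> str:
        nid = _node_id(ref)
        if nid not in g:
            has_known = ref in known_paths
            g.add_node(
                nid,
                species=ref.species,
                pathways=";".join(sorted(set(known_paths.get(ref, [])))),
                predicted_pathways=";".join(sorted(set(predicted_paths.get(ref, [])))),
                status="known" if has_known or ref not in predicted_paths
                else "predicted",
            )
        return nid

    for ref in dataset.registry:
        add_node(ref)
    for p in predictions:
        add_node(p.protein)
    for i in dataset.interactions:
        u, v = add_node(i.source), add_node(i.target)
        g.add_edge(u, v, evidence=i.evidence, effect=i.effect, status="known",
                   relation="known")
    for il in interologs:
        a, b = sorted(il.pair)
        u, v = add_node(a), add_node(b)
        if not g.has_edge(u, v):
            g.add_edge(u, v, evidence="indirect", effect="unknown",
                       status="predicted", relation="interolog")
    return g


def export_network(
    dataset: Dataset,
    predictions=(),
    interologs=(),
    fmt: str = "graphml",
    path: str | Path = "network.graphml",
) -> None:
    """Write the known + predicted network as SIF or GraphML.

    SIF lines are ``node<TAB>relation<TAB>node`` with relation ``known`` or
    ``interolog``; GraphML carries the full node/edge attribute set.
    """
    fmt = fmt.lower()
    if fmt not in {"sif", "graphml"}:
        raise ValidationError(f"unsupported export format {fmt!r}")
    g = build_network(dataset, predictions, interologs)
    path = Path(path)
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        with path.open("w", encoding="utf-8") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{data['relation']}\t{v}\n")
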