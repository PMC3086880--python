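import itertools

import pytest

from signalog import (
    Dataset,
    GeneratorConfig,
    OrthologCluster,
    PathwayAnnotation,
    ProteinRef,
    build_ortholog_map,
    generate,
    load_fixture,
)

SPECIES_PAIRS = [("CEL", "DME"), ("CEL", "HSA"), ("DME", "HSA")]


@pytest.fixture
def table1():
    return load_fixture("table1_notch")


@pytest.fixture
def table1_maps(table1):
    return [build_ortholog_map(table1.clusters, pair) for pair in SPECIES_PAIRS]


def make_random_dataset(seed: int, n: int = 40, **overrides) -> Dataset:
    params = dict(
        seed=seed,
        n_proteins_per_species=n,
        cluster_coverage=0.6,
        inparalog_extra_rate=0.6,
        annotation_rate=0.5,
        multi_pathway_rate=0.2,
        interaction_density=1.0,
    )
    params.update(overrides)
    return generate(GeneratorConfig(**params))


def all_maps(dataset, threshold: float = 0.3):
    pairs = {frozenset(c.species_pair) for c in dataset.clusters}
    return [
        build_ortholog_map(dataset.clusters, p, threshold)
        for p in sorted(pairs, key=sorted)
    ]


@pytest.fixture
def tiny_dataset() -> Dataset:
    """Two worm proteins with annotated fly/human orthologs, one known edge."""
    ds = Dataset()
    w1 = ds.registry.add(ProteinRef("CEL", "w1"))
    w2 = ds.registry.add(ProteinRef("CEL", "w2"))
    f1 = ds.registry.add(ProteinRef("DME", "f1"))
    f2 = ds.registry.add(ProteinRef("DME", "f2"))
    ds.clusters = [
        OrthologCluster("c1", frozenset({"CEL", "DME"}), ((w1, 1.0), (f1, 1.0))),
        OrthologCluster("c2", frozenset({"CEL", "DME"}), ((w2, 1.0), (f2, 1.0))),
    ]
    ds.annotations = [
        PathwayAnnotation(f1, "Notch", "receptor"),
        PathwayAnnotation(f2, "WNT", "ligand"),
    ]
    from signalog import Interaction

    ds.interactions = [Interaction("DME", f1, f2, "direct", "stimulation")]
    ds.validate()
    return ds


def cross_species_pairs(codes):
    return list(itertools.combinations(codes, 2))
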