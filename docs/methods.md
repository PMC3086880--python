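# Methods

## Model

The package treats cross-species pathway annotation transfer as a
three-step procedure.

**1. Orthology.** Input orthology is given as InParanoid-style clusters for
each species pair. A cluster groups sequences related by descent; each
member carries an inparalog score in (0, 1], with exactly one score-1.0
member per species (the *seed* pair, the best reciprocal match anchoring
the cluster). From a cluster, every cross-species member pair is a
candidate ortholog link. A counterpart is *retained* from a protein's
perspective when it is the protein's only counterpart in the cluster, when
it is a seed (score 1.0), or when its inparalog score strictly exceeds the
threshold (default 0.3). A link survives only when retained from both
perspectives. The two-sided rule is a design choice — the one-sided variant
would make "x is an ortholog of y" asymmetric, which propagates confusingly
into prediction provenance — and it makes the link relation symmetric by
construction. Strictness ("higher than 0.3", not "at least") follows the
usual reading of the filter. Consequences tested as properties: raising the
threshold never adds links, and at threshold 1.0 only seed–seed links
remain.

**2. Transfer.** For a chosen target species, the candidate universe is
every target-species protein appearing in any cluster; proteins without
orthology can never receive a transfer. For candidate *p* and each pathway
*P* annotated to any retained ortholog of *p* (in any other species),
(*p*, *P*) is emitted unless that exact membership is already curated. A
protein already annotated to *some* pathway can still receive a different
one; `is_new_protein` distinguishes entirely unannotated proteins.
Predictions supported from several source species are merged into a single
record whose provenance lists every supporting ortholog, so each (protein,
pathway) pair is counted once. The precondition "no known signaling role"
is operationalized per (protein, pathway) pair; the stricter variant that
excludes any protein participating in a known interaction is available as
`require_no_interactions` (CLI `--require-no-interactions`), because both
readings are defensible and they differ on proteins that interact with
pathway members without being annotated themselves.

**3. Assessment.**

- *Coverage statistics* justify the transfer direction: per species, the
  percentage of annotated proteins with ≥ 1 ortholog; of those, the
  percentage with ≥ 1 ortholog that is itself annotated; and with ≥ 1
  ortholog sharing an identical pathway. The latter two use
  "annotated proteins with ≥ 1 ortholog" as denominator — the quantity of
  interest is the conditional success rate of transfer given that orthology
  exists. The summary mean is the unweighted arithmetic mean of the
  per-species ortholog-signaling fractions; species without annotated
  proteins are reported as missing and excluded with a warning.
- *Novelty classes* grade predictions 1–5 from literature-derived flags:
  5 = orthology, function, and some pathway membership already documented;
  4 = orthology and function known; 3 = function known only; 2 = orthology
  known only; 1 = neither. The informal "and/or" overlap between the lowest
  classes is resolved most-specific-first so the classes partition all
  eight flag combinations. "Known orthologs" here means orthology
  documented in the literature (an attribute flag), deliberately distinct
  from the cluster-derived orthology driving the transfer — the method's
  point is precisely to annotate proteins whose orthology had not been
  appreciated.
- *Reference overlap*: a signalog is "present" in a KEGG/Reactome-like
  table when listed under any pathway (resolvable or not); "same pathway"
  requires a predicted pathway to match a reference pathway after synonym
  mapping (ErbB/JNK/MAPK → EGF/MAPK, applied before comparison). The novel
  fraction is protein-level: `100 − 100·n_same_pathway/n_present_in_ref`,
  and 100.0 when nothing is present. Comparisons against another
  prediction set count synonym-mapped (protein, pathway) pairs restricted
  to the shared proteins.
- *Interologs*: a known directed interaction a′→b′ in species Y maps to the
  undirected target pair (a, b) for every combination of target orthologs.
  Self-pairs (a, a) are suppressed; a self-interaction mapping onto two
  distinct inparalogs is kept. Overlap percentages between interolog sets
  are reported against the union and against each set, since the natural
  denominator is ambiguous.
- *Drug-target relevance* is the count (0–4) of membrane localization,
  enzymatic activity, kinase domain, and disease relatedness. Candidate
  tables have one row per signalog protein, sorted by score (descending)
  then protein id — lexicographic tie-break for determinism.

## Identifiers, formats, numerics

Protein identifiers are compared after trimming and case-folding, with
original casing preserved in output (worm, fly, and human symbol
conventions differ only in case). Synonyms resolve through a registry;
resolution is idempotent. Both gene symbols and accession-style ids pass
through the same normalization, so either may be used. All tables are
UTF-8 TSV with a header row, `#` comments, `;`-separated list cells, and
0/1 booleans. Missing attribute records resolve to all-false flags with a
warning — curated attribute sources are always incomplete and a missing
record must not abort a prediction run. Percentages are rounded to one
decimal with banker's (half-even) rounding so printed values are exactly
reproducible. Networks export to GraphML (full attributes) or SIF
(`node relation node`, relation `known` or `interolog`).

## Synthetic data

The generator emulates the statistical shape of the curated inputs, one
deterministic stream per stage derived from a single seed (same seed ⇒
byte-identical files). Defaults: 3 species × 200 proteins; 70 % of each
species' proteins anchor a cluster per pair (between the observed
per-species orthology coverage extremes); Poisson(0.4) extra inparalogs per
cluster side with uniform (0, 1) scores; 50 % of clustered proteins
annotated; 15 % of annotated proteins get a second pathway (matching the
observed multi-pathway share of predictions); 1.5 interactions per
annotated protein; attribute flag rates of 0.30 (membrane), 0.40 (enzyme),
0.15 (kinase domain), 0.25 (disease, matching the observed share among
human signalogs), 0.50 (orthology/function known), 0.07 with a known drug.

What the generator does **not** emulate: realistic inparalog-score
distributions (scores are uniform, real scores cluster near 1), phylogenetic
correlation between the three pairwise cluster sets (each pair is sampled
independently, so three-way ortholog triangles are rare), pathway-size
imbalance (real pathways differ widely in membership), and annotation bias
toward well-studied proteins. Passing tests on generated data therefore
demonstrate algorithmic correctness — oracle equivalence, invariants,
determinism — not biological recall on real resources.

Packaged fixtures hand-encode the published worked examples: the six
validated worm Notch signalogs with their fly/human orthologs and novelty
flags; the 19-row human drug-target relevance table (the four underlying
flags are printed only as a score, so they are synthetic placeholders
filled in a fixed order — membrane, enzyme, kinase, disease — consistent
with the two documented all-four proteins and the two three-without-disease
proteins); the worm and fly orthodisease tables; and the headline
prediction-count breakdown (253 proteins, 88/92/73 per species, 39
multi-pathway proteins carrying 87 annotations, 301 annotations). Fixture
attributes not printed in the source tables default to false and are
documented as placeholders.

## Problem sizes and known limitations

Property suites run the brute-force oracles on 200 random instances of 12
proteins per species (plus larger single instances up to 60), which keeps
the full suite under a few seconds while exercising every retention/transfer
branch; the oracle implementations in the tests are independent
re-derivations, not calls back into the library. The genome-scale counts of
a real run depend on specific InParanoid and pathway-database releases and
are not reproducible from fixtures; the packaged checks therefore target
the worked examples and arithmetic-consistent summaries. Other limitations:
clusters are assumed pairwise (no multi-species clusters); interolog
confidence filtering beyond orthology is out of scope; and attribute flags
are taken as given rather than mined from the literature.
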