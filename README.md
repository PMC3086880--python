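# signalog

Orthology-based transfer of signaling-pathway membership between species.

Signal transduction pathways are curated at very different depths in
different organisms: the same pathway may be mapped in detail in the fly but
only sketched in the worm or in humans. `signalog` closes such gaps by
systematic annotation transfer: a protein is predicted to be a member of a
signaling pathway — a *signalog* — whenever an ortholog in another species
is a known member of that pathway. The package implements the full workflow
for a configurable species set (defaults: *C. elegans* `CEL`,
*D. melanogaster* `DME`, *H. sapiens* `HSA`) over eight canonical pathways
(EGF/MAPK, TGF-beta, IGF/insulin, Notch, WNT, Hedgehog, JAK/STAT, NHR):

- **Ortholog maps** from InParanoid-style clusters. Each cluster of a
  species pair anchors one *seed* ortholog per side (inparalog score 1.0)
  plus inparalogs scored in (0, 1). For a protein with more than one
  counterpart in its cluster, only counterparts with score > 0.3 (strict,
  configurable) are used; a sole counterpart and seed orthologs are always
  kept, and retention is applied from both sides so the map is symmetric.
- **Signalog prediction**: for each target-species protein *p* in a cluster
  and each pathway *P* annotated to an ortholog of *p*, emit (*p*, *P*)
  unless that membership is already curated. Provenance records every
  supporting ortholog.
- **Interologs**: predicted undirected interactions — two target-species
  proteins are linked if their orthologs interact in another species — plus
  set-algebra comparison against external interolog collections.
- **Novelty assessment**: a five-class grading from literature flags
  (orthology known / biochemical function known / pathway already known),
  and overlap statistics against KEGG/Reactome-like reference tables with a
  pathway-synonym map (ErbB/JNK/MAPK fold into EGF/MAPK).
- **Drug-target relevance**: score 0–4 counting membrane localization,
  enzymatic activity, kinase domain, disease relatedness; candidate ranking
  and orthodisease reports (model-organism signalogs whose human orthologs
  are disease-linked).
- **Synthetic data + packaged fixtures** so every stage runs offline, and a
  `signalog` CLI with SIF/GraphML network export.

## Worked example

The six experimentally validated worm Notch-pathway signalogs, recovered
from their annotated fly/human orthologs:

```python
import signalog as sg

ds = sg.load_fixture("table1_notch")
maps = [sg.build_ortholog_map(ds.clusters, pair)
        for pair in [("CEL", "DME"), ("CEL", "HSA"), ("DME", "HSA")]]
preds = sg.predict_signalogs(ds, maps, "CEL")
for p in preds:
    support = ", ".join(f"{sp}:{o.primary_id}" for sp, o, _ in sorted(p.provenance))
    print(f"{p.protein.primary_id:<10} -> {p.pathway}  (orthologs: {support})")
```

prints

```
aqp-6      -> Notch  (orthologs: DME:bip)
crb-1      -> Notch  (orthologs: DME:crb, HSA:NOTCH2)
D1009.3    -> Notch  (orthologs: DME:sca)
F10D7.5    -> Notch  (orthologs: DME:neur, HSA:NEURL)
nsh-1      -> Notch  (orthologs: DME:sno, HSA:SBNO1)
num-1      -> Notch  (orthologs: DME:numb, HSA:NUMB)
```

Each worm gene had no prior pathway annotation; its fly (and, where
present, human) ortholog is a curated Notch member, so Notch membership is
transferred with the supporting orthologs as provenance.
`sg.summarize_predictions(preds)` reports 6 signalog proteins carrying 6
pathway annotations, all in Notch.

The same run from the shell:

```sh
signalog simulate --seed 7 --out data/          # or point --data at real TSVs
signalog predict --data data/ --target CEL --threshold 0.3 --out predictions.tsv
signalog interologs --data data/ --target CEL --signalog-only --out interologs.tsv
signalog export --data data/ --target CEL --fmt graphml --out network.graphml
```

Input dialects (tab-separated, `#` comments, `;`-separated lists) are
documented in `signalog/io.py`; `docs/methods.md` describes the model,
parameter choices, and limitations.

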