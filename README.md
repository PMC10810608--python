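# bcrep

Paired single-cell B-cell-receptor (BCR) repertoire simulation and
analysis: germline-based V(D)J rearrangement simulation under genotype
presets, alignment-based annotation with a four-way productivity
classification, κ/λ repertoire-skew statistics, and Levenshtein-1 CDR3
similarity networks for clonal-expansion detection.

## The problem

During B-cell development each cell assembles its antigen receptor by
V(D)J recombination: first the heavy chain (Igh), then a light chain —
the κ locus (Igk) is tried first, and the λ locus (Igl) is a fallback
used when Igk rearrangement fails or the resulting receptor is
autoreactive and receptor editing exhausts the κ options. Secondary Igk
rearrangements walk to downstream J genes (so a raised *Igkj5* share is a
molecular signature of editing), and the murine Igl locus is organised in
two cassettes — {*Iglv2*, *Iglv3*} → *Iglj2-c2* (λ2) and {*Iglv1*} →
*Iglj3-c3* (λ3) / *Iglj1-c1* (λ1) — with recombination essentially
confined within a cassette.

Genetic perturbations of this pathway shift measurable repertoire
statistics: the κ:λ isotype ratio, λ-family usage, V/J gene-usage vectors
(compared across genotypes by Pearson correlation), V–J pairing matrices,
productive/unproductive read fractions, and the clonality of CDR3
networks. `bcrep` packages both a simulator that generates paired
single-cell repertoires with exactly this statistical structure (so every
analysis step can be validated as a parameter-recovery experiment) and
the analysis pipeline itself, which also accepts externally produced
reads or AIRR-style tables against a user-supplied germline FASTA.

At its core are:

* a **two-mode genotype simulator** — *empirical* (frequency presets,
  e.g. κ share = 0.83 for a control repertoire, 0.98 for the
  λ-deficient knockout) and *mechanistic* (a per-cell state machine over
  Igl-locus opening probability, precursor life-span, and
  receptor-editing efficiency);
* **V(D)J annotation** by affine-gap local alignment against the
  germline set, IMGT-style junction extraction (Cys…Trp/Phe), and the
  four-way productivity call {productive, out_of_frame, stop_codon,
  non_ig};
* **repertoire statistics** (usage tables, Pearson r between usage
  vectors, V–J pairing with cross-cassette mass, editing signature, CDR3
  length/charge, clonotype tables);
* **CDR3 similarity networks**: nodes are unique CDR3 amino-acid
  sequences, edges connect pairs at Levenshtein distance exactly 1
  (deletion-neighborhood hashing, verified exactly), connected
  components of size ≥ 3 flag candidate clonal expansions.

## Worked example

```python
import bcrep
from bcrep import stats as S

gs = bcrep.build_default_germline()              # toy murine Igh/Igk/Igl
preset = bcrep.get_preset("ctrl")                # control genotype
cells, reads, manifest = bcrep.simulate_repertoire(gs, preset, 2000, seed=11)
records = bcrep.annotate_repertoire(reads, gs)   # AIRR-style DataFrame

iso, fam = S.isotype_family_frequencies(records, gs)
print("kappa share:", round(float(iso["kappa"]), 3))
_, jk5 = S.editing_signature(records)
print("Igkj5 share:", round(float(jk5), 3))
pf = S.productivity_fractions(records).set_index("locus")
print("IGH unproductive:", round(float(pf.loc["IGH", "unproductive"]), 3))

filtered = S.preprocess(records)
kappa = filtered[filtered["locus"] == "IGK"]
net = bcrep.build_network(kappa["cdr3_aa"].value_counts().to_dict())
print(len(net.nodes), "nodes,", len(net.edges), "edges,",
      len(net.expanded_components), "expanded components")
```

prints

```
kappa share: 0.835
Igkj5 share: 0.105
IGH unproductive: 0.91
214 nodes, 647 edges, 4 expanded components
```

At 2,000 cells the κ share (0.835) and Igkj5 share (0.105) recover the
control preset (0.83 / 0.10) within binomial noise; 91% of raw heavy
reads are classified unproductive against a truth fraction of 92%. The κ
CDR3 network is polyclonal: many nodes, no dominant component.

The same stages run from the shell:

```bash
bcrep simulate --seed 1 --preset ctrl --n-cells 2000 --out run/
bcrep annotate --out run/ run/reads.fasta
bcrep stats    --out run/ run/rearrangements.tsv
bcrep network  --out run/ run/rearrangements.tsv
bcrep compare  --seed 1 --preset-a ctrl --preset-b bko --n-cells 2000 --out cmp/
```

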