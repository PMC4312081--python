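# tundradiet

A tested pipeline for DNA-metabarcoding diet analysis of sympatric
herbivores, built around the winter-diet question for the two High-Arctic
lemmings — collared (*Dicrostonyx groenlandicus*) and brown (*Lemmus
trimucronatus*) — whose fecal pellets can be profiled with the plant trnL
P6-loop barcode. It takes per-sample sequence-variant count tables from two
complementary primer pairs (*g-h*, vascular-biased; *c-h*, universal for
plants) and produces diet profiles, niche-overlap and specialization
statistics, and food-selection ratios against quadrat-sampled plant
availability. A synthetic-data generator reproduces the structure of every
input with known ground truth, so each stage is testable end to end.

## What it computes

With p_ij the proportion of plant family *j* in pellet sample *i* and
q_j the population mean diet:

- **Schoener overlap** between two diets p, q:
  `O = 1 − ½ Σ_j |p_j − q_j|` (0 disjoint, 1 identical).
- **Trophic niche width**: Shannon entropy `TNW = −Σ_j q_j ln q_j` (nats).
- **Individual specialization**:
  `IS = (1/N) Σ_i [1 − ½ Σ_j |p_ij − q_j|]`, with a sample-size-matched
  resampling comparator for unequal cohorts.
- **Manly selection ratio** (design II, use and availability both sampled):
  `ŵ_i = ō_i / π̄_i`, with delta-method variance
  `Var(ŵ_i) = s²_o/(n_o π̄_i²) + ō_i² s²_π/(n_π π̄_i⁴)` and a z-based
  significance class (−, (−), 0, (+), +) against neutrality w = 1.
- **Two-marker fusion**: vascular family composition from *g-h*, the
  vascular:bryophyte split and moss family composition from *c-h*.
- Supporting machinery: in-silico PCR with an IUPAC-aware mismatch budget,
  lowest-common-ancestor taxon assignment with a local-flora filter,
  consumer species ID from diagnostic amplicon lengths, and rank-transform /
  aligned-rank-transform ANOVAs for group and interaction tests.

## Worked example

Generate a ground-truthed synthetic survey (76 pellet samples, 16
availability quadrats), fuse the two markers, and compute the statistics:

```sh
tundradiet simulate --preset bylot-like --seed 1 --outdir demo
tundradiet compose --gh demo/family_counts.tsv --ch demo/family_counts.tsv \
    --metadata demo/metadata.tsv --out demo/composition.tsv
tundradiet nichestats --composition demo/composition.tsv \
    --resample 22:100:1 --out demo/niche.tsv
tundradiet selection --composition demo/composition.tsv \
    --quadrats demo/quadrats.tsv --group vascular \
    --exclude-family Ericaceae --out demo/selection.tsv
```

`demo/niche.tsv` from that run:

```
statistic           group              value
tnw                 Dicrostonyx        0.900
is                  Dicrostonyx        0.848
is_resampled_mean   Dicrostonyx        0.848
is_resampled_sd     Dicrostonyx        0.000
tnw                 Lemmus             1.545
is                  Lemmus             0.786
is_resampled_mean   Lemmus             0.790
is_resampled_sd     Lemmus             0.011
schoener_overlap    between-species    0.723
```

The brown lemming (Lemmus) cohort has the wider niche (TNW 1.54 vs 0.90 —
it eats mosses, the collared cohort essentially does not) and slightly
stronger individual specialization (IS 0.79 vs 0.85; 1 means everyone eats
the population diet). The 22-of-54 resampled IS matches the full-sample
value, so the comparison is not a sample-size artifact. `demo/selection.tsv`
shows Salicaceae — the dominant food of both species — eaten in proportion
to its availability (w = 1.0, class 0) and Juncaceae avoided (w = 0.2,
class −), mirroring the survey the generator emulates.

The same commands run on real data: `assign` turns variant tables into
family counts against a reference library formatted with `refmake`, and
`speciesid` classifies pellet samples by diagnostic amplicon length.

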