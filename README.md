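# promoterpath

Tools for predicting — and then testing the prediction of — promoter-motif
evolution in the transcription network of bacteriophage T7.

## The problem

T7's ~40-kb genome is transcribed almost entirely by its own single-subunit
RNA polymerase through a set of 17 highly similar promoters. Promoter
specificity is dominated by a three-nucleotide motif at positions −11..−9:
fifteen wild-type promoters carry `GAC`, two carry `AAC`. When a phage
lacking its polymerase gene (T7Δ1) is forced to grow on an engineered
polymerase whose optimal motif is `CGG` — three substitutions away from
`GAC` — every promoter in the genome comes under selection to re-match the
new enzyme. Because the motif is only three bases, the genotype space is
just 4³ = 64 triplets, and the shortest mutational routes from `GAC` to
`CGG` form a 3-cube with 3! = 6 direct paths through 6 intermediates.

`promoterpath` implements that prediction-and-test loop:

1. **Sequence space** (`sequence_space`): enumeration of the 64-triplet
   space, Hamming distances, the 2^d − 2 direct intermediates and the d!
   direct paths between two motifs.
2. **Landscape** (`landscape`): in vitro transcription activities (percent
   of a reference polymerase/promoter pair, triplicate SEM) attached to
   motifs; from them the layered *prediction matrix*, a *greedy prediction
   DAG* (from each reachable motif, step to the highest-activity adjacent
   motif one layer closer to the target, keeping near-ties within a
   relative tolerance, default 0.15), counts of *accessible* direct paths
   (activity strictly increasing at every step), and strong-selection
   weak-mutation step probabilities `P(g→h) ∝ max(0, a(h)/a(g) − 1)`.
3. **Serial-passage simulator** (`passage_sim`): multi-promoter phage
   genomes evolving under a landscape-derived fitness
   `w = Σ_l weight_l · x_l/(K + x_l)` with
   `x_l = copy_number_l · expression · a(triplet_l)`, through repeated
   growth (fitness-weighted multinomial resampling with per-base mutation
   and per-locus duplication) and bottleneck transfer, plus finite-depth
   sequencing sampling of allele frequencies.
4. **Observed data** (`observed_data`): promoter annotations (BED-like TSV
   or GFF3), variant tables from population sequencing, assignment of
   genome positions to promoter motif windows, and the scoring of every
   observed triplet as ancestral / target / predicted single / predicted
   double / unanticipated.
5. **Phenotypes** (`phenotype`): lysis time from OD600 curves, plate
   fitness as doublings/hour, endpoint transcription activity.
6. **Synthetic data** (`synthetic_data`): deterministic, seeded generators
   for every input, including the bundled observation fixture encoding the
   text-reported outcome of the 4-line, 100-passage experiment.

## Worked example

```sh
promoterpath synth   --outdir inputs --seed 11
promoterpath predict --activity-table inputs/activity.tsv --out predict
```

```
prediction DAG: 5 edges; 6 accessible direct path(s)
```

The greedy DAG on the synthetic activity table reproduces the predicted
step structure — ancestral `GAC` to the best single mutant `GAG`, then the
two near-tied double mutants, then the target:

```
from  to   from_activity_pct  to_activity_pct
CAG   CGG  52.4               76.2
GAC   GAG  1.9                18.1
GAG   CAG  18.1               52.4
GAG   GGG  18.1               48.5
GGG   CGG  48.5               76.2
```

and all 6 of the 6 direct paths are accessible (activity increases
strictly along every ordering) because the synthetic truth table is
layer-monotone. Scoring the bundled observation table against this
prediction:

```sh
promoterpath compare --annotation inputs/annotation_T7_delta1.tsv \
    --observations inputs/observed_variants.tsv \
    --activity-table inputs/activity.tsv --out compare
```

```
Prediction comparison (GAC -> CGG)
  promoters annotated: 16
  promoters with substitutions: 5 (phi1.5, phi2.5, phi6.5, phiOL, phiOR)
  distinct observed triplets: 6
  predicted (single/double/target): 2 (GAG, GGG)
  unanticipated: 3 (AAG, CCC, GCC)
  promoters with duplications: phi6.5, phiOL
  fixed: phi1.5 -> GAG in 4 line(s) (line1, line2, line3, line4)
```

Only 5 of the 16 promoters evolved at all; one promoter swept to the
predicted first step `GAG` in every line, while three observed triplets
(`GCC`, `CCC`, `AAG`) lie off every direct path and were therefore
unanticipated by the original prediction. Observations at the `AAC`-
background promoter are flagged: its mutational neighbourhood was never
assayed, so no prediction existed for it. Lysis phenotypes:

```sh
promoterpath phenotype --curves inputs/od_curves.tsv --out pheno
```

```
ancestor: 91.0
evolved: 31.0
uninfected: no lysis
```

minutes to lysis for synthetic curves with drop midpoints at 90 and 30
minutes (the ancestral vs evolved phenotype gap), and a no-lysis control.

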