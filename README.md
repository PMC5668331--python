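# hexmap

Integrated linkage mapping, haplotype reconstruction and multi-allelic
QTL analysis for polysomic polyploids.

## The problem

Outcrossing hexaploids such as chrysanthemum or sweet potato inherit
chromosomes polysomically: at meiosis all six homologues pair at random
into three bivalents, and a bi-allelic SNP can occur in any dosage from
0 to 6 (seven classes, five of them heterozygous). This breaks nearly
every diploid mapping tool. Building a single *integrated* linkage map
— one in which all markers of a chromosome are placed relative to each
other regardless of which homologue carries their alleles — requires
recombination-fraction likelihoods for every combination of marker
dosage types and phases, a strategy for assembling homologues and
chromosomal linkage groups (CLGs) from pairwise linkage alone, and a
weighted ordering algorithm that copes with tens of thousands of
markers. With a phased integrated map one can then reconstruct, for
every F1 individual and every locus, the probability that each of the
twelve parental homologues was inherited (identity-by-descent, IBD),
and regress phenotypes on those probabilities to find QTL whose
multiple alleles act in different directions.

`hexmap` implements that whole chain for any even ploidy, for a
bi-parental F1 design, and validates it against its own meiosis
simulator with known truth:

* **dosage** — dosage-matrix ingestion, segregation chi-square tests
  against the polysomic expectation, marker/individual filtering,
  duplicate-marker binning;
* **sim** — random-bivalent-pairing meiosis (15 pairing scenarios at
  ploidy 6, Haldane crossovers, no double reduction) producing
  populations with known phases and inheritance vectors;
* **linkage** — one generic maximum-likelihood engine for pairwise
  recombination fraction r, LOD and phase for *any* pair of segregation
  types: joint offspring dosage distributions are polynomials in r
  built from the pairing/transmission model, evaluated over all phase
  classes (shared-homologue counts) and maximized over r in [0, 0.5);
* **grouping** — simplex (1×0 / 0×1) backbone clusters at LOD ≥ 10 in
  coupling, CLG identification through 1×1 bridge markers, assignment
  and phasing of all other markers via ≥ 5 coupling linkages at
  LOD > 5;
* **ordering** — weighted multidimensional scaling (LOD² weights,
  Haldane distances), principal-curve projection, 1-D stress polish,
  nearest-neighbour-fit pruning (threshold 4 cM), duplicate
  re-attachment and same-contig RMSE diagnostics;
* **ibd** — IBD probabilities from fully informative dosages, nearest
  informative marker via Haldane's function (P = 1 − r / P = r),
  per-parent normalization to 3, cubic-spline gridding at 1 cM, and
  genotype information content GIC = 1 − (2/n) Σ |P − ⌊P⌉|;
* **qtl** — the additive multi-allelic scan
  Y = μ + α₂X₂ + … + α₆X₆ + α₈X₈ + … + α₁₂X₁₂ (homologues 1 and 7 are
  reference classes), permutation thresholds (5th percentile of the
  per-permutation minimum p), per-allele simple regressions, variance
  explained and ANOVA heritability.

## Worked example

```python
import numpy as np
from hexmap import sim, pipeline, evaluation

rng = np.random.default_rng(42)
p1, p2, design = sim.design_population(
    ploidy=6, n_chromosomes=2, chrom_length_cM=90.0,
    n_simplex_per_homologue=60, n_duplex=40, n_simplex_simplex=40,
    seed=rng,
)
matrix, truth = sim.simulate_f1(
    p1, p2, 400, rng, missing_rate=0.01, marker_ids=design.marker_ids
)
result = pipeline.run_pipeline(matrix, pipeline.RunConfig(seed=1))
print(result.stage_counts)
print(evaluation.ordering_concordance(result, design))
print("phasing accuracy:", evaluation.phasing_accuracy(result, design))
```

prints (about a minute on a laptop):

```
{'markers_input': 1600, 'individuals_input': 400,
 'markers_filtered': 1596, 'individuals_filtered': 400,
 'markers_unique': 1398, 'backbone_clusters': 24, 'clgs': 2,
 'ambiguous_bridges': 0, 'markers_assigned': 1398,
 'markers_phased': 1398, 'markers_ordered': 1395,
 'markers_mapped_with_duplicates': 1592}
   CLG  true_chromosome  purity  kendall_tau  map_length  true_span
0    1                0     1.0     0.960008   89.011061   89.808450
1    2                1     1.0     0.966894   86.124642   89.901285
phasing accuracy: 1.0
```

Read: the 1600 simulated markers collapse to 1398 unique segregating
ones; their simplex backbone forms 24 clusters — the 2 × 12 homologues
of the two parents over two chromosomes — which the 1×1 bridge markers
join into 2 CLGs. Every marker is phased correctly, the marker order
within each CLG agrees with the simulated order at Kendall tau ≥ 0.96,
and the ~90 cM chromosome lengths are recovered within a few cM.
`result.ibd_grid` then holds the per-individual homologue probabilities
on a 1 cM grid and `hexmap.qtl.scan_with_threshold` runs the
multi-allelic genome scan against any phenotype.

The same pipeline is available from the shell:

```bash
hexmap simulate --chromosomes 2 --individuals 400 \
    --simplex-per-homologue 60 --simplex-simplex 40 --duplex 40 \
    --seed 42 --out simdata
hexmap run --dosages simdata/dosages.tsv --seed 1 --out mapped
```

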