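# Methods

This note documents the models behind `hexmap`, the defaults and why
they are set where they are, what the simulator does and does not
emulate, and the numerical choices that a maintainer would otherwise
have to reverse-engineer.

## Inheritance model

All computations assume polysomic inheritance with complete random
bivalent pairing and no double reduction. At meiosis the `2m`
homologues of a chromosome form `m` bivalents; the pairing is uniform
over the `(2m−1)!!` perfect matchings (15 for a hexaploid, 3 for a
tetraploid). Each bivalent transmits one recombinant product; along the
chromosome the product's founder identity switches at the points of a
Poisson process of rate 1 per Morgan, which reproduces Haldane's
mapping function r = (1 − e^(−2d))/2 and ignores crossover
interference. Multivalent pairing and preferential pairing are outside
the model; both occur in real polyploid meiosis at low frequency and
bias recombination estimates slightly towards excess double
recombinants, which this package would misattribute to genotyping
error.

Under this model a parent of dosage `d` transmits `k` allele copies
with hypergeometric probability C(d,k)·C(2m−d, m−k)/C(2m, m); an F1
dosage distribution is the convolution of its two parents' gamete
distributions. The segregation chi-square test, the non-segregation
rule and the cross-incompatibility ("selfing") screen all derive from
these distributions rather than from a lookup table, so any even ploidy
works unchanged.

## Pairwise likelihood engine

For two markers A and B the phase of one parent is summarized by its
equivalence class: the number `s` of homologues carrying both markers'
alleles. All placements with equal `s` are equivalent under random
pairing, so the joint phase space of a pair is the product of the two
parents' admissible `s` ranges. For each per-parent class the joint
transmitted-dosage distribution is assembled by enumerating the
matchings once and convolving per-bivalent transmission polynomials;
the result is a coefficient tensor over (dosage at A, dosage at B,
power of r), cached per (ploidy, d_A, d_B, s). Offspring distributions
are convolutions of the two parental tensors, degree ≤ 2m in r.

Estimation maximizes the multinomial log-likelihood of the joint
dosage cross-tab over phases and over r on a 0.005 grid with
golden-section refinement; LOD is log₁₀ L(r̂) − log₁₀ L(0.5) *within
the winning phase class*. The r = 0.5 anchor is deliberately
phase-specific: when one parent carries two or more copies at both
loci, the shared bivalent partition correlates the loci even at free
recombination (two duplex loci cannot both transmit two copies when
their carriers share a bivalent), so the r = 0.5 likelihood differs
between phase classes and a phase-free null does not exist. For pairs
with a simplex side the familiar product-of-marginals independence
holds exactly. Phase ties within 1e−9 log-likelihood resolve to the
more-coupled class; they occur only at r̂ ≈ 0.5 where phase is moot.

The all-pairs stage groups pairs by segregation-type combination,
builds the joint cross-tabs by indicator-matrix products, evaluates the
grid for a whole group in one array operation and refines all pairs
simultaneously with a vectorized golden section; 2.6 × 10⁵ simplex
pairs at n = 400 take a few seconds. Missing data are handled
pairwise-complete. Cross-parent simplex pairs (1×0 against 0×1) carry
no linkage information — the two meioses are independent — and come
out at LOD ≈ 0; map integration across parents rests entirely on
bi-parental (1×1) markers, which is why the grouping stage insists on
them.

## Homologue clusters, CLGs, phasing

Backbone clustering is single linkage (connected components) on the
graph of one parent's simplex markers with edges where LOD ≥ 10 *and*
the best phase is coupling; repulsion edges are excluded because
hexaploid repulsion estimates are too noisy to trust (their estimator
spread at n = 400 is more than double the coupling spread, a property
the test suite asserts). Components below five markers are flagged and
take no further part in mapping. CLG identification attaches every 1×1
marker to its best coupling-linked cluster per parent at LOD > 5 and
merges clusters transitively; ambiguous bridges (tied best cluster) are
logged and skipped. Assignment and phasing of the remaining types
counts coupling linkages to backbone markers at LOD > 5: the marker
goes to the CLG with most qualifying links, each allele to every
cluster with at least five of them, and a marker whose per-parent
phased-homologue count does not match its parental dosage is kept on
the map but excluded from the phased set. 2×0 bridging is available
behind a flag but is not the default bridge type.

## Ordering

Within a CLG the input distances are Haldane-transformed r̂ with LOD²
weights. Ordering proceeds in four deterministic steps: (1) weighted
stress majorization (SMACOF) in two dimensions from a classical-scaling
start; (2) a principal curve through the embedding by iterated local
averaging and polyline projection, giving arc-length positions; (3) a
single weighted least-squares scale so local (< 30 cM) pairwise
distances are reproduced; (4) a 1-D stress polish, first on all pairs,
then restricted to pairs with estimated distance below a cap. The
short-pair pass exists because Haldane distances of loose linkages are
convexity-inflated (E[d(r̂)] > d(E r̂)), which stretches the map ends by
several cM and propagates into the terminal IBD probabilities; short
distances are nearly unbiased. The cap starts at 15 cM and is raised
(20, 30, 50) until the short-pair graph is connected and at least 95%
of markers retain ≥ 10 informative short partners — at low marker
density a too-small cap under-constrains positions and wrinkles the map
instead of fixing it. Orientation is anchored deterministically (the
lexicographically smallest marker id lands in the left half) and the
leftmost marker sits at 0 cM.

The nearest-neighbour fit of a marker is the *mean* |map − pairwise|
distance over its k = 10 nearest map neighbours among informative
pairs (LOD ≥ 5). Two definitions here matter and were chosen after
watching the alternatives fail on simulated truth: summing instead of
averaging puts the statistic on a k-dependent scale where the removal
threshold of 4 cM flags essentially every marker once r̂ noise is
realistic; and including near-uninformative neighbours (repulsion or
cross-parent pairs) swamps the diagnostic with noise distances.
Iterative pruning re-orders after removing markers above threshold and
accepts a round only if the *mean* per-marker fit decreases — the raw
total trivially decreases with the marker count and lets pruning
cascade until the map is destroyed (observed on simulation: 143 of 190
markers removed and Kendall tau degraded from 0.92 to 0.44 under the
total-fit rule). Duplicate-bin members re-attach at their
representative's position after the final round.

## IBD probabilities and GIC

Only fully informative dosages seed the IBD array: progeny dosage 0
proves absence of every allele-carrying homologue, dosage d₁+d₂ proves
presence; anything in between is ambiguous about which homologue
contributed and starts at 0.5. Each uninformative locus then takes its
value from the nearest informative marker of the same homologue via
P = 1 − r or P = r with r from Haldane's function on map distance;
equidistant conflicting neighbours average. Dosages above d₁+d₂ are
impossible under the cross and are counted as data inconsistencies.

Per parent the six homologue probabilities are then normalized to sum
to 3 (three homologues per gamete). The normalization redistributes the
surplus or deficit in proportion to each homologue's evidence
uncertainty p(1−p), clipping to [0, 1] and iterating to convergence
(8 rounds; sums are then exact to numerical precision). A plain
multiplicative rescale was tried first and is measurably miscalibrated:
near a recombination breakpoint the deficit boost lands mostly on
homologues that are already certain, gets clipped away, and leaves the
genuinely uncertain homologues under-corrected (observed presence
frequencies of 0.44–0.51 in bins predicted at 0.13–0.34). The
uncertainty-weighted scheme leaves hard calls untouched and moves the
correction onto the breakpoint candidates, which brings every
well-populated probability bin within ±0.1 of its observed truth
frequency on simulation. An exact conditioning on "3 of 6 transmitted"
(subset enumeration) was also tried and overshoots, because the
per-homologue evidence values are strongly dependent — they flow from
the same informative markers.

Gridding fits a natural cubic spline per individual and homologue
(knots at distinct marker positions, co-located markers averaged;
linear fallback below 4 knots), evaluates at 0, 1, 2, … cM, clips to
[0, 1] and re-normalizes. GIC per homologue and interval is
1 − (2/n) Σᵢ |Pᵢ − ⌊Pᵢ⌉| with 0.5 rounding down, so 1 is full
information; on simulated maps GIC sags at the chromosome ends, where
informative markers flank a locus from one side only.

Known limitation: this is a deliberately simple single-marker carrier
method, not an HMM. Its probabilities are honest in the dominant
near-0/near-1 mass and in the breakpoint bins, but the mid-range bins
(a fraction of a percent of all values at realistic marker density)
remain approximate — the method has no way to propagate joint
information along a homologue.

## QTL analysis

At each 1 cM locus the phenotype is regressed on the IBD probabilities
of homologues 2–6 and 8–12 (one reference class per parent, since each
parent always transmits exactly three homologues and the within-parent
probabilities sum to 3). The locus p-value is the overall F test of
that 10-parameter model against the intercept; rank-deficient loci
(an unrepresented homologue) fall back to their effective column space
and are flagged. Scans reuse a per-locus orthonormal basis so a
permutation run is a single matrix product per locus; 200 permutations
× 180 loci × n = 400 take seconds. The genome-wide threshold is the
5th percentile of the per-permutation minimum p-values (default 1000
permutations; 200 in the desk-scale calibration, which still brackets
the 5% genome-wide error within ±3% over 200 null replicates).
Per-allele effects come from twelve separate simple regressions
Y = μ + αᵢXᵢ, interpreting α̂ᵢ as the effect of full presence versus
full absence. Heritability uses the two-factor fixed-effects ANOVA
(trial + genotype): H² = σ²_G/(σ²_G + σ²_E) with
σ²_G = (MS_G − MS_E)/r̄. Interaction scanning is out of scope (400
genotype classes at ploidy 6 invite overfitting); a two-locus
interaction ANOVA on chosen predictors is provided instead.

## The simulator as oracle, and what passing tests mean

`hexmap.sim` generates exactly the model the estimators assume:
random bivalent pairing, Haldane crossovers, binary SNP alleles on
designed homologues, optional uniform missingness and ±1 dosage
errors. The reference population for the pipeline checks uses two 90 cM
chromosomes, 60 simplex markers per homologue, 40 duplex and 40 1×1
markers per chromosome, n = 400 and 1% missing calls; replicate counts
in the calibration checks (200 pair-recovery replicates, 200 null
scans × 200 permutations, 100 peak-recovery replicates) are sized to
keep the whole validation inside a desk-scale run while leaving the
binomial error on each rate well inside its acceptance band. Passing
these checks shows the chain is self-consistent and calibrated *under
its own model*. Real dosage data additionally contain dosage-calling
error that is correlated with dosage class, segregation distortion,
multivalent meiosis and assembly artefacts (chimeric contigs); the
filtering stage removes the grossest of these, but the simulator does
not emulate them, so simulation results bound what the method can do,
not what a given dataset will give.

## Numerical conventions

* Missing dosage is −1 in memory and `NA` on disk; dosage files are
  comma- or tab-delimited with columns `marker_id, P1, P2,
  <individuals…>`.
* r is searched on [0, 0.5) with grid step 0.005 and 22 golden-section
  iterations; r̂ is capped at 0.49999 and unlinked distances at 100 cM.
* Phase ties break toward the larger shared-homologue count.
* Cluster ids are `P{parent}_{k}` by descending size; CLGs are numbered
  by descending total marker count; within a CLG, slots h1–h6 are the
  parent-1 clusters by descending size, h7–h12 parent 2.
* All stochastic steps take a `numpy` Generator or integer seed; the
  pipeline config (and its hash) is serialized next to every artifact.
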