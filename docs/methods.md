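# Methods

## Scope and model of the data

`polyarray` implements the computational stages of a high-density SNP-array
experiment in an allopolyploid crop (the motivating system is hexaploid bread
wheat, subgenomes A, B and D), from two-channel probe intensities to genetic-map
summaries, together with the post-calling side of resequencing-based SNP
discovery. Everything runs on synthetic data whose generators are first-class,
tested code; no sequencing or array data is required.

## Signal space and the calling model

Each probeset yields two channel intensities per sample, one per allele. They
are transformed to

```
contrast = log2((a*100 + 100) / (b*100 + 100))
size     = [log2(a*100 + 100) + log2(b*100 + 100)] / 2
```

The +100 offset keeps both finite for any non-negative signal. A well-behaved
biallelic probeset shows up to three clusters along contrast (BB < AB < AA); a
probeset whose target is deleted in part of the panel shows a fourth cluster at
markedly lower size (the null allele / off-target variant, OTV).

Production arrays are called by proprietary software; the caller here is an
openly specified stand-in honouring the same described behaviour: a
diagonal-covariance two-dimensional Gaussian mixture per probeset, fitted by
EM. Design choices:

* **Model selection.** EM is run for k = 1, 2 and 3 genotype components with
  deterministic quantile-split initialisation along contrast (ties broken by
  sample order) and the best BIC fit is kept. This is what lets a monomorphic
  probeset resolve to one cluster and a no-minor-homozygote probeset to two,
  instead of shredding one cloud across three components.
* **Inbred penalty.** The AB component's prior weight is multiplied by
  `2^-penalty` and renormalised at every E-step. Penalty 4 ("mild") barely
  affects a genuine, well-separated het cluster — its likelihood term
  dominates — but penalty 16 ("strong") makes weakly supported het
  interpretations collapse, which is exactly the two-step protocol's intent.
  With the penalty active the raw log-likelihood is no longer guaranteed
  monotone, so the EM-ascent test pins the penalty-0 regime.
* **Pruning.** Components with posterior mass below `1/(2n)` (half an expected
  sample) are dropped during fitting.
* **Labels.** Components are labelled by contrast order. With two components,
  clusters flanking zero read BB/AA; two clusters on the same side read as the
  inner being AB — the classic geometry of a missing minor homozygote.
* **Calls.** Maximum posterior; posterior below the confidence threshold
  (default 0.95) or missing signals give NN. Variance floor 1e-6, at most 200
  EM iterations, relative log-likelihood tolerance 1e-8.

### OTV detection

Two routes, tried in order. (1) *Component route*: if one fitted component's
mean size lies at least `otv_size_gap` (default 2.0) pooled size-SDs below all
others, it is relabelled OTV — the mixture usually captures a sizeable null
cloud as a component of its own. (2) *Point route*: points that far below the
lowest genotype cluster form a candidate subpopulation; to avoid promoting
ordinary lower-tail points it must contain at least 2 samples and 5% of the
panel, and its mean must sit a further SD below the cut. Members of the OTV
component are called OO. If removing the cloud would leave fewer than two
points, the probeset is flagged degenerate and not split (no gap is definable
when everything is low). Detection runs in both calling passes.

## Probeset QC and categories

Per probeset: call rate, het rate, genotype counts, and two cluster-geometry
metrics. **HomRO** is the contrast position of the homozygous cluster nearest
zero (`min(c_AA, -c_BB)` when both exist); positive values mean the homozygous
clusters flank zero as at a diploid locus, negative values are the signature of
homoeologous signal compression. **HomFLD** is `|c_AA - c_BB|` over the
membership-weighted pooled within-cluster contrast SD. Undefined metrics (a
missing homozygous cluster) are NaN and fail every threshold comparison.

The category cascade: call rate < 0.97 → CRBT; OTV component → OTV;
monomorphic → MHR; both homozygote clusters with ≥ 2 minor homozygotes and
HomFLD ≥ 3.6 → PHR; missing/short minor homozygote → NMH; otherwise Other.
The call-rate threshold (0.97) and the minor-homozygote minimum (2) are Axiom
conventions, configurable; the HomFLD filter 3.6 and the diploidization rule
(converted ∧ HomRO > 0.3 ∧ HomFLD > 10) follow polyploid-array practice.
Evaluating CRBT before OTV is a choice: a probeset that cannot be called
reliably should not be promoted on the strength of a null cluster.
PHR + OTV are the *converted* categories; the two-step protocol reprocesses
only Other and NMH with the strong penalty.

## Diversity

PIC per locus is `1 - Σ p_i²` over A/B allele frequencies (AA contributes two
A's, AB one each). OO calls are excluded from allele frequencies — a null
allele is neither A nor B — but drive the presence/absence (PAV) analysis,
where OO encodes 0 and any called genotype 1, restricted to OTV loci with no
missing call. Pairwise accession distance is the simple-matching
dissimilarity with pairwise-complete missing handling; OO is by default a
fourth state (mismatching AA/AB/BB, matching OO), with an option to treat it
as missing, since array practice varies on this point. Ward clustering uses
the Lance–Williams recurrence (scipy), guaranteeing monotone merge heights;
the neighbor-joining tree is Saitou–Nei (scikit-bio) with negative branch
lengths clamped to zero and the length moved to the sibling. On an additive
matrix NJ is exact, which the tests verify against a brute-force topology
enumeration up to 8 taxa.

## Mapping preparation

Marker filters for a biparental F6 SSD population, applied in order with every
violated reason recorded: PHR category, diploidized flag, parents called +
homozygous + opposite, ≤ 15% missing in the progeny, and a one-df chi-square
of the homozygote counts against 1:1 with rejection at P ≤ 0.01 (no continuity
correction; residual heterozygotes are excluded from the counts, as they carry
no transmission-bias information — the convention is documented because the
field is not uniform here).

Cosegregation: two markers are compatible when they agree wherever both are
called. That relation is not transitive under missing data, so bins are its
single-linkage transitive closure, with bins whose members are not pairwise
compatible flagged; representatives have the fewest missing calls, ties by
identifier. Map summaries report, per chromosome: marker count, length
(max − min cM), distinct-cM-position count, singleton-bin count, and mean bin
length = length / distinct positions (2 decimals). Map ordering itself is out
of scope (external software in the original workflow); summaries accept any
supplied map. Map-to-map concordance is the Spearman rank correlation of
shared-marker positions per chromosome, averaged unweighted.

## Discovery

Post-calling filters keep records with depth ≥ 5 and RMS mapping quality ≥ 30
(inclusive). Locus classes from the observed genotype set: {AA,BB} → 1,
{AA,AB,BB} → 2, {AA,AB} → 3, all-AB → 4; the mirror pattern {BB,AB} is mapped
to class 3 by allele symmetry (a strict mode returns UNCLASSIFIED instead),
and missing genotypes are ignored. Only classes 1–2 are usable downstream: in
a polyploid, pervasive heterozygosity is the signature of collapsed
homoeologues rather than true allelic variation. Ts/Tv counts transitions
(A↔G, C↔T); the ratio is undefined only when there are no transversions. A
SNP is private when exactly one line among ≥ 2 called lines carries the
non-reference allele. Candidate selection requires ≥ 2 carrier lines,
polymorphism within the European pool, a single genome-wide hit and a usable
class; per-arm quotas are proportional to arm size with D-genome weights
doubled (compensating that subgenome's depressed polymorphism), integerised by
largest remainder so the total is exact. Within an arm, candidates are ranked
by descending carrier count, then position, then identifier — deterministic,
since no ordering is prescribed by the protocol being modelled.

## Synthetic data: what it emulates, and what it does not

* **Array signals.** Per-probeset classes with the spectrum observed on a
  polyploid wheat array (59% diploidized polymorphic, 9% null-allele, 17%
  monomorphic, 9% homoeologous-offset, 6% low-quality); 96 samples by
  default. (contrast, size) is drawn from the class geometry plus Gaussian
  noise and *inverted* into channel signals, so the transform round trip
  closes exactly. Diploidized geometry: homozygote centers ±1.2, SD 0.1,
  size 12 ± 0.15; homoeologous-offset shifts both homozygote clusters to one
  side (nearest 0.1 < 0.3); the null cloud sits 0.9 size units (≈ 6 SD) below
  its probeset's clusters with carrier frequency 0.25; low-quality probesets
  have broad overlapping clusters and extra missingness. Residual
  heterozygosity 1.5%, missingness 0.5%, both MCAR. Not emulated: plate and
  batch effects, spatial artefacts, allele-frequency-dependent cluster
  asymmetry, so passing tests certify the calling logic, not robustness to
  instrument drift.
* **Diversity panel.** Balding–Nichols group divergence: group frequency ~
  Beta around the ancestral frequency with variance `fst·p(1−p)`; fully
  inbred accessions; default 5 groups / 96 accessions / 500 loci / Fst 0.3.
  No linkage disequilibrium or admixture.
* **RIL F6.** Parental-origin Markov chains per chromosome with adjacent-
  marker recombination equal to the inverse Kosambi (or Haldane) function of
  the cM gap — matching how distances are re-estimated, with no interference
  beyond the mapping function. Chains, het and missing overlays are keyed by
  distinct genetic position, so co-located markers give bitwise-identical
  columns. Residual heterozygosity `(1/2)^(generation−1)` per locus (3.125%
  at F6), iid across loci — real residual het is blocky, which only matters
  for analyses of het tract length, none of which are performed here.
  Transmission distortion resamples alleles at the marker nearest the
  configured locus to hit the configured marginal bias; this perturbs local
  linkage only at that marker, sufficient for filter testing.
* **Variants.** Genotype patterns realise the configured class mix exactly;
  ref/alt pairs are transitions with probability `t/(1+t)` for target ratio
  t; depth/MQ from constant, Poisson or clipped-normal specifications; 21
  wheat-style chromosomes with realistic fraction proportions. The line count
  is a parameter (the modelled protocol described ten lines while eight were
  sequenced; the generators do not resolve that discrepancy).

Seeding: one master seed per config; each generator uses
`default_rng([seed, op_offset])` with fixed offsets, so outputs are bitwise
reproducible and independent across generators.

## Numerical choices and degenerate inputs

Variance floor 1e-6 in the mixture; allele-frequency validation tolerance
1e-9 in PIC; distances with zero compared loci are NaN and flagged via the
per-pair count matrix; coincident homozygote centers give HomFLD 0 (0/0 → 0);
all-identical signal points short-circuit to a single full-weight component;
an empty signal table produces empty outputs; largest-remainder ties in quota
allocation break by arm order.

## Problem sizes

Default test and acceptance runs use 1,000 probesets × 96 samples for the
array stage, 430 × 1,000 genotypes for RIL heterozygosity, 4,000 individuals
for the recombination-fraction check, 10,000 markers for the distortion-test
null, and 10,000 loci × 8 lines for discovery — sizes at which every binomial
acceptance band (±3 SE) is diagnostic while the whole suite stays fast.

## Known limitations

The caller is a stand-in: it reproduces the documented behaviours (cluster
geometry metrics, inbred penalty ordering, two-step recalling, null-allele
splitting) but not the numerical output of the proprietary pipeline. Category
proportions on real arrays depend on panel composition and assay chemistry
that the generators deliberately do not model. Map construction (linkage
grouping, ordering) is out of scope; all map summaries take positions as
given.
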