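# Methods

This note records the models behind each stage, the defaults and why
they were chosen, what the synthetic data does and does not emulate, and
the numerical decisions a maintainer would need to know.

## Coordinates and containers

All genomic computation runs on fixed-width, 0-based, half-open bins
that tile each chromosome (the last bin may be short); BED-adjacent
output follows BED's coordinate convention.  The central container is a
per-chromosome dense symmetric matrix with a state flag (`raw` counts,
`balanced`, or `observed-over-expected`).  Zero-coverage bins are masked
before balancing and propagate as no-calls through PC1, DI, IS and the
compartment labels.  Only intrachromosomal contacts are analyzed;
interchromosomal pairs are counted and dropped at binning.

## Balancing and normalization

Knight–Ruiz scaling (inner–outer Newton iteration with conjugate-gradient
inner solves) equalizes non-masked row sums; on non-convergence a
Sinkhorn/IPF fallback runs, and only if both fail is an error raised
naming the chromosome.  The balanced matrix is rescaled to the input's
total count so entries stay on a count-like scale, and the bias vector
(raw = balanced × bᵢbⱼ) is stored — the interaction caller needs it to
move back to the integer-count scale.  Quantile normalization across
samples (off by default) maps each sample's upper-triangle values onto
the average-quantile reference per chromosome, preserving within-sample
ranks; ties receive the mean reference value.

Replicate similarity is a stratum-adjusted correlation: matrices are
mean-filter smoothed (half-width 1 bin by default, `nearest` edge mode
so constant matrices stay constant), Pearson correlations are computed
per diagonal and combined with weights Nₖ·√(var·var), up to a default
maximum distance of 25% of the chromosome.  These defaults are
configurable because the reference tool's settings are conventions, not
constraints.

## Von Neumann entropy

Per chromosome, C = corr(log₂(A + 1)) over non-masked bins (pseudocount
1 because count matrices contain zeros), eigenvalues of C are clipped at
zero (numerical correlation matrices can carry tiny negative
eigenvalues), normalized to sum 1, and VNE = −Σ λ̄ᵢ ln λ̄ᵢ with
0·ln 0 := 0.  VNE lies in [0, ln n] and is invariant under simultaneous
row/column permutation.  Balanced input is the default; the statistic is
also defined on raw counts.  Group contrasts are reported as per-sample
values plus a rank-sum test — a description, not a model.

## Compartments

PC1 is the leading eigenvector of the Pearson correlation of the O/E
matrix (the convention that makes the checkerboard visible), computed
per chromosome with masked bins excluded and re-inserted as no-calls;
chromosomes with fewer than 10 usable bins are skipped.  The eigenvector
sign is arbitrary, so each chromosome is oriented by Spearman
correlation with GC content, falling back to gene count when
|ρ_GC| < 0.1; A = oriented PC1 > 0, B = < 0, exactly 0 = no-call.  The
A-B index of bin i is (meanA − meanB)/(meanA + meanB) over its O/E
contacts with A- and B-labeled bins (self excluded), bounded in [−1, 1]
and sign-consistent with the labels by construction.  Switches are
contiguous runs of bins whose labels differ between conditions; genes
attach to events by TSS bin (a deterministic single assignment).

## TAD calling

DI uses the ±10-bin window form with E = (A+B)/2 and a signed
chi-square-like statistic; it is exactly antisymmetric under genome
reversal.  A 3-state Gaussian HMM (emission means initialized at −1, 0,
+1 on standardized DI, self-transition prior 0.85, seeded Baum–Welch,
Viterbi decoding) labels each bin upstream-biased / none /
downstream-biased; a domain spans from a downstream-biased run start to
the end of the next upstream-biased run, orphan runs close at the track
edges, and domains shorter than 3 bins are dropped.

Because DI is a depth-scaled statistic, substructure inside a domain
also produces decodable excursions.  Each candidate junction is
therefore snapped (±3 bins) to the position maximizing a
distance-matched contact-depletion score on the O/E matrix — at each
diagonal offset the mean of cross-junction entries is compared with the
mean of same-offset within-side entries, so the score estimates
1 − 1/boost directly — and junctions depleting less than 0.45 are
merged away.  The threshold sits between the ~0.5 depletion of a full
domain boundary (2× enrichment) and the ~0.3 of sub-domain contrast
(1.4×), below the observed lower tail of true junctions.  The
insulation score (window 10 by default, mean contact in the square
crossing each bin, normalized as log₂(raw/chromosome mean)) supplies
sub-TAD partitioning: local minima with prominence ≥ 0.1 at least
3 bins from the parent's edges become split points, and the sub-TADs
tile the parent exactly.  Boundary dynamics match boundaries greedily
nearest-first within ±1 bin (ties leftmost); unmatched boundaries are
gained or lost.

## Promoter–enhancer interactions and RPS

Candidates are promoter-bin × partner-bin pairs within a distance
window.  The long-range preset (10 kb–1 Mb) is the default; a
short-range preset (10 kb–20 kb) is also named, since both windows are
defensible readings of the published protocol.  Adjacent bins
(|i−j| < 2) are never tested.

The expected model is domain-aware: the distance decay is estimated
separately inside each TAD (so domain-level enrichment is part of the
null) and for the cross-domain background, using empirical stratum means
where a stratum has ≥ 10 pairs and a log-log power-law fit as smoothing
for sparse strata — fitting alone would under-predict means
(retransformation bias) and break calibration on deep strata.  Flanking
domains are extended to the chromosome ends, where the domain caller
cannot assess membership.  A per-bin residual factor
rᵢ = observed marginal / model marginal (clipped to [0.2, 5], normalized
to mean 1) absorbs position effects the decay curves cannot represent —
notably balancing residue at chromosome edges.  The test is a one-sided
Poisson upper tail on the count scale: balanced values are mapped back
through the stored bias vectors, and the tail probability uses the
regularized incomplete-gamma identity so non-integer observations are
handled continuously.  Benjamini–Hochberg runs across all tested pairs;
retained records need q < 0.05, positive excess, and observed ≥ 2×
expected — on deep maps the Poisson tail alone also flags mild
systematic departures (compartment and sub-domain contrast), so a focal
interaction must clear a minimum fold as well.

RPS = Σ log₁₀(max(Iₙ, 1)) with Iₙ = observed − expected on the balanced
scale.  Clamping at 1 makes RPS non-negative and consistent with "no
interactions → zero score"; the literal sum is undefined for Iₙ ≤ 1.
Differential rewiring uses log₂FC on pseudocounted scores plus the raw
difference Δ; the strict published-style thresholds (|log₂FC| > 3,
|Δ| > 2) are the default and the alternative printed pair (>2, >3) is
available via arguments — both appear in the source protocol and they
conflict, so neither is hard-coded.

## Enhancer classes

H3K27ac signal is log₂((IP + c)/(input + c)) on FPKM-scaled 1-kb bins
with c = 0.5 (configurable; the scale protects against empty input
bins).  Peaks merge transitively within 12.5 kb; an element's aggregate
signal is the length-weighted sum of its peaks.  The ROSE cutoff scales
rank and signal to the unit square and takes the point furthest below
the diagonal — exactly where the piecewise-linear curve's slope crosses
1, and robust to non-convex noisy curves; elements strictly above the
cutoff signal are SE, the rest RE, and classification is invariant to
input order and to appending zero-signal elements.  Distal interaction
anchors overlapping no H3K27ac element are PE.  Peak calling from raw
reads is out of scope: the package accepts peak BED input (plus the
simulator's planted peaks).

## Integration

Differential-expression statistics are consumed, never fitted — the
boundary semantics are strict FDR < 0.05 with inclusive |log₂FC| ≥ 1.5.
A plain two-group log₂FC helper exists for synthetic data and carries no
inference.  Phenotype folds are treated/control ratios rounded half-up
at 2 decimals (printed-style precision).  The ortholog partition
enforces exact conservation (A-only + B-only + shared =
regulated-in-either) with percentages over the regulated set; shared
genes with recorded directions are additionally screened for discordant
regulation.  "Regulated" means: carries a compartment-switch annotation
or a significant differential-RPS call.

## Synthetic data: what it emulates, and what it does not

The generator plants, per condition: alternating A/B blocks with
geometric lengths (mean 50 bins ≈ 1 Mb at the 20-kb analog resolution —
compartments are megabase-scale, larger than TADs), large TADs of 20–30
bins each containing 2–3 sub-TADs (≥ 5 bins), focal promoter–distal
loops inside TADs (some promoters host 2–3 loops so enhancer counts
vary), and H3K27ac elements on ~75% of distal anchors with log-normal
heights plus two ~20× outliers per chromosome (so super-enhancers exist
and the unmarked anchors exercise the poised class).  Condition 2
derives from condition 1 by flipping an exact count of compartment bins
in short runs (2% of the genome by default), removing a requested number
of internal TAD boundaries (2 by default — near-total boundary
stability), and rewiring 30% of loops (half condition-1-specific, half
condition-2-specific).  Contact counts are Poisson around
λ(i,j) ∝ (1+|i−j|)^(−1) × 1.6^[same compartment] × 2^[same TAD] ×
1.4^[same sub-TAD] × 5^[loop], scaled to 2M contacts per 250-bin
chromosome — deep enough that per-pair counts behave like the deep maps
the statistics assume, small enough that the full two-condition study
runs in seconds.  Expression is negative-binomial (gamma–Poisson) with
log-mean coupled to compartment state and planted RPS; GC content is
higher in A bins, matching the orientation convention.

Not emulated: polymer-physics contact geometry, sequence-level biases
(GC/mappability coverage waves), translocations or copy-number effects,
overdispersed contact counts (Poisson is the null the enrichment test
assumes; NB dispersion is available as a stress parameter), and
inter-chromosomal contacts.  Passing recovery tests therefore
demonstrates that the estimators recover the planted statistical
structure at realistic depth — not that they are robust to every
artifact of real libraries.

## Problem sizes and determinism

The default study is 4 chromosomes × 250 bins × 2M contacts per
chromosome and two conditions; the recovery suite repeats it over
10 seeds and the null calibration runs 50 single-chromosome decay-only
maps — chosen so the whole test suite and the acceptance script each
finish in well under a minute on one CPU while keeping every recovery
margin wide.  All randomness flows through explicit integer seeds
(numpy `default_rng`, seeded HMM initialization), so every reported
number is bit-reproducible given the seed.

## Known limitations

- The HMM decodes standardized DI with Gaussian emissions; heavy-tailed
  DI distributions on shallow real data may need the junction-strength
  filter more than the simulator does.
- The junction-depletion threshold (0.45) is calibrated against the
  simulator's enrichment ratios; data with much weaker TAD contrast
  would warrant lowering it (it is an argument, not a constant).
- The interaction caller's Poisson null understates biological
  overdispersion in real replicate-pooled maps; the fold-enrichment
  floor compensates pragmatically, but counts from highly variable
  libraries deserve an explicit dispersion model.
- The A-B index loops over bins in Python; at the package's intended
  desk scale (≤ a few thousand bins per chromosome) this is negligible.
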