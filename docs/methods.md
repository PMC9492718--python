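# Methods

This note documents the statistical models, defaults and design decisions
behind `aqmeth`, in the spirit of the model documentation shipped by
packages like statsmodels or msprime.

## Data model

The pipeline's currency is the beta value β = M/(M+U) ∈ [0, 1], the
methylated fraction of signal at one CpG probe in one sample. Matrices
are probes × samples; a missing measurement (failed detection, absent
probe) is NaN and every statistic below is pairwise-complete over
unmasked values. Probe metadata follows manifest conventions: transcript
region tokens (TSS200, TSS1500, 5'UTR, 1stExon, Body, 3'UTR, ExonBnd),
an enhancer overlap flag, exclusion flags for polymorphism-linked,
sex-chromosome and aging-related probes, and platform membership
(EPIC / HM450). Coordinates are 1-based with `chr`-prefixed names.

Region classification collapses tokens with precedence
**promoter > body > other**, where promoter = {TSS200, TSS1500, 5'UTR,
1stExon} and body = {Body, 3'UTR}. The precedence rule resolves
multi-transcript conflicts toward the regulatory (promoter) reading; it
is a deliberate choice where the convention is genuinely open, and it is
exercised exhaustively in the tests over all token subsets.

## Preprocessing

- β from intensities uses the plain ratio (offset 0 by default; a
  nonnegative offset is available for near-zero total signal, in which
  case β = M/(M+U+offset)). Cells with zero denominator are masked.
- Detection masking removes cells with detection p > α (default 0.05):
  fluorescence not significantly above background is treated as missing,
  not as zero.
- Probe filtering drops any probe carrying a requested exclusion flag
  (default: all three of snp, sexchrom, age). The aging-probe list is
  whatever the annotation flags — no built-in clock list is assumed.
- Cross-platform analysis keeps probes present on *all* requested
  platforms.

## Purity (LUMP)

The leukocytes-unmethylation-for-purity score of a sample is
`min(1, mean β over the LUMP probe set / 0.85)`. The LUMP set — probes
unmethylated in leukocytes but methylated in the tissue of interest — is
a configurable input (the canonical 44-CpG list is not bundled);
synthetic cohorts designate their own set. The scale constant 0.85
follows the assay's published convention and is exposed as a parameter.
Gating removes samples with score strictly below the threshold (default
0.5, i.e. < 50% tumor fraction); a score exactly at the threshold is
retained. Samples with no unmasked LUMP probe get an undefined score and
are flagged rather than silently dropped.

## Differential methylation

Per probe, a two-sided Welch's t-test on unmasked values:

    t = (x̄_A − x̄_B) / sqrt(s²_A/n_A + s²_B/n_B),

with Welch–Satterthwaite degrees of freedom and the p-value from the t
distribution. Degenerate inputs are defined explicitly: both arms
constant with equal means gives t = 0, p = 1; both constant with unequal
means gives a signed infinite t, p = 0 and a `degenerate` flag. A probe
is skipped (with a reason) when either arm has fewer than 3 unmasked
values — the smallest arm allowing a variance plus one. Δβ is oriented
contrast arm minus reference arm, so "hyper" always means elevated in
arm A (tumor vs retina; salvage vs enucleated).

Selection applies **strict** thresholds — Δβ > δ and p < α for hyper,
Δβ < −δ and p < α for hypo — making the two sets disjoint for any δ > 0.
No multiple-testing correction is applied by default: the selection rule
couples a raw-p cutoff with a large effect-size cutoff, and the
effect-size filter dominates the error control (on a 50,000-probe null
cohort the joint filter selects essentially nothing, as the acceptance
suite measures). Benjamini–Hochberg adjustment is available
(`adjust="bh"`) for users who want q-values.

Enrichment reports, for the hyper set, hypo set and the probe universe,
the fraction per exclusive region class plus the (overlapping) enhancer
fraction; probes skipped for missingness never enter denominators.

## Methylation-regulated genes

Expression evidence first: a gene is "up" ("down") when its log2 fold
change exceeds +1 (falls below −1, i.e. 2-fold) in **both** of two
independent expression datasets; genes present in only one dataset are
excluded. Integration is conjunctive and gene-level with an
*any-qualifying-probe* rule: a gene is called, e.g.,
`promoter_hypo_up` when at least one of its promoter probes passes the
DM thresholds in the hypo direction and the gene is in the replicated
up set. The four categories follow the standard coupling (promoter
hypomethylation ↔ activation, body hypermethylation ↔ activation, and
the mirrored repressive patterns). A gene matching several categories is
reported in all, with the primary category taken from the probe of
largest |Δβ|. The p cutoff can be dropped (`p_thresh=None`) to reproduce
a Δβ-only probe selection. Gene symbols match exactly
(case-sensitive); harmonize aliases upstream.

## Signatures, clustering, MDS

- **Variance ranking** uses the unbiased per-probe SD over unmasked
  values; ties break lexicographically by probe id so the top-k list is
  fully deterministic (default k = 10,000).
- **Clustering** is agglomerative over sample–sample distances
  (Euclidean default; Pearson-correlation distance optional) with
  complete linkage by default (average and Ward exposed) — mirroring the
  defaults of the common heatmap tooling. Distances over incomplete
  pairs are rescaled to the full probe count so missingness does not
  shrink them; a sample missing more than half the panel is rejected by
  name. Flat clusters come from a deterministic k-cut of the tree; k = 2
  is the reproducible stand-in for reading two arms off a dendrogram.
- **MDS** is classical (Torgerson) scaling — double-centered squared
  distances, eigendecomposition, coordinates from the top components —
  rather than the leading-fold-change heuristic some expression tools
  use, which is expression-specific. Axes with negligible eigenvalues
  are zeroed; the sign convention fixes the largest-|coordinate| sample
  positive on each axis so embeddings are reproducible.
- **Panel derivation** is DM selection at stricter defaults
  (Δβ > 0.4, p < 0.01) with provenance (arms, thresholds) recorded in
  the serialized panel; it composes, so a second-round panel between
  assigned clusters is the same operation.
- **Cluster assignment** cuts the panel dendrogram at k = 2. With
  outcome annotations, the cluster with the larger salvaged (SV)
  fraction is labeled "A" and the other "B" (ties break toward the
  cluster containing the lexicographically first sample); without
  outcomes the labels are "1"/"2". The mean silhouette of the 2-cut is
  reported, and values below 0.1 set a `weak_separation` flag — the
  forced 2-cut of a homogeneous cohort should not be over-read.
- **Outcome association** binarizes outcomes as SV vs enucleated (PE and
  SE merged) — or uses any other two-level labeling as-is — and reports
  the 2×2 table, the odds ratio (∞ for a perfect zero cell), containment
  booleans (cluster A inside the positive level, B inside the negative),
  and an exact p-value computed as **twice the smaller hypergeometric
  tail, capped at 1**. This doubled-tail convention is one of the two
  standard two-sided conventions for Fisher's exact test (the other sums
  all tables with probability ≤ the observed); the tests cross-check
  both one-sided tails against an independent implementation.

## Concordance

Agreement between two profiles is r², the square of the Pearson
correlation over pairwise-complete probes (minimum 100 shared), reported
with its sign-carrying r — so perfect anticorrelation is r² = 1 with
r = −1, never conflated with agreement. A constant vector makes the
correlation undefined; it is flagged, not reported as 0. The best-match
report checks, per declared pair, that the partner maximizing r² is the
declared one; ties at the maximum count as failures.

## The synthetic cohort generator

The generator produces cohorts with the statistical structure the
analysis assumes, plus a ground-truth record, so recovery is measurable
exactly.

**Noise model.** Observed β values are drawn from a mean-preserving
two-parameter Beta distribution: β ~ Beta(μκ, (1−μ)κ) with mean μ and
variance μ(1−μ)/(κ+1). The precision κ is the single noise dial; it
respects the [0, 1] boundaries, reproduces the heteroscedastic scatter
of array data (variance shrinking near 0 and 1), and maps monotonically
to input DNA mass, which is how the low-input titration is emulated.
Exact 0 and 1 are fixed points.

**Layers.** Per-probe baseline means are a 50/50 mixture of Beta(3, 19)
and Beta(19, 3) (modes near 0.1 and 0.9), matching genome-wide β
bimodality. Each tumor draws an individual mean profile around its
subtype mean at precision κ_individual (default 1000) — inter-tumor
biological variability, without which all tumors of a subtype would be
statistically identical and paired-sample matching would be meaningless.
Each observed sample then draws at its role's observation precision
(default κ = 200 for every role, a calibration choice: the paper-scale
tumor/AH concordance emerges at this level, and the defaults are stated,
not fitted). An AH sample re-reads its paired tumor's individual mean
profile at the AH κ. Leukocytes get an independent baseline, zeroed at
the designated LUMP probes; impure samples are convex mixtures
α·tumor + (1−α)·leukocyte at the mean level, which is exactly what the
LUMP score estimates.

**Planted truth.** The tumor-vs-retina panel (default 500 probes at
|Δβ| = 0.4, 19% hyper / 81% hypo — the split characteristic of this
tumor type) shifts probes whose baselines are resampled so the full
shift stays inside [0.05, 0.95]; the subtype panel (default 500 probes
at |Δβ| = 0.5, half up, half down in subtype 2) is disjoint from it by
default so recovery tests are unconfounded. Forty regulated genes
(10 per coupling category, configurable) are embedded in the tumor panel
with the matching region class and direction, choosing genes whose other
probes stay out of all panels; expression tables then give planted genes
log2FC = sign·(2 + |ε|) and all other genes N(0, σ) noise (σ = 0.25 by
default, 0 for noiseless checks). Outcomes are linked to subtype:
subtype 1 ↔ salvaged (SV), subtype 2 ↔ enucleated (PE/SE alternating).
All randomness flows from one integer seed through named
`numpy.random.SeedSequence` child streams, so equal seeds give
byte-identical cohorts.

**What the generator does not emulate.** Probe-type (Infinium I/II)
chemistry differences, raw two-channel intensities and dye bias, batch
effects, cell-composition heterogeneity beyond the single leukocyte
compartment, spatially correlated (regional) methylation, and
genotype-driven outliers. Passing recovery tests therefore demonstrates
the correctness and calibration of the pipeline's statistics under the
stated noise model — not robustness to artifacts that upstream
normalization is supposed to remove.

## Problem sizes and numerical choices

The test and acceptance cohorts are sized for a laptop-class run while
keeping the statistics meaningful: null calibration uses 50,000 probes
at 12-vs-12; recovery uses 500-probe panels at 12-vs-8 (tumor) and
4-vs-8 (outcome, plus 50 external tumors and paired AH); purity uses
40 LUMP probes at α ∈ {0.2, 0.4, 0.6, 0.8}; the titration grid is
κ ∈ {5, 20, 80, 320}. Tolerances asserted in tests are stated there:
Welch p-values match an integrated t-CDF oracle to 1e-8, exact
embeddings reproduce to 1e-6, TSV round trips to the 6 printed decimals.
Thresholds are strict inequalities everywhere, matching the printed
selection rules they implement.

## Known limitations

- The Welch test on Beta-distributed values with a dozen samples per arm
  is very slightly conservative for probes with means near the
  boundaries; the null p < 0.05 fraction sits marginally below 0.05.
- Cluster labels "A"/"B" are outcome-anchored, not tree-anchored; with
  no outcome annotation the mapping to biology must come from the user.
- The regulated-gene caller trusts exact gene-symbol matches and does
  not weigh multiple supporting probes beyond the max-|Δβ| tie-break.
- r² is symmetric evidence of association, not calibration; a scaled or
  shifted copy of a profile still scores r² = 1.
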