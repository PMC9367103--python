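# Methods

## Purity/copy-number correction (rVAF)

The observed VAF of a somatic mutation is diluted by normal-cell DNA
and modulated by the local copy-number state.  With tumor cell fraction
`ρ ∈ (0, 1]`, total tumor copy number `n_tot ≥ 1` at the locus, and
`n_mut` mutated copies per tumor cell (`1 ≤ n_mut ≤ n_tot`), a fully
clonal mutation is expected at

    VAF_exp = n_mut ρ / (2 (1 − ρ) + n_tot ρ),

the mutated-copy yield of tumor cells over all allele copies in the
mixture (normal cells are assumed diploid wild type at somatic loci).
`rVAF = VAF_obs / VAF_exp` is reported raw — binomial sampling noise
pushes truly clonal mutations slightly above 1, and capping would bias
the mean — and clamped to [0, 1] only where it is used as a cellular
prevalence (displays, clustering input).  Multiplicity is estimated as
the `m ∈ {1..n_tot}` whose expected VAF is nearest the observation,
ties toward the smaller `m`; this exactly inverts `VAF_exp` on
noiseless input, which the tests assert over the full grid with
`n_tot ≤ 4` and `ρ ≥ 0.4`.

## Calling, trace rescue, and trajectories

Calling emulates a conventional exome pipeline on count data: a variant
passes when covered, `VAF ≥ min_vaf` (default 0.05) and
`alt ≥ min_alt` (default 3; a stringency stand-in for requiring two
independent callers to agree, since callers themselves cannot run on
count tables).  The first failing gate is recorded
(no_coverage → below_vaf → below_alt_reads).

Between two samples a mutation is persistent / emerging / disappearing
by its call pattern; mutations called in neither sample are outside the
called-variant universe and excluded from trajectory output.  For
emerging (disappearing) mutations the earlier (later) sample's raw
counts are re-scanned: ≥ 1 alt read at a covered, un-called locus is a
trace, reported with its uncapped read count.  Calling and trace
presence are mutually exclusive by construction.  Samples enter
comparisons only with tumor cellularity ≥ `min_cellularity` (default
0.20); when the intermediate timepoint fails the gate, the last sample
is compared directly to the first and the pairing is flagged as a
fallback in the output.

## Clonal clustering

Mutations are clustered jointly across timepoints on clamped-rVAF
vectors.  Cluster k has a prevalence parameter per timepoint; a
mutation with prevalence `x` at depth `d` contributes a binomial
log-likelihood with `x·d` pseudo-successes.  EM with 10 random restarts
per K is run for K = 1..k_max (default 10); K is selected by BIC with
ties to the smaller K, and empty clusters are dropped.  This finite
mixture is a deliberate desk-scale stand-in for Dirichlet-process MCMC
(PyClone-style): deterministic given a seed, adequate for
three-timepoint prevalence vectors, and not a reproduction of any
sampler's posterior.  Because rVAF rescaling inflates variance relative
to a raw binomial VAF (dividing by `VAF_exp < 1` multiplies the
sampling noise), the model is mildly overdispersed on real pipeline
output and BIC can split generously there; on data whose noise is
binomial at the stated depth, selection is sharp (the planted
three-cluster recovery test selects K = 3 in 10/10 seeds with mean
prevalence error ≈ 0.003).

Two display rules follow.  A single-mutation cluster is merged into the
non-singleton cluster minimizing the norm of its per-timepoint
z-vector, where each z standardizes the singleton's prevalence against
the cluster mean with the cluster's binomial standard error
`sqrt(θ(1−θ)/d̄)`; the merge is accepted only if every |z| ≤ 1,
otherwise the singleton is retained and flagged.  The ±1 window is our
operationalization of an otherwise underspecified z-score acceptance
rule and is documented as an interpretation.  Clusters with fewer than
3 mutations are then pruned from display output but kept, with
members, in a removed list — analysis-complete, display-pruned.
Parent guesses for fishplot-style rendering use containment: A can
parent B when A's prevalence ≥ B's at every timepoint; the tightest
container wins, exactly one maximal cluster is the root, and
non-contained non-root clusters are marked ambiguous (prevalences alone
cannot distinguish a new subclone carrying all truncal mutations from
one that lost some).

## CNA dynamics, TMB, response, association

Gains/losses are called against an integer baseline of 2; no
whole-genome-duplication adjustment is attempted by default (the
baseline is overridable per call).  Cohort dynamics are per-bin
differences, between two timepoints, in the fraction of patients
carrying a gain or a loss, over the patients present at both
timepoints.  Per-gene trajectories take the copy number of the segment
covering the largest share of the gene (length-weighted majority —
deterministic and order-independent); missing samples stay missing.
Paired comparisons use the Wilcoxon signed-rank test, exact null for
≤ 25 non-zero pairs and normal approximation above; an all-zero
difference vector is degenerate and reported with p = 1.

TMB divides the count of called, amino-acid-changing mutations
(missense, nonsense, frameshift, splice) by the target size in
megabases (default 50, an exome-capture-sized target; a mode counting
all variants is provided since conventions differ).  Response uses
single-lesion RECIST-style thresholds (CR at diameter 0, PR at ≥ 30%
shrinkage, PD at ≥ 20% growth, SD otherwise) dichotomized to
responders (CR/PR); a bidimensional product rule (≥ 25% growth in
largest × perpendicular diameter, boundary inclusive) overrides the
category to PD.  Association scans run a two-tailed Fisher exact test
per gene mutated in ≥ 3 patients with Benjamini–Hochberg correction
across tested genes; an ordered-group trend test (Cochran–Armitage
style, verified once against R's `prop.trend.test` and frozen in a
unit test) is provided for response-grade analyses.

## The simulator

The generator emulates the data shape of a three-timepoint neoadjuvant
exome cohort.  Per patient: a truncal clone (prevalence 1 at every
timepoint) plus 2–6 nested subclones, pretreatment prevalences by
stick-breaking within each parent's unallocated share, and per
transition a multiplicative log-normal drift (`expansion_sd = 0.5` on
the log scale) with extinction probability 0.3 for subclones below 0.1
prevalence, followed by top-down rescaling so children never exceed
their parent.  Prevalences are lineage-inclusive, so a mutation's CCF
is its clone's prevalence.  Mutations (8–25 per clone, infinite-sites)
are placed uniformly on a 44-arm genome model; copy number starts
diploid and directed gain/loss events fire at a stated timepoint with a
stated probability, persisting thereafter (somatic copy-number events
do not revert), with losses floored at total CN 1 in mutation-bearing
bins.  Read counts: depth ~ Poisson(150) — matching a mid-150s mean
exome coverage, rounded for readability — and
alt ~ Binomial(depth, CCF · VAF_exp); purity defaults to
(0.70, 0.45, 0.35) across the three timepoints, reflecting declining
tumor content under effective therapy while keeping default samples
above the 20% eligibility gate.  An optional per-base error rate adds
false alt reads for stressing trace-detection specificity; it defaults
to 0.

What the simulator does *not* emulate: trinucleotide mutation spectra,
germline contamination, mapping artifacts, subclonal copy number, or
region-dependent coverage.  Passing tests therefore demonstrate the
correctness and calibration of the algebra, gating, clustering, and
bookkeeping under the stated generative model — not robustness to
alignment-level artifacts in real exomes.  There is no literature
generative model for treatment-induced prevalence drift at this
granularity; the dynamics parameters are the package's own study
conditions, chosen once and exposed in `SimConfig`.

## Numerical and design notes

- Mixture EM clips prevalences to [1e−6, 1 − 1e−6] for finite
  log-likelihoods; binomial coefficients are dropped (constant across
  components and K, so BIC comparisons are unaffected).
- All randomness flows through `numpy.random.Generator`s seeded from a
  single configuration seed (per-patient streams via `SeedSequence`
  spawning), making cohort generation and the full pipeline
  byte-deterministic given the seed.
- The run manifest hashes the analysis configuration (excluding the
  output directory) so reruns are verifiably identical.
- Problem sizes in the test suite and acceptance script (10-patient
  cohorts, 10⁴-replicate calibrations, 10-seed clustering recovery)
  were chosen as the smallest sizes at which the Monte-Carlo standard
  errors are decisively below the asserted tolerances.
- Known limitations: the binomial mixture ignores rVAF overdispersion
  (see above); multiplicity estimation assumes clonal copy number; the
  containment parent heuristic can be ambiguous for crossing
  trajectories; trace re-scanning accepts supplied counts as-is, with
  no base/mapping-quality re-filtering.
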