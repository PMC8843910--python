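# Methods

## Mixture model

A genomic segment in a tumor sample is modelled as a two-population
mixture: diploid normal cells with heterozygous genotype AB, and a fraction
ρ ∈ (0, 1] of aberrant cells carrying N total copies of the segment, m of
which are the minor allele (NOMA). The observable summaries are

* sample-average copy number c = 2(1 − ρ) + Nρ,
* log2 ratio r = log2(c / 2),
* B-allele frequency at germline-heterozygous probes
  b = ((1 − ρ) + mρ) / c.

Array allele labels are arbitrary, so all computation folds the BAF to
min(b, 1 − b) ∈ [0, 0.5]. For fixed (N, m) the map ρ ↦ (folded BAF, log2R)
is the hypothesis's *fitting curve*; for m = 0, N ≥ 1 the folded BAF is
strictly decreasing in ρ (derivative −N/c² after folding), so ρ is
identifiable from BAF alone via the closed form
ρ = (1 − 2b) / (1 − m + (N − 2)b). Balanced hypotheses (2m = N, including
the diploid state and homozygous deletion N = 0) keep folded BAF pinned at
0.5 and are not invertible from BAF; copy-neutral LOH (N = 2) keeps log2R
pinned at 0 and is not invertible from log2R. This is why the pipeline
restricts clonal inference to NOMA = 0 states where at least one signal
moves.

## Segment fitting

`fit_segment` enumerates hypotheses N ∈ {0..4}, m ∈ {0..⌊N/2⌋}, ρ on a
0.01 grid over (0, 1], and minimises the weighted squared distance

    w_b (b_obs − b̂)² + w_r (r_obs − r̂)²,  w_b = 1.0, w_r = 0.25.

BAF is the primary signal — it is the quantity that distinguishes clones —
while log2R mainly disambiguates N; the 4:1 weighting encodes that, and
both weights are configurable. Ties break deterministically toward smaller
N, then smaller m, then smaller ρ (the grid is enumerated in that order and
`argmin` takes the first minimiser), so results are bit-for-bit
reproducible. A segment with no heterozygous probes is fitted on log2R
alone and can never qualify for the CC count.

A fitted segment **qualifies for CC** iff m = 0, N ∈ {1, 2}, the residuals
pass the curve gates (|Δb| ≤ 0.025, |Δr| ≤ 0.10), and ρ ≥ 0.05. The
qualifying set admits both hemizygous loss and copy-neutral LOH — the two
NOMA = 0 states with a normal-or-lower copy number; it is configurable.
ρ_min = 0.05 prevents noise-level "clones", and the gates are sized for
typical SNP-array segment noise (median over ≥ 50 probes).

## Clonal-composition calling

Per sample:

1. **Screen**: a segment is aberrant if folded BAF < 0.45 or
   |log2R| > 0.10, with at least 50 probes. The 0.45 floor also absorbs
   the small downward bias of median-of-folded-values summaries near 0.5.
2. **Fit** every aberrant segment as above.
3. **Stage-1 clustering**: single linkage over qualifying segments in
   (folded BAF, log2R) with per-axis tolerances (0.02, 0.08) — segments
   with the same signal belong to the same underlying event.
4. **Stage-2 merge**: single linkage of stage-1 clusters on their
   probe-weighted %AC with tolerance `merge_delta_ac` = 5 percentage
   points — events at the same cell fraction belong to one clone. Larger
   segments carry more probes, hence more weight. Single linkage with a
   scalar threshold makes the cluster count monotone non-increasing in the
   tolerance.
5. **CC number** = number of merged clusters. CC = 0 ⇒ mono-CC
   (homogeneous mass), CC ≥ 1 ⇒ poly-CC. A sample is **undetermined** when
   at least one segment passes the LOH screen but none survives the curve
   gates — its aberrations do not plot onto any admissible fitting curve.
   When only some LOH-screened segments are off-curve they are dropped
   with a warning and the rest are used.

Design choices made where the procedure was genuinely open: CC counts *all*
distinct %AC clusters (so CC = 0 is the homogeneous reading); an
alternative subclone-only count (clusters − 1) sits behind
`count_subclones_only` but is not the default. The merge tolerance is our
parameter — no published value exists for combining clusters "at the same
%AC". The undetermined rule (no qualifying segment despite LOH signal) is
one consistent reading of assignment failure; partial failures only drop
the offending segments.

## Synthetic cohort

The generator emulates molecular-inversion-probe array output: per-probe
log2R ~ Normal(r̂, σ_r = 0.25) and, at heterozygous probes (25% of probes),
unfolded BAF with a random allele phase per SNP (b̂ or 1 − b̂, then
Normal noise σ_b = 0.04, clipped to [0, 1]) — reproducing the mirror-band
geometry of real arrays; homozygous probes sit near 0/1. Segments carry
100–2000 probes (300–800 in cohort mode). Probes are summarised by medians,
robust to outliers.

Default cohort composition matches the study design being re-analyzed:
8 mono-CC samples (no qualifying aberration), 26 poly-CC samples with 1–3
clones (ρ drawn from [0.2, 0.9] with pairwise gaps > 2 × merge_delta_ac so
the true clone count is well-defined; a hard mode disables the separation),
and 2 samples whose LOH-like folded BAF (0.10–0.20) is paired with a
gain-like log2R (0.7–1.0), off every NOMA = 0 curve. Overlapping events
across clones are rejected: nested-subclone three-population mixtures are
outside the generator's scope.

Recurrence-free survival is exponential with the configured group median
(rate ln 2 / median): the minimal distribution with a specified median,
which is all the study-level information available. The poly arm's median
defaults to 7.0 months (the published value); the mono arm's "median not
reached" is encoded as a 60-month median inside a 60-month administrative
censoring window. The two undetermined samples draw from the mono arm (the
study's two unassignable cases were recurrence-free). Binary covariates
are Bernoulli with group-dependent prevalences loosely shaped on the
published clinical table.

What the generator does **not** emulate: real genome coordinates and
karyotypes, GC waves and other spatially correlated array noise, probe
dropout, whole-genome doubling, subclonal nesting, and any relationship
between covariates and survival beyond the CC grouping. Passing recovery
tests therefore demonstrates correctness of the inference pipeline under
its own model assumptions, not performance on real arrays.

## Cohort statistics

Implemented from first principles (scipy supplies only numeric primitives
such as the hypergeometric pmf), with scipy/lifelines as independent
cross-checks in the tests:

* **Fisher exact, two-sided**: sum of hypergeometric point probabilities
  ≤ that of the observed table (relative tolerance 1e−7 for floating
  ties) — the probability-ordering convention of the common clinical
  statistics packages, verified against ten published p-values.
* **Mann–Whitney U**: midranks for ties; exact enumeration for pooled
  n ≤ 12, otherwise normal approximation with tie and continuity
  corrections.
* **Kaplan–Meier**: product-limit estimator; at tied times events are
  processed before censorings. Median = first event time with S ≤ 0.5,
  else the explicit value "not reached".
* **Log-rank**: one-degree-of-freedom statistic (ΣO − E)²/ΣV with the
  hypergeometric variance at each distinct event time.

Per-variable p-values are reported unadjusted; no multiple-testing
correction is applied, matching the univariate reporting style of the
source tables.

## Problem sizes and numerical choices

The hypothesis grid is 9 (N, m) states × 100 ρ values; fitting is a
vectorised argmin and a full 36-sample cohort simulates and calls in well
under a second. Recovery properties are checked over 200 seeded tumors per
noise level; log-rank power and type-I error over 500 replicates of the
8-vs-26 design; the exponential-median calibration and the acceptance
quantity use n = 5,000 draws. All random streams are
`numpy.random.default_rng` seeded explicitly; identical (spec, seed) pairs
give byte-identical output files.

## Known limitations

* Purity/ploidy are not globally estimated (no ASCAT-style joint fit);
  each segment is fitted independently, so a genome-doubled tumor would be
  misread.
* The qualifying set and gates assume segment noise typical of ≥ 50-probe
  OncoScan segments; very short segments are excluded rather than modelled.
* CC is a lower bound on clonal diversity: clones without NOMA = 0
  copy-number events are invisible, and distinct clones at coincident cell
  fractions merge.
* The survival generator ties outcome to CC class only; it cannot probe
  confounding between covariates and survival.
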