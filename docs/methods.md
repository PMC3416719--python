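# Methods

`snpfreq` estimates SNP frequency in transcriptome contigs in a way that
accounts for both contig length and contig depth. This note documents the
models, the filter rules, the synthetic-data generators, the numerical
choices, and the limits of what the test suite demonstrates.

## The problem

In pooled-sample transcriptome sequencing, SNPs are discovered by comparing a
contig's consensus sequence with the reads assembled into it. The commonly
reported "SNPs per kb" statistic corrects for contig length only, but the
probability of observing a SNP also rises with the number of reads covering
the contig: a 100-read contig exposes rare alleles that a 2-read contig
cannot. `snpfreq` therefore models per-contig SNP counts jointly on length
and depth and reports a *standardized SNP frequency* — the expected SNP count
at a reference length and depth (say, 1 kb at 10 reads) — instead of a
per-kb rate.

## SNP calling

Input is a set of contig alignments: consensus sequence, per-base consensus
quality, and the aligned reads with per-base qualities (SAM + FASTA [+ QUAL],
or a per-column pileup TSV). A column yields a call only if every rule of the
cascade passes:

| rule | default | notes |
|---|---|---|
| contig length | ≥ 100 bp (501 bp for the "long" dataset) | eligibility gate |
| contig depth | ≥ 10 reads | depth = number of aligned reads, not per-base coverage |
| base quality | > 20 | exclusive; failing bases are ignored, not disqualifying |
| biallelic | exactly 2 bases among quality-passing reads | ≥3 bases (triallelic) excluded |
| indel exclusion | zero aligned gaps at the column | a gap carries no quality requirement |
| minor-allele support | MAF ≥ 0.01 **or** ≥ 2 minor reads | the two criteria combine with OR |
| flanks | 20 bp of high-quality consensus on each side | evaluated on consensus quality; `N` never counts |
| homopolymer | not in / adjacent to a run > 4 identical bases | run plus one base each side |

Design choices where the rules left room:

* **MAF denominator** is the quality-passing read count at the site, not the
  contig read count — the only consistent frequency when reads partially span
  a contig. With full-span reads the two coincide.
* **Flank quality** is consensus (assembler) quality, because "high-quality
  site" is defined by the consensus base score.
* **Homopolymer exclusion zone** covers the run and the two immediately
  adjacent positions, where pyrosequencing homopolymer miscalls concentrate.
* **Ties** (equal counts for the two alleles, MAF 0.5): the minor allele is
  the lexicographically later base; the call is kept.
* Coordinates are 0-based half-open internally, 1-based in all outputs
  (VCF convention). Output is minimal VCF 4.2 plus a flat TSV mirror.

Accepted substitutions are classified as transitions (A↔G, C↔T) or
transversions (the other four unordered pairs).

## Per-contig table and summaries

One record per eligible contig: `contig_id length depth cnc n_snp n_ti n_tv`,
with `cnc = 1` for protein-coding and `0` for non-coding transcripts (labels
are consumed as input; coding/non-coding classification is out of scope).
Contigs failing the eligibility gates never enter the table. The module
provides dataset summaries (totals and means, overall and per class), the
long-contig (≥ 501 bp) subset, Ti/Tv ratios, and Pearson correlations of
counts against length or depth (t-distribution p-values, raw counts,
no transformation).

## Count models and selection

Per-contig counts y_i (SNP, Ti, or Tv) follow an NB2 negative binomial,

    y_i ~ NB(μ_i, α),   log μ_i = β₀ + β_L·LENGTH_i + β_D·DEPTH_i + β_C·CNC_i,
    Var(y_i) = μ_i + α·μ_i²,

with covariates entered untransformed (bp; read counts). Four candidate mean
structures are compared, all carrying the intercept and CNC: the full model
M1 {LENGTH, DEPTH, CNC}, M2 {DEPTH, CNC}, M3 {LENGTH, CNC} (the "SNPs/kb"
surrogate), and M4 {CNC}.

* **Estimation**: joint ML over (β, α) via `statsmodels`
  `NegativeBinomial(loglike_method="nb2")`, seeded with a Poisson fit for β
  and α = 0.1; BFGS first, Nelder–Mead fallback with warm restart;
  convergence is verified and non-convergence raises with the optimizer
  trace. α is floored at 1e-8 and flagged as a Poisson-limit fit there.
* **Inference**: Wald standard errors from the joint observed-information
  matrix (α included), 95% limits = estimate ± 1.96·se, two-sided normal
  p-values. No multiple-testing correction.
* **AIC** = −2·logL + 2k with k = #β + 1 (the dispersion counts as an
  estimated parameter). Different software counts k differently, so absolute
  AICs are not comparable across implementations; all reported quantities
  derive from ΔAIC only.
* **Akaike weights** w_i = exp(−Δ_i/2)/Σ_j exp(−Δ_j/2) are computed in log
  space (log-sum-exp), so Δ ≈ 465 gives w ≈ 1.0×10⁻¹⁰¹ rather than
  underflowing; evidence ratios w_i/w_j return `inf` on an underflowed
  denominator rather than raising.
* **Prediction**: the standardized SNP frequency is exp(β·x) at the supplied
  (length, depth, class); a delta-method Wald interval
  exp(β·x ± 1.96·√(xᵀΣx)) accompanies it when the coefficient covariance is
  available. Reported coefficient tables without covariance (wrapped with
  `published_fit`) give point predictions only.

## Synthetic data

Real 454 transcriptome data are not bundled; two generators emulate them.

**Alignment simulator.** Contig lengths are truncated lognormals and depths
shifted truncated lognormals calibrated so the truncated means and ranges
match a typical 454 transcriptome assembly: all-contig dataset mean ≈ 811 bp
on [100, 5400] and ≈ 28 reads on [10, 315]; long-contig dataset mean
≈ 1003 bp on [501, 5354] and ≈ 32 reads. Defaults: coding fraction 0.47
(0.554 for the long-dataset count simulator), planted-SNP rate 0.81 per kb
(≈ 0.65 per mean-length contig), minor-allele fraction uniform on
[0.08, 0.5] with minor count clipped to [2, depth/2], and a 0.64 transition
share for planted substitutions (the Ti/Tv ≈ 1.8 regime). Correct bases get
qualities uniform on [25, 40]; per-base substitution errors (rate 10⁻³)
carry low qualities, uniform on [5, 20] — pyrosequencing miscalls are
predominantly low-confidence, and the caller's >20 quality filter is
precisely what removes them. Reads span the full contig by
default (so contig depth equals per-column depth); `full_span_reads=False`
enables ragged spans for stress tests. One RNG substream per contig is
derived from the root seed by spawn key, so contig *i* is bit-reproducible
independent of `n_contigs`.

Planted SNPs are placed only at sites that pass every filter rule, so on an
error-free run the truth table is exactly the callable set. Six decoy
classes each violate exactly one rule — homopolymer (a run of 5 is written
into the consensus around the variant), indel (aligned gaps at the column),
triallelic (two minor alleles, each ≥ 2 reads), low-minor (a singleton minor
read at MAF < 0.01; such contigs are forced to depth ≥ 150, since the OR
rule only rejects singletons at site depth > 100), edge (within 20 bp of a
contig end), and low-quality flank (a consensus-quality dip inside the
flank window). Events are spaced ≥ 2·flank + 8 bp apart so they cannot
interact.

**Count simulator.** Gamma–Poisson sampling of the NB2 model above, with
default β = (−0.9828, 0.0002, 0.0146, −0.0999) — coefficient magnitudes of a
fitted long-dataset SNP model — and transitions split binomially from each
count at Ti proportion 0.64 (the Ti/Tv ≈ 1.8 regime). The NB dispersion of
the original data is not published anywhere to take from; the default
α = 0.5 is a package choice representing moderate overdispersion (variance
≈ μ + 0.5μ²), stated in config and never inferred.

**What the simulators do not emulate**: flowgram chemistry and
basecalling, assembly errors and chimeric contigs, misclassified
coding/non-coding labels, correlated errors between reads, positional
quality decay, and high-confidence miscalls (every simulated error is
sub-threshold, so the simulated truth table is exact; real data would
contain a residue of quality-passing errors, and under the MAF-OR rule a
singleton high-quality error is accepted whenever site depth ≤ 100).
Passing tests therefore demonstrate correctness of the
scoring rules and estimators under the stated generating model, not
robustness to real-assembly artifacts.

## Verification strategy and problem sizes

* The caller is checked two independent ways: recall = precision = 1 against
  the planted truth (584 planted SNPs, ≥ 112 decoys in each of the six
  classes, error rate 0), and exact equality with a separately coded literal
  per-column scorer on 1,000 random ≤ 50-column alignments containing noise,
  gaps, `N`s and ragged reads.
* The NB2 likelihood is validated against a direct gamma-function evaluation
  (1e-8) and the full fit cross-checked against R's `MASS::glm.nb`.
* Parameter recovery runs 300 replicates at n = 3,181 with the default β and
  α; each coefficient's Wald 95% CI covers its true value in ≥ 90% of
  replicates. Finite-sample coverage under these conditions (mean count
  ≈ 0.8) is ~92–94%, approaching nominal as n grows; 300 replicates keep the
  Monte Carlo error of the coverage estimate near 1.5%.
* Model selection is exercised on 200 replicates simulated with β_L = 0 at
  n = 3,000: the DEPTH-containing models (M1 + M2) take combined weight
  ≥ 0.99 in ≥ 95% of replicates.

## Known limitations

* Wald intervals mildly undercover at low mean counts (above); profile or
  bootstrap intervals are not implemented.
* The caller assumes reads are already aligned to the consensus; it performs
  no realignment, and insertions relative to the consensus are ignored
  (they have no consensus column).
* The MAF-OR rule accepts singleton minor alleles whenever site depth ≤ 100
  (1/depth ≥ 0.01); with a nonzero sequencing error rate this admits some
  error-driven calls — a property of the rule itself, not of the
  implementation.
* Zero-inflated and quasi-likelihood alternatives, exposure offsets, and
  nucleotide-diversity estimators are out of scope.
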