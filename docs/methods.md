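# Methods

## Generative model of the synthetic repertoire

The generator emulates the structure of a human IGHV germline set and a
clonally independent mutated repertoire, with effect sizes planted so
that recovery is checkable.

**Alleles.** Each allele is a random ACGT sequence tiled by six
contiguous subregions with 1-based inclusive boundaries, in fixed order
L-intron-L (60 nt), FW1 (78), CDR1 (24), FW2 (51), CDR2 (24), FW3
(114) — plausible IMGT-like lengths; only the FW1 anchor is load-bearing.
Every allele carries an AGCT at V-segment positions 8–11 (FW1 starts the
V segment). With probability `ebox_fw1_prob` (default 0.8, reflecting
that most germline FW1 AGCTs sit in a CAGCTG context) the flanks at V
positions 7 and 12 are fixed to C and G, completing the E-box; otherwise
the flank pair is drawn uniformly from the 15 non-(C,G) combinations.
Extra AGCTs are planted per subregion (defaults: 1 in CDR1, FW2 and
CDR2, 2 in FW3) at interior positions with ≥6-nt margins and ≥10-nt
separation; random background sequence may of course contribute further
hotspots, as real sequence does.

**Per-site rates.** Site i of a germline receives

* `base_rate_at` (default 0.005) if A/T and not in a hotspot,
* `base_rate_cg` (default 0.01) if C/G and not in a hotspot,
* `hotspot_rate` (default 0.15) if it is the C of a top-strand WRCH or
  the G of a top-strand DGYW (the bottom-strand C). AGCT, palindromic,
  marks both central bases — AID deaminates on either strand.

The G and C of an AGCT inside a CAGCTG context are multiplied by
`ebox_multiplier` (default 0.3; values < 1 are suppressive). AGCT sites
then receive the PyPy effect on the logit scale,
`rate ← expit(logit(rate) + pypy_slope · n_PyPy)` with `pypy_slope`
defaulting to 0.15 per overlapping pyrimidine dimer in the 6 nt upstream
of the AGCT's A. Effects are ordered: E-box multiplier first, PyPy
second, then multiplicative lognormal noise `exp(N(0, noise_sd²))`
(default sd 0.3 — keeps rates positive and spreads them over orders of
magnitude, as SHM site rates are), then clipping to [0, 1]. Because the
noise is median-preserving, the expected realised rate of a site class
is its deterministic rate times `exp(noise_sd²/2)`, which the tests use
as the closed form.

**Repertoires.** Each of `n_clones` clonally independent sequences
mutates every site independently with its site rate; a mutated base is
replaced uniformly by one of the three alternatives (no transition bias
— the downstream contingency analysis needs only mutated-vs-not at
specific sites). No indels, no selection, no clonal phylogeny: one
representative per clonal group is drawn directly.

**What this does not emulate.** Real repertoires have transition-biased
substitution spectra, non-independent mutations within clones (shared
phylogeny), selection on productive rearrangements, allele-usage skew,
and sequencing error. Passing tests therefore demonstrate that the
pipeline's machinery recovers known planted structure, not that the
biological effect sizes are as modelled.

## k-mer dataset

Sliding 15-nt windows (no padding; a length-L sequence gives L−14
records), centre at window position 8, coordinates 1-based inclusive
throughout. A record is AGCT-centred when window positions 7–10
(central G) or 6–9 (central C) spell AGCT, so each interior AGCT yields
exactly two records. Observed frequency at a site is the fraction of
clones differing from germline. Ambiguity codes are not handled — the
synthetic data is clean; a window containing N would have to be dropped.
One-hot rows are ordered A, C, G, T.

## Convolutional regressor

One 1-D convolution (32 filters, width 5) over the 15 positions with 4
input channels, ReLU, then the position-resolved feature map is
**flattened** into a 16-unit dense ReLU layer and a sigmoid output;
mean-squared-error loss, Adam (lr 0.003, 100 epochs, batch 64). The
feature map is flattened rather than globally pooled because the target
is position-specific — the mutability of the central base depends on
where a motif sits relative to the centre, and pooling discards exactly
that information. Forward and backward passes are written in numpy; the
same backpropagation yields exact gradients of the prediction with
respect to the input, verified against finite differences. All
stochasticity (initialisation, shuffling) is keyed to `config.seed`.
Learning rates much above 0.003 destabilise Adam on these small, highly
skewed targets (predictions collapse to 0), which fixed the default.

## Integrated gradients

Attribution of F(x) against the all-zero baseline (natural for one-hot
input): `scores = x ⊙ (1/m) Σ_{k=1..m} ∇F((k/m)·x)` — a right-Riemann
approximation of the path integral, evaluated at interpolation points
k/m. A trapezoidal variant is available behind `method="trapezoid"`;
which sum the popular implementations use is not standardised, so the
choice is explicit. For a linear model the sum is exact at any step
count. The completeness residual |Σ scores − (F(x) − F(0))| is attached
to every attribution; at 500 steps it is required (and observed) to be
below 1% of |F(x) − F(0)|. Box-plot summaries use linear interpolation
between order statistics for quartiles and Tukey whiskers (most extreme
point within 1.5×IQR); logo tables are per-column letter frequencies.

## PWM scanning and the E-box census

Counts matrices are parsed from JASPAR text via Bio.motifs, re-keyed by
base letter so file row order is irrelevant. Log-odds use a pseudocount
of 1.0 distributed by the background (uniform by default) — the standard
choice that keeps scores finite. The p-value score threshold is the
smallest achievable score t with P(background score ≥ t) ≤ p, computed
by dynamic programming over per-column score distributions: exact (full
distribution, merged by value) for widths ≤ 12, discretised to a 0.001
grid beyond, and cross-checked against exhaustive 4^m enumeration at
small widths. When even the top score is more probable than p the
threshold is placed just above it, so no window matches (this happens
for narrow or degenerate matrices: a width-6 motif cannot reach
p = 0.001·4⁻⁶-level specificity if columns are flat). Scanning reports
forward hits and, for `strands="both"`, reverse-complement scores at the
forward-strand start coordinate. The per-15-mer "motif score" used in
correlations is the best passing window score over both strands; 15-mers
with no passing window carry no score.

The shipped default E-box matrix is synthetic — built from the CAGCTG
consensus (85% consensus weight per column), reverse-complement
symmetric like the real palindrome — because a measured SELEX matrix is
not redistributed with the package; any JASPAR text file can be supplied
via `pwm.jaspar_path`. The census scans the full allele and assigns each
CAGCTG/CANNTG match to the subregion containing its start, so
boundary-spanning motifs are counted exactly once.

## Context features

PyPy dimers are counted overlapping (5 dimers in 6 nt) by default, with
a `disjoint` convention behind a flag, since published counts do not pin
the convention down. The window is taken 5' of the AGCT's A on the
forward strand only. For central-C records the window would begin one
base before the 15-mer, so the count is undefined and raises; the
PyPy+E-box regressions are therefore fit on central-G records, where
both features exist. The E-box indicator is equivalent to flanks
(C, G) — both definitions are implemented and tested equivalent.
Synonymy uses the standard genetic code via Bio.Seq.

## Statistics

Pearson r is reported with the Wald p-value of the regression slope
(`scipy.stats.linregress`). The t-test is Welch's (unequal variances,
Welch–Satterthwaite df) — a deliberate choice where "t-test" alone would
be ambiguous. Mann-Whitney is exact (no ties, both n ≤ 20) or
normal-approximated with tie correction otherwise; Fisher is two-sided
by the ≤-probability summation convention. All tests are two-sided and
unadjusted for multiplicity. For very large tables the two-sided Fisher
p underflows double precision, so a certified log-space upper bound
`log10 p ≤ log10 2 + min(logcdf, logsf)` under the hypergeometric null
is reported alongside; conditional frequencies compared against printed
one-decimal percentages are rounded half-up. Degenerate inputs (constant
vectors, zero-variance samples, rank-deficient designs, empty clone
sets, zero denominators) raise or return NaN exactly as documented on
each function.

## Problem sizes

Default pipeline runs use 8 alleles × 2000 clones. The planted-effect
recovery analyses use 6 alleles × 10⁵ clones (≈50 AGCT central-G
records), where binomial noise on per-site frequencies is ~10⁻³ and the
×0.3 E-box and ×2 conditional-doubling effects are recovered within
10–20%. Model-fit checks train on ~2700 15-mers with noiseless targets.
These sizes were chosen so the full suite and the acceptance script each
run in well under a minute while leaving the planted effects many
standard errors from zero.

## Known limitations

* The regressor is a deliberately small architecture; it is not a
  reimplementation of any published SHM predictor's weights, and
  headline correlations from real BCR-seq datasets are not reproducible
  from synthetic data.
* The PyPy window convention and the strand handling of motif scoring
  are explicit package choices among defensible alternatives (flags
  where noted).
* The census treats subregion assignment by motif start; motifs spanning
  a boundary are not split.
* Real-data ingestion (IMGT-gapped numbering, productive/non-productive
  classification, clone inference) is out of scope; inputs are plain
  FASTA plus a boundaries TSV.
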