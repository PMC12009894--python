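# Methods

## Model

The unit of inference is the *extended haplotype*: a vector of biallelic
SNP alleles over a subset S of the flanking region, augmented with the
copy-number (CN) allele of the gene, treated as one extra multiallelic
locus.  Individuals are assumed to be formed by random pairing of
haplotypes (Hardy–Weinberg equilibrium), so with haplotype frequencies f
the likelihood of an individual's unphased data is the sum of f(h₁)·f(h₂)
over every ordered haplotype pair compatible with the SNP genotype (at
non-missing sites) and the CN label.  CN labels may be a known
per-haplotype pair or only a diploid total; in the latter case the pair
decomposition is treated as latent along with the phase.  Missing SNP
genotypes are marginalized — the site places no constraint — never imputed.

Consequences of the HWE assumption worth keeping in mind: inbred or highly
structured reference panels violate random pairing and will bias the fitted
frequencies; the simulator deliberately samples under HWE, so the test
suite does not probe that failure mode.

## EM estimation

Frequencies are fitted by expectation–maximization over the latent phase.
The state space is initialized to the union, across individuals, of
haplotypes appearing in at least one compatible configuration (not the full
2^|S| × |CN| space), with uniform starting frequencies.  Per iteration the
observed-data log-likelihood is asserted non-decreasing.  Defaults:
convergence at |Δ log L| < 1e-6, at most 200 iterations.  At convergence,
haplotypes below `prune_freq` (default 1/(4·N), N the effective in-bag
size) are removed once and frequencies renormalized; pruning never orphans
an individual — any sample whose every compatible configuration would
vanish keeps its most probable configuration.  Per-individual configuration
enumeration is capped (default 65,536 configurations); during subset growth
a candidate subset that exceeds the cap is simply treated as non-improving.

Internally haplotypes are bit-packed integers, capping |S| at 60 SNPs —
far above the default subset limit of 25 — and letting the posterior be
evaluated for all samples at once with vectorized mask arithmetic.

## Classifier training

One classifier per bootstrap replicate.  In-bag individuals (drawn with
replacement, carried as multiplicity weights) supply the EM data; the
out-of-bag (OOB) complement — fraction (1−1/n)ⁿ ≈ 37% in expectation —
scores the classifier.  The SNP subset starts from the best single SNP
among an initial random draw of `mtry` candidates and grows by rounds:
draw `mtry` SNPs not yet in the subset, refit EM for each tentative
addition, accept the best if it strictly improves OOB accuracy.  Candidate
ties break by higher in-bag log-likelihood, then lower SNP index, so builds
are bit-reproducible.  One redraw is allowed after a failed round before
growth stops ("patience 1"): the stopping rule the source description
leaves open ("until maximum accuracy is achieved") needed a concrete,
deterministic form, and bounded patience avoids premature stops from an
unlucky draw.  Deletion/backtracking steps are not implemented.  Rejected
candidates stay drawable in later rounds, so `mtry ≥ |pool|` reduces to
deterministic greedy forward selection.  Defaults: `mtry = ⌈√P⌉`,
`max_snps = min(P, 25)`, K = 25 classifiers.  K is a repository choice —
the method description does not state a value — sized so that every sample
is out-of-bag for ≈9 classifiers in expectation, enough for stable
OOB-aggregated validation at desk scale.

Per-classifier seeds derive from the model seed via
`SeedSequence(entropy=seed, spawn_key=(k,))`; an empty OOB draw (possible
at tiny n) is retried at seed+1 … seed+10, then errors.

## Prediction

Target SNPs are matched to the model universe by snp_id, falling back to
chrom+position.  Allele reconciliation: identical → keep; swapped → recode
g ↦ 2−g; complementary → strand-flip and re-compare (possibly also
swapped).  Palindromic A/T and C/G SNPs are dropped by default
(`keep_palindromic` assumes shared strand), and model SNPs absent from the
target become all-missing columns, handled by marginalization.  A
classifier with no usable SNP abstains for every sample.

The ensemble distribution is the arithmetic mean of the non-abstaining
classifiers' posteriors (no accuracy weighting — the source describes plain
averaging), renormalized.  The call is the CN *pair* with the highest
aggregated probability; exact probability ties go to the lexicographically
smallest pair.  The call threshold compares that maximum pair probability
(not the total-CN probability: confidence is described per imputed CNV
pair); samples below CT are reported as no-calls, not errors.

## Quality control and windows

Per-SNP filters follow the removal rules: minor allele frequency ≤ 5%,
call rate ≤ 95%, or Hardy–Weinberg exact-test p < 1e-5 (retention is
strict inequality).  The HWE test is the full-enumeration two-sided exact
test — all heterozygote counts compatible with the allele counts, summing
probabilities ≤ that of the observed configuration — rather than a
chi-square approximation, because behavior at an extreme cutoff like 1e-5
with panel-sized counts is exactly where the approximation is worst; mid-p
is not used.  Flanking windows are closed intervals center ± w kb with
1-based coordinates (PLINK/VCF convention).  Genotype codes count copies
of `allele_b`, stated explicitly because PLINK dialects differ.  Whether
SNPs inside the gene body should be excluded is genuinely open (windows
are measured from the gene center, yet the method is described as using
flanking SNPs); the region is supplied by the caller, and the simulator
places no special SNPs at the center, so the package takes no position.

## Synthetic panels

The generator builds a founder pool of extended haplotypes: each CN allele
gets a distinct random "core" SNP haplotype; a founder copies each SNP from
its core with probability `ld_strength`, otherwise draws from a background
frequency (uniform on 0.1–0.9), so SNP–CN r² rises smoothly from 0 to 1.
Pool slots are apportioned to CN alleles by largest remainder (the default
pool of 1000 reproduces the default frequencies exactly).  Designated tag
SNPs are deterministic indicators of specific CN alleles (r² = 1), and an
optional informative radius zeroes the LD of SNPs beyond a distance from
the gene center — the device behind the window-sweep plateau fixtures.
Individuals are two independent pool draws (HWE); missingness is i.i.d.
Default CN-allele frequencies follow the shape reported for LILRA6-like
variation in a Japanese population (0.926/0.051/0.019/0.004 for
1/2/0/3 copies); the window-sweep fixtures use a less skewed, African-like
spectrum so that every tag SNP comfortably survives the 5% MAF filter.
What the simulator does *not* emulate: realistic LD decay along the
chromosome (background SNPs are exchangeable), genotyping error,
population structure, and CN-label error — so passing tests demonstrate
correctness of the estimation machinery under its own assumptions, not
field performance on real arrays.

## Evaluation

Primary accuracy is the unordered CN-pair match; total-CN accuracy and
confusion are reported alongside (the two differ whenever a total
decomposes multiple ways).  OOB internal validation scores each sample by
aggregating only the classifiers whose OOB set contains it; k-fold
cross-validation (stratified by CN genotype, unstratified with a warning
when a class has fewer than two members) is provided for comparison.
Classifier abstentions count as incorrect in OOB scoring.  Per-class
metrics are one-vs-rest SEN/SPE/PPV/NPV with 0/0 ratios reported as
not-available (NaN), never 0.  Sweep grids: windows 10–100 kb in 10 kb
steps; call thresholds 0–0.95 in 0.05 steps, with call-rate monotonicity
asserted.

## Problem sizes

Test and acceptance fixtures use panels of 30–400 individuals, 3–30 SNPs,
and K = 8–25 classifiers; the simplex-grid oracle for the EM check uses
resolution 1/8 (1/4 when the support exceeds 8 haplotypes).  These sizes
were chosen as the smallest at which the statistical properties under test
(OOB mass, plateau shape, LD monotonicity) are stable across seeds.

## Model files

Models serialize to versioned JSON (`libag-model-1`), storing the SNP
universe, per-classifier bootstrap indices, subsets, haplotypes and
frequencies.  Floats round-trip exactly (shortest-repr encoding), so a
serialized and reloaded model makes bit-identical predictions; a version
mismatch is an explicit error naming both versions.
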