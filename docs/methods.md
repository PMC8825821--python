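# Methods

## Problem and model

In a TMT experiment, up to 11 samples are labeled with isobaric reagents,
pooled, and quantified together; each MS2 spectrum yields one reporter-ion
intensity per channel. A variant peptide — a tryptic peptide spanning a
non-synonymous SNP — is only produced by samples carrying the alternate
allele, so its per-channel intensities encode allele dosage: channels from
AA (non-carrier) samples see background noise, BB channels see full
signal, AB channels roughly half. `smapkit` exploits this to infer a
genotype vector per channel and match it against a reference panel.

The package treats genotypes as the three diploid classes AA/AB/BB plus
missing. The reference panel is a samples x SNPs matrix (read from VCF,
`0/0 -> AA`, `0/1 -> AB`, `1/1 -> BB`, `./. -> missing`; phased
separators accepted; multi-allelic records skipped because the
variant-peptide table keys on a single alternate allele). The minor
allele frequency is computed from the panel itself,
`(2·#BB + #AB) / (2·#non-missing)`, folded to <= 0.5.

## Preprocessing

The quantification pipeline applies, in fixed order: (1) isotope-impurity
correction, solving `t · M = o` per peptide row where `M[i, j]` is the
fraction of channel *i*'s reagent signal appearing in channel *j* (the
shipped example row for the 126 reagent is 91.8 / 7.9 / 0.3% into 126 /
127 / 128); (2) loading normalization, rescaling each channel so its
trimmed median (default trim fraction 0.1 per tail) equals the grand
trimmed median; (3) log2 transform, with zero intensities floored at the
batch minimum positive intensity and flagged — zeros are legitimate
observations (allele absent) but the scaling needs finite values;
(4) optional PSM-to-peptide averaging; (5) per-peptide min-max scaling to
[0, 1]. Constant peptides (max = min) carry no genotype signal and are
dropped rather than mapped to 0.5. Mean-centering is offered only as a
reporting transform; min-max scaling subsumes it for inference.

## Noise model and peptide filters

The minimum log2 intensity of a variant peptide across sample channels is
bimodal: peptides with at least one non-carrier channel contribute a
noise-mode value, peptides whose channels all carry the allele contribute
a signal-mode value. A two-component 1-D Gaussian mixture is fit by EM
with deterministic initialization (split at the sample median; per-side
moments as starting parameters; seeded jitter only to restart degenerate
iterations; component SDs floored at 1e-3 of the data range). Components
are labeled by mean; the log-likelihood trace is retained and is
non-decreasing by construction of EM.

Filters, with defaults: minimum-signal cutoff `noise mean + 1.5·SD`
(log2 units); per-peptide signal-to-noise ratio, defined as the
linear-scale mean of values at or above the cutoff divided by the
linear-scale mean of values below it, at least 3; panel MAF strictly
above 1%. Peptides entirely below the cutoff are removed as noise. The
S/N ratio has no universally fixed formula in this setting; the
linear-mean ratio across the EM cutoff was chosen because the signal
side is dominated by mutant-homozygote channels and the noise side by
non-carriers, making the ratio an estimate of the BB/AA intensity
contrast. The EM fit is per batch by default; a global scope (fit once,
reuse the cutoff) is available by configuration.

## Genotype inference

Per SNP, a dosage prior restricts the classes that can be called: only
classes observed in the reference genotypes are eligible. The prior's
scope defaults to the samples named in the batch manifest
(`dosage_scope="batch"`): inference happens one multiplexed batch at a
time, and the genotypes actually present among ~10 samples are the
relevant prior. At moderate allele frequencies a batch often carries only
two classes at a SNP, which routes the call through the sharper
two-class rule; measured on synthetic batches this raises per-call
accuracy by ~0.1 and widens the ΔCscore margin substantially. The whole
cohort can be used instead (`dosage_scope="panel"`). Mislabeling within
the cohort barely perturbs the batch-scoped prior, since it only needs
the *set* of classes, not per-sample assignments.

Three-class SNPs use the quartile rule on the scaled values: below the
25th percentile AA, the closed interval [Q1, Q3] AB, above the 75th
percentile BB. Quantiles use linear interpolation between order
statistics (numpy default); values exactly at Q1 or Q3 take the
interquartile class. Quartiles are computed per peptide within one batch
— the comparison is between channels of one spectrum — and include the
internal-control channel by default (pooled controls sit mid-range).
Two-class SNPs split at 0.5, the higher scaled value taking the higher
class in the order AA < AB < BB; this generalizes the mutant vs
non-mutant case to {AA, AB} and {AB, BB} panels. Monomorphic SNPs are
skipped: they cannot discriminate samples. Multiple peptides covering
one SNP are combined by per-channel majority vote, ties giving missing.

The quartile rule imposes ~25/50/25 class proportions regardless of the
true genotype distribution, so individual calls are noisy whenever class
frequencies are skewed — matching tolerates this because identity rests
on hundreds of SNPs, but single calls should not be over-interpreted.

## Matching and thresholds

Every channel is scored against every genotyped sample in the cohort
(not only its batch; mix-ups cross batches). Fraction-mode Cscore is the
fraction of exactly matching calls over positions where both vectors are
non-missing; at least 20 compared SNPs are required (guarding against
spuriously perfect scores on tiny overlaps), otherwise the score is
missing. ΔCscore is (best − second)/best; an exact tie gives 0 and hence
an unassignable channel; a single candidate gives 1.0 by convention.

Status assignment needs a Cscore threshold. By default it is calibrated
from the pooled internal-control channels: their best scores estimate
the background concordance an arbitrary inferred vector achieves against
the cohort, and the threshold is their mean (globally across batches
when several are processed together). This mirrors how such thresholds
are set in practice — the control channels are a built-in negative
control — and adapts to scoring mode, SNP count and cohort composition.
Fixed constants can be supplied instead (`cscore_min`); without controls
the fallback constants are 0.80 (fraction) and 1.50 (weighted). The
ΔCscore threshold defaults to 0.20. The weighted mode scores a matched
position by a per-class weight (1/2/3 for AA/AB/BB), emphasizing rarer
mutant matches and yielding score scales above 1; the two modes rank
candidates nearly identically and fraction mode is the default because
it is exactly the "percentage of matched genotypes" definition.

Corrections (label != best match, thresholds passed) form a directed
graph original -> assigned; weakly connected components are classified as
reciprocal (2-cycle), cyclic (single directed cycle of length >= 3),
one-way (simple path), or complex for any other shape real correction
sets can produce.

## Synthetic data

The generator emulates the study design: a Hardy-Weinberg panel with
per-SNP MAF uniform on [0.05, 0.5] (420 samples x 500 SNPs by default
for the shuffling benchmark), and 11-plex batches with one variant
peptide per SNP, log2 intensities drawn per channel from the genotype's
mode — noise N(14.06, 1.39²) for AA, signal N(18.22, 1.29²) for BB, the
midpoint and average SD for AB, all in log2 units of reporter intensity;
these are the EM-fitted modes of real minimum-signal distributions. A
pooled control channel receives the across-channel mean plus jitter, and
multiplicative channel loading biases (log2-normal, SD 0.25) are applied
so normalization is exercised. What the generator does not emulate:
multiple PSMs/peptides per SNP, missingness patterns, allele-specific
expression imbalance, linkage disequilibrium, relatedness or population
structure, batch-to-batch drift. Passing end-to-end tests therefore show
the inference-and-matching machinery is sound under the stated intensity
model, not that real cohorts will reach the same accuracy.

## Shuffling benchmark

To measure how much genotype corruption matching tolerates, one sample
has `round(alpha% x n_snps)` positions (sampled without replacement)
resampled from the panel's per-SNP genotype class frequencies, and the
corrupted vector is scored against all candidates. Replacement draws
from the full class distribution by default (`any_class`), so a
resampled position may keep its class by chance — the corrupted sample
then behaves like a random cohort member at resampled positions, which
is the regime in which heavily corrupted samples remain identifiable:
with 420 samples x 500 SNPs the true sample still ranks first in >= 95%
of replicates at 80% corruption. A `different_class` policy forces every
resampled position to change class (drawn from the renormalized
remaining frequencies), making alpha the exact realized error rate
(fraction-mode self-concordance exactly 1 − alpha/100); under that
policy corrupted positions are systematically anti-correlated with the
panel and ranking degrades much sooner, so it is the harsher, less
representative model of mislabeling-like corruption. Positions whose SNP
is monomorphic in the panel cannot change class and are skipped in favor
of other positions under `different_class`.

The benchmark summary reports, per alpha, the rate at which the true
sample ranks first (ties counted as failures), and the headline quantity
is the smallest intact percentage (100 − alpha) with recovery >= 0.95,
scanning from the largest qualifying alpha. Default 50 replicates per
alpha; the acceptance script uses 100 to narrow the binomial error at
the 95% boundary.

## Numerical and design notes

- Genotype calls are int8 codes (AA=0, AB=1, BB=2, missing=-1); scoring
  is vectorized over the candidate panel and verified against a
  position-by-position counting oracle in the tests.
- EM convergence: |Δ log-likelihood| < 1e-8 or 500 iterations; a
  non-converged fit is returned flagged rather than raised.
- Impurity correction can produce small negative solutions for noisy
  rows; they are clamped to zero with a logged count.
- Determinism: every stochastic component takes a seed or Generator;
  identical configuration and seed give byte-identical outputs.
- Problem sizes in the test suite (40-sample cohorts, 300-SNP batches,
  20 replicate runs; 100 replicates per alpha in the benchmark) were
  chosen to estimate the reported rates with standard errors comfortably
  below the asserted margins.

## Known limitations

- Heterozygote-only panels ({AB} with both homozygotes absent) use the
  generalized two-class rule; expression imbalance can defeat it.
- The control-calibrated threshold needs at least one pooled control
  channel; designs without internal controls fall back to fixed
  constants that may need manual tuning.
- Genotype calls are hard labels; no likelihood or quality score is
  propagated.
- The quartile rule's fixed 25/50/25 allocation biases per-call accuracy
  at skewed allele frequencies (see above); identity matching is robust
  to this, expression-QTL-style downstream use would not be.
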