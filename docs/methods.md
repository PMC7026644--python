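# Methods

This note documents the models implemented in `coda`, the choices made
where the design was genuinely open, and what the synthetic benchmark does
and does not establish.

## Relative activity from selection sequencing

A self-cleaving ribozyme's activity readout is the fraction of its
transcripts that have cleaved by the time of reverse transcription.  With
cleaved/total read counts per variant and for the wild type,

    RA(var) = N_cleaved(var) · N_total(wt) / (N_total(var) · N_cleaved(wt)),

so RA(wt) = 1 by construction, RA is invariant under uniform rescaling of
read counts, and values above 1 (variants more active than the wild type)
are legitimate.  Variants need at least `min_reads = 5` total reads;
barcodes mapping to several sequences keep the majority sequence only when
its frequency exceeds 50%; reads whose length differs from the reference
are discarded (the variant model is substitution-only — indels from
error-prone PCR are rare and carry no pairing signal here).  Counts from
different barcodes carrying the same substitution set are summed before RA
is computed, and batches are merged by arithmetic mean of RA.

Triple mutants extend double-mutation coverage: for a triple XYZ whose
third mutation is near-neutral (RA(Z) > 0.5), RA(XY) ≈ RA(XYZ)/RA(Z).
Every qualifying Z contributes, estimates for the same double key are
averaged, and directly measured doubles are never replaced; the reduction
only applies at position pairs with no direct double at all.

## CODA: covariation-induced deviation of activity

The null model is mutation independence: the double-mutant RA is a smooth
function of its two single-mutant RAs, learned by ε-SVR with an RBF kernel
(C = 2000, γ = 2.0) on *all* observed doubles — functional and
nonfunctional alike — with no structural input.  Including nonfunctional
variants is essential: the rescue signal is a nonfunctional-single /
functional-double contrast, and the acceptance suite shows that discarding
variants with RA < 0.5 collapses the max-MCC of the scores.

Implementation choices:

- **Symmetry.** The regression has no natural argument order, so training
  rows are duplicated with swapped arguments and prediction averages the
  two orderings; `predict(a, b) == predict(b, a)` to machine precision.
- **ε and the training cap.** ε = 0.01 so that on noiseless multiplicative
  data the fitted surface reproduces the product to a few hundredths
  (ε-insensitive fitting would otherwise leave deviations up to ε).
  libsvm training is superlinear in sample count, so above `max_train =
  2000` doubles a seeded random subsample is used; the response surface
  has two inputs and is smooth, and predictions are indistinguishable from
  an uncapped fit.
- Predictions are floored at 0 (activities are nonnegative).

The per-double score is

    CODA = (RA_obs − RA_pred) / (RA_pred + shift),   shift = 0.2,

a relative activity excess; the shift keeps the denominator away from 0
and results are insensitive to it across 0.1–0.5.

**Mixture de-mixing.** CODA scores mix a dominant near-zero component
(unpaired) with a sparse high-mean component (paired).  Because the paired
mass is ~1%, the bulk statistics (a1, sd1) are estimated from all scores;
the paired component (a2, sd2) from the outlier subset beyond
a1 + k_sd·sd1 (k_sd = 3), whose relative size is the prior P(paired).
Note the subset mean is a *truncated* mean: refitting on draws from a
known two-Gaussian mixture returns the closed-form truncated expectation
(verified in the tests), which sits above the generating component mean.
The estimator is used for classification, where this bias is benign: the
pairing score ranking it induces is what matters.

**Pairing score.** A two-state naive-Bayes log score (natural log,
strictly positive densities):

    Ps = ln p(CODA | paired) / p(CODA),
    p(CODA) = p(CODA|paired)·P(paired) + p(CODA|unpaired)·(1 − P(paired)).

Ps saturates at −ln P(paired) for strong outliers.  Per position pair the
score is the maximum over the up-to-nine observed mutation combinations —
a single strong compensatory rescue is enough evidence; the mean is
available as a configurable alternative.  Reduced-triple doubles are
scored identically to direct doubles.

## Energy model and Monte Carlo search

Structures are partner maps — one partner per base, crossing pairs
allowed, at least 3 unpaired bases inside every hairpin.  The energy is

    E = Σ stack ΔG37 + 0.45 per AU/GU helix end + P_lone + P_noncanonical
        − W · Σ_paired max(Ps(i,j), 0) / m,

with Turner 2004 nearest-neighbor stacking free energies (embedded at the
0.1 kcal/mol granularity of the machine-readable Turner 2004 parameter
set) for adjacent canonical pairs; the (i+1, j−1) adjacency rule remains
well-defined under crossings, so helices inside pseudoknots stack
normally.  Stacks involving a noncanonical pair contribute 0 (no measured
parameters exist); the pair instead pays the noncanonical penalty.  A lone
pair — neither diagonal neighbor paired — pays the lone penalty, plus the
terminal AU/GU penalty once (not twice) if applicable.  The lone and
noncanonical penalties share a single adjustable value, 3.0 kcal/mol,
chosen so unrestrained search yields no lone or noncanonical pair;
unrestrained results are unchanged anywhere in 2–5 kcal/mol.

**Restraint normalization and clipping.**  m is the mean of the positive
per-position pairing scores: the raw mean is typically negative and would
flip the restraint's sign.  Negative Ps values are clipped out of the
restraint by default (`clip_negative` in `restraint_matrix` restores the
signed form).  The reasons are documented at the clip site and matter
enough to restate: a true helix-edge pair covered by only one or two
non-compensatory doubles earns a large negative naive-Bayes score that
overstates the evidence, and repelling such pairs blocks the stacking
terms from completing sparsely covered helices — precisely the gap the
folding stage exists to fill.  With clipping, covariation-silent pairs are
treated like unscored pairs (zero restraint) and recovered by stacking.

**Search.**  Each Monte Carlo step draws one candidate position pair
uniformly from the fixed geometric candidate set (span > min_loop, any
base combination — noncanonical pairs are penalized, never forbidden) and
toggles it: remove if currently paired, add if both ends are free, else a
no-op.  Creation and destruction of any given pair are proposed with
equal probability, so the bare Metropolis rule exp(−ΔE/T) satisfies
detailed balance, and fixed-temperature chains reproduce exact
enumeration Boltzmann marginals in the tests.

Annealing returns the lowest-energy structure visited, not the final
snapshot (standard annealing elitism).  This matters because random
sequences are rife with near-degenerate minima: at the final temperature
of 0.1 a structure 0.05–0.2 kcal/mol above the minimum retains
substantial Boltzmann weight, so the last-step state loses an
already-found minimum appreciably often.  Two alternatives were measured
on the ≤18-nt enumeration suite at 10,000 steps per temperature and
rejected: the classic ½-remove/½-add proposal under plain Metropolis
(its uncorrected asymmetry acts as an entropic penalty of roughly
T·ln(candidates/pairs) per pair, delaying helix condensation to low
temperature where mobility is gone; 18/100 runs reached the minimum) and
final-snapshot return under the symmetric proposal (68/100, the
degeneracy loss above).  The symmetric proposal with elitism reached the
enumerated minimum in 100/100 runs.  Energy updates are incremental and
O(1) per step; the inner loops are numba kernels, with the reference
energy implementation in `coda.energy` held in lockstep by tests.

Annealing runs from T = 10 down to 0.1, ×0.95 per stage, 500,000 steps per
stage by default; temperature is unitless against kcal/mol energies.
Repeating the run under distinct derived seeds gives per-pair frequencies;
the consensus takes pairs in descending frequency, keeping those at
frequency ≥ 0.5 whose bases are still free (ties break lexicographically).

## Evaluation

The negative universe is all C(L,2) unordered position pairs (no diagonal
exclusion); with pairs ~50× rarer than non-pairs, the headline metric is
MCC together with the precision-recall curve (ties grouped per threshold,
area by trapezoid with the first threshold's precision extended to recall
zero) and the MCC-maximizing cutoff (ties resolve to the sparser
prediction).  Noncanonical reference pairs count as positives; pairs never
scored rank below every scored pair.  Degenerate denominators return 0.
An alternative universe convention (e.g. excluding near-diagonal pairs)
would shift TN counts; the convention here reproduces the worked examples
in the acceptance suite.

## Synthetic benchmark

A designed 50-nt ribozyme with 14 planted pairs: a 5-bp and a 6-bp helix,
a 2-bp kissing pseudoknot between the two hairpin loops, and one lone pair
crossing the first stem.  Design constraints, fixed once: unpaired
positions use only A and C (which cannot pair with each other) and the
tertiary pairs are A-U, so every stackable register outside the planted
structure collides with planted positions and loses the consensus, making
the planted structure the unique stable ground truth; A/U-rich tertiary
pairs also receive the elevated AT mutation rate, mirroring the
composition of real tertiary contacts.  The sequence is a frozen constant;
the seed drives loop-effect draws, library sampling, and Monte Carlo
seeds.

Activities are multiplicative: factor 1 for a planted pair that remains
canonical in the variant (compensatory rescue — the signal CODA exploits),
0.05 for a disrupted helix pair, 0.2 for a disrupted
pseudoknot/lone pair (tertiary contacts give weaker covariation), a fixed
per-(position, alternate) factor in U[0.3, 1.1] per mutated unpaired
position, and lognormal noise (sd 0.1).  Libraries draw substitutions per
base per error-prone-PCR round (rate 0.008, 3 rounds, AT positions 2.5×)
— 2.4%/6.0% per-position totals for GC/AT, within the realistic epPCR
range, mean ≈ 2 substitutions per variant; depth is lognormal around a
median of 50 reads and cleaved counts are binomial.  30,000 variants give
100% single and ≈50% double coverage after triple reduction, with GC
helix pairs systematically undersampled — the regime the method is
designed for.

What the benchmark does *not* emulate: sequencing errors, PCR duplicates,
batch effects, partial rescues (compensatory swaps restore full activity
here), or long-range/allosteric activity coupling.  Passing tests
establish that the implementation recovers planted structure under the
stated generative model, not field performance on real libraries.

**Scaled run sizes.**  The test and acceptance configurations use 20
annealing runs of 150,000 steps per temperature for the 50-nt benchmark
(frequencies resolved to 0.05), and 10,000 steps per temperature for the
≤18-nt oracle comparisons; both are documented package choices that leave
conclusions unchanged relative to the 100 × 500,000 default.

**Known parameter sensitivities.**  On the benchmark the positive
pairing scores all saturate at the ceiling −ln P(paired), so the
normalizer m equals the ceiling and every covariation-supported pair
receives a restraint of exactly W kcal/mol.  A lone pair therefore enters
the consensus only when W exceeds its lone + AU-end cost (3.45 kcal/mol):
at the default W = 2 the consensus recovers 13/14 planted pairs, and from
W = 5 it is exact.  This is the expected behavior of a
restraint-vs-penalty margin, not a sampling artifact: isolated pairs are
exactly the structures the lone penalty exists to suppress.  The
pseudoknot pairs, which stack on each other (cost 0.9 against restraint
2W), are recovered at every W ≥ 2, and the restrained consensus is
unchanged across the whole 2–5 kcal/mol penalty range.

## Reproducibility

Every stochastic step — library sampling, SVR subsampling, annealing —
derives from explicit seeds; pipeline stage seeds derive from the master
seed via CRC-tagged `SeedSequence`.  Identical configuration and seed
reproduce identical tables byte for byte.
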