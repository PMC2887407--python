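# Methods

## The codon substitution model

All likelihood computations use the Goldman–Yang (1994) Markov model over
the 61 sense codons of the standard genetic code.  The instantaneous rate
from codon *i* to codon *j* is zero unless the codons differ at exactly one
position, and otherwise proportional to the target codon's stationary
frequency π_j, multiplied by κ for transitions and by ω for nonsynonymous
changes.  Each generator is scaled so that one unit of branch length equals
one expected substitution per codon at stationarity.  The chain is
time-reversible, so P(t) = exp(Qt) is computed from the symmetric
eigendecomposition of `diag(π)^{1/2} Q diag(π)^{-1/2}`; this is both faster
and better conditioned than a general matrix exponential and lets a single
decomposition serve every branch length.

Codon frequencies default to F3x4 (the product of position-specific
nucleotide frequencies estimated from the alignment, stop codons removed
and the rest renormalized), with `equal` and `empirical` (observed codon
proportions) as alternatives; frequencies are floored at 1e-10 to keep the
similarity transform finite.

### Branch models

A `LabeledTree` carries one class label per branch.  A branch model is a
partition of classes into shared-ω groups; the duplication ladder M0, M2r,
M3r, M4r, M5r and the free-ratio model Mf are provided as named
constructors.  Each group's generator is scaled to unit rate
independently, so branch lengths retain their substitutions-per-codon
meaning under every model.  Note that M3r (stems tied to their crown
clades) and M4r (the two stems tied to each other) are *not* nested in one
another, although both contain M2r and both sit inside M5r; the
likelihood-ratio machinery therefore takes its two models explicitly and
reports a flagged, untruncated negative statistic when a comparison is
mis-specified.

### Site and branch-site models

Site models are finite mixtures over ω classes: M1 (0 < ω₀ < 1 plus a
neutral class), M2 (adds ω₂ ≥ 1), M3 (K free classes, default 3), M7
(beta-distributed ω discretized into 10 equal-probability categories via
quantile midpoints), and M8 (beta plus one free ω ≥ 1 class).  Branch-site
models A and B use the four-class structure: classes 0 and 1 keep their
background ratios everywhere, classes 2a/2b switch to a shared ω₂ on the
designated foreground branches, with proportions
(p₀, p₁, p₂·p₀/(p₀+p₁), p₂·p₁/(p₀+p₁)).  Model A fixes ω₁ = 1 and bounds
ω₂ ≥ 1; model B frees ω₀, ω₁ and ω₂.  Mixture generators share a joint,
proportion-weighted rate scaling (computed separately for foreground and
background branch sets in branch-site models), so a high-ω class evolves
faster than a constrained one, as it should.

Per-site posteriors are naive empirical Bayes: mixture parameters are fixed
at their maximum-likelihood estimates and the posterior of class *k* at
site *h* is p_k L_h(k) / Σ_j p_j L_h(j).  Sites whose total posterior in
ω > 1 classes reaches 0.95 are flagged with the first sequence's amino acid
as the reference residue.  The output labels the method NEB explicitly;
the fuller hierarchical (Bayes empirical Bayes) integration over parameter
uncertainty is not implemented, so weak-data false positives are damped
only by the fixed-parameter posterior itself.

## Likelihood evaluation and optimization

Felsenstein pruning runs over compressed site patterns (unique codon
columns with multiplicities).  Codons containing gaps or N are treated as
fully missing data (an all-ones partial likelihood); columns that are
entirely missing contribute log 1 = 0.  Per-node rescaling guards against
underflow.

`CodonModel.fit` maximizes the log-likelihood with L-BFGS-B under box
constraints: ω in [1e-6, 999] (estimates ≥ 990 are reported as unbounded
and rendered `inf`), κ in [0.01, 100], branch lengths in [1e-8, 50],
beta shapes in [0.005, 99], and mixture proportions through stick-breaking
variables in (0, 1).  Gradients with respect to branch lengths are
analytic — an inside-outside pass that costs about two extra likelihood
evaluations regardless of the number of branches — while the few global
parameters use central finite differences.  A short tighter-tolerance
polish pass follows the main optimization so that converged likelihoods
honor nesting inequalities to ~1e-7.  The search is deterministic: the
multi-start ladder seeds ω at fixed values (0.05, 0.5, 2 by default) with
no randomness, and the best final likelihood wins.  Non-convergence is
reported on the results object and warned about, never silent.

The default protocol is two-stage, as is customary at this data scale:
branch lengths and κ are estimated jointly under M0, then held fixed (and
κ passed explicitly) for every other model.  This differs from tools that
re-estimate branch lengths under each model; a `refit_branch_lengths`
switch in the pipeline (and `optimize_branch_lengths=True` in `fit`)
restores that behavior.  `n_params` on a results object counts only the
ω-structure parameters (ω's, proportions, beta shapes) — the count used
for LRT degrees of freedom under this protocol — while `n_free_total`
counts everything optimized in that particular fit.

## Counting statistics

Nei–Gojobori (1986) site counts split each codon position into synonymous
and nonsynonymous fractions over its three single-nucleotide changes,
excluding changes to stop codons from the denominator, so every sense
codon contributes exactly three sites.  Codons differing at several
positions are averaged over all minimal substitution pathways with equal
weights; pathways through stops are excluded, and a codon pair whose
pathways are all blocked is dropped with a warning.  Gapped or ambiguous
codons are deleted pairwise, not list-wise.  Proportions are corrected
with the Jukes–Cantor transform d = −(3/4)·ln(1 − 4p/3); p ≥ 3/4 sets a
saturation flag and an undefined (NaN) distance.  dN/dS with dS = 0 is
reported as undefined (None) rather than infinity so window means never
absorb non-finite values.

Sliding windows default to 30 nt with a 9 nt step (ten amino acids stepped
by three), suitable for genes of a few hundred base pairs; per-window
means over the supplied pair set are reported with 1-based inclusive
coordinates, and windows where no pair has a defined ratio carry NaN.

The NJ paralog classifier builds a neighbor-joining tree (scikit-bio) from
JC distances over references plus queries.  A query that falls on one
label's side of every bipartition that perfectly separates the two
reference sets takes that label; queries attached along the inter-clade
path are resolved by mean patristic distance, with a 2% relative margin
below which the call is `ambiguous`.  Queries overlapping the references
at fewer than half their sites are excluded with a warning.

## Rate tests and usage statistics

Tajima's relative rate test counts, over nucleotide sites where all three
sequences are unambiguous, the sites where only lineage A differs (m₁) and
only lineage B differs (m₂); (m₁−m₂)²/(m₁+m₂) is referred to χ²₁, and the
reported rate ratio is m₁/m₂ (the counts the one-degree-of-freedom test is
built on; the test is undefined, and flagged, when m₁+m₂ = 0).  Group
contrasts of per-sequence statistics use Welch's unequal-variance t-test.

Wright's effective number of codons is computed per sequence from family
homozygosities F = (nΣp² − 1)/(n − 1) — and, in the pipeline's report,
also once per group on the concatenated sequences, since short genes make
either summary alone noisy.  Amino acids observed fewer than
twice, or with F ≤ 0, are excluded from their degeneracy-class mean.  Ile
is the sole 3-fold family and the 6-fold families (Leu, Ser, Arg) are kept
intact.  A missing 3-fold class is imputed as the mean of the 2- and
4-fold classes (Wright's rule); any other missing class falls back to the
weighted mean of the available classes, with the imputation recorded on
the result.  Values above 61 are clamped (flagged); ENC is intrinsically
sensitive near that unbiased limit, where the O(1/n) term of F is
amplified — a limitation worth remembering when comparing short sequences.

## dS-clock dating

Given the synonymous distance between orthologs of two species whose split
is dated at T million years, the per-lineage synonymous rate is
r = dS_orth/(2T) and a paralog pair dates the duplication at
t = dS_para/(2r) = dS_para·T/dS_orth.  The operation takes the three
numbers directly (or distances computed by the divergence module), returns
the unrounded estimate plus a nearest-integer rendering, and makes no
attempt at confidence intervals or rate-variation corrections.

## The synthetic-data generator

The generator is the package's stand-in for a real duplicated-gene data
set and defines the conditions under which the estimators are validated.
Its default fixture emulates a short (87-codon), strongly constrained
nuclear gene sampled from two paralog clades of six species each plus two
successively diverging single-copy outgroup lineages (14 taxa), with
transition bias κ = 2 and GC3-rich biased codon usage.  Branch classes
follow the duplication structure (pre, two stems, two crowns); the
`three_ratio` preset uses ω = 0.044 / 0.118 / 0.060 for
pre-duplication / fast-paralog / slow-paralog branches and the `one_ratio`
preset ω = 0.055 everywhere.

Two calibrations make the fixture quantitatively realistic, both solved by
deterministic root-finding on analytic expectations rather than tuned on
simulation output:

* **Composition** — position-3 G+C of the F3x4 frequency model is solved
  (bisection) so the *sense-codon* stationary distribution realizes the
  requested GC3 (0.759 by default; removing stop codons shifts raw
  position frequencies, which the solve absorbs).
* **Divergence** — the expected NG86 dS between stationary endpoints of a
  path is computed exactly from the joint codon-pair distribution
  π_i [ΠP(t_k)]_ij and the pathway-averaged difference counts; crown
  depths are solved so the mean within-clade expected dS hits 0.155 (fast
  clade) and 0.131 (slow clade), and the stem depth so the cross-clade
  expected dS hits 0.55.

Evolution is sampled per branch with one categorical draw per site from
P(t) — exact for the model, since only endpoint states matter.  Site
classes for mixture regimes are drawn once at the root and inherited;
branch-site regimes switch the selected classes' ω on foreground branches
using the same joint rate scaling as the likelihood engine.  Output is
bit-reproducible given the simulation parameters and seed.

Inputs to every analysis are assumed to be coding-only, in-frame
alignments: intron removal and alignment curation are upstream of this
package.  IUPAC ambiguity codes collapse to N on input and N-containing
codons are treated as missing, matching pairwise-deletion practice.

What the generator does **not** emulate: indels and alignment error,
intron evolution, recombination and gene conversion, among-site synonymous
rate variation, and lineage-specific codon-usage shifts (one π serves the
whole tree, so the two paralogs share a GC3 target even though real
paralog pairs can differ).  Passing recovery tests therefore demonstrate
correctness of the estimators under the model's own assumptions, not
robustness to these violations.

## Validation sizes and numerical choices

The recovery suite simulates at 14 taxa × 2,000 codons (25 replicates for
the one-ratio recovery, 3 for the three-ratio regime), the
likelihood-ratio calibration at 5 taxa × 400 codons (100 null replicates),
and the generator-fidelity checks at 5,000 codons — sizes chosen so the
whole suite runs on a single CPU in well under half an hour while leaving
the binomial tolerances meaningful.  Oracle tests compare the pruning
engine against brute-force summation over internal states (3 taxa,
5 codons, 1e-10) and the NG86 implementation against exhaustive pathway
enumeration (1e-12).

Ties and degeneracies: zero-length branches use P(0) = I exactly; an
alignment column that is all gaps contributes nothing; fits are idempotent
(re-running reproduces lnL to 1e-6); and every fit records the number of
function evaluations, starts and the optimizer message for auditability.
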