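# Methods

## Sequence model and classifier

A dataset X is the set of all overlapping width-w subsequences of the
input sequences, modelled by a two-component mixture (TCM): each window
is a motif occurrence with prior λ or background otherwise.  A motif
model φ = {θ₀, θ₁, λ} yields a log-odds matrix LO_{j,k} =
ln(f_{j,k}/f_{0,k}) and threshold t = ln((1−λ)/λ); a window is called a
site when its score s = Σⱼ LO_{j,x_j} exceeds t (equivalently, when its
occurrence posterior, a sigmoid of s − t, exceeds ½).  Natural
logarithms are used for scores, likelihoods and BIC; bits (base-2) for
information content and Jensen–Shannon divergence, which keeps the
similarity threshold t_sim on a [0, 1] scale.  Predicted sites are
thinned to a non-overlapping set greedily by descending score (leftmost
on ties) within each sequence; windows containing non-ACGT characters
are skipped.  Coordinates are 0-based half-open internally and 1-based
inclusive in GFF3 output.

The likelihood entering the BIC is evaluated over the predicted sites
only, log L = Σᵢ ln[p(xᵢ|θ₁)λ + p(xᵢ|θ₀)(1−λ)], and the BIC is
−2 log L + 3(w+1)·ln n_pred, with 3(w+1) the free parameters of a
width-w model.  A candidate with no sites receives BIC = +∞ and cannot
be selected (an error is raised if no usable candidate remains).

## MCOIN

Pairwise containment statistics are computed for every (shorter,
longer) width pair in a single pass over the original candidate set: no
cascading after removals, and every shorter width is tested against
*all* longer widths, any one match sufficing to discard it.  "Mean root
JSD per column" is implemented as the mean over aligned columns of
√JS — not the root of the mean — because each column then contributes
a [0, 1] term commensurate with t_sim.  The IC/col of each model is
computed against that model's own background θ₀.  BIC ties break toward
the shorter width (fewer parameters).  Reverse-complement containment
scanning exists behind a flag but is off by default; the synthetic
benchmark is single-stranded.

t_sim defaults to 0.32, the value that minimised width RMSE on the
synthetic benchmark (see calibration below).

## Perfect candidate models ("width determination without discovery")

To evaluate width selection independently of discovery quality,
candidate models are built directly from the planted occurrences: at
the true width the empirical PWM of the occurrences; below it the
centred sub-window of the alignment (columns trimmed alternately right
then left); above it the alignment extended into flanking sequence
(columns added alternately right then left, shifted inward at sequence
boundaries).  λ is the planted-site density among width-w windows and
θ₀ is estimated from positions outside the width-w site footprints.
Two deliberate choices here:

* **Centred, not max-IC, sub-windows.**  Because planted conservation
  is homogeneous across columns, every sub-window is equally good in
  expectation; picking the empirically best one would overfit column
  noise, systematically inflate the short model's IC and so deflate the
  longer/shorter IC ratio that the discard rule tests.  (A max-IC
  sub-window utility is still exported for heterogeneous alignments.)
* **Construction sites as the discovered occurrence set.**  An ideal
  discovery run returns the model *and* its sites, so each candidate
  carries the (trimmed/extended) planted sites as x_pred for its
  likelihood/BIC.  Deriving x_pred from the threshold classifier
  instead makes the site count flicker across widths at weak
  conservation, and those count differences — not model quality —
  then dominate the BIC comparison.

Classification metrics of a chosen model (sSn, sPPV, AUC) are always
computed from the Bayes classifier's own predictions on the sequences,
and the alignment E-value is likewise computed on the classifier's
predicted alignment: it measures the significance of what a model finds
in the data.

## E-value of the alignment

For each candidate, the predicted sites are stacked into an alignment;
each column's log-likelihood ratio Σₖ cₖ ln(ĉₖ/(n·f₀ₖ)) (MLE
frequencies with a 0.01 pseudocount per cell) receives an exact tail
p-value by enumeration over all multinomial count vectors for n ≤ 30
sites, or a χ²(3 df) approximation on 2·LLR above that.  The p-value of
the product of k column p-values uses the QFAST closed form
ρ·Σ_{i<k}(−ln ρ)ⁱ/i!, evaluated in log space, and the E-value
multiplies in C(total windows, n_pred) position selections.  Widths are
compared on log E; ties break toward the shorter width.  These
concretisation details (enumeration cutoff, χ² fallback, pseudocount,
selection count) are this package's own; the estimator's qualitative
behaviour — exact at strong conservation, progressively shortening
motifs as weak flanking columns stop paying for themselves in the
QFAST correction — is insensitive to them.

## Synthetic benchmark generator

Defaults mirror the evaluation regime throughout: 20 sequences × 200 bp
per dataset, one planted width-12 motif occurrence per sequence at a
uniform random admissible offset, collections at mean conservation
{0.51, 0.76, 1.08, 1.49, 2.00} bits/col.  Background is i.i.d.
multinomial (uniform by default; composition configurable for
GC-skewed genomes) — real intergenic sequence structure (repeats,
local composition) is deliberately not modelled, so tests passing on
this generator say nothing about correlated backgrounds.

Conservation is controlled per position: each column redraws m of its
n entries uniformly over the four bases (a redraw may restore the
consensus), with m calibrated so that the *expected empirical* IC of
the column equals the target.  The expectation is computed exactly by
summing over all multinomial redraw outcomes, and fractional m is
rounded stochastically per column, under which the expectation
interpolates linearly.  Two points matter:

* Calibration targets the empirical alignment IC, which carries the
  small-sample upward bias of plug-in entropy (≈0.11 bits at n = 20);
  calibrating on the generating distribution's IC instead would leave
  realised conservation ~0.1 bits above target at every level.
  Targets below the bias floor are rejected as unreachable.
* A fixed redraw count per column, rather than per-entry binomial
  mutation, is what "controlled at each position" is taken to mean
  here; binomial mutation adds substantial column-to-column IC
  variance, which feeds directly into the noise of the IC-ratio discard
  rule and roughly doubles MCOIN's width error at the lowest
  conservation level.  Realised IC is recorded per dataset (vs a
  uniform reference, irrespective of background composition).

## EM discovery core

`em_fit_tcm` runs EM on the window mixture: posteriors in the E-step;
θ₁ from posterior-weighted counts (+0.01 pseudocount), θ₀ from the
complementary weights, λ from the mean posterior (clamped to
[1/(2·n_windows), ½]) in the M-step.  θ₁ seeds from a random data
window sharpened to 0.7/0.1, λ from one expected site per two
sequences; best of 5 starts (3 in the large benchmark loops) by final
likelihood, stopping when the log-likelihood gains less than 10⁻⁴ or at
200 iterations (the best iterate is returned with a flag if
unconverged).  Posterior overlap erasure within EM is not implemented;
non-overlap is enforced only at prediction time.  This is a
deliberately compact core: no multi-motif support, palindrome
constraints, or anti-shifting corrections.

## Evaluation

A prediction is a true positive when it overlaps a true site by at
least a quarter of the true width (integer overlap ≥ w*/4, no rounding
up); matching is greedy one-to-one by overlap.  The ROC is site-level:
at a threshold on the occurrence posterior, a true site counts as
detected when any window quarter-overlapping it clears the threshold —
so each true site enters through the maximum posterior among its
overlapping windows — while false-positive counts come from windows
overlapping no true site.  (Labelling every overlapping window positive
would cap even an exact model's AUC near 0.5, since only the unshifted
window can score highly.)  AUC uses the trapezoid rule with tied scores
grouped, equal to the Mann–Whitney statistic.  Width estimation is
summarised by MAE and RMSE of chosen vs true width over a collection.

## Calibration of t_sim

The similarity threshold is calibrated by grid search
(0.20–0.44, step 0.02) over the five conservation levels, minimising
pooled width RMSE, with **EM-discovered** candidate models: with
ground-truth-derived candidates every containment divergence is
essentially zero, so t_sim has no effect and the grid is flat — the
calibration is only meaningful against an imperfect discovery core.
Containment statistics are independent of t_sim, so they are computed
once per dataset and re-thresholded across the grid; exact ties resolve
to the smallest grid value.  The optimum is a shallow one: the RMSE
range across the grid is a few percent, and the better the discovery
core, the flatter the curve (with a sufficiently strong core the
minimiser drifts upward, because wide candidates are information-
diluted and the IC-ratio test alone blocks overestimation).  The
package default remains t_sim = 0.32.

## Problem sizes and determinism

The packaged benchmark runs use 100 datasets per conservation level for
the perfect-model protocol and 50 (24 in the test suite) per level for
the EM calibration grid; collection generation, EM restarts and all
selection rules are deterministic given the base seed, which derives
per-dataset streams via `numpy` seed sequences.

## Known limitations

Single-motif, single-strand analysis; zero-order background; the E-value
baseline is a reconstruction, not a bit-exact replica of any existing
implementation; benchmark conclusions are conditional on the i.i.d.
background and homogeneous per-column conservation of the generator —
real TFBS alignments cluster their conserved positions, which makes
containment-based width selection easier than the homogeneous synthetic
case at equal mean conservation.
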