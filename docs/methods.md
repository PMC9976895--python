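# Methods

## Setting and input model

The unit of input is a gene × screen matrix of log₂ Bayes factors (BFs) as
emitted by a BAGEL-style classifier: per gene and screen, the log₂ likelihood
ratio of the gene's guide fold changes under an essential versus a
nonessential model. A gene is a plain *hit* in a screen when BF ≥ 10
(inclusive; the literature alternates between ≥ and >, one convention is
fixed and applied everywhere here). Screens carry a tissue/lineage label and
a quality score: the F-measure against gold-standard essential and
nonessential reference sets at BF ≥ 5, with screens below 0.80 dropped
(both comparisons inclusive). Missing BF entries are refused on read by
default; optionally genes with any missing screen are dropped, because every
per-tissue analysis operates on the genes scored in all of that tissue's
screens.

All logarithms are base 2. The pipeline treats the classifier's output as
already log-scaled and adds it directly to log-prior odds; with the
background expectation that 10% of human genes are essential, the
uninformative prior odds are log₂(0.1/0.9) = −3.17, used as the rounded
constant −3 throughout (the exact value is available via
`uninformative_log_prior`). The rounded constant is what makes the standard
correspondences exact: BF 10 → posterior odds 7 → 99.2% probability;
BF 5 → posterior odds 2 → exactly 80%.

## Cumulative curves and the synthetic-genome fit

The observed cumulative-essentials curve is a bootstrap: per iteration,
`set_size` screens are sampled without replacement and the running union of
hit genes recorded; means and SDs are taken over iterations (default 100).

The simulator draws screens from a genome of N genes (default 18 111, a
genome-scale library) containing n essentials. Each screen reports h hits
(default 1287, a typical per-screen hit count at the strict threshold),
split `round(h·fdr)` nonessential and the rest essential — the
nearest-integer rounding reproduces the canonical 129/1158 split at h = 1287
and FDR 10%. Draws are without replacement within a screen and independent
across screens; whether false positives may recur across screens is not
constrained by the sampling story, and independence is the simplest
assumption.

Implementation note: because only cumulative unique counts are needed, the
simulator does not materialise gene identities. Conditional on U ids already
seen from a population of size P, the number of new uniques in a draw of d
distinct ids is Hypergeometric(P − U good, U bad, d sampled); chaining this
per screen is exactly equivalent in distribution to id-level sampling and
makes the grid fit cheap on one core. The closed-form check
E[unique essentials after k screens] = n(1 − (1 − e/n)^k), with e the
essential draws per screen, is asserted in the tests at the corners of the
default grid.

The fit minimises RMSE between the simulated mean cumulative curve and the
reference curve over the k curve points, on a grid of (n, fdr). Defaults:
FDR 1–15% in 0.5% steps (the plausible per-screen error range); n 1300–2000
in steps of 50, covering the region where genome-scale fits land — the grid
is configurable since no canonical bounds exist. k = 8 because saturation
behaviour is judged in that region and the fit should weight it rather than
the long-tail regime. 100 simulator iterations per grid point match the
bootstrap depth of the reference curve. Points violating feasibility
(draws exceeding a population) are skipped with a warning. Alongside the
argmin, the region with RMSE < 2×RMSE_min is reported as the plateau of
statistically indistinguishable fits. The screen false negative rate is the
composition FNR = 1 − mean_observed_hits/n̂ (1287 observed against n̂ = 1600
gives 19.6%, i.e. ~20%).

## Saturation resampling and bin-wise FDR

Per tissue with at least 2k screens (default k = 8, so ≥ 16), each iteration
draws k initial and k subsequent screens disjointly without replacement.
Genes are binned 1..k by initial-set hit frequency (the TP histogram). Genes
with zero initial hits but ≥ 1 subsequent hit are putative false positives;
by default they enter the FP histogram at their subsequent-set frequency
(a `flag_once` option collapses them into bin 1 instead, for the reading in
which each new gene is tallied once). The working assumption — that the
initial set is saturated, so every subsequent new hit is spurious — is
conservative: some new hits are genuinely subtype-restricted essentials, so
the resulting FDR is an upper bound.

Bin-wise FDR is the ratio of mean FP to mean TP counts in the bin,
FDR_b = FP_b/TP_b, clipped to [0, 1] (e.g. 247/648 ≈ 38% in bin 1). Bins
with no initial hits inherit the nearest populated lower bin's FDR, or 0
when there is none — such bins arise only for very frequent hits, where the
FDR is negligible anyway. The prior-update table converts each FDR to
log₂((1 − FDR)/FDR), clipped to [−3, 9]. The cap at 9 prevents numerical
blow-up from near-zero FDR estimates; the floor at −3 (the uninformative
prior) means accumulated evidence can never penalise a gene below the flat
prior — which guarantees the JLOE call set always contains the plain
threshold call set, a tested invariant.

Genes at mean initial frequency ≥ 3 of 8 (inclusive) form the tissue's
high-confidence essential set; intersecting tissues gives common essentials,
per-tissue differences the context and tissue-unique sets. Two diagnostic
profiles accompany the histograms: mean expression per bin (genes averaged
over the cell lines where they were hits — rising expression with bin is the
signature of expression-coupled false negatives), and the mean BF of each
binned gene in its non-hit screens (false negatives sit near BF 0; truly
context-restricted genes sit deeply negative).

## JLOE

Per gene within a k-screen set, screens are ranked by descending BF with
ties broken by lexicographic screen id (stable and reproducible). Rank 1 is
evaluated with the uninformative prior; a binary call is made when
posterior = BF + prior strictly exceeds 7. At rank j > 1 the prior is the
table entry for c = number of calls among ranks 1..j−1 (the count of JLOE
calls, not plain hits — essentiality having just been defined by the
posterior call), falling back to the uninformative prior at c = 0. The
"joint" posterior is BF_j + prior_j: evidence accumulates only through the
prior, never as a running BF sum, which is what makes the cap at 9
meaningful. Counts beyond the largest tabulated bin reuse the top bin, whose
FDR is negligible by construction.

Tissue-level runs repeat the k-sample 100 times without replacement within
each iteration, and convert to cell-line level by normalising each gene ×
cell-line call count by the number of iterations that sampled that cell
line; posterior log odds are normalised by the same denominator. Cell lines
never sampled are reported as missing, not zero. Prior tables are estimated
per tissue by default (a pooled or user-supplied table is accepted — which
also enables tissues with fewer than 2k screens, via a smaller k).

False negatives are the genes below saturation under plain thresholding
(mean initial frequency < k) whose JLOE mean frequency equals k (tolerance
1e−9 on the equality side). Set concordance is summarised by the Jaccard
coefficient, and the cost of any calling strategy by its unexpressed-hit
count: called genes with log₂(TPM) strictly below 1.0 in that cell line, a
proxy for false positives when comparing JLOE against simply relaxing the
BF threshold.

## Synthetic data generator

The generator emulates the structure these analyses assume: a core essential
population hit in nearly every screen; per-screen false-negative dropout;
i.i.d. background false positives among nonessentials; and subtype-restricted
context essentials within each tissue. Per (gene, screen) a latent state is
drawn first — true-hit, false-negative, true-negative, false-positive — and
recorded in the truth table; the BF is then emitted from that state's
normal distribution, truncated at the hit threshold (hit states ≥ 10, miss
states < 10) so the latent state exactly determines the realised hit.

Defaults and why:

- 2000 genes, two tissues × 20 screens, 300 core essentials, 40 context
  essentials per subtype (two equal subtypes per tissue): a reduced-scale
  panel that keeps the full suite fast while populating every frequency bin
  and satisfying the ≥ 2k screens-per-tissue requirement.
- p_fn = 0.2: the per-screen dropout rate among essentials, matching the
  ~20% screen FNR the cumulative analysis estimates. Gene-level dropout
  propensity is modulated by expression (clip(p_fn(1 − 0.8z), 0, 1) for the
  gene's expression z-score), reproducing the observation that false
  negatives concentrate among moderately expressed genes while keeping the
  mean rate at p_fn.
- p_fp = 0.015 per nonessential gene per screen: sized so that roughly a
  tenth of a screen's hits are spurious, the per-screen FDR scale the
  genome model estimates.
- Emissions: essential hits N(30, 6); dropouts N(0, 1.5) — near zero, not
  deeply negative, the observed profile of missed essentials; nonessentials
  N(−10, 6), wide enough that a realistic sliver of nonessentials lands in
  the marginal BF 5–10 band (what distinguishes threshold-relaxation from
  JLOE); false positives N(15, 2).
- Expression: essentials high (log₂TPM ≈ 6), context slightly lower, 30% of
  nonessentials unexpressed (< 1.0) to exercise the false-positive proxy.

What the generator does **not** emulate: guide-level counts, copy-number
artifacts, screen-to-screen correlation of false positives, library-specific
false negatives, or continuous gradations of context essentiality. Passing
tests therefore demonstrate correctness of the machinery under the stated
generative assumptions, not performance on any real screen panel.

## Numerical choices and degenerate inputs

- Probability conversion 2^x/(1+2^x) is computed in the numerically stable
  branch for each sign of x; beyond |x| ≈ 25 the probability itself cannot
  carry more log-odds precision than float64 allows.
- FDR → prior at the boundaries: FDR 0 maps to the cap, FDR 1 to the floor.
- F-measure is 0 when precision + recall is 0; disjointness of the reference
  sets is enforced.
- Filtering that removes every screen warns rather than raises; an FNR ratio
  above 1 (observed hits exceeding the fitted essential count) warns and
  returns the negative value.
- All resampling uses numpy's PCG64 generator; every public stochastic
  function takes an explicit seed, and fixed seeds give bit-identical
  output.

## Problem sizes used in the shipped checks

The test suite and acceptance checks run the simulator grid fit at 100
iterations per grid point (the same depth as the reference bootstrap),
parameter-recovery over 20 seeded repeats, closed-form checks at 1000
iterations, and the end-to-end rescue analysis on the default 2000 × 40
population with 100 resampling iterations per tissue — sizes chosen to make
Monte-Carlo error comfortably smaller than the tested margins on a single
core.

## Known limitations

- The saturation FDR is an upper bound; subtype structure inflates it,
  especially in heterogeneous tissues.
- The simulator's independence assumptions (across screens, between
  essential and nonessential draws) ignore correlated artifacts such as
  copy-number-driven false positives.
- JLOE operates within one tissue at a time; cross-tissue joint analysis
  and re-estimation of the prior table inside the JLOE loop are out of
  scope by design (the table is computed once from saturation resampling).
- With k = 1 JLOE reduces exactly to plain thresholding; with very small
  tissues the normalisation denominators are small and per-cell-line scores
  correspondingly noisy.
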