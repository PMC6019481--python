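# Methods

`protectomics` implements the transcriptomic analysis chain used to
quantify how a hormonal treatment protects functional pathways against a
neurological insult, in the setting of a two-color (dual-channel)
microarray study of the rat dentate gyrus: four groups of ovariectomized
females — oil-injected or estradiol-replaced, each without or with
kainate-induced status epilepticus (CON, CEN, COS, CES) — with four
biological replicates per group.  The two scientific comparisons are
COS vs CON (the insult without protection) and CES vs CEN (the insult
under estradiol replacement).

## Normalization model

Arrays follow the "multiple yellow" design: the two channels of each
array carry two differently labelled *biological replicates of the same
condition*.  Pre-processing is:

1. **Validity filter.** A non-control spot is valid iff its foreground
   fluorescence is at least twice its background (`fg >= 2*bg`,
   inclusive).  Negative fluorescence anywhere aborts with the row index.
2. **Background subtraction and median anchoring.** Each valid spot's
   background-subtracted signal is divided by the median signal of all
   valid spots with the same label on the same array, so every
   (array, label) channel has median 1.  This removes label bias and
   array-scale effects exactly (the pipeline is invariant to rescaling
   any single channel by any positive constant).
3. **Redundancy collapse.** Redundant spots probing the same gene are
   averaged (arithmetic mean) per sample; a gene with no valid spot in a
   sample is masked, not imputed.  The spot-group-level values are
   retained for the regulation test, and the squared standard error of
   the spot mean is kept to fold measurement error into the gene's CV.
4. **Iterative cross-condition renormalization.** Each pass rescales
   every sample by the median of its per-gene ratios to the across-sample
   geometric-mean reference (recomputed each pass); the loop stops when
   the mean absolute relative change of all per-gene cross-condition
   expression ratios between successive passes falls below the tolerance
   (default 5%), and fails loudly after `max_iter` (default 100) passes.
   The geometric mean is the natural anchor for ratio-scale data; the
   reference and update order are this package's declared choices.
   Even-sized medians use the midpoint convention throughout.

Per condition, a gene's mean expression is the mean of its valid
replicate values and its coefficient of variation pools the replicate
spread with the mean squared spot SEM:
`CV = sqrt(Var_rep + mean(SEM_spot^2)) / mu`.  A gene is *quantifiable*
in a condition when valid in at least n-1 of its n replicates, and
*absent* when valid in at most 1; both thresholds are configurable
package defaults (the source study does not state them).

## Regulation calls

The signed expression ratio of B vs A is `x = mu_B/mu_A` when B is
larger, else `-mu_A/mu_B`; down-regulation is negative and `|x| >= 1`
always (ties report +1).  Instead of a uniform 1.5x threshold, every
gene gets its own cut-off combining technical noise and biological
variability in the two compared conditions:

    CUT = 1 + sqrt(CV_A^2 + CV_B^2)

The quadrature form is this package's declared estimator: it is the
noise floor a fold change must clear to exceed the combined relative
uncertainty of the two means, is exact (CUT = 1) in the noiseless limit,
is monotone in each CV, and at typical per-gene CVs near 0.32 yields the
~1.45 average cut-off scale reported for experiments of this design.  A
chi-square median-unbiased CV correction is available behind
`cut_estimator="chi2"`.

Significance uses the heteroscedastic (Welch) two-tailed t-test of equal
mean log expression (log scale by default, `test_scale="raw"`
available), run separately for each distinct redundant spot group, with
a Bonferroni-type correction across the k testable groups:
`p = min(1, k * min_j p_j)`.  k counts the groups with at least three
valid replicates on both sides, since only those contribute a candidate
minimum.  A gene is called up iff `x >= CUT` and `p < alpha` (default
0.05), down iff `x <= -CUT` and `p < alpha`; equality at the cut-off is
inclusive.  No across-gene FDR correction is applied, matching the
per-gene design of the method.  Genes quantifiable in one condition but
absent in the other are reported as turned ON/OFF rather than given a
ratio.

## Pathway quantifiers

Percentages of up-/down-regulated genes are computed over *quantified*
pathway members only; unquantified members are excluded from the
denominator and reported via `n_members` vs `n_quantified`.

WPR (Weighted Pathway Regulation) is the mean over quantified members of
`c_i = (|x_i| - 1) * (1 - p_i)`.  The contribution function is this
package's declared default: it is continuous, involves no cut-off,
vanishes exactly for unregulated genes (|x| = 1) or uninformative tests
(p = 1), and satisfies the dominance requirement that a 2x gene at
p = 0.01 outweighs a 1.5x gene at p = 0.05 by more than a factor of two
(0.99 vs 0.475).  The mean (rather than sum) aggregation keeps pathways
of different sizes comparable; `aggregation="sum"` is available.

For a (unprotected, protected) comparison pair:

* `PPR = 100 * (WPR_u - WPR_p) / WPR_u` — percent reduction of WPR;
  negative when the "protected" arm fared worse; undefined (missing)
  when `WPR_u = 0`.
* `TPR = 100 * (pct_u - pct_p) / pct_u` — percent reduction of the
  regulated-gene fraction; an optional side-effect mode additionally
  debits the percentage regulated by the treatment alone
  (`TPR_adj = 100 * (pct_u - pct_p - pct_side) / pct_u`).  The simple
  mode is the default since the adjustment is only verbally specified in
  the literature this follows.

## Coordination networks

Within one condition, the coordination of two genes is the Pearson
correlation of their (log, by default) expression levels across the
biological replicates, restricted to genes valid in every replicate.
Significance uses the exact t-transform `t = r*sqrt((n-2)/(1-r^2))` with
n-2 degrees of freedom — not the Fisher z approximation, which is badly
miscalibrated at n = 4.  At n = 4, alpha = 0.05 the critical value is
exactly |r| = 0.95.  Classes: S (synergistic, r >= r_crit), A
(antagonistic, r <= -r_crit), I (independent, |r| <= r_ind, default
0.25 — a declared near-zero band, since no rigorous independence test
exists at n = 4), U (undetermined: not enough evidence, drawn as no line
in network figures).  Pair enumeration is unordered and exhaustive
(G(G-1)/2 pairs), blocked so memory scales with the block size; desk-
scale runs use a few hundred genes, and the full-transcriptome run
(12,710 genes, 80,765,695 pairs per condition) is reachable through the
same interface with a larger gene list.

Three-layer networks connect the estrogen-signaling pathway (ESG) to a
neurotransmission pathway through their common genes (CG): edges are
emitted only for ESG-CG and CG-NT pairs with class S, A or I, and CG
genes are counted once, in the CG layer, for cross-set percentages.  A
*switch* is a pair whose class differs between two conditions, with the
S→A and A→S directions tallied separately; switch detection is
equivalent to recomputing both class maps and differencing them, and is
tested against that brute-force oracle.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not array physics: no probe sequences, hybridization chemistry, spatial
gradients or saturation.  Conclusions from passing tests therefore
concern the *analysis chain*, not the wet-lab platform.

* Expression is lognormal: per-gene base log-level uniform in
  `expression_log_mean_range` (default (4.5, 8.0) natural-log units,
  i.e. levels ~90–3000 fluorescence units over a background of mean 30),
  per-gene biological CV uniform in `biological_cv_range` (default
  (0.10, 0.50), chosen so the average CUT lands in the mid-1.4 to 1.6
  range), spot-level technical CV 0.10.
* Regulation is planted multiplicatively on the condition mean of COS
  (vs CON) and CES (vs CEN) independently; signed fold changes with
  `|FC| >= 1`.
* Coordination is planted through shared latent factors: within a block,
  gene i's standardized replicate deviation is
  `l_i * F + sqrt(1 - l_i^2) * eps`, so the planted correlation of genes
  i, j is `l_i * l_j`; per-condition sign flips of selected genes plant
  coordination switches.  The raw latent form
  (`a*F + sqrt(s2)*eps`, expected r `a*b/sqrt((a^2+s2)(b^2+s2))`) is
  exposed and verified against its closed form by Monte Carlo.
* Each array carries two replicates of the same condition on its two
  channels (multiple-yellow design); per-channel label bias (default
  (1.0, 1.35)) exercises the within-label normalization; a configurable
  fraction of spots (default 5%) is drawn with foreground below twice
  background to exercise the validity filter; ~3% control spots are
  added and must be ignored.
* All draws come from one seeded NumPy generator stream: identical seed
  and config give byte-identical output tables.

The default study-scale dataset (`default_config`) has 500 genes whose
head carries the packaged pathway panel's symbols, 20% planted regulated
in COS:CON and 5% in CES:CEN (|FC| cycling over 1.5–4, alternating
sign — a strong insult with substantial protection), plus two planted
coordination blocks (rho = 0.9), one of which flips sign in CES to plant
S→A switches.

## Numerical and design notes

* Degenerate Welch inputs (both arms constant) return p = 1 when equal
  and p = 0 otherwise, so noise-free identity data yields no calls.
* Exact ties `x = +/-CUT` are called regulated; the tie at `mu_A = mu_B`
  reports x = +1.
* Floating-point background subtraction can flip the sign of an exact
  expression-ratio tie (|x| = 1 + 1e-16); consumers should compare |x|.
* The packaged GMT panel (`pathways_synthetic.gmt`, 12 sets, plus the
  ESG/neurotransmission common-gene list) is a hand-curated synthetic
  stand-in with plausible rat symbols per pathway; it is a fixture for
  desk-scale runs, not a KEGG export.
* Desk-scale problem sizes — 500 genes for the default dataset, 60–80
  genes and 20 seeds for the parameter-recovery suites, a few hundred
  genes for coordination — are the package's chosen test scale; all
  stages stream or vectorize so larger runs only cost time.

## Known limitations

* The CUT and WPR formulas are declared defaults satisfying the verbal
  constraints of the method they implement, not reconstructions of the
  (unpublished) originals; both sit behind config switches.
* The I ("independent") class is a threshold band, not a significance
  statement.
* TPR's side-effect adjustment can be negative and is not bounded below.
* The generator's invalid spots are missing-at-random; real arrays lose
  spots preferentially at low intensity, so ON/OFF calls on real data
  are harsher than the synthetic tests suggest.
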