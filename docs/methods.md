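# Methods

`diallelome` implements an analysis chain for full reciprocal diallel
metabolome studies in maize primary roots: discretize each hybrid
metabolite level relative to its two parents, screen which of these
discretized traits are predictable from the concatenated parental
profiles, aggregate classifier feature weights into a global ranking of
parental metabolite levels, and validate the ranking by predicting hybrid
root biomass.  This note records the model, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Study structure

A full reciprocal diallel over p parents contains every ordered cross
(mother x father, no selfs): p(p-1) hybrids.  The reference layout is four
inbred parents (two flint, two dent pools), their twelve reciprocal
hybrids, six biological replicates per genotype, 112 GC-MS metabolite
intensities per sample measured in three batches, and the fresh weight of
pooled primary roots as the heterotic trait.  Replicate notation: P is the
(p*r) x m matrix of parental log10 profiles, H the hybrid analogue, and
X_pp the (hybrids*r) x 2m matrix whose rows concatenate one maternal and
one paternal replicate profile (all columns autoscaled).

## Preprocessing

Fixed order, each step deterministic:

1. log10 transform (intensities must be positive; masked cells stay
   masked),
2. additive two-factor ANOVA (genotype + batch) per metabolite, with
   sum-to-zero batch effects subtracted and genotype effects untouched,
3. a single pass of outlier elimination: cells whose externally
   studentized residual from the same two-factor fit exceeds 4 in absolute
   value are masked (the cut is applied to |r|; the procedure is not
   iterated),
4. per-sample median scaling within genotype, implemented as a log-scale
   subtraction (the sample's median metabolite level minus the median over
   all cells of its genotype group) -- identical to dividing by the
   intensity-scale ratio of medians, but keeps one numeric scale
   throughout.

Column autoscaling (mean 0, unit variance, ddof 1) is deferred to the
moment classifier input matrices are built.  All two-factor fits share one
design matrix across metabolites and are solved by least squares (QR for
leverages); columns with masked cells are refit per missingness pattern.
Masked cells propagate as missing; group statistics use available cases
and any (genotype, metabolite) cell with fewer than two unmasked
replicates is reported as untestable rather than guessed.

## Combined Relative Level (CRL)

Each hybrid metabolite is compared separately against its maternal and
paternal replicate groups with moderated t-statistics.  The per-metabolite
pooled two-sample variances s2_j (df d = n1 + n2 - 2) are shrunk toward a
scaled inverse-chi-square prior (d0, s0^2) fitted to the whole metabolite
ensemble by moment matching on log variances; the moderated statistic uses
the posterior variance s2_post = (d0 s0^2 + d s2) / (d0 + d) and d0 + d
degrees of freedom.  When the empirical log-variance spread falls at or
below the chi-square baseline the moment solution degenerates to d0 =
infinity (complete shrinkage to s0^2); with fewer than three positive
finite variances no shrinkage is attempted (d0 = 0, ordinary pooled t).
Zero pooled variances (identical replicates) are handled by convention:
t = 0 for a zero mean difference, signed infinity otherwise, with an
absolute tolerance of 1e-8 on the difference and a floor of 1e-16 on the
variance so float jitter cannot fake an effect.  The implementation agrees
with limma's `eBayes` to ~1e-10 on shared inputs (frozen cross-check in
the test suite).

P-values within each (hybrid, parent) comparison family are
Benjamini-Hochberg adjusted across the m metabolites at alpha = 0.05
(both configurable; the choice of multiple-testing procedure is this
package's, BH being the field default for metabolite families).  Tests are two-sided with the direction read off the sign
of the mean difference.  The label is then:

* +2 / -2 - significantly above / below both parents (overdominance),
* +1 / -1 - significantly above / below exactly one parent,
  indistinguishable from the other (dominance),
* 0 - indistinguishable from both, or significantly above one and below
  the other (additivity; the crossing pattern also maps to 0).

Negating all data flips every label's sign (antisymmetry), and under a
global null the nonzero-label fraction is bounded by roughly twice the
FDR level.

**Balance filter.**  A metabolite whose modal label count reaches
ceil(0.75 * n_hybrids) (9 of 12) is removed from classification (weight
0).  A generalized rescue is available (and on by default): if dropping
all rows of exactly one hybrid genotype brings the modal count back under
the cut, that drop is recorded and the metabolite kept.  Note the two
rules genuinely differ at modal count exactly 9 - one modal-row drop
always cures it - so `balance_filter(..., rescue=False)` reproduces the
plain remove-at-nine behaviour.

## Predictability screen

Per balanced metabolite, the hybrid label column is treated as a
classification target over X_pp with five classifier families: linear SVM
(C = 1), LDA with Ledoit-Wolf shrinkage of the pooled covariance (the
224-feature problem is always singular), random forest (500 trees), and
PLS dimension reduction to at most 10 components followed by LDA or RF.
Per repetition (25 by default): one permuted label vector is drawn by
permuting labels across hybrids (replicate rows keep a common label), and
stratified 3-fold cross-validation is run independently for the original
and the permuted labels.  Folds are stratified at the genotype level and
replicate rows of one hybrid never straddle train/test (replicate leakage
would otherwise make every metabolite "predictable").  The per-repetition
statistic is the median over the three fold misclassification rates.

Two decision rules are implemented and both verdicts always recorded:

* quartile rule (primary): choose the two overall best methods by Borda
  aggregation of their original-label and permuted-label median-error
  ranks (ties broken by mean error, then by the fixed order SVM, LDA,
  PLS-LDA, PLS-RF, RF); the metabolite is predictable iff for both chosen
  methods the third quartile of the original medians lies below the first
  quartile of the permuted medians;
* min-median rule: the minimum original median error over all methods is
  smaller than the minimum permuted median error.

The quartile rule is deliberately strict; the min-median rule is the more
liberal operating point.  Column autoscaling is done once on the full
matrix, not per training fold; the induced optimism is accepted for
fidelity to the protocol and affects original and permuted runs equally.
Note one intrinsic property of screening a single fixed dataset: a label
assignment can carry accidental, fold-generalizable correlation with the
features (the hybrid-mean component of the replicate noise is shared by
all folds).  For an arbitrary fixed label column over 12 hybrids the
measured per-metabolite false-positive rate of the quartile rule is
10-15% and does not vanish with more repetitions -- it conditions on the
one observed label draw.  In the pipeline this is heavily damped by the
CRL + balance-filter front end: on global-null data almost every label
column is all-additive and removed before screening, and the fraction of
null datasets producing any predictable call is ~2%.

## Feature ranking

For every predictable metabolite a linear SVM (C = 1) is refit on all
rows, one-vs-one for more than two classes; a feature's importance is the
maximum absolute weight over the binary machines, converted to descending
ranks (average ranks on ties) and scaled by 1/(2m).  Features are ordered
by the median of their scaled ranks over predictable metabolites.  An
SVM-RFE mode (iterative elimination of the lowest-weight half) is
available behind `rfe_steps` but off by default: the protocol ranks
weights from a single fit.  Ranking stability is assessed by removing all
replicates of one hybrid at a time and re-running label assignment,
screening and ranking; agreement is summarized by the Spearman
correlation of the median scaled ranks and the overlap of the top-20
sets.  Stability grows with the number of predictable metabolites the
median is taken over; the desk-scale stability fixture uses ~28 driven
metabolites (a full 112-metabolite dataset would typically supply 50+).

## Biomass validation

An RBF-kernel support vector regressor (C = 1, epsilon = 0.1, bandwidth
by the `scale` heuristic, training targets standardized) predicts
per-sample hybrid biomass from feature subsets of X_pp: the top 5 ranked
features, 5 drawn at random from the top 10/20/50 pool, 5 from the bottom
pool, or all features.  Each of the 500 constructions redraws the 60/40
train/test split (all replicate rows of a hybrid stay on one side --
row-level splitting would leak genotype identity), the within-hybrid
assignment of biomass replicates to X_pp rows, the random subset where
applicable, and the permutation of the null variants: block-permuted
biomass (replicates of a hybrid move together) and a cell-permuted X_pp
(every column shuffled independently, destroying row coherence while
preserving column marginals).  Redrawing permutations per construction
matters: a single unlucky block permutation of 12 hybrids can hold the
median correlation near -0.5 across all repetitions.  Performance is the
Pearson correlation between predicted and observed test biomass;
degenerate fits (constant predictions) record r = 0 and are flagged.

With only 12 hybrids a test set holds ~5 genotype clusters, so single-split
correlations are noisy and only medians over many constructions are
meaningful; the expected ordering is top5 ~ all > random-of-top pools >
bottom pools ~ permutation nulls ~ 0.

## Synthetic data generator

The generator emulates: log-normal intensities (log10 scale, metabolite
means ~ Normal(5, 1)), between-parent variation, replicate noise,
additive per-batch offsets with round-robin batch assignment over a
randomized sample order, planted heterosis driven by parental "driver"
features, and biomass as a linear function of the driver parental levels
(baseline 350 mg, ~30 mg per log10 unit) plus noise.

Identifiability shaped three deliberate choices.  With four parents every
maternal (or paternal) feature block has rank 4, so feature identity is
carried by signal strength alone, and the maternal and paternal columns of
any strong metabolite are equally strong:

1. drivers are planted as maternal+paternal pairs of a few driver
   metabolites whose parent means sit on a wide evenly spaced grid
   (spacing 1.0 on log10), while background metabolites get a small
   between-parent spread (tau = 0.06);
2. driven metabolites default to pure-overdominance patterns with
   identical parent means: their additive cells are exact nulls (robust
   label recovery) and their own parental columns carry no signal (no
   competition with the drivers in the ranking);
3. each driven metabolite's labels come from deterministic rank thresholds
   on a signed dense mixture of the driver z-scores, with maternal
   features weighted 1.5x - reproducing the maternal-dominance trend of
   seed metabolism (triploid endosperm dosage, plastid inheritance)
   without hiding paternal drivers.

A `dominance_fraction` parameter plants +/-1 dominance patterns instead
(hybrid at one parent's level, the other parent separated by a 0.4 grid);
these exercise the one-parent geometry but their strong parental columns
compete with the drivers, so the feature-recovery studies keep the
fraction at 0.  The overdominant shift is `effect_size` times the
replicate noise SD, with a fixed 0.05 log10 offset substituted at zero
noise so the planted geometry stays strict.  `effect_size = 0` means no
heterosis anywhere (all hybrids exactly mid-parent).  Labels are balanced
two/three-class columns by construction; real label columns are messier,
and the generator does not emulate metabolite-metabolite correlation,
missing cells, retention-index artifacts, or non-Gaussian noise - so
passing tests demonstrate the machinery recovers planted structure under
the stated model, not performance on real chromatograms.

## Problem sizes and defaults

Protocol constants are package defaults: outlier cut 4, balance cut
9-of-12, 3-fold CV with 25 repetitions over five methods, 60% training
fraction, 500 SVR constructions, 5-feature subsets, alpha 0.05 with BH.
The validation studies in `diallelome.studies` (used by the test suite
and `scripts/acceptance.py`) run at desk scale: 12-112 metabolites, 6
drivers, 10-28 driven metabolites, screens with the SVM and LDA methods
at 10 repetitions (plus separate five-method calibration runs with 25
trees per forest), 100 SVR constructions pooled over 5 fixtures, and 20
fixtures for driver recovery.  A full protocol-scale run (112 metabolites,
five methods, 25 repetitions, 500-tree forests) takes hours of CPU and is
what the `diallelome run-all` CLI executes with an unmodified config.

## Known limitations

* Four parents give rank-4 parental blocks; conclusions about *which*
  feature drives an outcome are only as identifiable as the planted
  signal-strength separation - a caveat that applies to the real design
  as much as to the simulation.
* The permutation screen conditions on one observed label assignment;
  accidental predictability cannot be ruled out for single metabolites,
  only controlled in aggregate.
* Biomass medians over few genotypes are noisy; the chain ordering is a
  statement about medians over hundreds of constructions, not about any
  single split.
* The min-median and quartile rules can disagree; neither is silently
  preferred and both verdicts are stored per metabolite.
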