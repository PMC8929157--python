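# Methods

## Data model

The unit of observation is a normalized expression value `a(group, gene,
spot, replicate)`. A gene may be probed redundantly by `Rᵢ` spots (1–11 on
the targeted microarray platform), every group carries the same spot layout,
and each (group, gene, spot) cell holds exactly `J` biological replicas
(default 4). Values are strictly positive; anything at or below `1e-6` is
rejected rather than clamped because log2 is taken downstream and a clamped
zero would masquerade as a real measurement. Incomplete replica blocks are
rejected as well: the method's variance estimates assume balanced replicas,
and imputation would bias REV downward. Validation (`validate_dataset`) is a
pure reporting pass; all computation refuses datasets with a non-empty
report.

Normalization (`normalize_to_median`) divides each physical array — one
(group, replicate) column — by the median of its spot values, so AVE is
expressed in multiples of the median gene. It is idempotent up to floating
point and is optional in the pipeline: inputs are normally already
median-normalized.

## Fabric statistics

**AVE** is the mean over spots of per-spot replicate means; with balanced
replicas this equals the gene's grand mean.

**REV** is the pooled per-spot coefficient of variation, multiplied by the
mid chi-square interval estimate of the unit standard deviation on
`r = 4Rᵢ − 1` degrees of freedom:
`½(√(r/χ²(r;0.975)) + √(r/χ²(r;0.025)))`, where `χ²(r;α)` is the
*upper-tail* quantile (probability α to the right). This convention — square
roots inside the average, upper-tail quantiles — is fixed by the two known
values of the coefficient (2.15 at `Rᵢ = 1`, 1.05 at `Rᵢ = 11`); other
readings of the formula do not reproduce them. Per-spot standard deviations
use the n−1 denominator. REV is computed on the linear scale and reported in
percent.

**COR** pools over spot pairs on the log2 scale: the numerator sums products
of replicate deviations over every (spot-of-i, spot-of-g) pair, the
denominator pools each gene's full sum of squared deviations, and deviations
are taken from the gene-level log2 mean (not per-spot means). As written,
the pooled form is not algebraically confined to [−1, 1] for multi-spot
genes (the numerator factorizes through spot-summed deviations while the
denominator does not), so values are clamped; the diagonal is defined as 1
for genes with nonzero variance. For single-spot pairs the statistic is
exactly the Pearson correlation of the two log2 replicate vectors (tested as
an algebraic identity). Zero-variance genes have undefined COR: they are
flagged, excluded from coordination averages, never silently dropped.

Significance of a pair uses the two-sided p < 0.05 critical Pearson value at
`n = 4·min(Rᵢ, R_g)` paired observations — the less-redundant gene limits
the information. This keying reproduces both known cutoffs (0.95 at n = 4,
0.71 at n = 8) and decreases with redundancy. An additional *independent*
call for `|COR| ≤ 0.05` is provided for completeness; no distributional test
underlies it, so it is labelled experimental and never feeds predictions.

The full N×N COR matrix is materialized per group (O(N²) memory, a few MB at
N ≈ 2,000); per-pair queries (`compute_cor`) avoid materialization when a
single coordination profile is needed. At array scale (~20k genes) the
matrix path (~3 GB) is feasible but the per-gene path is recommended.

## Hierarchy and panel

`GCHᵢ = (⟨REV⟩/REVᵢ) · exp(4 · mean COR²)` with the median over
post-validation (quantified) genes. By default the coordination mean runs
over *all* defined partners `g ≠ i`, as the score's definition states; a
`significant` mode restricts it to pairs beyond their cutoff, because at
small gene universes the all-pairs mean is dominated by sampling noise from
4-replica correlations. Both modes are exposed; the default is the
definition. Genes with `REV = 0` (possible only in degenerate synthetic
data) get no finite GCH; they are flagged "infinite control" and ranked
above all finite scores rather than assigned infinity. Ties in GCH break by
lower REV, then gene symbol; ranking is deterministic.

Panel selection takes, per nodule, the highest-GCH gene whose selectivity
ratio (GCH in nodule / GCH in normal tissue) meets `min_ratio` (default 10 —
the observed GMR contrast between a commanded region and the other regions
is typically well above this, but the threshold is configurable because no
exact value is prescribed). A gene topping several nodules stays where its
GCH is higher; losing nodules advance to their next qualifying gene, so
panel genes are pairwise distinct. A nodule with no qualifying gene yields a
flagged empty entry, never a silent omission.

## Regulation

The composite criterion requires both `|x| > CUT` and `p < 0.05`. The cutoff
`CUT = 1 + √(2(REV²_n + REV²_c))/100` (REVs in percent) tends to 1 as
variability vanishes and grows with either group's REV, replacing uniform
fold-change thresholds. The p-value is a two-sided Welch t-test on log2
replicate values per spot (Satterthwaite degrees of freedom, scipy
implementation), combined over the gene's spots by minP-Bonferroni:
`p = min(1, Rᵢ · minₖ pₖ)`. The family is the gene's spots, not the gene
universe — the correction addresses redundant probing, and no cross-gene FDR
is applied (per-gene composite calls only). Log2 is used for the t-test for
variance stabilization, consistent with COR's log2 convention; the linear
scale is retained for AVE/REV, whose units are meaningful there. Degenerate
spots (zero variance in both groups) contribute p = 1 at equal means, p = 0
otherwise.

`WIR = AVE_normal · sign(x) · (|x| − 1) · (1 − p)` is defined for every gene
(|x| ≥ 1 by construction of the signed ratio; x = 1 at exact equality gives
WIR = 0). WPR is the arithmetic mean of WIR over a pathway's quantified
members; unquantified members are counted and reported, never imputed, and a
pathway with none gives an undefined (NaN) WPR. Gene sets come from
user-supplied GMT files — no pathway database is bundled (versions drift and
licenses vary).

## Predictions

Manipulation predictions are direction-only: synergistic partners follow the
GMR's direction, antagonistic partners oppose it; partners below their
significance cutoff get no prediction. No magnitude model exists for these
shifts, and the output headers carry the caveat that the predictions are
theoretical. The restoring direction for a GMR is read from its own
regulation record (up if significantly down in the nodule, down if up);
an unregulated GMR defaults to knockdown, configurable. Pathway crossing
ranks by coordinated-member count with coordinated-fraction and name
tie-breaks; no enrichment p-value is computed since none is defined for
this statistic.

## Synthetic data

The generator's defaults are the study conditions the tests run at: 500
genes, 4 replicas, one normal group plus three nodules, spot counts drawn
from a distribution concentrated at 1 with a tail to 11, log-normal
baselines (log2 sd 2.0, giving the hundreds-vs-units spread of real
normalized arrays), background replicate CV 20%, and per nodule one hub at
CV 1% with 100 partners at target |COR| 0.97, a quarter of them
antagonistic. Planted fold-changes default to ±4× in 25 genes per nodule.

Coordination is induced by one per-replica latent factor per hub: gene *i*
loads `±√(target) · σᵢ` on it, so every hub-partner and partner-partner pair
has population correlation equal to the target. The latent draw is
standardized to sample mean 0 and variance 1 across the replicas: with as
few as four replicas, an unstandardized draw moves every realized
correlation in the group up or down together, defeating the calibration the
planted-recovery checks rely on. Hub and partner genes are assigned exactly
one spot: the pooled COR denominator attenuates (or, conversely, the
spot-summed numerator can inflate) correlations for multi-spot genes, so
single-spot planting keeps the realized |COR| at the target while background
genes still exercise the multi-spot pooling in AVE, REV and the Bonferroni
correction. Spot effects are multiplicative, replicate-independent and
centered within each gene; they displace neither per-spot CVs nor replicate
correlations.

What the generator does **not** emulate: spatial array artifacts, dye bias,
intensity-dependent variance, missing spots, and correlated background
structure (real transcriptomes have pervasive co-expression; the background
here is independent). Passing recovery tests therefore demonstrates that the
statistics identify the planted structure under the model's own assumptions,
not that they would rank genes identically on a real tumor profile.

## Problem sizes and numerical choices

Tests and the acceptance checks run at 500–2,000 genes with the full COR
matrix materialized — large enough for ≥ 2,000 independent pairs in null
calibrations and for the planted-hub geometry (100 partners in 500 genes),
small enough to keep the whole suite near ten seconds. Recovery claims use
20 fixed seeds. Floating-point equality in oracle tests is 1e-10 relative;
COR clamping bounds overshoot at ~1e-15. All ranking tie-breaks are
deterministic; no stage consumes randomness outside the generator.

## Known limitations

* The pooled COR of multi-spot gene pairs is implemented exactly as defined,
  including its unbounded-then-clamped behavior; an alternative (averaging
  per-spot-pair Pearson coefficients) would be bounded but is a different
  statistic and is not provided.
* The "independent expression" call is a placeholder band, not a test.
* GCH magnitudes depend on the gene universe through ⟨REV⟩ and the
  coordination mean; scores from differently filtered datasets are not
  directly comparable.
* Predictions are qualitative; no post-perturbation expression values are
  simulated.
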