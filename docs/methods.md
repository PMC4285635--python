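# Methods

## Quantification model

Each gene's standard curve is an ordinary least-squares line
`Cq = intercept + slope·log₁₀(quantity)` fit to a serially diluted plasmid
series (≥3 points). Amplification efficiency is `10^(−1/slope) − 1`
(perfect doubling: slope −3.32, efficiency 1.0); values outside (0, 1.2]
raise a quality warning. Duplicate wells are averaged on the Cq scale
before back-transformation — the conventional choice; averaging quantities
instead would weight the lower Cq more. Quantities are relative (plasmid
copy scale); no inter-plate calibrator is modelled. A duplicate spread
above 1 cycle is a recorded warning, not an error.

Normalization subtracts, per sample, the arithmetic mean of the log₂
values of the housekeeping genes. This equals the log₂ geometric mean of
their linear quantities, so the "geometric mean on linear scale" and
"mean of logs" readings coincide — there is no ambiguity in the
implemented definition. Normalization is idempotent by construction (a
guard rejects double application), and within-sample differences of two
target genes are invariant to it. That invariance is what lets the ratio
screen operate on un-normalized data: a common per-sample offset — whether
the normalization factor or an RNA-loading artifact that shifts all of a
sample's Cq values equally (given a shared curve slope) — cancels in every
ratio.

## Day grouping

Replication thins near the terminal molt, so days 11–12 and 13–14 are
combined into groups labelled by their midpoints (11.5, 13.5) and days
15–16 are excluded (beyond the median stage duration). Combined-group
statistics are computed over the union of the member days' samples, not as
a mean of per-day means: the groups exist precisely because per-day n is
unbalanced (2+1), and pooling keeps n = 3 per group. Range fold changes
use day-group means as the "observed values" — daily aggregates, not
individual replicates — which matches how the profiles are summarized;
using raw replicates would systematically inflate ranges by noise.

## PCA and periodization

PCA is computed by eigendecomposition of the gene-wise covariance of the
mean-centered normalized matrix. Genes are centered but not scaled to unit
variance: all genes live on the same log₂ scale and the loadings should
reflect response magnitude. (`run_pca` is deterministic; the sign of each
eigenvector is fixed by making its largest-magnitude loading positive.)
Variance fractions are reported over all components and sum to 1.

Daily mean (PC1, PC2) scores are segmented into `k = 3` contiguous periods
by exhaustively scoring all C(D−1, k−1) two-breakpoint partitions of the
ordered day groups and minimizing the total within-segment sum of squared
Euclidean distances to segment centroids. Exhaustive search is exact and
cheap at this scale (D ≤ 14), needs no seed, and — unlike unconstrained
clustering — cannot produce temporally interleaved periods. Ties break
toward the earliest breakpoints, so degenerate (e.g. constant) inputs give
a deterministic (1, 1, rest) split. Labels are positional: the leftmost
segment is always `early`.

## Ratio screen

For every unordered pair of target genes (housekeeping genes never enter),
per-sample log₂ ratios are contrasted between the early period (day groups
1–5; 15 samples under the default design) and the late period (groups 10,
11.5, 13.5; 9 samples) with a pooled-variance Student's *t*
(df = n₁+n₂−2). Pairs are reported in the orientation that puts the
late-high gene in the numerator and ranked by descending *t* (equivalent
to |t| over unordered pairs). p-values are two-sided — conservative given
the directional ranking — and compared against the Bonferroni cutoff
α/66. A pair with zero pooled variance but nonzero separation is reported
with the sentinel t = ∞, p = 0 and a degeneracy flag rather than an error.
No FDR alternative or permutation null is offered; family-wise control
over exactly the 66 candidate ratios is the procedure being modelled.

## Two-group tests and concordance

The pooled-variance *t* CDF is evaluated through the regularized
incomplete beta function, `p = I_{df/(df+t²)}(df/2, ½)`, exact for odd and
even df alike; the suite cross-checks it against an independent reference
implementation and verifies null-uniformity by Kolmogorov–Smirnov on 10⁴
simulated datasets. Pre/post-apolysis contrasts are filtered at a nominal
p < 0.05 with no multiplicity correction — twelve pre-selected candidate
genes are screened individually, and that choice is reported rather than
hidden. Cross-platform concordance is the Pearson correlation of per-gene
log₂ fold changes (day 3 vs day 10) between RNA-seq and qPCR; its p-value
uses the t transform `t = r·√((n−2)/(1−r²))`. The packaged table stores
the published two-decimal values and is consumed as data; the RNA-seq
column is never recomputed.

## Synthetic cohort generator

The generator emulates the study design: for each sampling day (defaults:
days 1–10 plus combined-day groups represented as pseudo-days 11.5 and
13.5, giving the 36 analyzed samples), three pools of three freshly drawn
individuals are formed (sampling is destructive; individuals never
recur). Each individual receives an apolysis day ~ Normal(8, 2) truncated
at zero — apolysis is first seen around day 6 and its prevalence rises
non-monotonically, so a 2-day spread is the realistic scale of
developmental asynchrony. Pool values average the members on the *linear*
scale and re-log: homogenized tissue mixes RNA mass additively. Pool
molt-phase labels follow the member majority (≥2 of 3). Noise is additive
Gaussian on the log₂ scale per individual and gene (lognormal in linear
units), the standard model for qPCR-scale biological scatter.

Trajectories are smooth archetypes: logistic ramps (`increasing`,
`decreasing`; width = days spanning ~76% of the transition), Gaussian
bumps (`u_shaped`, `inverted_u`; width = sd), a `surge` (Gaussian descent
into a trough 2 days before the breakpoint, depth 2.5 log₂, then a steep
logistic rise of the full amplitude from the trough), a `spike_then_rise`
(transient day-6 Gaussian spike at 0.6× amplitude plus a late ramp), and
`flat`. Genes flagged `phase_locked` (EcR, Fem-1) are evaluated at
`day − (apolysis_day − mean)`: their expression rides molt progress, not
calendar age, so replicate variance grows with asynchrony — the suite
verifies this monotonically.

`default_paper_profiles()` encodes the twelve observed trajectories.
Amplitudes are fixed by each gene's observed min-to-max range fold change
(e.g. ELOV log₂30, FTZ-F1 log₂32, Torso-like log₂1024.2). Timing and
steepness encode the qualitative record: the lipid genes peak early and
lose most of their expression by day 10 (logistic centered day 6, widths
4–4.5, matching ELOV's −4.7 log₂ day-3→10 drop); HR78/ERR/HR3/HR38a
change steadily across the series (center 7, width 6); Vtg's rise is
late-loaded (center 11.5) because its day-3→10 change is tiny relative to
its ~600× range; Torso-like declines ~6-fold into a day-6.5 trough and
then jumps ~768-fold between days 7 and 10; HR38b and FTZ-F1 are U-shaped
with mid-cycle minima (6.5 and 6); EcR's weak inverted-U peaks at day 9,
so its expression also rises across apolysis. Per-gene noise is a base
level (default 0.5 log₂ units) times a scatter multiplier (lipid genes
3.5×, steady decliners 3×, moderate risers and phase-locked genes 1.5×,
Torso-like and the U-genes 1×), reflecting the strongly unequal replicate
ribbons of the measured profiles.

Two built-in features make `(Torso-like, HR38b)` the planted best
discriminator, as the ground truth declares: Torso-like's pre-surge
decline parallels HR38b's descent into its minimum, so their ratio is
nearly constant through the early period, and both genes are among the
least noisy. The wide-swing alternatives (ELOV, FABP, HR78) pay for their
larger early-to-late separation with proportionally larger replicate
scatter and within-period drift. Under the defaults the planted pair
ranks first in ≈99% of seeded cohorts, the recovered periods match
early {1–5} / middle {6–9} / late {10–14} within one boundary in ~100%,
and PC1's daily score is strongly rank-correlated with day
(mean |ρ| ≈ 0.85).

`simulate_phase_pools` emulates the companion known-phase design: animals
sampled on days 8/10 are staged individually and pooled only with
same-phase animals (3 pre- and 4 post-apolysis pools), removing the
phase/day confound that majority-labelled calendar pools carry.

**What the generator does not emulate.** Technical plate effects,
efficiency differences between genes, censoring of animals that die or
molt before sampling, diapause-track physiology, inter-gene biological
correlation beyond shared apolysis timing, and count noise at very low
copy number. Passing recovery tests therefore demonstrates that the
pipeline's inference machinery is correct under the declared statistical
structure — not that real cohorts will match any particular recovery
rate.

## Problem sizes and numerics

Simulation-based tests use the study-scale design (36 samples × 16 genes)
over 15–100 seeds; segmentation is verified against an independent
exhaustive enumerator for all series lengths up to 14; t-test calibration
uses 10⁴ null draws. Reconstruction and conservation checks use 10⁻⁹
absolute tolerances; normalization-invariance of the screen is exact to
10⁻¹². All randomness flows through `numpy.random.default_rng` seeds;
fixed seeds give byte-identical pipeline outputs.

## Known limitations

Median stage duration uses completed molt-to-molt intervals only; daily
observation makes durations interval-censored by ±1 day and right-censored
animals are ignored. The screen's Student's *t* assumes equal period
variances (Welch is deliberately not offered, to model the stated
procedure). Range fold changes depend on the day-grouping choice through
the group means. The CLI's `simulate` truth sidecar is a flat key-value
text file, not a schema.
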