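# Methods

This note documents the statistical procedures saspkit implements, the
assumptions behind them, the defaults and why, and what the synthetic-data
generators do and do not emulate.

## Plate normalization (plate_stats)

**B-score.** Each plate layout (rows × columns) is decomposed by two-way
median polish into `value = overall + row effect + column effect + residual`
(alternating row/column median sweeps, rows first, until the change in the
total absolute residual is ≤ 1e-6 or 100 iterations). The polish is fitted on
sample wells only; control wells sit at fixed positions and would otherwise
bias the positional estimates, so they are scored through the fitted effects
(an entirely unobserved row or column — e.g. a dedicated control column —
gets effect 0, the neutral value of the median-centred estimates). The
B-score is `b = residual / (1.4826 × MAD of the plate's sample-well
residuals)`; 1.4826 is the normal-consistency constant of the MAD.

A calibration caveat, measured here and reproducible with R's
`medpolish` + `mad`: median-polish residuals are leptokurtic (the sweeps pin
the central values of each row/column near zero), so the MAD underestimates
the tail scale and the null fraction of wells with `b ≤ −2` is ≈ 6.3%, not
the 2.28% a standard normal would give. B-score cutoffs are therefore
conventional screening thresholds, not calibrated tail probabilities. The
acceptance checks report this tail as measured.

**NPI.** Normalized percent inhibition rescales a well affinely between the
plate's own control means: `npi(x) = (x − pos_mean) / (neg_mean − pos_mean)`,
so scramble-like wells score 1 and fully inhibited wells 0. The secondary
screen's `NPI < 0.8` rule therefore reads "at least 20% of the control
inhibition"; it is applied to the mean of the three replicate NPIs.

## Hit calling and triage (screen_calls)

Primary hits require the replicate-consensus rule on both cytokine readouts:
`b ≤ −2` (down) or `b ≥ +2` (up) in at least 2 of 3 replicates for both IL-8
and IL-6. The symmetric ±2 default follows the ±2 SD scramble band; the
published legend's asymmetric wording (down < −2, up > 3) is preserved as an
`as_printed` mode because the two readings cannot be reconciled from the
text alone.

Secondary validation compares each siRNA's three replicate NPIs with all
scramble NPIs by a two-sided pooled-variance (Student) t-test (Welch
optional); an siRNA qualifies on a readout iff mean NPI < 0.8 and p ≤ 0.05,
and a gene validates when ≥ 2 sibling siRNAs qualify on both readouts. Raw p
is used, as in the screen; a BH-adjusted mode exists. Note the test's
type-I rate is exactly 0.05 only marginally over scramble draws — with a
single shared scramble set the conditional rate varies widely, which is why
the calibration checks simulate per-plate scramble sets.

Phenotype triage clusters the SASP-repressing siRNAs on their per-replicate
p16/p21/BrdU B-scores with K-means (k = 4, k-means++, 10 restarts, best by
within-cluster sum of squares, seeded). Centroids are labelled against the
scramble reference with a margin of 2 B-score units, precedence
reverted > exacerbated > SASP-only: arrest-reverted (BrdU up and p16 or p21
down), arrest-exacerbated (p21 up), SASP-only (all three markers within the
margin — the cluster of interest), otherwise "other".

## Splicing (splicing)

PSI for a cassette exon averages the two inclusion junctions before
normalizing: `I = (inc1 + inc2)/2`, `PSI = I/(I + skip)` — a cassette exon
contributes two inclusion junctions but only one skipping junction, and the
averaging removes that asymmetry. PSI from RT-PCR fragment concentrations is
`c_long / (c_long + c_short)`.

Differential splicing pools replicate counts within each condition and runs
a two-sided Fisher exact test on the 2×2 table `[round(I), skip] ×
[condition A, B]` (inclusion rounded half-up). This is a deliberate,
self-contained substitute for a likelihood-ratio splicing engine: the
scientific content carried here is the cutoff logic, not the test engine.
Events are classed by `ΔPSI = Ψ(knockdown) − Ψ(control)`: repressed if
ΔPSI ≥ 0.2 and BH FDR < 0.05 (inclusion rises when the repressor falls),
enhanced if ΔPSI ≤ −0.2 at the same FDR, else unchanged. Shortlisting is
two-tier: events also regulated in the reference (senescence) contrast pass
at the base 0.2 cutoff (tier 1); events regulated only in the knockdown
contrast must pass a stricter cutoff, default 0.3 (tier 2; the stricter
value is configurable since only its existence, not its value, is fixed).

The inclusion/skipping direction summary uses a one-sided Pearson chi-square
test against 0.5: `chi2 = Σ(obs − n/2)²/(n/2)`, one-sided p = half the
chi-square(1) tail when the observed proportion exceeds 0.5, else one minus
that half.

## Motif maps (rna_map)

PWMs are column-stochastic over the DNA alphabet (RNA input is canonicalized
U→T); scoring is log2-odds against the background after pseudocount mixing
`q = (p + pc)/(1 + 4pc)`. Occurrence p-values are exact tail probabilities
of the word-score distribution under the background model, computed by
dynamic programming over a discretized score distribution: for widths ≤ 10
the discretization is a 2^-40 integer lattice whose state space is the set
of achievable score sums (≤ 4^w), making p exact to ~1e-12; wider matrices
use an adaptively refined binned DP (bin count doubled until the survival
function is stable to 1e-8). Scanning is sense-strand only — RNA-binding
motifs have no reverse-complement site — and N positions are skipped.

Occurrences are anchored to the alternative exon's splice sites in
transcript orientation (minus-strand coordinates are reflected): offset 0 at
the 3′ splice site is the first exonic base, negative offsets run into the
upstream intron. Default extents: 300 nt of upstream intron, 50 nt into the
exon, and the mirror image at the 5′ splice site. The RNA map reports, per
response group, the per-position fraction of exons with ≥ 1 overlapping
occurrence, and per 31-nt moving window (step 1 nt, offset = window center)
a Fisher exact test on exons-with versus exons-without an occurrence in the
window, regulated group versus unchanged group, one-sided for enrichment
(two-sided available). The exon — not the occurrence count — is the sampling
unit. Raw window p-values are the headline statistic; BH adjustment across
windows is available but off by default.

The shipped CU-rich example matrix (consensus TCTTTCTT) is a synthetic
stand-in mimicking pyrimidine-rich PTBP1-type sites, not a published matrix.
It is 8 nt wide because a 6-nt motif's single best word already has exact
p = 4⁻⁶ ≈ 2.4e-4 under a uniform background, above the conventional 1e-4
scan threshold.

## Enrichment (enrichment)

BH FDR is the standard step-up procedure (statsmodels backend, domain
checks added). Preranked GSEA: genes sorted by score descending (stable
gene-id tiebreak); walking the list, set members add
`|score|^w / Σ_set |score|^w` (w = 1 by default; w = 0 gives the unweighted
KS statistic) and non-members subtract `1/(N − k)`; ES is the signed maximum
deviation. The null is gene-label permutation: random same-size sets,
`n_perm` draws (the null depends only on set size, so draws are shared
between equal-size sets — a pure efficiency measure that leaves the
distribution unchanged). NES divides ES by the mean |null ES| of matching
sign; nominal p is the same-sign null tail with a +1 continuity correction;
FDR q compares each observed NES against the pooled per-set-normalized null
NES, sign-stratified, clipped to (0, 1]. All-zero hit weights fall back to
equal weights.

## Cross-tissue analysis (cross_tissue)

Genes are kept when their CPM summed over all samples is strictly above 10.
Quantile normalization is rank-based with the tie rule "tied values receive
the mean of the reference values their ranks span"; it is idempotent and
makes sorted columns exactly equal. Samples are dichotomized either at the
mean of a regulator's expression (boundary sample labelled high) or at the
valley of a bimodal PSI distribution: a Gaussian KDE (Silverman bandwidth,
512-point grid on [0, 1]) whose minimum between the two highest local maxima
is the cutoff; maxima below 5% of the top peak are treated as tail ripples
of the estimate rather than modes, and a unimodal estimate raises an error
so the caller can fall back to a fixed cutoff. Because the downstream
question is oriented by exon *skipping*, the PSI dichotomy is inverted
(high = low inclusion) before ranking. Genes are ranked by the ordinary
two-sample pooled-variance t-statistic (high − low); no empirical-Bayes
variance moderation is applied, a deliberate simplification — on the
synthetic data the downstream enrichment is insensitive to it. Genes whose
pooled standard error is ≤ 1e-9 relative to the group means (exact-tie
artifacts of quantile normalization) get t = 0 with a flag.

## Synthetic data (synthetic_data)

*Screen*: 96-well plates, 88 sample wells, column 12 holds 4 scramble and 4
positive-control wells; well value = baseline (50) + per-plate/replicate row
and column artifacts (SD 0.5) + gene effect × noise SD (sample wells only;
positive controls carry −6 SD on IL-8/IL-6) + N(0, 1) noise. Effects are
specified per gene in noise-SD units. What it does not emulate: spatial
gradients beyond additive row/column terms, batch drift between replicates,
cell-count covariates.

*Splicing*: per event, true control PSI uniform with a 0.05 margin;
repressed events gain +ΔPSI (default 0.3) on knockdown, enhanced lose it;
junction counts inc1, inc2 ~ Binomial(coverage, PSI) and skip ~
Binomial(coverage, 1 − PSI), matching the estimator's two-inclusion/one-skip
structure. Flanks are i.i.d. uniform ACGT; repressed events carry one
embedded motif instance uniformly placed in [−60, −20) before the 3′ splice
site. Not emulated: read-level noise, overdispersed junction capture, motif
avoidance in unchanged exons, realistic base composition.

*Tissue*: half the samples are regulator-high (log2 modes 6 vs 9, SD 0.3);
PSI is drawn from the low-inclusion mode (0.2, SD 0.05) in regulator-high
samples and the high mode (0.8) otherwise — anti-correlation by
construction. The planted 30-gene set is up-shifted 1 log2 unit in
high-skipping samples. Counts are negative-binomial (Gamma-Poisson,
dispersion 0.1 ≈ biological CV 0.3) around log-normal baselines with ±10%
library-size factors; the default 4,000-gene universe keeps the planted set
below 1% of genes, the compositional regime of a real hallmark set in a
genome-wide matrix (pure Poisson counts or a small universe produce
unrealistically extreme t-statistics and quantile-normalization
compositional artifacts). Not emulated: tissue-type structure, covariates
(age, batch), correlated co-expression modules.

Passing tests on these generators show the estimators and decision rules
recover known planted structure under the stated noise families; they do
not certify behaviour under real-data pathologies (spatial plate effects,
junction mapping bias, expression covariance).

## Problem sizes in the checks

The test suite and `scripts/acceptance.py` use: 100 plates for the polish
oracle, 50 plates for the B-score null tail, a 1,000-gene screen with 30
planted hits plus a 100,000-siRNA null screen, 10,000 null siRNAs for the
t-test calibration, 2,000 events per splicing calibration, exhaustive 4^w
enumeration for widths 3–6, a 400-event RNA map, 20 seeds × (1 planted + 50
decoy sets) × 1,000 permutations for GSEA, and 100 seeds × 2,000 draws for
the density valley. These sizes give sampling error comfortably inside each
asserted band.
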