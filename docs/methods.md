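# Methods

## The measurement model

Each array hybridizes Cy3-labelled cDNA from one culture against
Cy5-labelled genomic DNA. Because every gene is present in the genomic
reference at (essentially) one copy, the reference channel's expectation for
a gene is the same on every array, so the normalized log-ratio
`Mg = log2(cDNA/gDNA)` is proportional to the log transcript abundance and
is comparable across arrays without a between-array normalization step.
Differential transcription is the contrast `Mc = mean Mg(mutant) − mean
Mg(wild type)`; the sign convention is mutant minus wild type, so a gene
transcribed more strongly in a mutant has positive Mc.

## Normalization

Per array, in a fixed order:

1. `M = log2(fg_cdna/fg_gdna)`, `A = ½·log2(fg_cdna·fg_gdna)`. The default
   background policy is **none** (no subtraction): subtraction inflates
   missing values at low intensity; a `subtract` mode with floor ε = 0.5 is
   available. Spots with a non-positive operand become missing and are kept
   as missing downstream, never dropped.
2. **Print-tip correction**: within each print-tip block, subtract the
   weighted median of M (smallest value whose cumulative normalized weight
   reaches 0.5 over value-sorted spots; the lower value is taken at an
   exact 0.5 tie). This removes pin-specific offsets exactly: the weighted
   median of the corrected block is 0 to machine precision.
3. **Global loess**: subtract a weighted local-linear loess fit of M on A
   (tricube kernel over the nearest `span·n` points, default span 0.3,
   3 bisquare robustifying iterations). The smoother is written here
   because the usual lowess implementations accept no prior observation
   weights; at unit weights it agrees with statsmodels' lowess to ~0.01 and
   for large arrays it is evaluated on a 200-point quantile grid with
   linear interpolation (the standard delta shortcut).

The order is fixed — tip correction before loess — so the *final* Mg no
longer has exactly zero per-tip medians: the loess subtraction perturbs them
by a small amount (the per-tip medians of the tip-corrected intermediate,
which `normalize_array` records, are exactly zero). Normalization is
strictly per-array; no information crosses arrays.

## Spot and array quality weights

The quantification software attaches Boolean quality indicators to each
spot. An ordered first-match rule table (configuration, since indicator
sets differ between scanners) maps indicator combinations to a flag, best
quality = 1.00. Weights are then estimated from replicate reproducibility:
for each physical spot position, the variance of Mg across the replicate
arrays of a strain is computed; every spot inherits its position's
within-strain variance; variances are grouped by flag (pooling across
strains by simple averaging) and

    weight(flag) = 1 / mean variance(flag),  normalized so max weight = 1.

Flag groups with fewer than 30 spots inherit the default flag's weight.
This estimator attributes a position's replicate variance to the flag of the
spots at that position, which is unbiased when flags are positional
(print-run artefacts) and conservative when flags vary from hybridization to
hybridization — in the latter case the group means share a common
contamination term and the weight *ratios* are compressed toward 1.

Array weights use a simplified iterative moment scheme rather than a full
REML fit: given current variance factors γ_j, genewise strain means are
fitted with weights `spot_weight/γ_j`, each array's γ_j is re-estimated as
the leverage-corrected mean of standardized squared residuals on that
array, and the loop runs to a 1e-6 fixed point (max 50 iterations, last
iterate returned with `converged=False` if exhausted). The array weight is
1/γ_j, mean-normalized to 1.

## Genewise linear model and moderated t

Per gene, Mg is regressed on strain indicators by generalized least
squares. Observation variances are proportional to
1/(spot weight × array weight) and the two duplicate spots of a gene on one
array share an exchangeable correlation ρ. ρ is estimated by computing,
per gene, the Pearson correlation across arrays between the two duplicates'
residuals (strain-and-duplicate means removed) and pooling the genewise
values by a 15%-trimmed mean on the Fisher-z scale. Estimates are invariant
to a common rescaling of the weights. Residual df = n_obs − n_strains; a
contrast is reported missing when either strain has fewer than two
informative arrays for that gene.

Genewise variances s² are shrunk toward a prior: (d0, s0²) are estimated by
moment matching on log s² (digamma/trigamma equations, trigamma inverse by
Newton iteration); a non-positive moment estimate yields d0 = +∞ (complete
pooling). The posterior variance is s̃² = (d0·s0² + df·s²)/(d0 + df), the
moderated statistic t̃ = Mc/(u·s̃) (u the unscaled standard error) is
referred to a t distribution with d0 + df degrees of freedom (normal when
d0 = ∞), two-sided, and p-values are Benjamini–Hochberg adjusted per
contrast. With correct weights the weighted residual variances are nearly
exchangeable across genes, so on the default synthetic data the moment
estimate typically returns d0 = ∞; the d0 = 0 and d0 = ∞ limits are exposed
for forcing in analyses and tests.

## Rank products and pfp

For a contrast, all K = nB×nA pairwise differences of duplicate-averaged Mg
between mutant and wild-type replicates are formed; genes are ranked within
each column (rank 1 = most up-regulated for RP_up, most down-regulated for
RP_down, ties averaged) and RP is the geometric mean rank over the observed
columns. `estimate_pfp` calibrates RP against the classical null in which
each column's ranks are an independent uniform permutation of 1..G, with
add-one smoothing: p(g) = (#null ≤ RP(g) + 1)/(G·n_perm + 1) and
pfp(g) = p(g)·G/rank(g).

**Design note.** With the all-pairs unpaired construction the K columns are
built from only nA + nB arrays and are strongly dependent, so the
independent-rank null substantially understates the spread of null rank
products: on the default simulation ~9% of truly null genes reach
pfp < 0.05 and the combined decision rule loses false-discovery control.
The pipeline therefore defaults to a **sample-label permutation null**
(`rank_product_analysis(..., null="label")`): each permutation re-assigns
the strain labels among the contrast's arrays, rebuilds the fold-change
matrix and recomputes both directions' rank products (pooled, as the label
null is direction-symmetric). This preserves the column dependence and
restores calibration; the classical independent null remains available as
`null="rank"` and is what `estimate_pfp` implements. n_perm defaults to
1000 and the seed is mandatory in the CLI.

## Combined significance and summaries

SS(gene, contrast) = (FDR p < α) OR (pfp < α AND raw p < α), α = 0.05,
where pfp is the direction matching the sign of Mc. The rule is monotone in
all three inputs. Summaries report per-contrast counts, union,
intersection, and how many intersection genes agree in Mc sign across the
two mutant contrasts. Gene-set profiles report per-gene and mean Mc per
contrast plus the members passing a relaxed uncorrected p < 0.05 — a
profile-level descriptive criterion only (used for weakly-responding
curated sets such as an antibiotic biosynthesis cluster), never part of the
primary SS rule.

## qPCR and concordance

2^−ΔΔCt with amplification efficiency fixed at 2: technical replicates are
averaged on the Ct scale, ΔCt = Ct(gene) − Ct(reference) per sample (plate
offsets cancel), ΔΔCt is relative to the calibrator sample (wild type by
default; fold = 1 there by construction). Concordance with microarray Mc is
the squared Pearson correlation plus the OLS line of qPCR log2 fold on Mc.

## Regulator classification

`is_lal = has_hth AND has_atp_motif AND length ≥ min_length`, with
min_length defaulting to 700 aa — the published inventory gives no explicit
cutoff, and 700 is the value that separates it cleanly (a 606-aa
motif-bearing protein excluded, a 780-aa regulator included); it is
configurable. The HTH flag defaults to true for LuxR-family inputs (the
family is defined by the HTH); a Walker A scanner (`G-x(4)-GK[ST]`,
configurable regex) is provided for de-novo protein sequences.

## The synthetic-data generator

Defaults emulate the study design: 1000 genes (scaled down from the 7728 on
the real arrays for test-sized runs), duplicate arity 2, 8 print-tip
blocks, 3 strains × 5 biological replicates, and designed effects — 25
up-regulated genes with Mc ~ U[+1, +3] and 13 down-regulated genes with
Mc ~ U[−1.5, −0.5], drawn independently per mutant contrast (so shared
genes always agree in sign, as in the modelled experiment).

* Gene brightness (capture efficiency × base expression, lognormal with
  σ = 0.8 and 1.0 on the natural-log scale around a base intensity of 1000)
  scales **both** channels: with a single-copy genomic reference the
  per-gene abundance offset is a gene-level constant absorbed by every
  contrast, so the generator centres null M at 0, giving normalization
  diagnostics a known target.
* Noise lives on the M (log2) scale — the cDNA channel is gDNA × 2^M — with
  baseline σ0 = 0.25, multiplied per spot by the flag multiplier and by the
  square root of the array's variance factor. Flag model:
  flag 1.00 (p = 0.85, ×1), 0.5 (p = 0.10, ×2), 0.1 (p = 0.05, ×4). Flags
  are drawn **per physical position** and kept across replicate arrays
  (print-run artefacts), which is also the regime in which the Table-style
  per-flag variance estimator is unbiased.
* Duplicate spots of a gene share a gene-by-array latent term:
  spot noise = σ_spot·(√ρ·z_gene,array + √(1−ρ)·ε_spot), giving exactly the
  exchangeable correlation ρ (default 0.6) the duplicate-correlation
  estimator assumes, for every flag combination.
* Dye bias is a smooth cubic in standardized A, coefficients
  (0.2, 0.1, 0, 0.025) — about 1.3 log2 units of total curvature across the
  A range, comparable to typical two-colour MA plots — and per-tip additive
  offsets default to an even spread in [−0.3, +0.3].

What it does **not** emulate: probe-sequence effects and
cross-hybridization, spatial row/column gradients beyond per-tip offsets,
intensity-dependent variance on the raw scale, and missing spots. Passing
recovery tests therefore demonstrates the statistical machinery under the
assumed model, not robustness to every artefact of scanned slides.

A known, deliberate property: the strain effect moves a DE gene's observed
A by Mc/2 in mutant arrays (the log-ratio feeds back into mean intensity),
so the loess step evaluates the dye-bias curve at a shifted abscissa and
attenuates strong effects by roughly dye-slope × Mc/2 (≈ 0.05–0.1 log2
units at the default settings). Real loess-normalized two-colour data share
this behaviour; the gene-set profile recovery tolerance (±0.15) reflects
it.

## Problem sizes and numerical choices

The test suite and examples run the default 1000-gene × 15-array
configuration (a deliberate scale-down of the 7728-gene arrays that keeps
every per-flag group in the hundreds of positions); error-control checks
use 500-gene two-strain nulls over 10 seeds and n_perm = 200–500 for the
permutation pfp. Everything stochastic is seeded: identical config + seed
reproduce every output byte for byte (rerun checks are part of the suite).
Degenerate inputs fail loudly with typed errors: all-missing print-tip
blocks, fewer than 10 points for loess, all-zero weight groups,
out-of-range p-values, mismatched gene universes, unknown strain labels,
inconsistent duplicate counts. Ties: weighted median takes the lower value
at exact 0.5; rank ties get average ranks; BH adjustment caps at 1 and
passes missing values through untouched.
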