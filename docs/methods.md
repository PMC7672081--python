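# Methods

## Model and procedure

The screen asks, for every drug *D* and unordered gene pair (*A*, *B*),
whether cell lines damaged in *both* genes (MM) are more sensitive to *D*
than all other lines. Sensitivity is the natural-log IC50 (ln μM);
replicate measurements from different sites are collapsed by arithmetic
mean on the log scale before any testing. The test statistic is a
two-sample Student's *t* (pooled variance by default; Welch selectable) of
MM versus the pooled WW+WM+MW lines, two-sided. Direction is enforced
separately — the MM mean must be below the pooled non-MM mean — rather
than by a one-sided test, so the reported P keeps its conventional
two-sided meaning. Per drug, the P values of all pairs passing the
group-size filter form one Benjamini–Hochberg batch; the adjusted value is
the Q value. The remaining synergy filter compares the MM maximum with the
WW median.

Assumptions worth stating: ln IC50 is treated as approximately normal
within groups with common variance (the pooled *t*); pairs are tested
marginally, so overlapping pairs are not independent and BH is used in its
plain (positive-dependence-tolerant) form; and the mutation indicator is
binary — zygosity, allele frequency and expression of the variant are not
modelled.

## Damaging-mutation calls

A coding variant is damaging if it is stop-loss or nonsense (LoF), or
missense with SIFT < 0.05 *and* PolyPhen > 0.908; both inequalities are
strict, and a missing predictor score never supports a damaging call
(missing is encoded as missing, never as 0). A gene-level homozygous
deletion is the third damaging category. The per-gene line count is over
*distinct* damaged cell lines — a line hit by an LoF variant, a damaging
missense and a deletion in the same gene counts once — and genes below the
minimum (default 10 lines) are removed before pair enumeration. The
conjunction ("both") reading of the missense rule is the default; a union
("either") option is retained because the two predictors overlap only
partially in practice. The ≥10-line filter is applied to the union
indicator rather than to any single category.

## Group-size and synergy filters

The minimum group size defaults to 5: interaction tables in this
literature report MM groups of exactly five lines, so the sensible reading
of "more than five cell lines" is inclusive; the threshold is
configurable. The MM-max/WW-median filter defaults to requiring
max(MM) < median(WW) — the direction consistent with a *sensitivity*
criterion (even the least-sensitive doubly-mutant line responds better
than the median wild-type line); the opposite direction is selectable as
`mm_max_gt_ww_median` for completeness. The FDR level defaults to
Q < 0.05, matching the conventional significance level used throughout
this kind of analysis. The BH batch is defined as the size-passing pairs
of one drug; pairs failing the size filter receive no Q and can never be
candidates.

## Combined partners and burden

Partners of an anchor gene are pooled from candidate pairs — per drug
(drug-specific) or unioned across a drug cluster (multidrug) — and each
line is relabelled by (anchor status, any-partner status). The combined
grouping uses the same damaging matrix as the screen; no variant is
re-filtered. The burden analysis stratifies anchor-mutated lines by the
number of mutated partners, either exactly or as 0 / 1 / 2+, and reports
stratum means, all pairwise *t* tests with at least two lines per side,
and a one-way ANOVA. A singleton partner set reproduces the pairwise
WW/WM/MW/MM partition exactly (tested). Tissue-restricted reanalysis is a
row filter on the cell-line metadata applied before any operation, not a
separate code path.

## Clustering and enrichment

The gene x drug table is binary membership in ≥1 candidate pair, keeping
only genes that appear at least twice across candidate pairs (an
appearance is counted per pair, so one drug with two partners counts
twice). The drug x tissue table counts MM lines per tissue of origin
(either descriptor level) and is min–max normalised within each drug row;
a constant row maps to 0 by convention (logged). Both tables are clustered
with complete linkage on Euclidean distance of the raw rows (no similarity
transform), via scipy; complete linkage guarantees monotone merge heights,
and scipy's deterministic tie-handling makes dendrograms reproducible.
Tissue enrichment is a chi-squared homogeneity test on the tissue x
{MM, background} count table without continuity correction; expected cells
below 5 trigger a logged warning rather than an error.

## Cohort survival

Patients are classified from MAF-style calls: missense, nonsense,
splice-site and translation-start-site variants are damaging; everything
else (Silent included) is not. Inclusion requires presence in both the
mutation and clinical tables; an exposure filter keeps patients treated
with at least one of a configurable inhibitor list (default: dabrafenib,
sorafenib, trametinib, vemurafenib, selumetinib). Kaplan–Meier medians use
the standard product-limit definition (smallest time with survival ≤ 0.5,
equal to the sample median for odd-sized uncensored samples). Pairwise
contrasts use the log-rank test, with the hazard ratio from a Cox model
refit on the two groups compared. The joint model encodes the mutation
profile as a 4-level factor with WWC as reference, alongside age, sex and
a melanoma-vs-other indicator. Ties use Efron's method (lifelines
default); convergence warnings (e.g. monotone likelihood from a tiny
group) are collected into result flags instead of being swallowed.

## Synthetic data: what it emulates and what it does not

`generate_panel` draws a gene x line Bernoulli mutation matrix
(independent across genes unless a pairwise odds-ratio knob is set), emits
raw variant/CNV records whose classifications and scores *guarantee* the
intended damaging call (plus benign noise rows that never pass the
filter), assigns two-level tissue labels with melanoma/colorectal shares
mirroring a pan-cancer panel, and samples ln IC50 per drug as
Normal(baseline mean 2.5 ln μM, SD 1.0) — a normality choice made because
the screen's *t* test assumes it, not because real dose-response data are
exactly normal. Planted pair effects add a fixed delta to the true MM
lines; a planted combined effect adds a per-partner delta times the
partner burden to anchor-mutated lines. Forced group layouts
(`n_mm`/`n_mw`/`n_wm`) make power conditions exact. Replicate measurements
are emitted as two sites symmetric about the true value, so replicate
averaging is exactly invertible. `generate_cohort` apportions group sizes
deterministically (largest remainder), draws exponential survival with
group hazard ratios about a 27.13-month baseline median, and independent
exponential censoring tuned to the target censoring probability.

Not emulated: mutational signatures, tissue-specific mutation spectra,
gene length effects, drug mechanism, IC50 curve fitting, or correlated
measurement error. Passing tests therefore demonstrate the *statistical
machinery* — error control, recovery, oracle equivalence — under the
stated generative conditions, not biological validity on real panels.

## Problem sizes and numerical choices

The packaged studies use desk-scale versions of the screen: null panels of
21 genes x 120 lines x 3 drugs (200 pairs per drug, 100 replicates),
power panels of 8 genes x 120 lines with a planted −2 shift at SD 0.5 and
10 MM lines (100 replicates), burden panels of 300 lines with −0.5 per
partner (20 replicates), and survival cohorts of 500 patients per arm with
hazard ratio 0.44 and 20% censoring (50 replicates). Degenerate inputs are
explicit errors: a *t* test with zero variance in both samples, an empty
cell-line universe, a drug without measurements, an anchor without
candidate partners, a Cox fit with zero events. Q values are clipped at 1;
BH is computed by statsmodels and cross-checked in the test suite against
a literal step-up enumeration. All randomness flows from a single
`numpy.random.default_rng(seed)` per generator call, so outputs are
bit-reproducible per seed.

## Known limitations

Marginal pair testing ignores the dependence of overlapping pairs; the
screen's FDR guarantee is per drug, not family-wide across drugs. The
combined-partner analysis inherits whichever candidate set the screen
produced and does not propagate its selection uncertainty. The cohort
classifier treats any damaging partner variant as equivalent regardless of
gene or variant effect size. None of the higher-level summaries
(clustering stability, pathway interpretation) are statistically
calibrated here.
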