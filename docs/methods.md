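# Methods

This note documents the statistical procedures `fmtselect` implements, the
generative models behind its synthetic data, the numerical choices that are
genuinely free, and what the test suite does and does not demonstrate.

## Data model

The common currency is a samples × genera matrix of relative abundances
(fractions; rows sum to 1 within 1e-6, renormalization only behind an
explicit flag so silently bad data is never rescaled). Feature-level
(ASV/OTU) tables are converted by per-row division by total reads and
collapsed to genus by summing member features. Genus extraction accepts
both the GreenGenes `g__Genus` dialect and plain six-rank
semicolon-delimited lineages; empty or ambiguous genus fields
(`g__`, "uncultured", …) pool into a reserved `unclassified` column, which
panel matching ignores — a panel is a set of *named* genera. Collapse
conserves each sample's total abundance exactly. TSV (UTF-8, header row,
first column `sample_id`) is the only ingestion format.

## Taxon-panel scoring

A panel score is the plain sum of the panel genera's relative abundances in
a sample; panel members absent from a cohort's vocabulary contribute zero
rather than erroring, because 16S surveys routinely miss low-abundance
genera. Matching is exact after normalization (strip `g__`, case-fold),
avoiding silent dialect mismatches.

The shipped default panel is a curated genus-level list of prevalent,
butyrate-pathway-carrying genera (Anaerostipes, Butyricicoccus,
Butyrivibrio, Coprococcus, Faecalibacterium, Odoribacter, Oscillibacter,
Roseburia, Subdoligranulum). Species-level Eubacterium taxa are excluded:
the genus does not share conserved butyrate production, so a genus-level
score would misattribute it. The panel is a JSON config and fully
user-overridable; none of the package's statistical guarantees depend on
its content.

Association with response maps each patient to the score of the donor
whose material they received and applies a two-sided *equal-variance*
two-sample t-test (Student), with Welch behind a flag. Equal-variance is
the primary test because it is the common library default for this
comparison and keeps the result reproducible against standard tooling.
Degenerate inputs: both groups constant and equal means → t = 0, p = 1;
constant with unequal means → p = 0 with an explicit
`degenerate_variance` flag rather than a silent NaN. Studies are never
pooled by default: response definitions (ΔMayo, PUCAI, …) differ between
trials, so cross-study pooling is a user decision.

## Metabolomics donor ranking

Donors with multiple sampled timepoints are profiled by the arithmetic
mean of each metabolite across their timepoints (missing values excluded
per metabolite; a donor with *no* measurement of a required metabolite is
an error, not a silent NaN). The SCFA score is the unweighted mean of
butyrate, isovalerate and propionate in raw platform units; a z-scored
variant exists behind a flag for platforms whose units differ wildly
across metabolites, but raw means are the primary metric. The bile-acid
conversion ratio is (lithocholate + deoxycholate) / (chenodeoxycholate +
cholate); it is scale-invariant, 0 when no secondary bile acids are
present, +inf when primaries are absent but secondaries are not, and an
error at 0/0. When a metabolite was measured in several chromatography
modes (`name|mode` columns), a preference list picks one mode
deterministically — C-18 negative for lithocholate, so all four bile acids
come from the same mode; otherwise lexicographically first.

Ranking is descending (rank 1 = best) on each metric with ties broken by
donor id, so selection lists are reproducible. The joint-selection cutoff
is ceil(q·n) ranks, inclusive — at q = 0.25 and n = 83 donors, ranks 1–21
qualify — and a donor is selected when inside the cutoff on both metrics.
Ceil was chosen because "top 25 %" with a fractional boundary should not
exclude the boundary rank; selection is monotone in q by construction.

## Power simulation

Signal-to-noise per genus: difference in mean natural-log abundance
between cases and controls, divided by the sample (n−1) standard deviation
of log abundance over all samples. Zeros are handled by a fixed
pseudocount of 1e-6 added before the log; pseudocount, log base and SD
flavor are recorded in every result's provenance because alternative
choices change the statistic. Genera with zero variance are excluded and
reported. |SNR| ties break lexicographically, so top-k sets are total
orders.

Simulated trials draw responders uniformly without replacement from the
cases and non-responders from the controls, with
n_responders = round(n_fmt · response_rate) (ties-to-even). Each genus is
tested with the two-group tie-corrected Kruskal–Wallis H against the
chi-square reference (df = 1) — the rank-test formulation standard
libraries implement; an exact permutation version exists only as a test
oracle. Genera constant across the whole subsample (typically all-zero)
are untestable: they are skipped, reported, excluded from the BH family m,
and can therefore never be "recovered". Benjamini–Hochberg runs within
each replicate over the genera actually tested, and recovery is
|{q < 0.05} ∩ top-k|.

Reproducibility: replicate r of design d uses an RNG sub-stream spawned
from the master seed at key (d, r), so any single replicate can be re-run
in isolation and adding designs or replicates never perturbs earlier ones.
Results carry seed, design, transform constants and a dataset content hash.

## Synthetic data: what it emulates, what it does not

**Case-control tables.** Per-genus baseline log-means are drawn once from
Normal(0, 2.0) — a spread of roughly four natural-log units, matching the
several orders of magnitude spanned by real genus-level gut profiles.
Affected genera receive an additive shift `effect_delta` on the log scale
in case samples; entries are exp(Normal(mean, sigma)), zeroed with
probability `zero_prob`, then renormalized per row (all-zero rows have
their zero mask redrawn). Zero inflation is applied *before*
renormalization so zeros hit the downstream log transform exactly as real
sparse tables do. The lognormal-with-additive-shift form was chosen so a
planted effect is expressed on the same scale the SNR statistic measures.

One consequence is worth stating plainly: because renormalization pins
typical abundances near 1/n_genera while zeros map to log(1e-6), each
zeroed entry sits ~9 log units below the data and zero inflation at 10 %
contributes ~7 to a genus's log-abundance variance. Planted SNR is
therefore capped near 0.5 under the default conditions, and the SNR top-10
recovers on average ~8 of 10 planted genera rather than all of them. The
Kruskal–Wallis recovery pipeline is rank-based and unaffected.

**Metabolomes.** Each donor has a latent SCFA production level and a
latent bile-acid conversion propensity, both lognormal across donors
(log-SD 1 — order-of-magnitude donor-to-donor spread, as observed in real
stool SCFA panels). SCFA observations scale with the first latent,
secondary bile acids with the second, primaries with neither; per-timepoint
observations multiply in lognormal noise (sigma, default 0.3). At sigma = 0
the empirical rankings equal the latent rankings exactly, which anchors
the ranking code's correctness.

**Trial cohorts.** Donor panel abundances are uniform on (0.05, 0.95);
panel and background genus masses are split by Dirichlet weights; patients
start panel-depleted (uniform on (0, 0.3)), mimicking the dysbiotic
baseline. Each patient links to one uniformly chosen donor and responds
with probability expit(logit(p₀) + β·(donor panel − cohort mean)); β = 0
is the calibration null.

None of the generators simulate sequencing reads, strain-level structure,
compositional covariance between specific taxa, or longitudinal dynamics.
Passing tests therefore demonstrate the *statistical machinery* is correct
and calibrated — not that real FMT cohorts satisfy the generative
assumptions.

**RNG discipline.** Every generator takes one seed, split deterministically
into per-stage child streams; identical seeds give byte-identical outputs,
which the CLI determinism tests assert at the file level.

## Problem sizes used by the acceptance script

The acceptance script regenerates each quantity at the scale the package
treats as its reference conditions: 50 replicate case-control datasets
(200+200 samples, 100 genera, 10 planted, shift 2, noise 1, 10 % zeros)
for SNR recovery; a power grid at FMT-arm sizes {10, 30, 100, 200} with 50
replicates per design; 200 null datasets (50+50, 50 genera) for realized
FDR; 500 null cohorts (20 donors, 100 patients) for t-test calibration;
20 metabolome replicates (50 donors, 3 timepoints, sigma 0.3) plus one
83-donor cohort for the quartile selection.

## Known limitations

- Genus-level panels cannot see species- or strain-level function; a donor
  can rank high on butyrate-producer abundance and still produce little
  butyrate. The metabolomics ranking exists precisely because of this gap.
- The Kruskal–Wallis chi-square reference is approximate for very small
  arms (≤ 4 per group); the test suite brackets it against the exact
  permutation null at those sizes.
- The power simulation models discovery at the genus level; finer
  taxonomic levels multiply the testing burden and would need larger arms
  still.
- Ratios with near-zero primary bile acids are numerically legal (+inf)
  but scientifically suspect; inspect such donors' raw chromatograms
  before acting on their rank.
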