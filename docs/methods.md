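# Methods

## Scope and data model

`sigrecover` analyzes studies with three roles: a *naive* group (healthy
baseline), an untreated disease *reference* group, and one or more
*treatment* arms. Inputs are a gene-level count matrix (genes × samples), a
sample-to-group design, and one or more literature gene-signature lists.
The pipeline deliberately starts at gene-level counts: transcript
quantification, alignment and differential-expression inference (e.g.
moderated t-statistics) are out of scope — the recovery and correlation
analysis needs only expression levels and group-mean fold changes.

## Normalization and filtering

Between-sample normalization is trimmed-mean-of-M-values (TMM): for each
sample, per-gene log2 ratios of relative abundance against a reference
column are doubly trimmed (30% per tail on the log-ratios, 5% per tail on
average abundance) and combined by inverse-variance weighting; the
reference column is the sample whose upper-quartile relative abundance is
closest to the mean upper quartile (smallest index on ties, so the result
is invariant to sample relabeling). Factors are rescaled to geometric mean
1. The implementation was cross-checked against the reference Bioconductor
implementation (edgeR `calcNormFactors`/`cpm`) and agrees to < 1e-10 on
random matrices; one test re-runs this check whenever `Rscript` is
available.

Genes are kept iff their TMM-adjusted CPM is ≥ 0.5 in at least 4 samples
(both configurable); factors are then recomputed on the filtered matrix.
logCPM uses a prior count (default 2) scaled to each sample's relative
effective library size:

    logCPM = log2((count + prior_s) / (lib_eff + 2·prior_s) × 1e6)

which is finite everywhere and depth-consistent.

## Group summaries and per-gene metrics

Percent changes of expression are only scale-meaningful on the linear
scale, so group summaries are linear CPM values: by default the
back-transformed group-mean logCPM (a geometric mean, consistent with
averaging in the log domain where the noise is closer to additive); an
arithmetic-mean option exists. For a gene with group means X_naive, X_pain,
X_SCS:

- %C = (X_pain − X_naive)/X_naive × 100
- R_f = (X_pain − X_SCS)/(X_pain − X_naive); undefined when
  X_pain = X_naive (such genes are excluded from recovery denominators and
  counted, so n_input = n_used + n_excluded always reconciles)
- %C_SCS = (X_SCS − X_naive)/X_naive × 100

R_f is invariant under affine maps of all three expressions and %C under
rescaling; both invariances are property-tested.

## Transcriptome summaries and thresholds

Per signature (restricted to symbols present in the filtered universe;
absentees are counted and reported):

- `%C_p`: share of genes with |%C| ≥ `change_min` (default 0.10, i.e. 10%),
  split into up- and down-regulated shares.
- `%R_SCS`: share of *changed* genes whose R_f satisfies the recovery rule.
  Two rules are always computed side by side. `le_one` (R_f ≤ `rf_cut`,
  default 1) treats everything short of overshoot as recovery — including
  genes that moved *away* from baseline (R_f < 0). `unit_interval`
  (0 ≤ R_f ≤ `rf_cut`) requires movement toward, and not past, the
  baseline. The two rules answer different questions; the package reports
  both rather than choosing silently. Note that `le_one` is by construction
  nearly non-discriminative between treatment arms whose per-gene recovery
  is broadly distributed around different means: it only penalizes
  overshoot, so arms that barely move genes score as well as arms that
  restore them. The unit-interval rule is the one that orders arms by
  effectiveness, and it is the one the synthetic-study validation tests
  assert on.
- `%D_n`: share of changed genes with |%C_SCS| ≤ `near_naive_max`
  (default 0.15, inclusive).
- Pearson R (with two-sided t-transform p, df = n − 2) between the
  treatment-vs-reference and naive-vs-reference log2 fold-change profiles
  over all of the signature's expressed genes; `significant` ⇔ p < `alpha`
  (default 0.05). Qualitative strength labels (< 0.2 very weak, < 0.4 weak,
  < 0.6 moderate, < 0.8 strong, else very strong) are cosmetic and never
  gate logic. Raw p-values are reported (matching the descriptive design);
  a Bonferroni-adjusted column is added in the summary table for
  transparency only.

Denominator choice: `%R_SCS` and `%D_n` are shares of the *disease-changed*
genes, not of the whole signature — recovery presupposes displacement.
Marker panels use the opposite boundary convention from %D_n on purpose:
a marker is displayed iff |%C| is *strictly greater* than its threshold
(default 15%), while %D_n's band is inclusive.

Heat maps follow the inverted polarity convention of the source analyses —
blue = up-regulation, red = down-regulation — with a flag to restore the
usual orientation; genes are ordered by the naive-contrast fold change by
default (deterministic), with fixed-linkage hierarchical clustering as an
option.

## Synthetic-study generator

The generator emulates a five-group stimulation study: naive n = 7,
untreated reference n = 10, and three arms n = 9/10/11. Gene-wise baseline
abundances are lognormal (log2 mean 7, sd 1.5), counts are negative
binomial via a gamma–Poisson mixture with a single dispersion (default
0.005), and library sizes are drawn uniformly (default 1.5–2.5 million) so
TMM is non-trivial. Three planted signatures mirror the shape of published
microglial composites: disease-changed fractions 0.38/0.33/0.58 with up
splits 0.49/0.61/0.47, planted effect 1.0 log2FC, and 90% of each
signature's listed symbols present in the simulated universe (the rest are
deliberate absentees that exercise the overlap accounting).

The dispersion default sits at the low (near-isogenic inbred) end of the
bulk RNA-seq range. This is a deliberate property of the emulated
conditions: the analysis uses a *fixed absolute* change threshold (10%),
and a closed-form expectation calculation shows that the per-gene
false-positive rate for that threshold is Φ-tail of
`log2(1.1) / (σ_gene · sqrt(1/n_pain + 1/n_naive))`; with per-sample log2
sd around 0.12 (dispersion 0.005 at typical depth) the noise-induced
changed share stays in the low single digits, so `%C_p` estimates track the
planted fraction. At dispersions typical of outbred biological replicates
(≥ 0.05) the 10%-threshold statistic is dominated by sampling noise at
n ≈ 10 — a property of the statistic itself, not of the implementation.

Treatment arms recover each perturbed gene by a per-gene fraction

    r_g ~ Normal(ρ_arm, recovery_spread · (1 − ρ_arm)),
    treatment log2 mean = pain mean − r_g · (pain mean − naive mean)

with ρ in [0, 1.5] (ρ > 1 models overshoot; ρ = 1 with zero spread returns
genes exactly to baseline). `recovery_spread = 0` gives the homogeneous
limit in which every gene recovers by exactly ρ. The default spread of 1 is
essential, not decorative: with homogeneous recovery and any symmetric
measurement noise, threshold rules at R_f = 1 *cannot* order arms by ρ
(under `le_one` the only failures are overshooters, which high-ρ arms
produce more of; under `unit_interval` the failure probability is minimized
at R_f = 0.5, so a ρ = 0.5 arm always beats a ρ = 0.8 arm). Heterogeneous
per-gene responsiveness — weakly recovering programs leaving many genes
drifting away from baseline (r_g < 0) while strongly recovering programs
act consistently — is what makes recovery shares discriminate arms the way
real studies observe, and the `(1 − ρ)` coupling makes the expected
unit-interval share monotone in ρ (property-tested). Every planted
quantity, including each gene's applied r_g, is stored in the truth record.

What the generator does *not* emulate: gene–gene correlation, gene-wise
dispersion trends, batch effects, sex differences, compositional shifts
beyond the planted effects, and ortholog mismatch between species (symbol
lists are generated in-universe; the ortholog-map hook is exercised with
synthetic mappings). Passing tests therefore validate the pipeline's
arithmetic and its behavior under a clean planted-effect model, not
robustness to those real-data complications.

## Calibration caveat: the shared-reference correlation

The profile-correlation design correlates the treatment-vs-reference with
the naive-vs-reference fold-change vector. Both vectors contain the *same*
reference-group sampling noise, so under a complete null (nothing planted)
their correlation is not centered at zero: it concentrates near

    Var(m_ref) / sqrt((Var(m_naive)+Var(m_ref))(Var(m_treat)+Var(m_ref)))

≈ 0.45 for group sizes 7/10/9–11, independent of the noise scale, and is
declared significant essentially always at n in the hundreds of genes.
This is a structural property of correlating two contrasts that share a
baseline, not an implementation artifact; the test suite contains a
calibration test documenting the nominal expectation (null R centered on 0,
5% significance rate), and it fails by exactly this margin. Observed
correlations should therefore be read against a positive null floor, and
differences *between* arms (which share the same bias) are more
interpretable than any single correlation's significance.

## Numerical and interface choices

- Symbol matching is case-insensitive (trimmed, upper-cased), with an
  optional two-column ortholog-map TSV applied after case folding;
  duplicates collapse to first appearance and are logged.
- Genes appearing in several composites are scored independently in each;
  duplicates across sources within a composite count once in the union.
- Signature genes removed by the expression filter count as "not
  overlapped"; every summary reports its exclusion counts.
- TMM short-circuits to 1.0 when all finite log-ratios are below 1e-6
  (identical or purely depth-scaled columns give exactly 1.0).
- All tabular outputs are TSV with a fixed float format; identical config
  and seed reproduce `recovery_summary.tsv` byte for byte.
- Validation problem sizes: hand oracles run on 6–10-gene fixtures;
  simulation-based checks use 1 200–2 000 genes with 3–20 seeds, chosen as
  the smallest sizes at which Monte-Carlo error is well inside the asserted
  tolerances (±5 percentage points).

## Known limitations

- The 10% / 15% thresholds are absolute and interact with sequencing depth
  and dispersion (see above); they are faithful to the source analysis
  rather than statistically optimal.
- `%R_SCS` under the `le_one` rule admits genes that moved away from
  baseline; treat the side-by-side unit-interval column as the
  effectiveness-ordering statistic.
- No gene-level inferential statistics (no moderated tests, no FDR): the
  pipeline is descriptive by design.
- Correlations are computed on log2 fold changes (display scale); a linear
  fold-change option exists but shares the same shared-reference caveat.
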