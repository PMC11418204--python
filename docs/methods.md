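# Methods

This note documents the models and procedures the package implements, the
conventions chosen where the field leaves room, and what the synthetic
cohort does and does not emulate.

## S/D analysis of taxon-stratified metatranscriptomes

**Input model.** A gene-family abundance table in the joined-profiler
dialect: one row per feature (`FEATURE`) plus optional per-taxon stratum
rows (`FEATURE|g__Genus.s__species`), one numeric column per sample.
Stratum rows must not exceed their feature's total (relative tolerance
1e-6); the unattributed remainder is carried as an explicit
"unclassified" stratum and never redistributed.

**CPM renormalization.** Counts are rescaled per sample so the feature
totals sum to 10⁶; strata are scaled by the same factor, preserving the
taxon decomposition. The operation refuses tables whose units tag is
already `cpm` or `relab` (no silent double normalization).

**Role aggregation.** An annotation table maps features (EC identifiers or
gene-family accessions) to (vitamin, role) with role ∈ {S, D, T}. Roles
follow the colonic-absorption convention: enzymes producing the form
absorbed in the colon count as synthesis — in particular the thiamine
pyrophosphokinase (TPP is the colonically absorbed B1 form) and the
bacterial pantothenate/pyridoxal kinases (host lumenal phosphatases
dephosphorylate their products back to absorbable forms). Transport (T)
records are carried but excluded from both sums by default;
`transport_as_downstream=True` merges them into D. A role's relative
abundance is 100 × ΣCPM/10⁶ — percent of **all** non-host mapped
transcripts, not of B-vitamin transcripts only.

**log2 S/D ratio.** Computed per sample and vitamin. If any sample in the
analysis set has D = 0 for a vitamin, 1 is added to S and D of *every*
sample of that vitamin ("plus one to all values") before the log; the
`pseudocount_applied` flag records this per vitamin. The pseudocount is
applied on the percent scale by default; a `cpm` option rescales first
(the ratio itself is scale-free, only the pseudocount magnitude changes).
S = 0 with D > 0 legitimately yields −∞ on the plain path; 0/0 cannot
occur (D = 0 forces the pseudocount path).

**Group comparison.** Two-sided unpaired t tests (classical, equal
variance) on per-sample ratios, per vitamin; the ratio is computed per
sample and tested across samples because a t test needs within-group
replicates. Family-wise BH adjustment is applied by the caller across the
vitamins of one comparison.

## Metabolome processing

**Detection call.** A metabolite is present in a sample iff its
concentration is reported and strictly positive; present in a group iff
present in ≥ 1 sample of the group.

**Prevalence filter.** Keep metabolite *m* iff some group *g* satisfies
the integer inequality 2·detected(m, g) ≥ n_g (so 2 of 4 passes, 2 of 5
fails). Idempotent by construction.

**Normalization and autoscaling.** Concentration → concentration /
size-factor (cecal weight in g or serum volume in µL) → imputation →
log10 → per-metabolite z-scaling with the sample SD (n−1 denominator).
Missing values surviving the filter are imputed at one-fifth of the
metabolite's minimum observed normalized value — a common metabolomics-
suite default, recorded in the matrix provenance rather than claimed to be
universal. Zero-variance rows are dropped and listed. Log base and
imputation rule are provenance fields so downstream users can audit them.

**Differential ranking.** Per metabolite, z is modeled on the group factor
with a chosen reference level; the overall F (identical to one-way ANOVA
F regardless of coding) gives p, BH-adjusted across metabolites; the top-k
by raw ascending p are returned. An optional empirical-Bayes variant
shrinks residual variances toward a method-of-moments scaled-inverse-χ²
prior (limma-style) and augments the denominator df; it is off by default
because the plain F is exactly reproducible from first principles.

**Ward ordering.** Row order for heatmaps is the dendrogram leaf order of
Ward (D2) agglomerative clustering on Euclidean row distances, via the
standard nearest-neighbor-chain implementation. The order is deterministic
for a given input row order; exact distance ties (measure zero in
continuous data) resolve by the linkage implementation's internal order,
so the guaranteed invariant is cluster-block structure, not leaf order,
under row permutation.

**Set analysis.** Per-colonization detected sets (optionally restricted to
one diet) induce all exclusive intersection regions (UpSet-style); the
exclusive regions partition the union. Microbiota-dependent metabolites
are (SPF ∪ 14SM) \ GF.

## Statistical core

**ROUT outlier exclusion** (univariate, constant model): robust location =
median; robust scale RSDR = 68.27th percentile of absolute residuals ×
n/(n−K) with K = 1 (the small-sample correction); each residual converts
to a two-sided t p-value with df = n−K; the flagged set is the
Benjamini–Hochberg rejection set at rate Q. At Q = 1% the measured
any-flag rate on clean normal samples (n = 10–50) is ≈ 1.4%, and a single
contaminant 8 robust spreads out is caught in ≈ 100% of draws. Zero RSDR
(e.g. all values identical) flags nothing, explicitly. Fewer than 3
finite values is refused. The exact variant is recorded in
`OutlierReport.method_detail`.

**Normality-gated group test**: Shapiro–Wilk per group at α = 0.05 (a
convention; the gate itself is a pure function of the per-group p-values).
If all groups pass, the heteroscedastic ANOVA branch reports Welch's
ANOVA as the decision p with the Brown–Forsythe F* alongside (both from
the textbook formulas; the combined "Brown–Forsythe and Welch" output of
graphical packages is two statistics, not one). Any failing group — or a
zero-variance group, where Shapiro–Wilk is undefined — routes to
Kruskal–Wallis with a logged warning.

**BH adjustment** is the standard step-up (delegated to statsmodels);
**Pearson correlation** uses the t transform for p, returns the (NaN, NaN)
sentinel for zero-variance input, and snaps |r| within 1e-12 of 1 to
exactly ±1 so exact affine dependence reports ±1.

## Vitamin–immune correlation

Vitamin concentrations are log10-transformed (consistent with the
metabolome module); frequencies are used as-is (% of CD45⁺). Groups with
matched per-mouse measurements are joined on sample ID; groups without
them can be *pooled*: both tables are sorted by sample ID within the group
and paired by rank, a labeled, reproducible convention — the output
records the mode per group, and a *strict* mode drops unmatched groups
instead. Cells are BH-adjusted jointly across the matrix; zero-variance
cells carry the NaN sentinel and are never significant.

## Synthetic cohort

The generator emulates the study conditions: group palette diets
{SC1, SC2, IN, FS, FF} × colonization {SPF, 14SM, GF} with n = 4 mice per
group (the metatranscriptome default generates IN/SC2/FF × SPF, the
metabolome default the full published palette, and the correlation design
24 colonized samples).

- **Gene families**: gamma-Poisson counts (dispersion 0.03) around a
  heavy-tailed baseline composition, per-sample depth uniform on
  1–4 × 10⁶. Planted effects: for each chosen vitamin, the D features'
  expected share ×2^δ in fiber-free samples (B2/B3/B7 style) or the S
  features' share ×2^−δ (B9 style), δ = 2 by default, so the expected
  group difference in log2 S/D equals δ. Taxon strata are Dirichlet shares
  over a 5-taxon panel plus "unclassified", with mucin-associated taxa
  up-weighted 3× under fiber deprivation.
- **Metabolome**: log-normal concentrations (σ = 0.35 sample noise around
  a log-normal baseline); B vitamins ×4 in colonized fiber-rich groups,
  ×1 in colonized FF/FS, ×0.5 in GF; 30% of non-vitamin metabolites are
  microbiota-dependent (structurally missing in GF); 10% random detection
  dropout elsewhere. So that the planted detection truth stays exact, the
  generator restores one detection per colonization group for
  non-dependent metabolites (and per colonized diet for dependent ones)
  when dropout would have removed them all — without this, ~1 metabolite
  per cohort would spuriously join the colonized-only set.
- **Immune frequencies**: ten populations (mast cells, NK, Th17, Tregs,
  …) with realistic base means; planted correlations against log10
  vitamin concentrations via a shared latent factor, population =
  base·(1 + 0.25·(Σrᵢzᵢ + √(1−Σrᵢ²)·ε)), clipped to [0.01, 100]. Requests
  with Σr² ≥ 1 on one population are refused as unattainable.

All randomness flows from one integer seed through named substreams of
NumPy's PCG64; identical configs give byte-identical tables.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: compositional coupling between features
(planted effects perturb shares independently), phylogenetic structure in
the taxon panel, batch effects, heteroscedastic or intensity-dependent
missingness in the metabolome (dropout is uniform at random, not
concentration-dependent), correlated immune populations, and any
systematic measurement bias. Recovery rates measured here are therefore
statements about the statistical machinery under a clean generative
model, not about profiler or instrument artifacts.

## Problem sizes and determinism

The statistical checks run at: 200 synthetic cohorts for S/D recovery and
for type-I error (n = 4 per group, the study's group size), 1,000 draws
for ROUT calibration, 1,000 randomized instances for the prevalence and
BH oracles, 100 cohorts at n = 24 for correlation recovery — sizes at
which the binomial noise on a 95% criterion is ≈ 1.5 percentage points.
All tests and the acceptance script are seeded; reruns are bit-identical.

## Known limitations

- The bundled annotation is a small curated demonstration covering all
  eight B vitamins with real EC numbers; a production analysis should
  supply the full curated table via `load_annotation`.
- ROUT here is the univariate constant-model specialization; it does not
  cover regression models.
- The pooled pairing convention for unmatched groups is one defensible
  choice among several; results from pooled groups should be read as
  group-level association, not per-mouse coupling.
- The empirical-Bayes moderation is a simplified method-of-moments fit; it
  is not intended to replicate any specific package's shrinkage exactly.
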