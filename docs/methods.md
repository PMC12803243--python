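# Methods

## Sorted-reporter screen model and simulator

The generator (`simdata.simulate_screen`) models each cell as carrying
one guide; its log2 reporter ratio (stability reporter relative to a
co-translated expression marker) is `r = δ_g + ε`, `ε ~ N(0, σ)`, where
`δ_g` is the knockout's planted effect on reporter stability (δ < 0 =
destabilized reporter → negative stability score) and σ absorbs all
per-cell variability. The reporter quantity is modeled directly as the
log-ratio; construct-expression variation is not simulated separately,
since the marker normalization exists precisely to cancel it.

Sort gates are the 5% and 95% quantiles of the *pooled* population
mixture (a guide-abundance-weighted Normal mixture), as a cytometer
would set them — not per-gene gates. Gate positions are found by
Brent's method on the mixture CDF; per-guide tail probabilities follow
from the Normal tail beyond each gate and are clamped at 1e−12 (with a
warning) so extreme effects cannot underflow the share normalization.
Sequencing counts are negative-binomial (gamma–Poisson,
`var = μ + α μ²`, one dispersion knob `α`, Poisson at α = 0) around the
expected guide share of each fraction. Ground truth (`SimTruth`)
records the exact probabilities and expected contrasts used, so
estimators can be validated against an independent numeric-integration
oracle.

Desk-scale defaults: 1,000 genes × 4 guides, σ = 1, 5% tails,
dispersion 0.05, library skew SD 0.25 (log scale), input depth 500
reads/guide, and sorted-tail coverage of 26 cells/guide — the
per-guide coverage implied by sorting ~2×10⁶ cells per 5% tail over a
77,441-guide genome-wide library. Sorter purity and per-guide cutting
efficiency are not modeled. The planted default (50 destabilizers at
δ = −1.5 among 1,000 genes, three experiments) is the study condition
used throughout the analysis scripts and end-to-end tests.

## Stability score

Guide LFCs use median-of-ratios size factors (computed over guides
nonzero in every sample, rescaled to geometric mean 1, falling back to
total-count scaling below 100 qualifying guides) and a pseudocount of
0.5 on normalized counts. A transparent estimator was chosen over a
moderated negative-binomial GLM deliberately: the gene statistic
averages and then re-normalizes guide LFCs, so shrinkage is
non-essential, and the simple estimator is exactly testable against
brute-force arithmetic. A moderation hook can be added at the
`guide_lfc` boundary without touching downstream code.

The sorting contrast is `(high vs input) − (low vs input)`: the input
is used once as a common reference, which makes the null symmetric.
(The alternative reading — a direct high-vs-low contrast with input
only for QC — differs by a constant under size-factor normalization and
is recoverable from the same guide table.)

Gene scores are mean contrasts over unflagged guides (genes with zero
surviving guides are dropped and logged). Per experiment, scores are
normalized by subtracting the KDE mode (Gaussian kernel, Silverman
bandwidth, 512-point grid spanning [min − 3h, max + 3h]; ties break
toward the smaller grid value) and dividing by the RMS deviation from
that mode. Mode centering is preferred over mean/median centering
because true hits are asymmetric mass in one tail; the mode tracks the
null bulk. Degenerate inputs (< 10 values, or RMSD < 1e−12) are
rejected.

The combined stability score is the mean of per-experiment normalized
scores. P-values default to Stouffer's combination against a standard
normal — justified because the normalized scores are approximately
unit-variance z-scores under the null (verified by simulation: the
null p ≤ 0.05 rate is ~5%). A guide-permutation null (shuffling the
guide→gene map, seeded; empirical p pooled by guide count) is provided
for users who prefer not to rely on normality. BH FDR is reported
alongside, but the triage thresholds consume raw p (p ≤ 0.05), matching
the screen-profile definitions.

## Guide QC

Two policies: an explicit blocklist, and a reference-screen policy in
which each guide of a declared essential gene is ranked by depletion
among essential-gene guides across reference screens (rank percentile,
averaged over screens) and the worst fraction τ (default 0.13, the
removal fraction observed in genome-wide practice for this screen
family) is flagged. The precise criterion used by the original
essential-gene datasets is not public; the rank policy is a stated,
testable approximation, validated by planted-truth recovery (≥ 90% of
deliberately inert guides flagged at τ = 0.10).

## Proximity-proteomics enrichment

Channels (`<bait|control>_rep<k>`) are floor-imputed at each channel's
1st percentile of positive intensities (avoids infinite log-ratios,
preserves rank) and median-centered in log2 to the grand median, which
removes per-channel multiplicative scalings exactly. Enrichment is the
mean over replicates of the paired difference
`log2(bait_r) − log2(control_r)` — pairing removes replicate batch
shifts — with a plain two-sided one-sample t-test (n − 1 df; p = 1 when
all differences are exactly 0; p missing below 2 replicates). With
n = 3 the triage axis is the enrichment threshold, not p, so variance
moderation is left as a hook. Technical duplicate injections are
assumed pre-combined into biological replicates.

## Candidate triage

Gene symbols are harmonized by upper-casing only (alias resolution
would require external tables). CSS per gene is the mean over declared
RAS-dependent lines. Three built-in profiles carry the published-style
cuts: regulator (score ≤ −0.8, p ≤ 0.05, enrichment ≥ 1.0, CSS ≤ −1.0),
ubiquitin (score > 0 and p ≤ 0.05, enrichment ≥ 1.0, CSS ≥ 0.5; the
increased-expression side has no printed score cut, so any positive
score with significant p qualifies), and kinase (score ≤ −0.5,
enrichment ≥ 0.8, CSS < −1.0, no p cut). Genes missing from a table
fail that axis and are recorded, never silently dropped; the optional
universe list (e.g. ubiquitin-related or kinome genes) restricts all
axes first. Venn region counts are exclusive-region counts summing to
the union.

## Half-life estimation

Chase series are normalized per lane to the loading control and to the
t = 0 lane (`y_0 = 1`), then fitted by OLS of `ln y` on `t`; `k =
−slope`, `t½ = ln 2 / k`, SE by the delta method (`se = ln2/k² · se_k`).
Log-linear OLS is exact on the model and carries closed-form
uncertainty; a nonlinear refit adds nothing once y₀ is pinned to 1.
Series with `k ≤ 0` are censored and reported as `t½ >` the chase
window rather than as a huge fitted number — honest within-window
inference for stable lines. Replicate series (n = 2, as in typical
blot quantification) are fitted jointly by stacking points, not by
averaging first. Group contrasts use the ratio of mean half-lives with
a seeded percentile bootstrap over series; censored fits enter as
lower bounds at their window, making the ratio conservative. The
log-OLS estimator's median bias under multiplicative log-normal noise
at CV ≤ 0.2 is below 5% (Monte-Carlo, 1,000 replicates, in the test
suite).

## PLA detection and scoring

The detection chain is this package's defined, testable operator (the
original counting macro is an external ImageJ artifact): inverted
Laplacian-of-Gaussian response at the PSF scale → local maxima with
pairwise separation ≥ 2·σ_psf (a mild robust pre-screen on the
response removes the bulk of noise maxima) → a candidate is kept when
its raw intensity reaches `median(bg) + k·1.4826·MAD(bg)` with
k = 5, background taken outside dilated candidate regions. Because the
threshold is built from the field's own robust background statistics,
detection is invariant to global affine intensity rescaling and
equivariant to translation. Counts are per field; per-cell counting
(nearest-nucleus assignment) is possible on the simulated fields but
per-field matches the stated normalization without requiring
segmentation fidelity.

PLA scores are `100 × count / mean(control counts)`, so the control
mean is 100 by identity. Group comparison versus control uses the
pooled-SD t statistic per condition with family-wise adjusted p from a
seeded max-T permutation of condition labels — a Dunnett-type
many-to-one test that is exactly specifiable, reproducible under seed,
and valid for non-normal counts (the multivariate-t quantile version
is intentionally not the normative path). The permutation null's
family-wise error at α = 0.05 calibrates to [0.02, 0.08] in simulation.

The image simulator renders nuclei/membrane/puncta channels with cells
as non-overlapping disks (dart-throwing with bounded retries), puncta
as 2-D Gaussians at Poisson(λ·n_cells) uniform locations within cells,
and Gaussian background noise. It does not emulate optical
aberrations, illumination gradients, autofluorescence texture, or
z-structure — so passing detection tests demonstrates correctness of
the operator chain on well-posed fields, not robustness to microscopy
artifacts. In the crowded regime (spot spacing below the resolvability
limit) detected counts undercount truth by design; the scoring is
ratio-based, which cancels density-independent undercounting between
conditions only approximately.

## Numerical conventions

- All generators and all stochastic procedures take explicit integer
  seeds (`numpy.random.default_rng`); same config + seed is
  byte-identical.
- Coordinates are 0-based (row, col), origin top-left, matching the
  TIFF raster; multi-page TIFFs are 16-bit with page order puncta,
  nuclei, membrane.
- Problem sizes in the test-suite simulations (desk-scale screens of
  300–1,000 genes, 100–200 Monte-Carlo replicates, 192²–256² pixel
  fields) were chosen as the smallest sizes at which the statistical
  properties under test are stable; full genome-wide scale (77,441
  guides) is supported by the same code paths.

## Known limitations

- The guide-QC reference policy approximates an unpublished criterion;
  only its planted-truth behavior is guaranteed.
- Stouffer p-values lean on the near-normality of mode/RMSD scores;
  heavy planted-hit contamination inflates the RMSD and makes null
  p-values conservative (never anticonservative in our simulations).
- The stability-ratio bootstrap resamples series, not timepoints;
  with very few lines per group the CI is optimistic.
- No alias resolution in gene-symbol harmonization; inputs must share
  nomenclature.
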