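# Methods

This note documents the models and estimators implemented in `somportraits`,
the defaults and why they were chosen, the numerical conventions, and what
the synthetic-data tests do and do not demonstrate.

## Data model and preprocessing

Input is a positive, linear-scale expression matrix E_g,m,r (gene, condition,
replicate) or an already-logged matrix (declared via `scale: log10`). The
chain is: quantile normalization of the sample columns (average-rank tie
dialect — tied values receive the mean of the reference values at their rank
positions, which is deterministic but departs from exact column-multiset
identity in the presence of ties), log10, replicate averaging, and gene
centering. Normalization precedes replicate averaging; both steps are
switchable. Replicate standard deviations use the population (divide-by-R)
form, matching the averaging-bracket convention of the downstream error
model; the LPE curve built from them is therefore biased low by the familiar
factor √((R−1)/R)·c₄(R), which the noise-recovery test accounts for
explicitly.

## SOM

* **Initialization** is deterministic along the two leading unit-norm
  eigenvectors of the M × M covariance of the gene profiles, with the
  coefficient grid spanning [−1, 1]² and the eigenvector sign fixed
  (largest-magnitude component positive) for cross-platform reproducibility.
  Eigenvectors are used unscaled; training adapts the amplitude within the
  first sweeps, and keeping the printed formula literal makes the
  initialization testable against an independent eigendecomposition.
* **Training** is the classical online rule with a Gaussian neighborhood
  exp(−d²/2σ_i²) on grid distance. The learning rate decays linearly
  (default 0.05 → 0.01) and the radius exponentially (K_x/2 → 0.5) over the
  presentation budget (default 250,000 single-gene presentations, not
  epochs). Genes are presented in seeded shuffled cyclic sweeps so
  presentation counts differ by at most one. Updates skip tiles whose
  neighborhood factor is below exp(−16) — a pure speed device with effect
  below double rounding at the retained tiles' scale.
* **Mapping** assigns each gene to the Euclidean-nearest metagene, ties to
  the lowest row-major linear index. Empty miniclusters are legal and are
  masked (white) in every rendered map.

## Portraits

Color is a two-segment linear interpolation blue (0,0,255) → green (0,128,0)
on [min, mean] and green → maroon (128,0,0) on [mean, max], anchored at the
unmasked field's own min/arithmetic-mean/max — hence affine-equivariant and
per-sample self-normalized (a global gallery scale is not implemented; the
per-sample convention matches the portrait idea of showing each sample's own
relief). Fields whose span is below 1e-12 relative render uniformly green.

## Spot detection

Thresholds use the type-1 (inverted CDF) empirical quantile so the "98%"
criterion is a reproducible order statistic; tiles strictly beyond it are
kept, giving ⌈(1−q)K⌉ tiles for a continuous state. Underexpression is the
exact mirror: the negated field thresholded at q, which (unlike taking the
(1−q) quantile of the raw field, from which it differs by one order
statistic) makes over/under selection exactly symmetric under negation.
Components are 8-connected — diagonal tiles read as one blob in the
portraits — and are labeled A, B, C… by decreasing peak magnitude
(lowercase for underexpression), so labeling is deterministic. No minimum
spot size is enforced by default.

## Differential expression

* **WAD** up-weights strongly expressed genes; within a sample the weight is
  a positive affine function of Δe, so on all-nonnegative columns WAD and
  logFC rank identically (a tested invariant).
* **Shrinkage t.** σ²_shr = λσ² + (1−λ)σ²_LPE(e) with λ default 0.5
  (no principled default exists; 0.5 weights the gene-specific and pooled
  error equally and the parameter is exposed). The LPE curve is a centered,
  edge-truncated moving-window mean (default W = 200 genes) over the
  expression-sorted replicate SDs, evaluated by step interpolation — no
  smoothing, so the curve is reproducible to the bit. The default standard
  error is σ_shr/√R_m; `se_mode="exact"` adds the variance of the
  cross-condition mean, ⟨σ²_shr⟩_m/ΣR_m. Conditions with a single replicate
  carry no own variance: they fall back to the pure LPE error with a normal
  p-value; otherwise p is two-sided Student-t with df = R_m − 1 (df is not
  dictated by the model; R_m − 1 is the replicate-variance df). Zero SE is
  resolved by sign: Δe ≠ 0 → p = 0, Δe = 0 → t = 0, p = 1.
* **fdr/Fdr.** ρ̂(p) is the Grenander estimator — slopes of the least
  concave majorant of the p-value ECDF anchored at (0,0) and (1,1). The raw
  Grenander slope is identically 0 beyond the largest observation, so the
  null level is estimated first from the upper tail,
  η₀ = #{p > λ}/(n(1−λ)) with λ = 0.5 (the vanishing-DE assumption: the
  alternative contributes no mass there), and the density is floored at η₀.
  This yields fdr(1) = 1 identically. Fdr uses the unfloored majorant CDF,
  so Fdr(1) = η₀ and Fdr(0) = fdr(0) hold exactly, and concavity of the
  majorant gives Fdr(p) ≤ fdr(p) everywhere. The small inconsistency
  (density floored, CDF not) is the price of an η₀ read at the boundary;
  it affects only the region where ρ̂ < η₀, i.e. beyond the last data point.
* **Ranking** is by descending score magnitude with lexicographic gene-id
  tie-break; rank products use average ranks and the geometric mean over
  samples (the standard definition; details of the original's variant were
  not recoverable, so the standard form is used and stated).

## Gene sets

* The hypergeometric tail is strictly greater, P(X > N₊), as the primary
  definition; `inclusive=True` gives the conventional P(X ≥ N₊) for
  interoperability.
* The GSZ variance follows the exact law-of-total-variance form
  SE² = 4[var(S)(N₊ᴴᴳ(N_list − N₊ᴴᴳ) − var N₊)/(N_list − 1) + ⟨S⟩²var N₊]
  with population (divide-by-N_list) var(S); an asymptotic large-N mode is
  available and agrees within a few percent for N ≥ 1,000. With S ≡ 1 the
  exact form reduces *algebraically* to the binary overrepresentation Z.
  For the full list (N_list = N) it reduces to the overexpression Z with a
  finite-population factor (N − N_set)/(N − 1) in the denominator;
  `gsz_full_list` defaults to the simple form (⟨S⟩_set − ⟨S⟩)/√(var(S)/N_set)
  — the version practitioners expect, exact in the N_set ≪ N limit — and
  exposes `finite_population=True` for the exact reduction, which the test
  suite uses as the oracle.
* Regularization: SE₀² is the asymptotic variance evaluated at the minimum
  sizes (defaults N_list^min = N_set^min = 10) and
  λ = 1 − min(1, (N_list^min/N_list)(N_set^min/N_set)), read as a [0, 1]
  weight. Permutation nulls draw size-matched random sets from the analyzed
  universe, seeded, with the add-one estimator p = (1 + #exceed)/(1 + B),
  B default 1,000; one- and two-tailed variants.
* The top-three heatmap takes the three top sets per (sample, spot) context,
  deduplicates the union, fills −log10 p, and orders rows by average-linkage
  hierarchical clustering on Euclidean distance (linkage/metric are a
  convention choice, fixed for determinism); colors white→yellow→red.
* Benjamini–Hochberg adjusted values can be obtained from the raw p columns
  of the enrichment tables; the tables report raw p plus permutation p.

## Synthetic data

The generator plants disjoint modules of co-expressed genes on a log10
baseline ~ Normal(2.5, 0.7) (≈ three decades of dynamic range, microarray-
like), shifts module genes by a fixed effect (default 1.0 log10 unit) in
their active sample group, and draws replicate noise with
SD = σ₀ + slope·max(0, e₀ − e) (defaults 0.05 + 0.2·max(0, 2.0 − e)), so the
log-scale error inflates at low expression. Present calls flag
replicate-averaged expression above a detection floor (default 1.5). The
standard recovery experiment uses 3 modules × 100 genes among N = 5,000,
M = 12 conditions in 4 groups, 3 replicates, a 20 × 20 grid and a 30,000-
presentation schedule — sizes chosen so the full experiment runs in seconds
while leaving the planted structure overwhelmingly recoverable; the default
60 × 60/250,000 settings remain the production configuration.

Not modeled: probe-level effects, batch effects, correlation outside planted
modules, heavy-tailed noise. Passing tests therefore demonstrate correctness
of the estimators and the recovery machinery under block-structured signal
with expression-dependent Gaussian noise — not robustness to those real-data
artefacts.

## Degenerate inputs and edge conventions

Constant expression states yield zero spots (with a warning) rather than
arbitrary ones; constant score columns make WAD undefined (error); genes
with constant profiles are excluded from correlation filtering (r
undefined); rank-1 data rejects linear initialization with a suggestion to
jitter; all-masked fields refuse to render. Quantile normalization and the
fdr estimator reject non-finite input and fewer than 10 p-values,
respectively.

## Known limitations

Only rectangular grids with the online algorithm (no toroidal/hexagonal
topology, no batch SOM); spot selection only by the quantile criterion (no
k-means/correlation clustering); no probe-level preprocessing (the package
consumes calibrated expression values); the gene-set profile's significance
line is a permutation quantile across the profile, not a per-sample
adjusted threshold.
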