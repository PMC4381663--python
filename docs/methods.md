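# Methods

## Model and rationale

The observable is, per symbiont cell, the proportion
X = C_C100 / C_TOTAL of the cell's ITS2 rDNA copies belonging to the
diagnostic ribotype C100 (the remainder being essentially C109). Because
rDNA is multi-copy and subject to concerted evolution, the *distribution*
of X across the cells of one coral colony distinguishes three biological
scenarios:

- **H0 — one heterogeneous population.** Every cell carries both variants
  at a similar dosage, as expected for a non-diagnostic polymorphism inside
  one clonal population. X follows a unimodal interior beta: Beta(α, β)
  with α > 1, β > 1.
- **H1 — two homogeneous populations.** Cells are pure C100 or pure C109;
  X piles up at the boundaries. A U-shaped beta with α < 1, β < 1.
- **H2 — homogeneous plus heterogeneous populations.** Pure-ribotype cells
  coexist with co-dominant cells — the pattern expected when the two
  lineages recombine and F₁-like genomes persist. A two-component beta
  mixture π·Beta(α₁, β₁) + (1 − π)·Beta(α₂, β₂), 0 < π < 1.

Candidates are compared by AICc (−2 logL + 2k + 2k(k+1)/(n−k−1); k = 2, 2,
5) and Akaike weights; a weight above 0.90 (configurable
`unambiguity_cutoff`) is called unambiguous. n is the number of cells in
the colony with branches pooled. The H2 component shapes are left
unconstrained (only π is bounded away from 0 and 1): the heterogeneous
component is identified post hoc from its fitted mean rather than forced
by the parameter box.

## Likelihood fitting

- **Boundary ratios.** Observed ratios of exactly 0 (pure C109 arrays)
  break the beta likelihood, so ratios are clamped into (0, 1) before
  fitting: 0 ↦ ε, 1 ↦ 1 − ε with ε = 1e−3 by default. The alternative
  `half-copy` policy uses εᵢ = 1/(2·C_TOTALᵢ). Clamping preserves ordering
  and bounds the influence of boundary cells on the log-likelihood.
- **Bounds.** Strict inequalities become closed boxes with margin δ = 1e−3:
  H0 shapes ∈ [1+δ, 200], H1 shapes ∈ [δ, 1−δ], H2 shapes ∈ [δ, 500] and
  π ∈ [0.01, 0.99]. The caps 200/500 exceed any plausible estimate at
  n = 30; a fit landing on a box edge is flagged `at_boundary`.
- **Optimizer.** L-BFGS-B with analytic gradients (digamma-based for the
  single betas; responsibility-weighted for the mixture), relative logL
  tolerance 1e−8 and gradient tolerance 1e−6.
- **Multi-start.** A fixed, seedless grid: H0 shapes over {1.5, 3, 10, 50}²,
  H1 over {0.1, 0.3, 0.5, 0.9}², and for H2 every pair of distinct component
  means from {0.05, 0.5, 0.8, 0.95} at concentrations {5, 50}
  (α = m·c, β = (1−m)·c) crossed with π ∈ {0.2, 0.5, 0.8} — 36 starts. The
  reported optimum is never below the likelihood at any start; equal logL
  resolves to the lowest start index, and equal weights resolve toward the
  hypothesis with fewer parameters. Fits are therefore deterministic.
- **Label switching.** H2 components are reported in ascending order of
  mean α/(α+β), with π re-attached accordingly.

## Cell classification

After selection, each component of the best model gets a role from its
mean m = α/(α+β): `homogeneous-C109` if m < t_low (default 0.15),
`homogeneous-C100` if m > t_high (default 0.85; gel screens cannot detect
the minor variant above that ratio, so such cells are operationally pure),
`both-homogeneous` if the component is U-shaped (α < 1 and β < 1), else
`heterogeneous`. Cells join the component with the largest posterior
responsibility; within a U-shaped component they split to the two
homogeneous roles at x = 0.5. The reported *proportion of heterogeneous
cells* is the fraction of cells landing in heterogeneous-role components.
This counting convention is an explicit package decision — summaries of
fitted mixtures map to cell proportions in more than one defensible way —
and is exactly reproducible from the per-cell classification table. If
both components share a role the result is returned but flagged ambiguous.

## qPCR quantification

Standard curves are ordinary least squares of mean Ct on log₁₀ copies over
a serial dilution (≥3 levels); efficiency E = (10^(−1/slope) − 1)·100, with
95% < E < 100% flagged as the acceptance band. Copies invert the curve at
the duplicate-mean Ct (mean taken after the SD filter — copies from mean
Ct, not the mean of per-well copies, matching standard practice). QC: mean
Ct below the intercept (≥1 template copy), duplicate SD < 0.5 cycles, SYBR
Tm within 1 °C of the plasmid reference. A non-detect (or below-intercept
signal) in exactly one TaqMan assay contributes 0 copies so that ratios of
exactly 0 and 1 are representable; a double non-detect excludes the cell.
Template dilution (10³/10⁴ per site in the emulated design) and the nested
pre-amplification are config constants; pre-amplification is modeled as a
ratio-preserving scale factor with default gain 2²⁴ (ideal doubling over
24 cycles), with an optional per-assay bias multiplier for sensitivity
analysis. The assay-validation helpers regress predicted against nominal
mixture ratios under the fixed line y = x (R² about the identity line,
which can be negative).

## Colony statistics

Ratios are arcsin(√x)-transformed (the standard variance-stabilising
transform for proportions; plain arcsin is available by flag) and
decomposed by a balanced two-level nested ANOVA. Branch is a random factor
nested in colony, so the colony effect is tested against the branch mean
square (F_colony = MS_colony/MS_branch) and branch against the residual —
the convention consistent with the F ratios implied by the printed SS/df of
the reference design. The copy-number analysis fits
C_TOTAL = b₀ + b₁·X + b₂·X² by least squares with the overall F test;
orientation (ratio as predictor) reflects the finding that copy number
differs by genotype class, and the regression direction is configurable.

## Synthetic data generator

The generator emulates the study conditions: 6 colonies × 3 branches × 10
cells; per-colony population mixtures over {homC109, homC100, het} (four
colonies contain all three classes, two lack homC109; the heterogeneous
fraction spans 0.07–0.885); class ratio models Beta(3.48, 66.21),
Beta(26.08, 10.89) and Beta(114.8, 2.32) for homC109 / het / homC100
(representative fitted components, truncated by resampling to the class
bands < 0.15, interior, > 0.85); total copies log-uniform on [500, 30000]
with homC100 drawn from the upper half of the log-range (a switch disables
this to probe the regression's null); duplicate wells with independent
Normal(0, 0.15) Ct noise; Tm noise 0.2 °C; calibration curves with slopes
−3.38 to −3.44 (efficiencies inside 95–100%). One integer seed drives a
single root generator. Emitted tables use exactly the CSV dialects the
qPCR reader consumes, including non-detect rows (empty Ct) below one copy
per reaction and per-colony template-free controls.

What the generator does *not* emulate: pipetting/extraction losses,
inhibition, pre-amplification bias (available only as an explicit knob),
melt-curve shapes beyond the Tm scalar, and inter-assay Ct correlation.
Passing roundtrip tests therefore demonstrates correctness of the
estimation chain under the stated noise model, not robustness to every
bench artifact.

## Problem sizes and numerical checks

The Monte-Carlo checks use the sizes the analysis is designed around:
colonies of n = 30 cells for model-selection accuracy (100 replicates per
generating family), n = 1000 for parameter recovery (20 replicates), the
eight-point plasmid mixture test, and the full 180-cell study for the
quantification roundtrip. Fitted mixture densities are verified to
integrate to 1 (quadrature, 1e−6); vectorised log-likelihoods are verified
against per-point summation at 1e−10.

## Known limitations

- Two mixture components at most: colonies hosting three well-separated
  modes are still summarised by the best two-component fit (one component
  often turns U-shaped to absorb both boundary classes), which is the
  model family's intended behaviour but blurs the three-class structure.
- No uncertainty on fitted parameters (no bootstrap/Bayesian machinery);
  Akaike weights quantify model—not parameter—uncertainty.
- The nested ANOVA assumes a balanced (or near-balanced) design and uses
  sums of squares, not REML.
- AICc requires n > k + 1; with fewer than 7 cells the mixture hypothesis
  is dropped (weight 0, logged) rather than fitted.
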