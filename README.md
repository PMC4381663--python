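# symratio

Single-cell qPCR quantification of intra-genomic rDNA ratios, and
beta-mixture model selection for detecting admixed (putatively recombinant)
*Symbiodinium* populations.

## The problem

Reef corals host dinoflagellate symbionts (*Symbiodinium*) whose lineages
are usually told apart by the multi-copy ITS2 rDNA marker. Because ITS2
exists in hundreds to tens of thousands of copies per genome, a single cell
can carry a *mixture* of sequence variants — and the within-cell proportion
of a diagnostic variant is itself informative: a population of cells whose
genomes co-dominantly carry two divergent variants, coexisting with cells
carrying either variant in pure form, is the signature expected if the two
lineages recombine.

`symratio` implements the full quantitative chain for this question:

1. **qPCR layer** (`symratio.qpcr`) — log-linear standard curves
   (Ct = intercept + slope·log₁₀ copies, efficiency
   E = (10^(−1/slope) − 1)·100%), duplicate-well QC (mean Ct below the curve
   intercept, duplicate SD < 0.5 cycles, SYBR melt temperature within 1 °C of
   the plasmid reference), and per-cell copy-number estimation from the two
   allele-specific TaqMan assays: C100⁺ counts copies of ribotype C100
   (C_C100), C100⁻ counts all other clade-C copies. The analysis variable is
   X = C_C100 / C_TOTAL ∈ [0, 1].

2. **Mixture-model layer** (`symratio.betamodels`) — three candidate models
   for the within-colony distribution of X:

   - H0: X ~ Beta(α, β), α > 1, β > 1 — one heterogeneous population;
   - H1: X ~ Beta(α, β), α < 1, β < 1 — two homogeneous populations;
   - H2: X ~ π·Beta(α₁, β₁) + (1 − π)·Beta(α₂, β₂), 0 < π < 1 — homogeneous
     *and* heterogeneous populations, consistent with recombination.

   Each is fitted by bounded maximum likelihood (L-BFGS-B, fixed multi-start
   grid) and compared through small-sample Akaike weights
   w_i = exp(−Δᵢ/2) / Σ exp(−Δⱼ/2) with Δᵢ = AICcᵢ − min AICc; w > 0.90 is
   treated as unambiguous support. Cells are then assigned to mixture
   components by posterior responsibility and components to biological roles
   (homogeneous-C109, homogeneous-C100, heterogeneous) by their means.

3. **Colony statistics** (`symratio.colonystats`) — arcsin(√x) transform,
   two-level nested ANOVA (`X ~ Colony + Branch(Colony)`, colony tested
   against the branch mean square), and a second-order polynomial regression
   of total copy number on X.

4. **Synthetic study generator** (`symratio.synthetic`) — six colonies ×
   three branches × ten cells by default, three latent cell populations with
   beta-distributed ratios, log-uniform total copy numbers (≈500–30,000,
   upper half for homogeneous-C100 cells), and raw duplicate-well Ct tables
   with Gaussian Ct noise, so the entire pipeline is testable end to end
   with no external data.

5. **Pipeline and CLI** (`symratio.workflow`, `symratio.cli`) — staged runs
   with per-exclusion logging and TSV/CSV reports.

## Worked example

```sh
symratio all --config examples/run.yaml
```

simulates the default six-colony study (seed 1, Ct noise 0.15 cycles),
calibrates, quantifies, and fits all three hypotheses per colony. The
printed model-selection report (also written to
`results/demo/model_selection.tsv`) is:

```
colony best         w_H0         w_H1     w_H2                                       params_best  prop_heterogeneous  unambiguous
     a   H2 8.219336e-08 4.839126e-11 1.000000 0.138*Beta(0.5401,0.2721)+0.862*Beta(38.53,12.33)            0.900000         True
     b   H2 3.415001e-07 9.684064e-06 0.999990 0.425*Beta(0.4908,0.3197)+0.575*Beta(54.62,18.91)            0.633333         True
     c   H2 4.551955e-09 3.037708e-16 1.000000     0.100*Beta(173.5,69.09)+0.900*Beta(166,3.326)            0.100000         True
     d   H2 1.389048e-01 2.568381e-02 0.835411    0.033*Beta(22.26,500)+0.967*Beta(3.644,0.9049)            0.966667        False
     e   H2 8.609651e-08 1.744441e-02 0.982556  0.636*Beta(1.024,0.5781)+0.364*Beta(271.4,4.442)            0.566667         True
     f   H2 3.730146e-06 1.875458e-08 0.999996     0.467*Beta(25.09,9.314)+0.533*Beta(123,2.342)            0.466667         True
```

Reading one row: colony *a* is best explained by the two-component mixture
(H2, Akaike weight ≈ 1.00) whose high component Beta(38.53, 12.33) has mean
0.76 — a heterogeneous C100/C109 population holding 86% of the mixture mass
— while the U-shaped low-weight component absorbs the boundary cells; 90%
of the colony's cells classify as heterogeneous. All six colonies select
H2, five of them unambiguously (w > 0.90), matching the admixture structure
the generator planted. The run also writes the per-cell quantification
(`cellquant.csv`), the nested-ANOVA table (`anova.tsv`), the per-cell
classification (`classification.csv`) and a log of every QC exclusion
(`run.log`).

Stages can be run separately: `symratio simulate | standards | quantify |
fit | report`, each taking `--config/--out/--seed`.

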