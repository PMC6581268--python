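# snppca

PCA of biallelic SNP matrices for elucidating population structure — with
the three methodological choices every such analysis makes treated as
first-class, reportable options: the kind of **graph** (biplot vs
monoplot), the **SNP coding** (which allele is 1), and the **PCA variant**
(which centering/standardization precedes the SVD).

It is written for geneticists and breeders who run PCA on
Individuals × SNPs 0/1 matrices (humans, crops, animals, microbes) and
want the joint structure of SNPs *and* Individuals — not just a cloud of
samples — displayed and interpreted correctly.

## The model

For a data matrix with entries `D_rc` (Individual r, SNP c), double-centered
PCA (DC-PCA) decomposes

```
D_rc = μ_r + μ_c − μ + Σ_n λ_n γ_rn δ_cn + ρ_rc
```

where `μ`, `μ_r`, `μ_c` are the grand, row, and column means, `λ_n` are
singular values of the double-centered (pure SNP-by-Individual interaction)
matrix, and `γ_rn`, `δ_cn` are unit eigenvectors. Scores are
`√λ_n · γ_rn` and `√λ_n · δ_cn`, so the product of an Individual score and
a SNP score estimates their interaction directly. Three-source ANOVA splits
the corrected total SS orthogonally into SNP main effects, Individual main
effects, and S×I interaction; DC-PCA then partitions S×I into interaction
principal components (IPCs) with Gollob degrees of freedom
(`p + n − 1 − 2k` for the k-th component of a p × n double-centered
matrix).

Six variants are implemented (`double_centered`, `snp_centered`,
`individual_centered`, `snp_standardized`, `individual_standardized`,
`grand_mean_centered`). For every variant other than DC-PCA each component
mixes main and interaction effects; the **augmented ANOVA table** quantifies
the mixture by subjecting each component's rank-1 expected-value matrix
`λ_n γ_n δ_nᵀ` to ANOVA. **AMMI** (additive main effects and multiplicative
interaction) keeps the main effects the DC-PCA discards; the AMMI1 biplot
plots means on the abscissa and IPC1 on the ordinate. **Correspondence
analysis** (reciprocal averaging) supplies the CA1-arranged matrix — rows
and columns permuted by ranked first-axis scores — whose diagonal
concentration, testable against a within-column randomization null,
reveals single-gradient structure, plus automated quantile group coloring
for both biplot panels.

Recommended defaults throughout: biplots, rare-allele-coded-1 (`rare1`)
polarity, DC-PCA (or AMMI1 when main effects matter).

## Worked example

Simulate a 20 × 24 single-gradient band matrix (the classic arch/horseshoe
generator) and analyze it:

```sh
snppca simulate --generator band --n-ind 20 --n-snp 24 --band-width 3 --seed 1 --out toy.tsv
snppca anova --in toy.tsv --variant dc -k 2
```

```
Total                479          55.467
  SNPs                  23           0.267
  Individuals           19           0.133
  SxI                  437          55.067
    IPC1                  41           8.824
    IPC2                  39           8.379
    Residual             357          37.863
```

Nearly all variation (55.067 of 55.467) is S×I interaction — the joint
structure only a biplot can show; IPC1 and IPC2 capture the gradient,
distorted into the usual arch. The main effects are tiny, so an AMMI1
biplot adds little here, but its anchors are still reported:

```sh
snppca ammi1 --in toy.tsv --coords-out ammi.tsv
# grand mean 0.13333; IPC1 captures 16.0% of SxI
```

The grand mean (0.13333) is the overall rare-allele frequency; the
ordinate (IPC1) carries 16.0% of the interaction SS. Finally, the CA1
arrangement concentrates the band along the diagonal, and randomizing each
SNP's column independently destroys it:

```sh
snppca ca-arrange --in toy.tsv --null-reps 99 --seed 7
# diagonal concentration: 0.9313
# null mean 0.5575 sd 0.2199 exceedance 0.000 (99 reps)
```

The observed concentration (0.9313) exceeds every one of 99 null
replicates — the diagonal structure is real, not an artifact of the
ordering. `snppca biplot` and `snppca heatmap` render the corresponding
figures; `snppca report --config run.json` executes the whole recommended
pipeline and writes a manifest recording the graph/coding/variant choices.

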