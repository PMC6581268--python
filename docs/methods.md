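# Methods

## Data model and orientation

All analyses operate on a complete biallelic genotype matrix with
Individuals in rows (R) and SNPs in columns (C), entries 0/1 (inbred/haploid
mode) or 0/1/2 with the heterozygote as 1 (diploid mode). Files oriented
SNPs-in-rows are transposed on entry; one internal convention keeps every
formula unambiguous. Missing values are a hard error by default — the
methods below assume a complete matrix — with opt-in per-SNP mean imputation
as a clearly marked extension for exploratory use only.

## SNP polarity and codings

A biallelic SNP's 0/1 labels are arbitrary ("polarity"); complementing a
column (x → 1−x, 2−x in diploid mode) changes nothing biological but a lot
statistically, because it moves the SNP's main effect and reflects its
centered column. Codings supported: `rare1` (minor allele = 1, the
recommended default), `common1`, `vcf:<id>` (a designated reference
individual reads 0 everywhere), seeded `random_mixed`, and explicit masks.
Ties (frequency exactly 0.5, possible only with an even number of
Individuals) are left unflipped by both `rare1` and `common1` and recorded:
"rare" is undefined there, and any other rule would manufacture a
biological claim. A consequence worth knowing: `common1` is the exact
elementwise complement of `rare1` — and therefore yields identical ANOVA
tables for all six PCA variants — only on tie-free matrices.

## The six transforms and the SVD

Per variant, the matrix decomposed is: column-centered (snp_centered),
row-centered (individual_centered), double-centered D − μ_r − μ_c + μ
(the pure S×I interaction), column- or row-standardized (centered then
scaled to unit SD with the n−1 denominator), or grand-mean-centered D − μ.
Standardization refuses zero-variance axes by name rather than inventing a
pseudocount — this is why VCF coding cannot be combined with
SNP-standardized PCA (the reference individual's columns have no variance
at the reference, and monomorphic columns none at all).

The SVD is computed in full by LAPACK (635 × 1341 takes about a second;
iterative top-k solvers are out of scope at this size). Scores default to
`√λ · eigenvector` on both axes, so paired score products estimate
interactions without a further multiplication; an `axis_principal` mode
(eigenvector × λ) is available for monoplots where inter-point distances
on one axis matter most. Component polarity is arbitrary (flipping both
axes' signs changes nothing), so a deterministic convention is applied:
each component is oriented to make its largest-magnitude SNP-eigenvector
entry positive.

Degrees of freedom follow the Gollob rule: the k-th multiplicative
component of a double-centered p × n matrix carries p + n − 1 − 2k df,
with one more df per uncentered axis (p + n − 2k singly centered,
p + n + 1 − 2k grand-mean-centered); the residual closes the source df.

## ANOVA and the augmented table

Three-source ANOVA splits the corrected total SS orthogonally into SNP
main, Individual main, and S×I interaction effects. The DC-PCA table then
partitions S×I into IPC rows (SS = λ²) plus residual. For the other five
variants the augmented table partitions each component's rank-1
expected-value matrix by the same ANOVA, restricted to the sources that
variant retains; the residual matrix (source minus all retained rank-1
terms) is partitioned identically.

Closure properties, and one deliberate asymmetry: portions always sum to
their row's SS exactly (the excluded sources' numerical residue, zero in
exact arithmetic, is folded into S×I). For singly centered and
standardized variants, portion columns also sum to their source SS,
because retained singular vectors have exactly zero mean along the
centered axis. Grand-mean-centered PCA has no such property — its rank-1
terms can carry nonzero grand means and non-orthogonal main-effect
projections — so that variant reports an explicit `Mean` portion column,
keeps exact row closure, and makes no column-closure promise. For
standardized variants, only rows on the standardized scale are emitted
(a raw-scale "Total" would not nest above a rescaled source).

A helper labels each component main-dominated, interaction-dominated, or
substantially mixed; "mixed" means the minority portion exceeds 20% of the
component's SS. The cutoff is a configurable reporting convention, not an
inferential threshold.

## AMMI

AMMI fits grand mean + main effects additively and the interaction
multiplicatively; its multiplicative part is, by construction, the same
decomposition DC-PCA computes, and the two share one ANOVA table. AMMI1
coordinates put means (not deviations, though a flag could trivially
recover them — means match how practitioners read allele frequencies) on
the abscissa and IPC1 scores on the ordinate, with a vertical reference at
the grand mean. Because the two axes carry different kinds of information,
AMMI1 is exempt from the equal-axis-scale rule enforced for
component-vs-component plots.

## Correspondence analysis and the arrangement null

CA decomposes the standardized residuals from independence,
S = (P − rcᵀ)/√(rcᵀ); the trivial margins axis is removed by the residual
subtraction and all singular values lie in (0, 1]. Both a full SVD and a
power-iteration route (deterministic centered-ramp start, tol 1e−10, max
10000 iterations, convergence checked up to sign) are provided; they agree
to the tolerance and the power route is linear in matrix entries when only
CA1 is needed. Zero-margin rows/columns are rejected by name. CA1 ties are
broken by original index; the arbitrary axis direction is fixed by
requiring the first arranged row's 1-entries to sit at smaller mean column
rank than the last row's (both orders reverse together, which leaves the
concentration statistic unchanged).

Diagonal concentration of an arranged matrix is
`1 − 2·Σ v·|r̃−c̃| / Σ v` with positions normalized to (rank−0.5)/size: 1
when all mass lies on the diagonal, ~1/3 for mass placed uniformly at
random, lower still for anti-diagonal structure. The significance device
is a within-column randomization null: shuffle each SNP's column
independently (destroying joint row structure while preserving every
SNP's frequency), re-run the CA1 arrangement, re-score; report the null
mean/SD and the exceedance proportion.

## Group schemes

Expert transfer assigns each SNP the Individual-group in which its
rare-allele frequency is highest; ties go to the larger group, then
lexicographic name, and are reported. Automated coloring cuts both axes'
CA1 orders into k contiguous groups of ⌊N/k⌋ with the remainder in the
last group (default k = 5). An anomaly report lists items whose expert
label disagrees with the majority label of their CA1 neighborhood — a
prompt for review, not a reclassification.

## Synthetic data

Two seeded generators supply every structure the package's arguments rely
on, so the full stack is testable without external data.

`diagonal_band_matrix` emulates a single environmental/causal gradient: a
0/1 band of a given width (in column units) along the diagonal, with the
band center clamped away from the matrix edges so each row carries a
full-width band — edge truncation otherwise exaggerates the involution of
the PCA arch and obscures the quadratic IPC1–IPC2 signature the generator
exists to produce. Optional independent bit-flip noise, then rare1
recoding. Default width 3 keeps the arch visually and numerically clear at
the 20 × 24 reference size.

`structured_bernoulli` draws independent Bernoulli entries with
π = clamp(base + a_r + b_c + Σ_t g_tr h_tc, 0.02, 0.98). Because the
binomial variance lost when π moves away from `base` exactly offsets the
systematic variance gained, the expected total ANOVA SS is
R·C·base·(1−base) regardless of effect sizes; each source's systematic SS
is therefore scaled directly to its requested share of that constant.
Effect vectors are balanced sign patterns of constant magnitude in seeded
random order — the flattest way to spend a variance budget, maximizing the
feasible share range before probabilities saturate (requests are rejected
when clamping would touch more than 10% of cells). `base` defaults to 0.5
for maximal headroom. `share_interaction` accepts a tuple to produce
several rank-1 interaction terms with well-separated singular values —
needed to exercise DC-PCA's near-immunity to polarity flips per component,
which is a statement about components whose singular values stand clear of
the noise bulk; components inside the bulk rotate freely under any
perturbation, so no per-component invariance can hold there. Binomial
noise lands almost entirely in the S×I stratum (its df dominate), so
realized interaction shares sit far above the requested systematic share;
main-effect shares track their requests closely.

What these generators do not emulate: linkage disequilibrium, coalescent
genealogy, discrete admixed subpopulations, missingness, or genotyping
error. Passing tests therefore demonstrate the statistical machinery —
decompositions, bookkeeping identities, geometric signatures, invariances
— not the method's behavior on any particular organism's data.

## Numerical conventions

Centering identities are asserted at 1e−9 absolute; energy conservation
(Σλ² = total SS) at 1e−6 relative; published table values at the printed
3-decimal precision; CA power-vs-SVD agreement at 1e−8 after sign
alignment. "Numerical zero" for scores scales as √λ, so ~1e−6 on unit-SS
problems. Rendering is deterministic (fixed SVG hash salt, no timestamps,
no jitter). The biplot axis-scale audit classifies the larger/smaller
data-per-length ratio as correct (≤1.01), slight (≤1.1), faulty (≤2), or
substantial (>2).

## Known limitations

Binary/diploid codings only (no polyploid or multi-allelic expansion);
no missing-data model beyond mean imputation; full SVD only (no
randomized/out-of-core path for biobank scale); CA beyond the first few
axes and detrended CA are out of scope; the published oat-panel
verification values are frozen in the test suite but the genotype matrix
itself must be supplied externally (journal supplementary files; too
large to bundle here).
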