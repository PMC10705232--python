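# Methods

This note documents the models, conventions and numerical choices behind
`missvuln`, in the order the pipeline runs.

## Synthetic study conditions

The generator (`missvuln.synthetic`) emulates the geometry of a whole-brain
mouse analysis — an ISH expression atlas over a regional parcellation, a
scRNAseq consensus signature matrix, and a panel of regional tau-pathology
experiments — at a scale where the complete pipeline runs in about a second.
Defaults (chosen once as the package's study conditions):

| parameter | default | full-scale analogue |
|---|---|---|
| genes | 120 | 3763 |
| cell types | 12 | 42 |
| voxels | 240 | 50 246 |
| regions | 24 | 424 |
| tau datasets | 12 | 12 |
| markers per type | 6 | — |
| planted vulnerable / resilient types | 3 / 2 | — |
| expression noise sd | 0.05 | unknown |
| tau noise sd | 0.1 | unknown |

**Signatures.**  Each cell type gets `markers_per_type` dedicated marker
genes at a high log-normal level (median 5) over a shared low per-gene
baseline (median 0.1, mild per-entry jitter).  Each of the four cell-type
classes (hippocampal glutamatergic, cortical glutamatergic, GABAergic,
non-neuronal) additionally gets class-marker genes expressed at a high level
in *all* member types, drawn from the gene pool left after the per-type
blocks; this is what makes same-class types transcriptomically similar, as
real subclasses within a neurotransmitter class are, and is what the
gene-space spectral embedding recovers.  If the signature matrix's condition
number is ≥ 10³ it is regenerated from a fresh sub-seed, keeping
least-squares recovery well posed; with the marker structure this
essentially never triggers.

**Density fields.**  Voxels are split into contiguous, near-equal regions.
Planted vulnerable types' regional base rates increase along an anatomical
gradient and planted resilient types decrease along it, each multiplied by
independent per-type regional log-normal jitter (σ = 0.25) so that no two
planted types are collinear; remaining types get independent log-normal
rates.  Every type's base rate is boosted to 1.25 × its maximum in a
designated home region, and voxel values carry multiplicative log-normal
jitter (σ = 0.15).  All densities are nonnegative by construction.

**Expression and tau.**  `E = C·D + ε` with i.i.d. Gaussian ε clipped at 0
(`noise_sd = 0` gives the exact product).  Each tau dataset is a positive
combination of the planted vulnerable types' regional densities — weights 1
with per-dataset log-normal jitter (σ = 0.2), zero on all other types — plus
clipped Gaussian noise.  Every dataset except the first gets one seeded
region, excluded from its stored tau vector; the first is unseeded,
emulating a model that develops pathology endogenously.

What the generator does **not** emulate: realistic neuroanatomy or
hemispheres, connectome-mediated tau spread, amyloid co-pathology, the
heavy-tailed and spatially correlated error structure of real ISH data
(noise is i.i.d. Gaussian with clipping, a stand-in rather than a claim
about ISH error).  Passing tests therefore demonstrate correctness of the
algorithms under controlled conditions, not performance guarantees on real
atlas data.

## Gene selection (MRx3)

Inputs are normalized first: the spatial matrix per gene row, the signature
matrix per cell-type column.  The full-scale sources state only "normalized
by gene" / "normalized by cell type", so the scheme is configurable
(`max`, `sum`, `l2`); the defaults are per-gene max and per-type sum, and
the scheme used is recorded in output metadata.  All-zero rows/columns pass
through as zeros with a warning.

**Noise trimming.**  With the unconstrained least-squares density fit
`D̂(G)` over all genes, the incremental-noise score of gene *g* is the
growth in squared reconstruction error attributable to including it,
normalized per voxel.  Dropping one gene row is a rank-one downdate of the
normal equations, giving the exact closed form
`score_g = ‖r_g‖² / ((1 − h_g)·N_v)` with residual row `r_g` and leverage
`h_g = c_gᵀ(CᵀC)⁻¹c_g`; the defining oracle is a from-scratch refit per gene
and the two must agree to 1e-8 (tested).  Leverage ≈ 1 (a gene pivotal for
identifiability) falls back to the direct refit; a rank-deficient normal
matrix falls back to the pseudo-inverse, logged.  The top decile by score is
removed (ceil of 0.10·|G|; ties removed earliest-identifier-first).

**Greedy mRMR.**  `V_i = F_i / Redund(i|S)`; `F_i` is the across-type sample
variance (N−1 denominator) of the gene's column-normalized expression —
operationally a one-way variance criterion.  Conventions where the formula
is undefined: the first pick maximizes `F_i` alone (redundancy has no
meaning for an empty S, matching standard mRMR initialization); zero
redundancy is floored at 1e-12 so V stays finite without disturbing the
argmax; zero-variance genes correlate 0 with everything.  All tie-breaks use
stable gene-identifier order, making selection deterministic given input
ordering, and greedy selection is validated against brute-force
re-evaluation of the criterion at every step.

**Subset size.**  One selection at the largest candidate size serves all
sizes (the greedy run has the prefix property).  Per size, the mean voxel
relative residual after deconvolution on the size-prefix is recorded; the
chosen size maximizes the discrete second difference
`r[i−1] − 2r[i] + r[i+1]` over interior points (maximum curvature).  Fewer
than three sizes: minimum-residual size, warned.  Flat curve: smallest size,
warned.  The pipeline default sweep spans roughly 15–75 % of the
post-trim pool in five sizes, mirroring the 400–3100-of-3763 sweep of the
full-scale analysis (recorded with the other full-atlas constants in
`missvuln.config.ATLAS_SCALE`).

## Deconvolution

Per voxel, `min ‖e_k − C_red·d_k‖₂` s.t. `d_k ≥ 0`, solved with the
Lawson–Hanson active-set method (scipy's `nnls`), which returns the exact
KKT-satisfying solution; whenever the unconstrained solution is already
nonnegative the two coincide (tested to 1e-10, and against an exhaustive
1e-3 grid on 2-D problems).  Voxels are independent — no smoothing or
spatial regularization — so results are invariant to voxel order.  Relative
residuals `‖e_k − C d_k‖/‖e_k‖` are reported per voxel; zero-expression
voxels are flagged undefined (NaN) rather than divided.

## Regionalization

Regional values are unweighted means over each region's voxels (background
label 0 excluded).  Projection into a tau dataset's region space copies 1:1
correspondences and merges many-to-one correspondences as volume-weighted
means; volumes default to voxel counts, physical volumes are accepted.
Dataset regions with no atlas match are dropped and logged — never imputed.
Seeded regions are removed from both the density matrix and the tau vector
before any statistic; hemispheres are not modelled (the tau quantifications
the design mirrors pooled both hemispheres).

## Univariate statistics

Pearson correlations with two-sided t-based p-values; zero-variance inputs
are reported missing rather than raising.  Per-entity mean R averages
non-missing datasets with equal weight.  Class tests pool each class's R
values over member types × datasets: a one-sample t against 0 per class and
Welch two-sample tests for every pair (the unequal-variance test is the
safer default; the pairwise test is not otherwise pinned down).  All
p-values are Bonferroni-corrected over the family of tests performed
(configurable); the correction multiplies and caps at 1, since an uncapped
product is not a probability.  Degenerate one-sample inputs (constant
nonzero) report t = ±∞, p = 0, flagged.

The chi-squared goodness-of-fit statistic is `Σ(O−E)²/E` with an upper-tail
p.  Degrees of freedom default to (categories with E > 0) − 1 but are an
explicit parameter: the selection-frequency test over four cell-type classes
can legitimately be run at df 2 or 3 depending on how the family is framed,
and the package does not guess.  Expected counts for "are classes equally
represented among selected features" default to proportional-to-class-size
(the fair null when classes differ in size); a flat expectation is
available.

## Multivariate models

Candidates are ordered by |R| — resilient, negatively correlated features
belong in the models, so signed ordering cannot be the operative rule;
signed ordering remains available.  The kept fraction (default 25 % for
cell types, 50 % for the gene panel) uses half-away-from-zero rounding,
minimum one feature.  Nested OLS models of dimensionality 2 … n_kept + 1
(counting the intercept) are scored with `BIC = n·ln(RSS/n) + (k+1)·ln(n)`;
constant-offset BIC variants cannot change the argmin at fixed n (tested).
The minimum-BIC model wins, ties to the smaller model; RSS is floored at
1e-300 and numerically exact fits are flagged.  The top-k model (k = 5)
fits the k most correlated features directly and is, by construction,
identical to the dimensionality-6 entry of the BIC trace — asserted on every
fixture.  Family comparison declares the lower-BIC family (cell types vs
genes) the winner per dataset and emits a results table with R², predictor
count, BIC and significance stars (* p<0.01, ** p<0.001, *** p<0.0001) on
the Bonferroni-corrected overall F-test.

The synthetic gene family uses a "risk-gene" panel of 2 × n_celltypes
baseline (non-marker) genes: real disease-risk genes are generally not
direct markers of the vulnerable cell types, and a panel of marker genes
would trivially proxy the densities and make the comparison meaningless.

## Spectral embedding

Cell types are compared by gene expression (signature rows over the selected
genes) or by regional density.  `D = 1 − R` (clipped to [0, 2]);
`s_ij = 1/d_ij` off-diagonal with distances floored at 1e-9 before
inversion; `s_ii = 0`.  Min-max normalization runs over the off-diagonal
entries only — including the pinned zero diagonal would make it trivial —
and a degenerate (constant) off-diagonal range maps to all ones, logged.
The unnormalized Laplacian `L = Δ − S` is eigendecomposed; eigenpairs are
sorted ascending and each eigenvector's sign is fixed so its
largest-magnitude loading is positive (reproducible plots and regressions).
`|λ₁| > 1e-6` warns that the connected-graph assumption is violated;
repeated eigenvalues are flagged since the axes are then not unique.  Mean
tau correlation is regressed on v₂ and v₃ per mode (simple OLS, t-based 95 %
CI); constant loadings are flagged undefined.

## Gene sets

SV-G/SR-G: rank genes by |mean R|, take the top `round(frac·N)` (default
decile) and split by sign.  This reading — rather than separate signed
deciles — is motivated by the full-scale set sizes, whose positive and
negative parts sum to one decile; the signed-decile alternative is behind a
flag.  DE z-scores standardize each gene row of the column-normalized
signature matrix with the N−1 standard deviation; zero-variance rows get
z = 0, flagged.  The per-type quota is `ceil(|SV-G| / n_vulnerable)` —
ceiling, not round-half, because the full-scale worked example (277 genes /
16 types → 18) is consistent only with ceiling; round-half is available and
its discrepancy documented.  SV-C is the union (first-contribution order,
duplicates removed, contributing types retained as provenance) of each
vulnerable type's quota of top-z genes; SR-C symmetric against SR-G.
Vulnerable types are those with positive mean R *and* at least one
multivariate-model selection; resilient types the symmetric rule (symmetry
assumed, as the resilient-side rule is not separately pinned down).  Sets
export as plain-text gene lists with provenance headers, suitable as input
to external GO-enrichment services; enrichment itself is out of scope
(version-dependent external databases).

## Orchestration and formats

TSV with `#`-prefixed provenance headers (config hash, seed, software
version) is the canonical matrix format, written with 17 significant digits
so round-trips are lossless; JSON carries metadata.  The eight stages write
separate directories; identical configuration and seed give byte-identical
numerical outputs.  NIfTI export of voxel volumes was left out: the
synthetic parcellations are 1-D voxel sequences and the TSV/JSON bundle is
the complete, diff-able record; nothing downstream consumes volume images.
The CLI (`missvuln`) is a thin layer over the library; partial-stage
subcommands run the (fast, deterministic) shared pipeline and point at the
requested stage directory.

## Problem sizes in tests

Unit and acceptance tests run the generator at 40–240 voxels, 2–12 cell
types and 20–120 genes, sizes at which every oracle (per-gene refits,
brute-force greedy selection, exhaustive NNLS grids) is exact and cheap;
stochastic properties (support recovery, null calibration, family
comparison) use 20–200 seeded replicates.  These sizes were chosen so the
oracles remain tractable while the matrices stay comfortably
overdetermined, the same regime the full-scale analysis operates in.

## Known limitations

* The elbow rule assumes a smooth residual-vs-size curve; on noisy synthetic
  sweeps the curve can be monotone increasing (more genes, worse relative
  fit), where "maximum curvature" is still well defined but less
  interpretable than on the canonical decreasing curve.
* Identified vulnerable types are a subset of the planted ones when the
  planted types are strongly collinear (the BIC model then needs only some
  of them) — expected behaviour of subset selection, not an error.
* The Gaussian-with-clipping noise model slightly inflates low-expression
  means; at the default noise levels the effect is negligible.
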