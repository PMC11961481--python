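# Methods

This note records the models, numerical conventions and design choices
behind `cortmapgen`, in the order the pipeline runs them.

## Coordinate and coding conventions

Genomic intervals are 0-based half-open internally; VCF positions are
converted on read and printed 1-based.  Genotypes are counts of the
**reference** allele, so betas carry the opposite sign to tools that count
ALT/effect alleles.  Strand is ignored throughout: SNPs are points and gene
intervals are strandless for assignment purposes.  Missing calls are `-1`.

## Synthetic cohort

The generator is the package's stand-in for a biobank cohort; its defaults
define the desk-scale study conditions used by every end-to-end check:
n = 2,000 participants, M = 5,000 SNPs, L = 642 cortical locations, two
phenotypes ("CT", "GWC").

* **Locations** are vertices of a unit icosphere (any requested L uses the
  smallest refinement with at least L vertices).  A uniform sphere is a
  deliberate simplification of a cortical surface: it is mesh-compatible,
  scalable and makes smooth effect maps easy to construct, but it has no
  folding, no hemispheric structure and no area distortion.
* **Genotypes**: per SNP, two haplotype alleles drawn independently at a
  reference-allele frequency of 1 − MAF, MAF ~ U(0.05, 0.5) (Hardy–Weinberg
  equilibrium).  Inside an LD block, adjacent loci are chained through the
  two-locus haplotype distribution whose coupling D = D′·D_max attains a
  target D′ (default 0.9, 10 blocks of 5 SNPs); the haplotypes themselves
  are recorded so LD estimators can be validated against phase-known data.
  Missingness is completely at random (default 2%).  150 SNPs are forced
  quasi-monomorphic, 50 lose their identifier and 50 get an invalid
  reference base, so the QC rules always have genuine work.
* **Effect maps ("archetypes")** are Gram–Schmidt-orthonormalized low-order
  polynomial harmonics of the vertex coordinates: smooth, unit-norm and
  mutually orthogonal (pairwise cosine 0, well inside the 0.3 bound the
  generator promises).
* **Phenotypes**: baseline 2.5 + Σ_causal β·archetype(ℓ)·genotype + linear
  age/sex/PC terms + a Gaussian per-site offset (SD 0.05) + N(0, 1) noise.
  Units are arbitrary phenotype units.  Missing genotypes contribute their
  per-SNP mean inside the generative model only, so phenotypes exist for
  every participant; the analysis side still drops those participants per
  SNP.  160 causal SNPs (40 per archetype) carry a per-allele effect of 8.0
  per unit archetype loading.  That default comes from a worst-case power
  argument: unit-norm archetypes on 642 vertices peak near 0.068, so at the
  lowest MAF (0.05, genotype SD 0.31) the peak-location t-statistic is
  about 8 × 0.068 × 0.31 × √2000 ≈ 7.5, putting every planted SNP above the
  1%-coverage detection floor — the regime the analysis is designed for.
* **A saturation effect worth knowing about**: with many strong planted
  effects, the residual variance at a location is dominated by the *other*
  causal SNPs, so the per-SNP peak t saturates near
  √(n·A²_peak / Σ_j A_j²) ≈ 7 at the default scale regardless of effect
  size.  Individual causal SNPs therefore retain a ~1–2% chance per seed of
  falling below 1% coverage; recovery checks assert that at least 90% of
  the causal set is selected (typically 158/160), not perfect containment.
* **Phantom**: two concentric spherical shells rasterized at 1 mm (WM
  interior 55, GM shell 35, background 0; radii 20/23 mm), with meshes
  taken from the same icosphere.  Thickness truth is the radial separation
  (3.0 mm); contrast truth follows from the configured intensities after
  normalization ((110 − 70)/180 = 0.2222 at the defaults).

What passing tests on this generator do **not** show: robustness to
population structure or relatedness, imputation uncertainty, realistic MAF
spectra, folded cortical geometry, scanner artifacts beyond an additive
site offset, or any biology.

## Phenotype extraction

Normalization is a single global multiplicative scale to a WM mean of 110;
nonuniform-field correction is out of scope.  CT is the one-directional
WM-vertex-to-pial-surface distance, computed as an exact point-to-triangle
minimum (vectorized Eberly region test, evaluated against all triangles in
chunks — no spatial-index approximation, so it equals the exhaustive
minimum by construction).  The symmetric average some surface tools use
differs from this by at most the mesh discretization on smooth surfaces.

Cylinder sampling decides voxel membership by the voxel **center**: axial
coordinate in the closed interval [0, ‖b−a‖] and perpendicular distance ≤
radius (inclusive), restricted to GM-labeled voxels.  A bounding-box
prefilter accelerates the scan but applies the identical predicate, so the
sampler equals the exhaustive-voxel oracle exactly.  When the vertex pair
is closer than half a voxel the cylinder would be empty by construction;
the sampler then falls back to the single GM voxel containing the WM
vertex, else reports the location as missing (a value, not an error).  The
WM term of the contrast uses the normalization target, not a locally
sampled WM intensity.  Atlas projection is nearest-subject-vertex
resampling.

## Association

OLS per SNP × location on [1, genotype, age, sex, pc1..pc5], complete-case
per SNP, no dosage imputation.  Degrees of freedom are the standard OLS
n_used − 9 (nine regressors including the intercept).  Imaging site is not
a covariate; it enters only the one-way-ANOVA variance diagnostic, whose
per-location R² = SS_between/SS_total is reported in percent.

QC rules run in fixed order, each SNP counted once under the first rule
that fires: (A) non-missing count below `min_n` — default scaled as
35,000/43,030 of the cohort; (B) modal genotype frequency among non-missing
calls above 0.99 (the conventional reading of a near-monomorphic filter);
(C) missing identifier; (D) invalid reference base.

BH correction defaults to the full SNP × location universe of one
phenotype (`bh_scope="global"`), the most conservative interpretation of
genome-wide FDR control; per-SNP and per-location scopes are options.  The
implementation delegates to statsmodels' step-up routine and is tested
against a from-scratch step-up oracle.

Numerical notes: per-SNP fits use masked cross-products (X^T diag(m) X),
a Cholesky-backed solve, and an explicit rank check via pivoted QR that
names the collinear column; noiseless data give SE = 0, t = ±inf, p = 0 by
convention, which ranks correctly downstream.

## Empirical deviation maps

Standardization uses the sample (n−1) SD and, by default, includes the
focal SNP in the ensemble moments; a leave-one-out mode matches the
alternative reading of the null hypothesis ("differs from the mean of all
*other* SNPs").  The two differ by ~z³/2m, negligible at ensemble scale and
bounded in tests.  The deviation p-value is a two-tailed standard-normal
tail probability by default (at genome scale indistinguishable from the
Student-t option with df = m − 1, which is provided).  Gene- and
cluster-averaged maps average **raw betas** first and then standardize the
average against the same ensemble moments as a single SNP.

## Rankings and gene assignment

Peak ranking sorts by each SNP's most significant corrected p, ties broken
by larger peak |β| and then SNP id; the coverage ranking sorts by
significant-location count with the same tie-break chain.  The tie-break
chain is this package's own deterministic convention.  "Top" = top 1%
(ceiling) of post-QC SNPs; "highest-ranked" and "broadest-reaching" = top
10 of the respective orderings.

Gene assignment: a SNP inside one or more genes goes to the overlapping
gene whose nearer boundary is closest; a SNP outside all genes goes to the
interval(s) at minimal distance; all ties are kept.  Distances are measured
to the stored half-open boundary coordinates.  A user-supplied override
table (snp_id → gene) substitutes for curated external mappings, which are
a living database and out of scope.

## Linkage disequilibrium

EM over the two-locus multinomial likelihood; initialization splits double
heterozygotes equally; convergence at max frequency change < 1e-8 or 1,000
iterations; the log-likelihood trace is kept so monotonicity is asserted,
and with no double heterozygotes the first M-step equals direct counting.
D′ is defined as 0 when D = 0 (avoiding 0/0).  Cross-chromosome pairs are
reported as undefined rather than computed.

## Clustering

UMAP is an external dependency treated as a deterministic-given-seed black
box with pinned parameters (15 neighbors, 2 components, min_dist 0.1,
Euclidean); the package's contribution is the protocol around it.  The
clustering radius replaces a visual-inspection choice with the 10th
percentile of pairwise embedding distances (configurable, overridable by a
fixed value), and cluster counts are reported so a user can replicate the
inspection.  Components come from an exact radius graph (KD-tree pair
enumeration + connected components), labels canonicalized by first
appearance.  ARI is computed from the contingency table; when both
partitions are trivial (the 0/0 case) it is defined as 1 for identical
partitions and 0 otherwise.  Stability runs use consecutive seeds
seed0..seed0+n_runs−1 and the mean is over off-diagonal pairwise entries.
On pipeline-estimated maps (as opposed to the clean archetype fixture) the
run-to-run mean ARI at desk scale typically lands between 0.7 and 1.0:
selected LD-partner SNPs carry attenuated maps that sit between clusters
and can switch components between runs.

## Pipeline and reproducibility

All randomness derives from one config seed.  Each stage writes its outputs
plus SHA-256 hashes into `manifest.json` (rewritten after every stage);
figures are registered as volatile and excluded from the reproducibility
contract, array intermediates are raw `.npy` (deterministic bytes).  Resume
reuses a completed stage only when every recorded hash matches and refuses
to proceed past a corrupted intermediate.  Two complete runs from the same
config are bit-identical on every registered table.

Problem sizes used by the test suite and the acceptance script — the
default desk-scale pipeline, 20,000-test null calibrations, 50-seed
recovery and stability checks, n = 10,000 LD draws — are chosen so the
whole suite runs in a few minutes on a single CPU while keeping every
Monte-Carlo tolerance at least three standard errors wide.

## Known limitations

No mixed models or relatedness correction; no dosage/imputation handling;
no X-chromosome conventions; single global intensity scale; spherical
location geometry; synthetic gene annotation in the pipeline stage (real
BED4 annotations are supported at the API and CLI level); 2D vertex
scatter rather than rendered cortical surfaces.
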