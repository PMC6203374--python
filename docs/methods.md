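# Methods

This note records the statistical procedures the package implements, the
defaults and why they were chosen, what the synthetic benchmark does and
does not emulate, and the numerical decisions a maintainer would want to
know about.

## Data model

A specimen carries a 14-landmark 2-D configuration (truss track) and/or a
row of named trait values (traditional track), plus a species label.
Landmark order follows the standard lateral-view scheme for small barbs:
1 snout tip, 2 nape, 3 dorsal-fin origin, 4 dorsal-fin end, 5 dorsal
caudal-membrane attachment, 6 posterior end of the vertebral column,
7 ventral caudal-membrane attachment, 8 anal-fin end, 9 anal-fin origin,
10 pelvic-fin insertion, 11 pectoral-fin insertion, 12 operculum end,
13 posterior eye, 14 anterior eye. TPS files are used exactly as stored
(no y-axis flip): distances and Procrustes shapes are invariant to axis
orientation. A `SCALE=` record converts to physical units on read;
otherwise coordinates stay in pixels and a warning is logged.

## Truss network

The full truss interconnects every landmark pair: k(k−1)/2 edges, ordered
lexicographically so column order is deterministic. The standard-length
edge defaults to landmarks 1–6 (configurable); it is the size proxy and is
excluded from analysis. Excluding twice is an error by design, so a
pipeline cannot silently drop an unrelated column.

## Size correction

**Ratio/log (traditional).** Morphometric variables are divided by SL, the
eight head variables (ED, PROL, POOL, IOD, IND, MHW, HDE, HDN) by HL, then
log10. Meristic counts are never divided — counts do not change with body
size — and pass through log10 only. SL is dropped from the output.

**M-transform (truss).** `M_trans = log10 M − b (log10 SL − log10 SL_mean)`.
The slope `b` is the *pooled* within-group least-squares slope: one `b` per
variable, fitted after centering both log SL and log M by their species
means. A per-species-slope variant exists behind a flag but is not the
default, because species-specific slopes make corrected values
incomparable across groups. `log SL_mean` is log10 of the arithmetic mean
SL by default (`mean_log_sl` switch available; the formula is ambiguous in
the field literature). With self-fitted pooled slopes the pooled
within-group covariance between every corrected variable and log SL is
exactly zero (a least-squares orthogonality identity, tested at 1e-8).

## Screening

Classical fixed-effects one-way ANOVA per character; variables with
p < α (default 0.05) are retained. No multiple-testing correction by
default — per-character raw p-values are what this style of analysis
reports — with Holm available behind a flag. Zero-variance characters are
reported as degenerate, not tested.

**Tukey's-b** is a stepwise range test whose critical value for a span of
r ordered means is the arithmetic mean of the Tukey HSD quantile (at the
full group count) and the Student–Newman–Keuls quantile (at span r), both
from the studentized-range distribution; unbalanced designs use the
harmonic mean group size, recorded in the output. Homogeneous subsets are
maximal runs of consecutive ordered means whose range statistic stays
below the critical value; a character whose subsets are all singletons
separates every species by itself. The exact unbalanced-design arithmetic
of the legacy statistics packages is undocumented; the harmonic-mean choice
is therefore stated in the result object.

## Multivariate discrimination

**PCA** on the correlation matrix (covariance available), components
retained while the eigenvalue is ≥ 0.7 (Jolliffe's rule for
correlation-matrix PCA, boundary inclusive). Eigenvector signs are fixed by
making the largest-magnitude loading positive, so runs are reproducible.

**DFA.** Canonical functions come from the generalized eigenproblem
B v = λ W v with W the pooled within-group scatter and B the between-group
scatter, scaled so canonical variates have unit pooled within-group
variance. Standardized coefficients multiply raw weights by pooled
within-group SDs; the top discriminators are ranked by the maximum
absolute standardized coefficient (a stepwise Wilks option is deliberately
not the default — standardized coefficients are what the classical output
tables show). Classification assigns each specimen to the nearest group
centroid in Mahalanobis distance under the pooled covariance with *equal
priors* (proportional priors by flag), keeping percentages comparable
across unbalanced groups. Leave-one-out refits the whole model without the
held-out specimen (every group therefore needs ≥ 2 specimens).

When the retained variable count reaches the within-group degrees of
freedom — e.g. 90 truss characters on 78 specimens — the pooled covariance
is singular. The low-level functions raise in that case; the *pipeline*
instead enables a ridge of 1e-8 on the pooled covariance, logs a warning
and records the fact in the run manifest. This keeps the default
end-to-end run usable at realistic sample sizes while leaving the
regularization explicit and auditable. Mahalanobis d² values computed under
a near-singular covariance are large and should be read as ordinal, not
metric — their UPGMA topology is stable, their magnitudes are not.

**Mahalanobis centroids.** d²(g,h) = (m_g − m_h)ᵀ S⁻¹ (m_g − m_h) with the
pooled within-group covariance; significance via the two-sample
Hotelling-type approximation F = ((n_g+n_h−p−1) n_g n_h) /
(p (n_g+n_h−2)(n_g+n_h)) · d² on (p, n_g+n_h−p−1) df, reported as NaN when
the second df is not positive. Distances are computed in the full variable
space by default (a reduced canonical-space mode is a one-line change via
PCA scores input).

**UPGMA** consumes the squared distances as produced (a plain DataFrame of
square-rooted distances can be passed instead). Merge height is half the
merging distance, the update is the member-count-weighted average (which
equals the unweighted mean over all original cross-pairs), and ties break
lexicographically on sorted leaf labels, so output is deterministic. The
implementation is verified against a brute-force agglomeration oracle and
against SciPy average linkage; an ultrametric input is reproduced exactly.

## Shape geometry

**GPA**: center, scale to unit centroid size, rotate (proper rotations
only) each configuration to the running consensus, re-estimate, iterate
until the consensus moves < 1e-10 (max 100 iterations). The reported
consensus is the plain coordinate-wise mean of the aligned shapes.
Residuals are returned in the Procrustes tangent space — the isotropic
scale and rotation directions at the consensus are projected out, and
translation components vanish because all shapes are centered — which caps
the nonzero shape dimensions at 2k − 4 and makes the variance identities
below exact. Datasets digitized from the right side must be pre-flipped;
reflections are never fitted.

**Relative warps.** The thin-plate-spline bending-energy matrix of the
consensus (kernel U(r) = r² log r²) supplies principal warps — its
eigenvectors on the non-affine subspace (the affine functions 1, x, y span
its null space, checked to 1e-10). Residuals are projected onto principal
warps with weight λ^(−α/2); the uniform (affine-minus-similarity,
2-dimensional) component is appended when included. Relative warps are the
principal components of the resulting weight matrix. Defaults α = 0 with
the uniform component included — the common default of the relative-warp
software lineage — under which the warp scores coincide exactly with a PCA
of the tangent-space residuals, and RW variances sum to the total
Procrustes variance. Deformation grids are exported as numeric
displacement fields, not images.

## Synthetic benchmark

The generator emulates the study conditions of the five-barb problem:
per-species sample sizes (18, 20, 9, 20, 11 — 78 specimens), standard
lengths drawn log-normally with the published per-species means and SDs
(delta-method conversion to log10 parameters), meristic counts as rounded
truncated Gaussians with the published means/SDs (Poisson cannot honor the
zero SDs of invariant fin-ray counts), and five hand-built mean outlines
differing at landmarks 3, 4, 5 and 8 with isotropic landmark noise
(default SD 0.01 body lengths, a typical digitizing + within-species
figure; the parameter-recovery tests use 0.001, the "small noise" regime).
Allometry is realized radially — landmark l sits at r_l · s^{b_l} from the
centroid — so per-edge growth exponents are exact when both endpoints
share b and approximate otherwise. The drawn (noise-free) SL of every
specimen is kept as `dataset.ground_truth["sl"]` for recovery checks.

What passing tests on this benchmark show: the pipeline's algebra,
calibration (ANOVA type-I error, chance-level LOOCV), and its ability to
recover planted structure (slopes, displaced landmarks, full separability
at high separation). What they do not show: performance on real images —
the generator has no digitizing operator effects, no arching/bending of
preserved specimens, no sexual dimorphism, and its within-species shape
noise is isotropic and landmark-independent, which real data are not.

## Numerical conventions

Eigen-decompositions use symmetric solvers with descending sort and
deterministic sign fixes; classification ties break on group label; UPGMA
ties break lexicographically; generator output is byte-identical for a
fixed seed; report CSV/JSON outputs are byte-identical across identical
runs (stage wall-times live only in the manifest). Chance-level
classification is measured with leave-one-out, not resubstitution:
resubstitution on pure noise is optimistically biased well above 1/k at
small n/p, which is precisely the bias the Lachenbruch procedure exists to
remove.

## Problem sizes

Default test and acceptance runs use the published sample sizes (n = 78)
for the benchmark, 100 specimens for the high-separation run, 40 × 50
specimens for the chance simulation, 500–1000 replicates for the ANOVA
calibration and n = 200 for slope recovery; the full suite runs in well
under a minute on one CPU.

## Known limitations

- Tukey's-b subsets for heavily unbalanced designs follow the
  harmonic-mean convention; other software may differ in edge cases.
- Mahalanobis d² under the ridge fallback is ordinal (see above).
- The replication tests against the study's deposited raw spreadsheets run
  only when those files are supplied under `data/`.
- 2-D landmarks only; no sliding semilandmarks.
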