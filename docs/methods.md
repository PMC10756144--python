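# Methods

`morphodelim` implements a numeric-morphometry species-delimitation
workflow for nest-structured insect samples: size correction, unsupervised
hypothesis formation over nest centroids, and confirmatory discriminant
analysis. This note describes the statistical model behind each stage, the
defaults and why they were chosen, and what the synthetic-data generator
does and does not emulate.

## Data model

A specimen is a vector of linear measurements in µm together with its nest
(colony), caste and provenance (`direct` measurement, collection-image
derived, or drawing derived). Two observer protocols are packaged: the SC
system (absolute traits, size character CL1 = maximum cephalic length) and
the BS system (trait/size indices, size character CS = (CL2 + CW)/2).
Synonym codes that denote the same anatomical measure in the two protocols
(`CWB` ≡ `CW`, `CLYD` ≡ `CLSPD`) are configurable aliases on the character
system, not hard-coded renames. `CLYW` and `PEL` are carried as opaque
codes; the package does not guess their anatomy. Castes are never mixed
within one analysis: worker and gyne allometries differ qualitatively, so
mixing them is rejected as an error.

All storage is in µm. Literature values quoted in mm enter only through two
explicit conversion operations: maximum head width from a reported "head
width before eyes" (default factor 1.148) and clypeal-dent distance from a
drawing-derived CLSPD/CW ratio.

## Removal of allometric variance (RAV)

Body size in ants is largely an environmental (nutritional) signal, and
shape changes disproportionately with size. RAV approximates the
genetically determined character space by stripping the linear size trend.
Two procedures are implemented.

**Nest-wise residuals** (SC style). Within every nest with at least
`min_nest_n` complete records (default 3 — ordinary least squares needs 2
points, and 3 guards against exact-fit artifacts) each trait is regressed
on the size character; the final line is the unweighted mean of the
per-nest slopes and intercepts, and corrected values are residuals in µm.
Nests excluded as too small or size-degenerate are counted per trait in the
model metadata, never silently dropped. This procedure needs no species
hypothesis but lets unevenly sampled species contribute unevenly.

**Index quotient** (BS style). Each shape index (CL2/CW and trait/CS) is
regressed on CS *within each hypothesised species*, and the final line is
the unweighted species mean, giving each species equal weight. The
corrected index is

    corrected = observed / f(CS) × f(CS_ref),

the index value the specimen would show at a common reference head size
(480 µm for workers, 850 µm for gynes). At CS = CS_ref the correction is
exactly the identity. The published coefficient sets for both castes (16
index functions each) and the 14 SC residual lines are packaged and
retrievable without fitting. The index lines are dimensionally consistent
only with CS in millimetres (f(0.480) = 1.1685 for CL2/CW); the API stores
µm and converts internally. Single-species index fitting is permitted but
must be requested explicitly (`allow_single_species=True`), mirroring the
situation where only one species has enough gynes.

Two of the 32 packaged index functions carry digit-level misprints in their
source constants: for the worker PPH line and the gyne MH line the trailing
multiplier printed with the function does not equal slope·reference +
intercept (0.3053 vs 0.3006, and 1.2955 vs 1.2854). The package stores both
the coefficients and the printed multiplier verbatim, but the correction
always uses the multiplier *computed* from slope and intercept, which keeps
the identity-at-reference-size property exact for every character.

## Exploratory stage: nest-centroid clustering

Specimen-level data are averaged to **nest centroids** (the nest is the
sampling unit; centroids suppress within-colony noise, including worker
size dimorphism). Over centroids the package builds Euclidean distance
matrices, UPGMA and Ward dendrograms (exported as Newick with branch
lengths equal to merge-height differences), k-means partitions, and
nonmetric MDS embeddings (SMACOF minimizing Kruskal stress-1, best of
seeded restarts).

The number of biologically meaningful clusters is estimated by **PART**, a
recursive procedure: test the current item set for substructure; if
substructure is found and every resulting subcluster has at least
`min_size` items (default 5), split and recurse, otherwise stop. A
proposed split that violates `min_size` is rejected entirely — the simplest
rule consistent with a minimum-cluster-size constraint. Substructure is
tested with the **gap statistic**: gap(k) = mean_ref log W_k − log W_k,
where W_k is the within-cluster dispersion of the base clustering and the
reference datasets (`b` of them, default 1000) are drawn uniformly in the
principal-component-aligned bounding box of the data; k is chosen by the
one-standard-error rule (smallest k with gap(k) ≥ gap(k+1) − s_{k+1}).

Two base clusterings are available inside PART: cutting the UPGMA tree at
the candidate k (`hclust`) and seeded k-means (`kmeans`, Lloyd's algorithm,
best of `n_init` starts). The pipeline default is `kmeans`: cutting an
average-linkage tree at k = 2 is sensitive to single outlying nests (the
first cut tends to split one extreme centroid off), which can hide a
genuine two-species split from the gap test, whereas the k-means base
recovers it reliably on data of the study's structure. Both bases are
implemented and tested.

Distances over mixed feature sets are z-standardized by default in the
pipeline. The clustering feature matrix appends CS (hundreds of µm) to
corrected indices (order 0.01–2); without standardization the size column
dominates Euclidean distance and the shape signal is lost. The low-level
`euclidean_distances` keeps standardization off by default so that callers
working with homogeneous residuals in µm get plain distances.

Every stochastic operation takes an explicit seed; composite procedures
derive child seeds deterministically from a master seed
(`numpy.random.SeedSequence`), so a fixed configuration and seed reproduce
a byte-identical report.

## Ordination

PCA is computed by singular value decomposition of the centered (optionally
scaled) matrix — covariance PCA by default, since residuals share µm units;
correlation PCA is available for mixed-scale inputs. The sign of each
loading vector is fixed by making its largest-magnitude element positive,
so results are deterministic. Type specimens and other new items are
projected onto a stored ordination with the training centering and scaling.

## Confirmatory stage: discriminant analysis

The exploratory clusters become candidate species labels, tested on
individual specimens by Fisher two-class LDA. The fitted direction is
w = S⁻¹(μ₊ − μ₋) with S the pooled within-class covariance, rescaled so
the pooled within-class score SD is 1, and offset so the two class score
means are symmetric about zero. Priors default to equal — consistent with
symmetric published class means despite unequal sample sizes — with
proportional priors as an option.

Validation is leave-one-out: each specimen is classified by a model fitted
without it, summarized in a confusion matrix with per-class percent correct
(reported to one decimal) and overall accuracy, which the package reports
separately rather than as a single "probability".

**Wild-cards** — typically name-bearing type specimens — are excluded from
all fitting and classified post hoc by Gaussian class-conditional
posteriors with the pooled covariance; a query that is also a training item
is rejected. Posteriors are invariant to affine rescaling of any input
character.

**Backward stepwise reduction** builds compact numeric keys: at each step
the character whose removal maximizes LOO accuracy is dropped (ties broken
by the smallest absolute standardized coefficient), down to a target count.
The two published keys are packaged with their printed constants: the
three-character worker key D3 = 0.060·ML − 0.047·CWB − 0.125·CLYW − 4.582
(µm) and the two-character gyne key 35.24·CW − 58.91·CLSPD − 22.59 (mm),
each with its printed class score ranges. The evaluator converts between
stored µm and a key's native units automatically. The published offsets
encode the original authors' convention and cannot be re-derived without
their raw data; the packaged keys therefore bypass fitting entirely.

## Synthetic data generator

The generator draws what the analyses assume: species → nest → specimen.
Each species has a grand mean size; every nest adds a Gaussian size effect
(shared larval nutrition), every specimen adds individual size noise, and
size can optionally follow a two-mode mixture (worker or gyne size
dimorphism). Every character is linear in size,
char = intercept + slope·size + N(0, σ), which is exactly the linear
allometry the RAV procedures remove. For CS-based systems CL2 and CW are
generated through a head-shape ratio line so that the computed CS equals
the latent size exactly. Values are kept positive by resampling the
specimen (not truncating), so moments stay on target; configurations that
would make non-positive sizes more than 1% likely are rejected.

The packaged two-species worker scenario uses 25 + 16 nests of 3–5 workers
with species sizes 491 ± 67 and 460 ± 48 µm CS; per-character lines are
derived from the published index functions and the per-species corrected
index means, so that after RAV the simulated indices reproduce the
published per-species means and SDs, and raw indices show the published
size dependence. The between-nest share of size variance is not reported
for the real material; the default sets between-nest SD to half the total
size SD (flagged in the config). The gyne scenario (897 ± 29 vs 798 ± 11 µm
CS) switches on the size mixture for the larger species (modes 905 and
825 µm, weight 0.9, preserving the target moments) so that its microgynes
overlap the other species' macrogynes — the configuration that makes size
alone useless and shape decisive. A one-species null scenario is the
negative control for cluster-number estimation.

What the generator does **not** emulate: character-level nest effects
(nests shift only size, not shape), measurement-system differences between
observers beyond character availability, non-linear (log–log) allometry,
and correlated residuals between characters. Passing recovery tests on
this generator therefore shows that the pipeline recovers the published
two-species structure *under the model the analyses assume*; it does not
certify performance on shape-correlated colony effects the model omits.

## Problem sizes and numerical choices

Recovery tests run the packaged scenarios at the study's own sample sizes
(41 nests, ~160 workers) over 10 seeds with the gap statistic at b = 100
bootstrap references, a size at which the procedure's decisions are already
stable; b = 1000 remains the analysis default. Degenerate inputs are
handled explicitly: all-identical data choose k = 1 with a warning;
constant columns make standardization and correlation PCA fail with the
column named; a singular pooled covariance raises with the advice to reduce
the character set; LDA classes with identical means are flagged as
degenerate rather than returning an arbitrary direction. k-means ties are
resolved by the seeded best-of-`n_init` rule; agglomeration ties follow the
deterministic scipy ordering.

## Limitations

- Only two-class LDA is provided (the delimitation question here is
  pairwise); no quadratic or regularized discriminants.
- No bootstrap support values on dendrograms and no model-based
  (mixture-model) clustering.
- The index RAV assumes a linear index–size relation; strongly curved
  allometries would need a transform before fitting.
- Published-constant evaluation inherits the two documented misprints in
  the source constants (PPH worker, MH gyne); their corrected values cannot
  be recovered from print.
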