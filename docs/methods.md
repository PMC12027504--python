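# Methods

This note documents the models, conventions and numerical choices
behind `chctax`, and what its synthetic data can and cannot show.

## Compound model and nomenclature

Compounds are restricted to the four classes observed on beetle elytra:
n-alkanes, monoenes, monomethyl- and dimethyl-alkanes. Labels follow
the field's shorthand (`n-C_25`, `9-C_27:1`, `3-meC_25`,
`9,13-dimeC_29`); an unknown branch position is written `X`, kept
explicit, and excluded from any mass prediction rather than imputed.
Double-bond positions are stored as named — numbered from the nearer
chain terminus — and are **not** canonicalised to IUPAC lowest-locant
numbering, because the DMDS arithmetic consumes the nearer-terminus
position directly. For the same reason `locate_double_bond` searches
only 2 ≤ d ≤ chain/2: a position beyond the midpoint names the same
molecule from the far end, and admitting both would make every
spectrum spuriously "ambiguous".

The bundled catalog records one published naming conflict (peak 25:
7-hentriacontene in the sex-resolved table, 9-hentriacontene in the
population table); the sex-resolved name is the default and the
alternative is kept in `ALT_LABELS`.

## Fragment prediction

All masses are nominal integers (C = 12, H = 1, S = 32; CH₂ = 14).
Saturated compounds with T total carbons have M = 14·T + 2, monoenes
14·T. For branched alkanes, every bond flanking a branch carbon is
cleaved and **both** charged fragments are emitted in both mass
parities (14·m for the even, H-transfer series; 14·m + 1 for the alkyl
cation), because published tables mix the two; matching is therefore
subset-based, never exact-set. M−15 is always emitted, M−29 only when
a methyl sits on carbon 3. The homologous alkene series ions 83/97/111
are treated as a fixed class signature for monoenes — they are
position-uninformative — and enter peak annotation as such.

Three published diagnostic ions cannot be produced by any single C–C
cleavage under these rules: 436 for 7-methylhentriacontane (this is
the molecular mass of unbranched C31, while the compound's M is 450
and M−15 is 435) and 126/168 for 5,17-dimethylhentriacontane (9- and
12-carbon fragments no bond flanking carbon 5 or 17 yields; plausibly
secondary fragments or co-elution). They are recorded verbatim in the
catalog's `UNEXPLAINED_IONS` registry and excluded from prediction;
the subset tests assert that the unexplained set is exactly this
registry, so a regression in the rules cannot hide behind it. The
ion 71 printed for 7-nonacosene is handled the same way.

The unit tests check the closed-form rules against an independent
brute-force oracle that builds the explicit carbon skeleton, cleaves
every bond, and sums atomic masses.

## Retention indices

Linear (temperature-programmed) interpolation is used:
RI = 100·n + 100·k·(t − tₙ)/(tₙ₊ₖ − tₙ), with k > 1 spanning gaps in
the standard mix, rounded half-up to an integer (all published indices
are integers). Logarithmic isothermal interpolation does **not**
reproduce the published values; linear does, so it is the only mode
offered. The ladder is built from the n-alkanes identified *in the
sample* (C25–C30); this in-sample ladder reproduces all 30 published
indices to ±1 unit (29 exactly; one is off by one unit, consistent
with the two-decimal truncation of the printed retention times).
Peaks eluting outside the ladder raise by default; nearest-segment
linear extrapolation must be requested explicitly
(`extrapolate=True`), and with it the out-of-range published indices
(2480, 3073, …) are also recovered.

## Profiles and univariate statistics

Relative percentages come from area normalization
(100·areaᵢ/Σarea); percentage-only input is accepted and renormalised.
"nd" (not detected) is an exact zero with a detection flag — absence,
not missingness — so distances and coding treat it as 0. Sex contrasts
default to Student's equal-variance t (Welch by option). Population
contrasts use one-way ANOVA followed by a Student–Newman–Keuls
stepwise range procedure on the ordered means, with studentized-range
critical values at α = 0.05 and the Kramer ½(1/nᵢ + 1/nⱼ) adjustment
for unequal n; compact letters mark the maximal homogeneous stretches.

The overall class percentages quoted for the species
(42.3/25.8/22.3/9.2 for n-alkanes/alkenes/monomethyl/dimethyl) are not
exactly recoverable from the published sex means under any weighting
tried; the closest reconstruction — sample-size-weighted male/female
means (N = 30/28) — gives 42.9/26.1/22.1/9.0, and the test asserts
agreement within ±1.5 points rather than forcing equality.

## Multivariate comparison

Individual-level analyses run on relative percentages, never on
ordinal codes. Bray–Curtis is computed on rows of the profile matrix.
NMDS delegates to scikit-learn's non-metric MDS with monotone
regression; stress is Kruskal stress-1 in [0, 1], the best of 20
random starts (default) is kept, and the seed is recorded in the
result. PERMANOVA uses Anderson's distance-based one-way formulation
(equivalent to Gower-centering the squared distance matrix):
SS_total = Σ_{i<j} d²ᵢⱼ/n, SS_within from within-group pairs, pseudo-F
with (k−1, n−k) degrees of freedom, R² = SS_among/SS_total, and
p = (b+1)/(n_perm+1) from free label permutation (999 by default),
bit-reproducible given a seed. Note that when all pairwise distances
are equal the statistic degenerates to F = 1, p = 1 with
R² = (k−1)/(n−1), not R² = 0.

## Chemotaxonomic trees

Taxon-level trees are built from the ordinal-coded matrix (the stated
character matrix), with a flag-free escape hatch: any taxa × components
matrix, including raw mean percentages, can be passed to the same
distance/UPGMA path. The coding bins leave their boundaries ambiguous
in the published wording ("<0.5; 0.5–1; 1–5; >5"); the convention here
is [0.5, 1) → 2, [1, 5] → 3, (5, ∞) → 4, chosen so every rounded
published mean codes unambiguously, and it is overridable through
`CodingScheme`.

UPGMA merges the closest pair, averages distances weighted by cluster
size, and sets node height to half the merge distance; ties are broken
by the lexicographically smallest pair of smallest member labels, so
trees are deterministic. Output is ultrametric by construction and
asserted. Newick serialisation is canonical (children ordered by
smallest leaf name) with heights quantised to 9 decimal places and
branch lengths produced by exact decimal subtraction, which makes
write → read → write byte-stable. Robinson–Foulds distances count the
non-trivial unrooted bipartitions present in exactly one tree, with a
normalised variant dividing by the total bipartition count of both
trees; external trees are parsed with scikit-bio and the
implementation is tested against dendropy and an exhaustive
bipartition oracle.

## Synthetic data generator

The generator emulates the study design: six populations (MJHL, WDLN,
GHIM, YCHL, EDJL, ARIM) with the published component means ± SE as
defaults and the published sample sizes (10, 12, 10, 8, 12, 6; the
smallest reflects limited field availability), a 1:1 sex ratio, and a
0.01 % detection threshold that censors trace components to nd before
renormalisation. Each individual's composition is a logistic-normal
perturbation of the population mean,
wᵢ = mᵢ·exp(σᵢεᵢ − σᵢ²/2), p = 100·w/Σw, with independent εᵢ ~ N(0,1).
A logistic-normal was preferred over a Dirichlet because the published
SEs are not consistent with a single concentration parameter; per-
component σᵢ can match each SE individually. Raw areas are the
composition times a lognormal total-area scalar (CV 0.3), so area
normalization is genuinely exercised. Fixed seed ⇒ byte-identical
output.

σᵢ is calibrated by bisection so that sd(pᵢ) across individuals equals
SEᵢ·√nᵢ. The sd response is evaluated by deterministic
Gaussian-quantile quadrature (4096 points) of pᵢ with the remaining
components held at their mean total. This choice matters: the
lognormal's extreme upper tail makes a random-draw estimate of the
achievable sd unstable for trace components whose SE is of the order
of their mean, whereas the quantile grid caps the tail at what a
finite cohort can realise and yields a smooth, stream-independent
response. The response rises with σ, peaks, and then collapses as the
distribution degenerates; bisection runs on the rising branch, and a
target above the peak raises a configuration error (an SE that the
logistic-normal family cannot realise at that mean).

What the generator does *not* emulate: within-individual covariance
between components (unreported; perturbations are independent),
retention-time drift between runs, detector saturation, and
chromatographic co-elution. Passing tests therefore demonstrate that
the analysis pipeline behaves correctly on data with the published
first- and second-moment structure, not that it is robust to every
artefact of real chromatograms.

## Problem sizes in the statistical checks

The statistical acceptance checks use 500 null replicates (one
common-mean population of 24 individuals, six arbitrary labels, 199
permutations — α·(n_perm+1) is an integer, so the permutation test is
exact at α = 0.05) and 50 power replicates of the full six-population
design at 999 permutations; the whole suite runs in well under a
minute on one core.

## Known limitations

- Only monoenes are modelled; dienes, trienes and oxygenated lipids
  are out of scope, as are E/Z stereochemistry and intensity
  prediction.
- Peak annotation ranks candidates by ion-subset evidence within a
  retention-index window; it does not perform spectral library
  matching.
- PERMANOVA is one-way with free permutation; there is no PERMDISP
  companion, so location and dispersion effects are confounded as in
  any PERMANOVA.
- The published individual-level ordination stress values cannot be
  reproduced because individual profiles are not published; NMDS is
  validated on recoverable configurations instead.
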