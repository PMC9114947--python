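# Methods

This note records the models, conventions and numerical choices behind
`epiclover`, in the spirit of a statistical package's model
documentation. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

All analyses operate on complete binary presence/absence matrices
(individuals × dominant markers). Missing fragment calls are not
representable: every downstream formula (band frequencies, squared
Euclidean distances, entropy) assumes complete data, so unclear samples
must be re-run or dropped upstream, which mirrors how fragment data are
produced in practice. Sample order is authoritative from the metadata
file; marker matrices are re-indexed to it so that genetic and
epigenetic distance matrices align row-for-row.

CSV with comma separator and "." decimal point is the canonical
dialect; ";" and tab are accepted as options. Result tables are written
with 12 significant digits, which round-trips integers exactly and
reals to ~5e-12 relative error.

## Subepilocus scoring (mixed scoring 2)

Each MSAP fragment yields three candidate indicator columns (u, m, h).
An individual scores 1 in exactly the column matching its state —
(HpaII, MspI) = (1,1) → u, (0,1) → m, (1,0) → h — and 0 elsewhere;
(0,0) individuals are uninformative and score 0 in all three. Only
columns that are all-zero across every individual are dropped;
monomorphic *present* columns are retained. Rationale: per-population
polymorphic percentages in real band data sit well below 100%, so the
scored set must contain monomorphic markers; dropping only empty
columns is the weakest defensible filter. Whether published marker
counts excluded monomorphic-present columns cannot be confirmed without
raw data; this drop rule is recorded as an assumption.

Because states are mutually exclusive, the scoring is invertible:
`reconstruct_profiles` rebuilds the exact (HpaII, MspI) call pairs, and
the test suite exercises this round trip on random and simulated
profiles.

The genotyping error rate compares cells (fragment × replicated
individual) between original and replicate matrices and reports
100 × mismatches / compared cells — one percentage per marker system,
averaged over all replicated individuals.

## Diversity

The Shannon information index per marker is the two-state entropy
−[p·log₂p + (1−p)·log₂(1−p)] of the band frequency, with 0·log₂0 ≡ 0,
averaged over all markers (monomorphic markers contribute 0). The
one-term reading −p·log₂p caps at 1/(e·ln2) ≈ 0.531, which published
per-population values for u-subepiloci exceed; only the two-term
entropy is consistent with such values, so it is the implemented
definition.

Polymorphism uses no minor-frequency threshold: with 16 individuals a
1/16 variant counts. "Private" means present in the focal population
and absent from every other. The table's `s.e.` row is the sample
standard deviation across populations divided by √(number of
populations).

## AMOVA

Distances are squared Euclidean on 0/1 band data — the number of
differing markers. For a partition into G groups, K populations,
N individuals:

    SS_total = (1/N) Σ_{i<j} d_ij
    SS_WP    = Σ_pops (1/n_k) Σ_{i<j∈k} d_ij
    SS_AP    = Σ_groups (1/N_g) Σ_{i<j∈g} d_ij − SS_WP
    SS_AG    = SS_total − SS_WP − SS_AP

with df (G−1, K−G, N−K) and MS = SS/df. Variance components use the
unequal-size coefficients

    n′  = (N − Σ_g Σ_{k∈g} n_k²/N_g) / (K−G)
    n″  = (Σ_g Σ_{k∈g} n_k²/N_g − Σ_k n_k²/N) / (G−1)
    n‴  = (N − Σ_g N_g²/N) / (G−1)

so Vc = MS_WP, Vb = (MS_AP − Vc)/n′, Va = (MS_AG − Vc − n″·Vb)/n‴. For
the balanced 2×5×16 design these reduce to n′ = n″ = 16, n‴ = 80
(asserted in closed form by the tests). Negative component estimates
are truncated to zero before percentages and Φ — the convention of the
standard band-data AMOVA tools, which report non-negative components.

Permutation p-values use the (b+1)/(m+1) estimator (never returns 0;
the observed arrangement effectively counts itself). Each Φ statistic
has its own scheme: Φ_PT shuffles individuals across all populations,
Φ_RT shuffles whole populations among groups, Φ_PR shuffles individuals
among populations within their group. Each statistic draws from its own
spawned RNG stream so single-statistic runs reproduce multi-statistic
runs. Degenerate input (all individuals identical) reports Φ = 0 with a
warning rather than NaN.

Pairwise population Φ_PT runs a one-level AMOVA per population pair;
its p-values are computed but nothing downstream consumes them — the
Φ_PT values themselves serve as the differentiation distance matrix for
the matrix tests.

Edge case: with exactly one population per group (K = G) the
among-population stratum has zero df; the model then reports that row
with SS = 0 and falls back to a one-level group decomposition for Va.

## Matrix tests

Geographic distances are haversine great circles with Earth radius
6371.0088 km on unprojected coordinates; at a ~100 km study extent the
difference from any projected planar distance is negligible. Habitat
dissimilarity codes cross-habitat pairs 1, same-habitat pairs 0.

The Mantel statistic is the Pearson correlation of the n(n−1)/2
upper-triangle entries. Significance permutes rows and columns of the
**first** matrix jointly and is **upper-tail by default** (positive
association), matching the convention of the ecology packages this
workflow descends from — large p-values for negative r are exactly what
an upper-tail test produces. A `two_sided` tail and an exact mode
(full enumeration of all n! relabelings, feasible to n = 7) are
available; the exact mode includes the identity, giving p ≥ 1/n!.

The partial Mantel statistic is the first-order partial correlation
r_AB·C = (r_AB − r_AC·r_BC)/√((1−r_AC²)(1−r_BC²)); A is permuted and
r_AB, r_AC recomputed each time while r_BC stays fixed. |r_AC| = 1 or
|r_BC| = 1 is rejected as degenerate conditioning.

MMRR unfolds each matrix to its upper-triangle vector, centres and
scales each to unit standard deviation, and fits OLS with intercept.
Coefficient significance is two-tailed on |t|, the overall F
upper-tailed, both by permuting the response matrix. With one predictor
the standardized coefficient *is* the Mantel r (both are correlations
of standardized unfolded vectors) — asserted numerically in the tests.
Predictor collinearity (condition number > 1e8) is rejected, naming the
offending pair. A perfect fit (zero residual variance) reports infinite
t and F rather than dividing by zero.

## Group statistics

Two-sample comparisons default to Welch's unequal-variance t — the
modern default of the statistical environments this analysis style uses
— with "if necessary" operationalized as a Shapiro–Wilk screen at
α = 0.05 on each group: if either fails, the Wilcoxon–Mann–Whitney test
(exact when sample sizes permit) runs instead, and the chosen branch is
logged so either can be audited. Both-groups-constant-and-equal returns
p = 1 with a warning; zero-variance paired differences are an error.
Pearson correlation uses the two-sided t transform on n−2 df. Spearman
is computed alongside Pearson for the genetic-vs-epigenetic diversity
association, since rank and linear versions of that correlation are
both in circulation for this analysis; the pipeline reports both and
asserts neither. No multiple-testing correction is applied by default
(a Bonferroni helper exists).

## Ellenberg indicator values

Per site: Σ(abundance × EIV)/Σ(abundance) over species with a numeric
value for the indicator; indifferent ("x") or unmatched species are
excluded from both sums, with unmatched names logged rather than
silently dropped. Abundances are used on whatever cover scale is
supplied — the weighted-mean formulation is scale-invariant under
common multipliers, and the field's surveys use several ordinal and
percentage scales interchangeably.

## Synthetic data generator

The generator emulates the study conditions of the reference design:
2 habitats × 5 populations × 16 individuals, 124 AFLP loci, 159 MSAP
fragments. Band presence is simulated directly at the band (phenotype)
level rather than through diploid dominant genetics: every downstream
statistic operates on band presence, and the band-level model keeps the
ground truth interpretable on the Φ scale.

Frequencies drift hierarchically: ancestral band frequency per locus
~ Uniform(0.1, 0.9); group frequency ~ Beta with mean p and variance
θ_group·p(1−p) (Balding–Nichols); population frequency likewise around
the group frequency with θ_pop. θ = 0 passes frequencies through
unchanged. This closed-form variance link makes θ directly the
Φ-differentiation target: the acceptance suite verifies that mean
estimated Φ_PT over 50 replicates at full design size lands within
±0.02 of θ for θ ∈ {0.05, 0.10, 0.20}. Defaults θ_pop = 0.05,
θ_group = 0.02 put the global Φ_PT near 0.07, the weak-differentiation
regime of the study system.

MSAP fragments share the presence model; present fragments draw a
(u, m, h) state from softmax logits composed of per-fragment baselines
N(0, 0.7), population-level drift N(0, `state_drift_sd` = 0.2), a
`habitat_methylation_shift` (default 0.5 log-odds) added to the m state
in the second habitat (meadows methylation-richer), and an environment
effect: logits are multiplied by exp(−`env_effect`·z_moisture), so
wetter sites have flatter state distributions and higher epiallele
diversity (default `env_effect` = 0.3). States emit calls u→(1,1),
m→(0,1), h→(1,0), absent→(0,0), and the emitted pairs round-trip
through state classification exactly.

Sites are scattered in a ~100 × 60 km box with alternating habitats;
covariates draw from habitat-specific normals (sd 0.25) centred on the
published habitat-level indicator means (CG: L 7.45, M 3.43, R 7.63,
N 2.69; OM: L 7.04, M 4.86, R 6.94, N 5.29), so simulated group
contrasts run in the observed directions. The relevé generator weights
a 25-species synthetic pool by proximity of each species' indicator
profile to the site's covariates, so abundance-weighted indicator means
approximately recover the site table. `ibd_strength` ∈ [0, 1] is the
fraction of population drift variance carried by a shared spatial
Gaussian field with 30 km correlation range (0 = independent Beta
drift, the default — the reference system shows no isolation by
distance).

What the generator does **not** emulate: linkage between loci,
genotype–epigenotype dependence (states are independent of the AFLP
draw, i.e. "pure" epigenetic variation), fragment-size homoplasy,
scoring noise, or seed-bank/pollination dynamics. Passing tests
therefore demonstrate correctness and calibration of the estimators
under a clean band-frequency model, not robustness to those real-data
complications.

## Calibration and problem sizes

Null calibration runs 500 exchangeable replicates with 199 permutations
per test and checks the rejection rate at α = 0.05 against the binomial
95% interval [0.031, 0.069]. Sizes were chosen as the smallest designs
that exercise every stratum: 10 random sites for Mantel/MMRR; 2 groups
× 3 populations × 6 individuals × 40 markers for Φ_PT/Φ_PR; 2 × 5 × 4
for Φ_RT (ten populations keep its permutation space, group
reassignments of whole populations, rich enough for a 5% tail).
Parameter recovery uses the full 160-individual design. The acceptance
script re-derives all of these from its `--seed`.

## Known limitations

- Two hierarchy levels only (group / population / individual); no
  three-level designs or model-based sequence distances.
- Exact Mantel enumeration is capped at n = 7 (5040 relabelings).
- The habitat-dissimilarity Mantel treats the 0/1 matrix like any
  distance matrix; its permutation distribution is highly discrete at
  10 sites, which is inherent to the design, not the implementation.
- Fragment-to-locus binning of raw electropherograms is upstream of
  this package; inputs are assumed already binned and binary.
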