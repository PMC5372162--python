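# Methods

## The inference problem

A guild of obligate exosymbionts (here: *Trapezia* crabs and *Alpheus
lottini* snapping-shrimp lineages) occupies a population of coral colonies.
The data are a binary occupancy matrix: N colonies × S species, cell 1 when
the species was found in the colony. Observed summaries — how many colonies
host exactly k species, how often two species share a colony, how often a
species lives alone — are compared to their distributions under null models
of random assembly. Non-random structure (attraction, repulsion,
monopolisation) is inferred when an observed count falls outside the central
95% interval of the null distribution.

Analyses are always run within a stratum (region × stage × host type),
never pooled, because species pools differ between regions and host types.
The packaged survey defines five analysis strata of 61, 48, 11, 56 and 40
colonies; the key-species set has exactly 5 members, chosen as the species
that drive compositional differences.

## Null models

All three models randomize the stratum's N × 5 key-species matrix and are
sampled by Monte Carlo (default 10,000 replicates):

* **M1 — unconstrained.** The observed grand total F of presences is placed
  uniformly at random over the N·S cells without replacement. Design choice:
  "unconstrained" is ambiguous in the literature; conditioning on F keeps
  every statistic on the observed scale while leaving both margins free. A
  per-cell Bernoulli(F/(N·S)) variant is available
  (`NullModelConfig(m1_variant="bernoulli")`).
* **M2 — frequency.** Each species keeps its observed occurrence count f_s;
  the f_s presences go to f_s distinct colonies chosen uniformly
  (independently per species). Column sums exact, row sums free.
* **M3 — richness.** Each colony keeps its observed species count r_i; the
  r_i presences go to r_i distinct species chosen uniformly (independently
  per colony). Row sums exact, column sums free. M3 makes every richness
  class n_k degenerate, so it is applied to co-occurrence and solitary
  statistics only.

A fixed-fixed (both-margin) swap algorithm is deliberately out of scope.

**Confidence intervals.** Count statistics are integers, so interval
endpoints use type-1 (inverse-ECDF) empirical quantiles at (1−level)/2 and
1−(1−level)/2: endpoints are attained sample values, and no interpolation
manufactures non-integer bounds. An observed value equal to an endpoint is
"inside" — rejection requires falling strictly outside the interval. With
reps = 1 the interval degenerates to the single sample.

**Reproducibility.** Randomization uses counter-based Philox streams keyed
on (master seed, replicate index), so results are bit-identical for a given
seed regardless of evaluation order, and all statistics of a run share the
same replicate stream (adding a statistic never perturbs another's samples).

**Known indeterminacy.** Published analyses of this kind rarely pin down the
exact "unconstrained" randomization, and printed interval endpoints can
disagree across reasonable readings (our frequency-model intervals coincide
with intervals elsewhere attributed to an unconstrained model). We therefore
treat *observed* counts as the reproducible quantities and validate the
interval machinery by construction — uniformity, margin conservation,
coverage, type-I error and power (below) — rather than against printed CI
endpoints.

## Guild statistics

For the 5-species stratum matrix (all colonies kept as rows, including
colonies hosting no key species — they can gain presences under M1/M2;
a switch restricts the analysis to occupied colonies only):

* richness profile n_k, k = 0..5, with Σ n_k = N and Σ k·n_k = Σ f_s.
  Non-key residents never count toward k. n_0 is reported but marked
  informational. Richness is compared under M1 and M2.
* pairwise counts c_ij = column inner products (c_ii = f_i, c_ij ≤
  min(f_i, f_j)), and solitary counts s_i (colonies where i is the only key
  species). Compared under M1, M2 and M3.

## Ordination and group tests

Correspondence analysis is computed classically: correspondence matrix
P = X/n, standardized residuals S = D_r^{−1/2}(P − rcᵀ)D_c^{−1/2}, SVD of S;
principal inertias are squared singular values and sum to the Pearson
χ²/n of the table; principal coordinates are scaled by singular values so
full-rank inter-row distances equal chi-square distances between row
profiles. Empty rows/columns are dropped first (chi-square profiles are
undefined for them); tables with fewer than two non-empty rows or columns
are rejected. A table of proportional rows legitimately has zero inertia
(axis percentages are then reported as zeros).

ANOSIM follows Clarke: midranks of the M = n(n−1)/2 dissimilarities,
R = (mean between-group rank − mean within-group rank)/(M/2) ∈ [−1, 1], and
a permutation p-value with the +1 correction, p = (1 + #{R* ≥ R})/(1 +
n_perm), so p is never 0. Groups need ≥ 2 members. The default
dissimilarity is Bray–Curtis (the convention of the reference software for
this test); chi-square profile distance is available to match the CA
geometry. Because the published community table records colony counts per
assemblage rather than individuals, the packaged survey's abundance coding
is presence (0/1); axis percentages and R values computed here are
therefore indicative rather than exact reproductions.

## Divergence summaries

p-distance uses pairwise deletion: sites with a gap or N in either sequence
are excluded; zero comparable sites is an error. Net divergence is Nei's
Da = d_XY − (d_X + d_Y)/2 on mean pairwise distances; single-sequence
groups contribute within-distance 0 (flagged by convention), and
Da(X, X) = 0. Distances are uncorrected by default — the simplest
assumption-free reading — with a Jukes–Cantor variant
(`correction="jc69"`) for comparison with model-corrected outputs. Da is
symmetric and never exceeds d_XY.

## Synthetic communities and calibration

The generator draws the 5 key species jointly from a pairwise
exponential-family (auto-logistic) model, P(x) ∝ exp(Σ α_s x_s + Σ_{s<t}
θ_st x_s x_t) over x ∈ {0,1}⁵. With only 32 states, the distribution and
all its moments are computed by explicit enumeration, giving exact oracles
for every downstream statistic; a fixed-point helper solves α to hit target
marginal prevalences (to 1e-6) for any moderate θ. Non-key taxa, which only
matter for ordination realism, are added independently with fixed
probabilities. What the generator does *not* emulate: spatial structure,
temporal recruitment, host-size effects, and abundance variation — so
passing calibration shows the decision procedure is sound for i.i.d.
colonies within a stratum, not that field data meet those assumptions.

Default study conditions mirror the field design: strata of N = 60
colonies, species prevalence 0.4, interaction strength θ = 2 (log-odds) for
the "structured" scenario.

Calibration results recomputed by the test suite and acceptance script, at
the problem sizes chosen for desk-scale runs:

* uniformity of each randomizer over its fully enumerated admissible set
  (matrices up to 12 cells; ≥ 200 draws per admissible state; χ² GOF
  p > 0.001);
* exact margin conservation on every draw (1,000 draws of the 61 × 5
  stratum matrix);
* CI coverage under the M2 null: 500 datasets × 2,000 replicates, nominal
  95%, accepted within [0.91, 0.99] (binomial noise + discreteness);
* per-pair type-I flag rate under θ = 0 (400 datasets × 1,000 replicates,
  N = 60, prevalence 0.4): within [0.01, 0.10] — conservative relative to
  the nominal 5% because ties at integer endpoints count as inside;
* power for an attractive pair at θ = +2: flag "above" in > 70% of 400
  datasets.

## Numerical and design notes

* Incidence is derived from abundance as (abundance > 0); the packaged
  survey stores presence counts of 1 (see `src/coralguild/data/NOTES.md`
  for transcription conventions and ambiguous-row readings).
* Colony rows keep input order, taxon columns keep taxon-set declaration
  order; indices are 0-based.
* Juvenile/adult size conventions (≤ 5 cm / > 10 cm diameter) produce
  validation warnings, not errors, because sizes are optional. Planar area
  is the ellipse πLl/4 with l ≤ L enforced.
* The CLI is a thin wrapper: exit code 2 for usage errors, 3 for data
  validation; every run logs its seed (drawn from entropy when omitted) and
  writes a JSON config echo next to its outputs.
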