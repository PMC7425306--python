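# Methods

`connectolesion` analyses weighted structural brain networks of a
lesioned (stroke) cohort against healthy controls, end to end: network
construction, proportional thresholding, graph-theoretical metrics with
null-model normalisation, group statistics with permutation-based
multiple-comparison control, and a mechanistic small-world lesion
simulation. Because no imaging data ship with the package, a synthetic
cohort generator reproduces the statistical structure the analysis
assumes; every operating characteristic quoted below is recomputed by
the test-suite or by `scripts/acceptance.py`, never asserted from memory.

## Network construction

Connectivity is encoded as symmetric, zero-diagonal, non-negative
matrices. Edge weights follow the tractography convention

    w(s, t) = counts(s, t) / (V_s + V_t),

streamline counts normalised by the summed volumes (mm³) of the two
regions, symmetrised by averaging with the transpose. The bilateral
parcellation has 41 regions per hemisphere (34 cortical in the
Desikan–Killiany scheme, 6 subcortical nuclei, one brainstem-level
node), 82 in total; intrahemispheric networks are the 41×41 principal
submatrices.

**Proportional thresholding.** A sparsity mask retains the
`round(κ·P)` strongest node pairs (P = n(n−1)/2; rounding half away
from zero; ties broken by upper-triangle lexicographic order so masks
from one reference are nested across densities). Masks are derived from
the *healthy group average* — whole-brain masks from whole-brain
averages, hemispheric masks from the pooled left+right healthy
hemispheres — and applied multiplicatively to every subject, so all
subjects share one topology per density. The default sweep is
κ = 0.20…0.80 in steps of 0.05 (13 levels); local (node- and edge-wise)
analyses use the fixed κ = 0.5 mask.

## Graph metrics

Brain Connectivity Toolbox conventions throughout:

* **q50** — median of the nonzero upper-triangle weights. A median over
  all entries of a sparse matrix would be 0 and uninformative.
* **Global efficiency** — mean over ordered node pairs of 1/d(i,j),
  with d the weighted shortest path on edge lengths 1/w; disconnected
  pairs contribute 0 (the standard convention for possibly fragmented
  thresholded networks).
* **Clustering** — mean Onnela coefficient: weights scaled by the
  network maximum, per-node geometric-mean triangle intensity divided
  by k(k−1); degree-<2 nodes contribute 0. Invariant to global weight
  rescaling.
* **Modularity** — weighted Newman–Girvan Q maximised by Louvain
  (igraph multilevel) with 20 seeded restarts at resolution γ = 1; each
  restart is polished by greedy single-node moves (including moves to a
  fresh singleton) to a local optimum, and a refinement from a random
  partition per restart diversifies the search. The best Q and its
  partition are returned, floored at the trivial one-community
  partition (Q = 0). On toy graphs small enough for exhaustive
  partition search the optimiser attains the global optimum, which the
  test-suite verifies to 1e-10.
* **Node strength** — row sum of weights.

**Null-model normalisation.** Raw efficiency and clustering confound
topology with overall connection strength, so both are reported as
ratios to the mean of an ensemble of random networks that preserve the
degree sequence exactly (Maslov–Sneppen double edge swaps, 10 attempted
swaps per edge, via igraph), the edge-weight multiset exactly (a
permutation of the original weights), and the node-strength sequence
approximately. Weight placement is a greedy rank matching — edges are
repeatedly ranked by the product of their endpoints' residual target
strengths and the largest unassigned weights are placed on the
top-ranked edges, a chunk at a time (default granularity 1/100 of the
edge count, configurable) — followed by an iterative polish: up to 10
sweeps of pairwise weight swaps that reduce the squared strength
error, with an early exit once the relative L2 error is below 2%. On
41-node κ = 0.5 fixtures this achieves ~1% (brain-like weights) to
~3% (heavily tied Watts–Strogatz weights) relative strength error,
within the 5% contract the package tests. The reference ensemble size
is 1000 for a full analysis; desk-scale runs use 30–100 (the
normalised group *differences* the pipeline tests are stable well
below 1000 nulls).

## Synthetic cohorts

The generator emulates a chronic-stroke study: 17 patients (8 with
left-sided lesions) and 21 controls, one connectome each.

**Healthy model.** Nodes of each hemisphere sit on a ring; expected
streamline counts decay exponentially with ring distance
(scale 400 at distance 1, e-folding 1.5), plus 45 fixed strong
long-range shortcut pairs per hemisphere (expected count 300, minimum
span 6) making the profile small-world, plus interhemispheric
connections dominated by homotopic pairs (expected count 220 versus a
distance-decaying heterotopic scale of 25). Counts are negative
binomial (gamma–Poisson) with dispersion α = 0.5. These values were
fixed once so that (a) weighted whole-brain density lands in 0.4–0.8
and (b) healthy group averages are small-world-like under the
degree/strength/weight-preserving normalisation: normalised clustering
1.3–2.7 across the density sweep with normalised efficiency ≈ 0.93–1.0.
Under this null class, normalised efficiency of any geometric or
small-world weight profile plateaus at ≈1 — randomising the placement
of strong weights can only match or improve weighted efficiency — so
small-worldness manifests as clustering above the nulls with efficiency
comparable to them, the classic γ ≫ 1, λ ≈ 1 regime.

**Planted lesion.** Patients' matrices are attenuated multiplicatively:
edges incident to a cortico-subcortical motor target set (pre/postcentral,
superior parietal, superior temporal, insula, caudate, putamen, pallidum,
thalamus) on the lesioned side by 0.50; other ipsilesional edges by the
milder √0.50 ≈ 0.71; contralesional edges by 0.90 (a diaschisis-like
remote effect); and the longest tercile of ipsilesional edges (ring
distance ≥ 14) additionally by 0.25. A per-patient latent severity
(log-normal, σ = 0.15 on the exponent) modulates attenuation depth.
Multiplicative log-normal edge noise (σ = 0.05) is added; with all
factors 1 and noise 0 the patient and control generative distributions
coincide, which the false-positive calibrations rely on. The default
factors were frozen after simulation calibration: 0.50/0.90 give a
decisive ipsilesional q50 deficit and Bonferroni-significant strength
deficits at the five motor regions, and the long-range factor of 0.25
is what makes the normalised-efficiency deficit direction consistent
(milder long-range attenuation leaves the weight-topology organisation
nearly unchanged and the efficiency ratio flat).

**Clinical scores.** The grip-strength difference between hands is
normal with mean 7 kg and SD 6.6 kg (standardised effect vs. zero near
d ≈ 1); UEFM concentrates at its ceiling of 66. By default scores are
independent of planted severity (matching a null clinical association);
`severity_score_corr` couples them through a Gaussian copula when a
detectable association is wanted.

**Seeding.** All randomness flows from one cohort seed; subject *i*
draws from `numpy.random.default_rng([seed, i])` (clinical and
side-assignment streams use reserved indices), a collision-free variant
of a seed+index derivation. A fixed seed reproduces the cohort bit for
bit, and `write_cohort`/`read_cohort` round-trip matrices losslessly
(full-precision reprs, round-trip float parsing).

**What the generator does not emulate.** No lesion geometry, partial
volume effects, tractography biases (gyral bias, distance bias beyond
the planted decay), head motion, or site effects; hemispheric symmetry
is exact in expectation. Passing tests therefore show that the
*pipeline* recovers effects of the planted kind at realistic sample
sizes — not that real tractography data meet the generator's
assumptions.

## Group statistics

**Lesion-status model.** Per-hemisphere summaries (q50, node strength)
are modelled as value ~ side + lesion status (healthy / contralesional /
ipsilesional) with a random intercept per subject (statsmodels MixedLM,
ML estimation on the standardised response — likelihood ratios and
p-values are scale-invariant and the optimizer is better conditioned).
The model is first fitted with the side×status interaction and refitted
without it when the interaction LR test has p ≥ 0.05. The omnibus
lesion-status test is the likelihood-ratio statistic Λ₂ against the
side-only model (χ² with 2 df); a Wald-F approximation (denominator df
= subjects − levels + 1) is reported alongside, and a Shapiro–Wilk p
for the residuals. Post-hoc pairwise mean separations use the
studentized-range (Tukey) adjustment with k = 3. On 200 null cohorts
the omnibus rejects 4–5% at nominal 5%. Optimizer: BFGS with a
fallback cascade (L-BFGS, Powell, Nelder–Mead) since the subject
variance can sit on the boundary.

**MTPC.** Density-swept metrics are tested with multi-threshold
permutation correction: per density, a one-way group F; subjects are
the exchangeable units (each subject's observations swap label blocks
as a unit, curves intact); the critical value A_crit is the 95th
percentile of the permutation distribution of the maximum F across
densities; contiguous supra-critical clusters are significant only if
their statistic-over-density AUC (trapezoid) also exceeds the mean
supra-critical cluster AUC of the permutations. The pooled analysis
first subtracts the healthy-group mean of each (hemisphere, density)
cell, removing side effects shared by all groups, then pools
hemispheres. The permutation statistic is the plain (not mixed) F —
permutation of subject labels guarantees validity, and the test-suite
confirms family-wise error ≤ 9% at nominal 5% and that MTPC is no more
liberal than a per-density Bonferroni scan.

**Mass-univariate nodes.** The lesion-status model per region (main
effect only) with Bonferroni threshold 0.05/41; −log10(p) profiles are
reported for inspection.

**NBS.** Edgewise pooled-variance two-sample t (zero-variance edges
excluded as t = 0), binarised at a primary threshold (default t = 3.1,
one-sided per direction, deficits and excesses run separately),
connected components scored by extent (edge count), and FWER p from the
permutation distribution of the maximum extent with add-one
correction. A threshold sweep over t = 1…5 reports the threshold
maximising the significance of the largest component, ties resolved
toward the larger (more conservative) threshold.

**Clinical regression.** OLS of a motor score on a connectome summary;
slope, Pearson r, two-sided p.

## Lesion simulation

Weighted Watts–Strogatz networks: n = 41 nodes (one hemisphere's worth),
mean degree k = 10, rewiring probability P = 0.25. The ring lattice
weight scheme defaults to distance decay (a lattice edge of offset d
carries weight 1/d; a rewired shortcut keeps the weight of the slot it
replaced), with a uniform alternative; the directional conclusions hold
under both. Rewiring moves edges and never deletes them, so the edge
count is exactly nk/2 = 205 and the realized mean degree exactly 10.
Lesioning deletes `round(q·count)` of the long-range edges (ring
distance > k/2 = 5, i.e. beyond the lattice neighbourhood — in practice
the rewired shortcuts) uniformly at random, default q = 0.5;
short-range edges are never touched. Arms of 21 intact and 17 lesioned
realizations are compared on null-normalised efficiency and clustering
plus modularity with Welch t-tests. The lesioned arm shows lower
normalised efficiency and higher normalised clustering and modularity —
the same triad as the lesioned hemispheres in the cohort analysis —
with all three directions at p < 0.005 in ≥ 90% of seeded replicates.

## Numerical and design choices

* Round-half-away-from-zero wherever a fractional count is rounded
  (mask pair counts, lesion removal counts).
* Degenerate inputs: zero-variance responses return a flagged
  zero-effect result with a warning rather than a crash; topologies
  admitting no edge swap return null copies with a warning; empty
  networks raise for q50 and modularity.
* Permutation procedures are exactly reproducible under a fixed seed;
  igraph's RNG is re-seeded per null/restart from the ensemble seed.
* Desk-scale problem sizes (chosen once as the package's defaults):
  null ensembles of 100 (30 inside the 20-seed recovery evaluation),
  200–500 permutations, 20 evaluation seeds/replicates. Paper-scale
  analysis (1000 nulls, 5000 permutations) sits behind
  `RunConfig(paper_scale=True)`.

## Known limitations

* The Wald-F denominator df is a coarse approximation; inference should
  rest on the LR omnibus and the permutation procedures.
* The Tukey adjustment uses a conservative residual-df approximation
  rather than a Satterthwaite computation.
* Normalised efficiency > 1 is not reachable under the
  degree/strength/weight-preserving null class (see above); the
  package characterises small-worldness via clustering ≫ nulls at
  efficiency ≈ nulls.
* The strength-matching error of the null ensemble grows when the
  weight multiset is heavily tied (e.g. distance-decay lattices, where
  many edges share identical weights); the swap polish keeps it within
  the tested 5% contract at the default granularity.
* The modularity optimiser remains a heuristic; on large dense
  networks the returned Q is a lower bound on the attainable optimum.
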