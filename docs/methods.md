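# Methods

This note documents the models implemented in `comanet`, the defaults and
why, the numerical conventions, and what the synthetic cohort does and does
not emulate.

## Connectivity matrices

The pipeline starts from per-ROI streamline-probability volumes (tractography
itself is upstream and out of scope). Streamline hit counts are divided by
the per-seed sample count (default protocol: 5000 samples), seed-voxel maps
are combined into one per-ROI map, and the connection probability
p_ij is the mean of ROI i's map over the voxels of ROI j. The diagonal is
structurally zero; asymmetry (p_ij ≠ p_ji) is expected and preserved.
Volumes are index-based arrays: no affine/world-space handling.

The "union" of seed-voxel maps is not uniquely defined; `comanet` defaults
to the probabilistic union under independence, 1 − Π(1 − p_s), with a
voxelwise `max` alternative. The choice matters little for rank-based
downstream statistics (both are monotone in the inputs) but is recorded so
results are unambiguous.

## Thresholding

Absolute thresholding removes entries strictly below τ (entries equal to τ
are kept — "below a target value" read literally). Proportional thresholding
keeps the m = round(p·n·(n−1)) largest off-diagonal entries, counting every
off-diagonal slot in the denominator (the convention of the standard brain
connectivity toolbox), saturating when fewer nonzero entries exist. Ties at
the retention boundary break by ascending (row, column) index: with that
fixed rule, retained edge sets are nested in both τ and p, which the test
suite asserts.

Defaults τ = 0.10 (absolute, binary metrics) and p = 0.08 (proportional,
weighted metrics) are the operating points shipped in the default config.

## Graph metrics

Edge direction is row → column everywhere. Binary directed clustering is the
Fagiolo total-triangle form,

    t_i = 1/2 Σ_{j≠h} (a_ij + a_ji)(a_ih + a_hi)(a_jh + a_hj)
    C_i = t_i / [k_i (k_i − 1) − 2 k_i↔]

with C_i := 0 when the denominator is ≤ 0 (k ≤ 1 nodes), which keeps group
means finite. The weighted variant replaces each adjacency factor in t_i by
w^(1/3) and keeps the binary-pattern denominator. Global efficiency is the
mean inverse shortest-path length over ordered pairs, with 1/∞ := 0; binary
distances are hop counts, weighted distances use L = 1/w (the convention of
the efficiency routine this mirrors — other mappings such as −log w exist
and would change absolute values but not the group ordering on these data).
Shortest paths go through `scipy.sparse.csgraph`. Correctness is pinned by
exhaustive comparison against naive triple-loop and Floyd–Warshall oracles
on all digraphs with n ≤ 4 plus 1000 random n = 5 digraphs.

## Null models and threshold selection

Random nulls use pairwise edge swaps (a→b, c→d) → (a→d, c→b), rejected when
they would create a duplicate or self-loop; in/out degrees are preserved
exactly by construction and asserted in tests. Weights travel with their
source edge. Latticization uses the same mechanics but accepts a swap only
when the total circular-index distance Σ min(|i−j|, n−|i−j|) over edges does
not increase, driving edges toward the diagonal band.

The "iterations" knob is the toolbox convention of swap attempts per edge.
The signature default is 1000; the pipeline and tests run 40 attempts per
edge on 116-node networks, the point at which latticization has converged
enough that the lattice null's clustering exceeds the real control networks'
across the informative threshold range (convergence was checked by cost
descent; beyond ~40 the sweep's qualitative structure is unchanged). One
null pair per network per threshold is generated by default (`n_null`
raises this with averaging).

The sweep evaluates the 0–1 grid in 0.01 steps (101 points). Absolute mode
binarizes and uses binary metrics; proportional mode keeps weights and uses
the weighted-directed metrics. When a thresholded matrix has ≤ 1 edge it is
used in place of its nulls and flagged degenerate. Threshold selection is
"sandwich-smallest": the smallest grid threshold where mean real clustering
lies strictly between the random and lattice means and mean real efficiency
strictly between the lattice and random means. The verbal criterion
("between the matched random and regular networks") does not say first-vs-any
threshold; smallest-qualifying is the formalization here, and a divergence
rule (first threshold where the real-vs-lattice clustering gap exceeds a
fraction of the lattice value) is provided as an alternative.

## Hub disruption index

Control nodal values (degree for binary analyses, strength for weighted) are
averaged over every control scan — all 12 in the default 4-participant ×
3-scan design — and ranked ascending, rank n to the strongest node, ties
broken by node index. For each participant, the per-node difference from the
control mean is regressed on the rank by unweighted OLS; the slope is the
hub index h. h < 0 means high-rank (hub) nodes lost disproportionately more
than low-rank nodes. Control participants' own indices are computed
in-sample against the pooled reference (a leave-one-out mode is a
straightforward variation but in-sample is the default, matching how the
reference is defined). Key hubs are the ceil(0.05·n) = 6 top nodes on 116;
ceiling keeps the printed "top 6 of 116" identity.

Note that even hub-neutral, uniform damage yields a slightly negative
expected h, because the regressor (rank) and the control means are
positively associated: h isolates *disproportionate* hub damage only in
comparison across groups, not as an absolute zero point.

## Group statistics

Controls are averaged over their three repeat scans before testing, so every
participant contributes one value per metric. Per metric: Kruskal–Wallis
omnibus (tie-corrected H, χ² upper tail, df = groups − 1), all pairwise
Wilcoxon rank-sum post-hocs (normal approximation, tie-corrected variance,
continuity correction on by default — the toggle exists because
"approximate method" does not pin the correction), and Kendall tau-b against
the ordinal outcome coding (short-term: Control 0 < AR 1 < No AR 2;
long-term: Control 0 < EMCS 1 < AR′ 2 < No AR 3). No multiplicity adjustment
is applied by default, mirroring the original reporting; Holm adjustment is
available behind a flag. Fisher's exact test is two-sided by the
sum-of-small-probabilities definition; tables with a zero margin are
degenerate and return p = 1. These are standard tests and are delegated to
`scipy.stats` behind the module interface; hand-computed small-sample values
(exact Wilcoxon enumeration, tied-rank Kruskal–Wallis H, tau-b with ties)
are frozen in the tests as an independent check.

## Synthetic cohorts

The generator emulates the *statistical design* of the study, not its
biology. Controls are directed Watts–Strogatz-style networks: a ring lattice
(k_ring = 8 neighbours per side), out-edges rewired with probability
β = 0.1, plus six designated hub nodes — the AAL indices of bilateral
precuneus, putamen and thalamus — whose incident ordered pairs gain missing
edges with probability 0.6. Edge weights are Beta(2, 2): unimodal on (0, 1),
symmetric around 0.5, so the default τ = 0.10 prunes the weak tail without
collapsing the graph. These choices make the control cohort reproduce the
two qualitative facts the analysis needs: small-world topology (clustering
between lattice and random nulls, efficiency between random and lattice)
and an identifiable hub set.

Injury multiplies each weight by (1 − a_ij) with

    a_ij = s (1 + γ H_ij) / (1 + γ),

where s is group severity, γ ≥ 0 the hub selectivity (H_ij = 1 when the edge
touches a hub), plus N(0, σ²) noise per surviving edge, clamped to [0, 1];
zeros stay zero. This is the minimal model producing severity-ordered
decline in all four metrics with disproportionate hub damage. Defaults:
γ = 2, σ = 0.02, severities Control 0.0 < EMCS 0.15 < AR′ 0.35 < No AR 0.55
— graded diffuse damage with moderate hub preference, chosen once as a
plausible severity ladder for the three outcome strata. Group sizes mirror
the study (4×3 control scans; EMCS 3, AR′ 7, No AR 8). Repeat control scans
re-draw only the noise term (σ_scan = 0.02) on a fixed base network,
treating the three time points as repeated measures. Seeding: one master
seed; child seeds derive per (group, participant, scan) through a
`SeedSequence` counter scheme, so cohorts are byte-reproducible.

A non-hub-selective diffuse mode is simply γ = 0 and is exercised in tests;
it is not a separate switch.

What the generator does **not** emulate: anatomical geometry and true AAL
adjacency, the heavy-tailed and distance-dependent weight distribution of
real tractography, registration/tractography artefacts, lesion masks, or
any physiological time-point dynamics. Passing recovery tests therefore
demonstrates that the *pipeline* detects severity-ordered, hub-selective
degradation when present — not that real patient effect sizes are
reproduced. The study's patient-level test statistics require the original
MRI data and are out of scope.

## Numerical conventions and degenerate inputs

- Matrices validate to [0, 1], finite, zero diagonal; |diagonal| < 1e−12 is
  zeroed with a warning, larger values are errors.
- Text round-trip uses 17 significant digits (bit-exact for doubles).
- Networks need n ≥ 2; metrics on empty networks return 0 (clustering,
  efficiency, degrees) rather than NaN.
- All randomized components take explicit integer seeds; the pipeline
  derives every stage seed from the master seed.

## Problem sizes

The test suite and examples run the full 116-node, 30-scan default cohort
for thresholding/metrics/statistics (sub-second per network), and the full
101-point sweep with 40 swap attempts per edge for threshold selection
(~2 minutes per sweep on one core). Exhaustive oracle checks cover all
digraphs on ≤ 4 nodes and 1000 random 5-node digraphs.
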