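# Methods

## Model and state space

The package models a network of N binarized regions as a pairwise
maximum-entropy (Ising) distribution at unit temperature:
P(σ|h,J) ∝ exp(−E(σ|h,J)) with
E(σ|h,J) = −Σ_i h_i σ_i − ½ Σ_i Σ_{j≠i} J_ij σ_i σ_j.
The ½ together with the double sum over ordered pairs means each unordered
pair {i, j} contributes J_ij σ_i σ_j exactly once. J is symmetric with a
zero diagonal; energies are in natural-log (dimensionless) units.

States are numbered 1..2^N with region 1 as the most significant bit and
−1 → 0, +1 → 1, so the all-inactive pattern is state 1 and the all-active
pattern is state 2^N (state 1024 for a 10-region network). Every operation
enumerates all 2^N states; a hard capacity guard rejects N > 20, and the
per-network configuration cap is 12 effective regions, beyond which the
exhaustive MLE is impractical.

## Binarization and bilateral reduction

Each region is thresholded at its own time average: σ_i(t) = +1 iff the
continuous signal strictly exceeds region i's mean (ties map to −1 — a
deterministic choice that only matters for integer-valued synthetic
fixtures; for real BOLD data ties have measure zero). A constant region is
an error, not a silent ±1. The threshold is the mean of the *continuous*
signal — thresholding an already-binarized sequence at its own mean would
be circular.

Networks above the 12-region cap are reduced by averaging homologous
left/right regions *on the continuous signals, before binarization*
(18 → 9 and 14 → 7 for default-mode- and visual-sized networks). Group
series are formed by concatenating already-binarized subjects, so each
subject keeps its own threshold; binarization is never re-applied after
concatenation. Group landscapes come from these concatenated fits, not from
averaging per-subject landscapes.

## Maximum-likelihood estimation

The likelihood is the i.i.d. product over time points (temporal
autocorrelation is deliberately ignored, consistent with the product-form
likelihood). The gradient of the mean log-likelihood in (h, J) is exactly
the moment mismatch, so the fit iterates

    h_i  += ε (⟨σ_i⟩_emp − ⟨σ_i⟩_model),
    J_ij += ε (⟨σ_iσ_j⟩_emp − ⟨σ_iσ_j⟩_model),

with exact model moments summed over all 2^N states each step. Defaults:
ε = 0.1, convergence when the max absolute moment mismatch ≤ 1e-5, budget
50,000 iterations, initialization h = J = 0 (the likelihood is concave, so
initialization affects speed only). A step that would lower the
log-likelihood is rejected and ε halved, making the accepted trajectory
monotone; the likelihood itself is computed cheaply from the moment form
h·⟨σ⟩_emp + ½ΣJ_ij⟨σσ⟩_emp − log Z. Non-convergence is reported in the
result (`converged=False`), never raised; parameter overflow raises a
divergence error advising a smaller ε. No pseudocounts or regularization
are used: unobserved patterns enter only through the partition function.

Bulk simulation work (per-subject fits in the statistical pipeline and the
acceptance script) uses tolerance 1e-4: per-subject moment noise at a few
hundred volumes is O(1/√T) ≈ 0.04, orders of magnitude above either
tolerance, so the looser setting changes no scientific conclusion while
keeping whole-study runs in seconds.

## Landscape, basins, barriers, tree

A local minimum is a state *strictly* below all N Hamming-1 neighbors;
plateaus are not minima (exact ties are measure-zero for continuous
energies; strictness makes integer fixtures deterministic). Basins follow
steepest descent to the lowest-energy strictly-lower neighbor, ties broken
toward the lowest state index — the tie-break used everywhere.

The minimax barrier between states a and b is min over hypercube paths of
the path's maximum energy (endpoints included, so barrier(a,a) = E(a)).
It is computed by a Dijkstra variant whose accumulated cost is the running
maximum. The disconnectivity tree is built independently by an
ascending-energy union-find sweep: states are activated in energy order
and merged with active neighbors; when components each holding a minimum
join, an internal node is recorded at the activating state's energy. By the
minimax-path/ultrametric correspondence the height of two leaves' lowest
common ancestor equals their minimax barrier — the equivalence of the two
routes (and of both against a threshold-connectivity BFS oracle) is
asserted in the test suite rather than assumed. All strict minima are
rendered; no depth-based pruning is applied.

## Group comparison

Per-subject energy samples for a candidate state are obtained by fitting
each subject's *own* MEM to that subject's series and evaluating the
state's energy under the subject-specific parameters. Candidates are all
local minima from both groups' landscapes; a state that is a minimum in
both groups is tested once but counted once per group in M, so M is the
pooled tally over all networks and both groups. The default test is the
pooled-variance two-sample Student t (Welch available by flag; the two
agree to 1e-10 for equal sizes and variances), two-sided p-values, and the
Bonferroni threshold α/M with α = 0.05. Testing *all* minima rather than
pre-screening by energy difference is conservative and consistent with
correcting by the full tally. Reports include per-group mean energies so
the direction of every effect is readable.

## Synthetic studies

Because 2^N is enumerable, binary series are sampled i.i.d. by inverse-CDF
lookup on the exact Boltzmann probabilities — no MCMC and hence no
mixing-time or autocorrelation concerns. The default design emulates the
two-group aging setting the pipeline targets: a 10-region
(attention-network-sized) model with uniform positive couplings J = 0.12
(so (N−1)·J ≈ 1: cooperative, with the all-active and all-inactive states
as deep minima, but not frozen), per-region biases ~N(0, 0.1²), 23 subjects
in one group and 47 in the other, 500 volumes per subject. Group effects
scale one group's J by a stated factor (0.5 in the effect scenarios),
which raises the weaker group's energy at the coherent states. Per-subject
seeds are spawned deterministically from the study seed, so datasets are
byte-reproducible and subjects statistically independent.

A continuous surrogate maps σ to σ + N(0, noise²) so the binarization
stage can be exercised end to end; with sub-unit noise and balanced series
re-binarization recovers the input exactly, and a warning is issued when it
does not.

What the generator does *not* emulate: hemodynamic (BOLD) forward
dynamics, temporal autocorrelation, scanner drift or motion artifacts, and
inter-subject parameter heterogeneity within a group. Passing tests
therefore demonstrate correctness of the estimator and landscape machinery
under the model's own assumptions, not robustness to real-fMRI deviations
from them.

## Problem sizes and test design

The statistical suite uses scaled-down studies chosen to keep whole runs in
seconds while leaving effects far above noise: the null calibration runs
200 replicates of a 4-region, 6+6-subject, 200-volume design tested at the
reference Bonferroni level 0.05/125 (family-wise error compared against
0.05 with a binomial 95% band); the group-effect check uses 6 regions,
20 subjects per group, and 2000 volumes with couplings halved in one group.
The acceptance script runs the full default design (10 regions, 23 vs 47
subjects, 500 volumes). Landscape oracles run on 50 random landscapes at
N ≤ 4, where exhaustive brute force is exact.

## Known limitations

* Exhaustive enumeration limits networks to ~12 regions; larger networks
  must be reduced bilaterally or split.
* Per-subject fits at short scan lengths are noisy; the t-test treats the
  fitted energies as exchangeable measurements and ignores their
  estimation error.
* Whether real studies threshold at per-subject or group means, and whether
  they pre-screen candidates by a numeric energy-difference cutoff, varies;
  this package thresholds per subject per region and tests all minima.
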