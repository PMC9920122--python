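# energylandscape

Energy-landscape analysis of resting-state brain networks: fit a pairwise
maximum-entropy (Ising) model to binarized fMRI ROI time series, enumerate
the full energy landscape, build disconnectivity trees over the stable
connectivity states, and extract group-discriminating **connectivity
signatures** with Bonferroni-corrected two-sample t-tests.

It is written for researchers who already have per-subject ROI time series
(e.g. AAL-parcellated resting-state fMRI averaged per region) for two
subject groups — such as young vs old adults — and want to know *which*
network states separate the groups and *how strongly* the regions in those
states work together.

## The model

Each region i at time t is binarized to σ_i(t) ∈ {−1, +1} by thresholding
its signal at its own time average. A network of N regions then occupies one
of 2^N activity patterns σ, modeled by the pairwise maximum-entropy
(Boltzmann) distribution

    P(σ | h, J) = exp(−E(σ | h, J)) / Σ_σ' exp(−E(σ' | h, J)),
    E(σ | h, J) = −Σ_i h_i σ_i − ½ Σ_i Σ_{j≠i} J_ij σ_i σ_j,

with per-region baselines h and symmetric, zero-diagonal couplings J
(J_ij = J_ji, J_ii = 0). The parameters are estimated by maximum likelihood
via gradient ascent until the model's first and second moments match the
empirical ones. From the fitted model:

* **local minima** — states whose energy is below all N single-bit-flip
  neighbors — are the stable connectivity states (lower energy = more
  frequently visited);
* **disconnectivity trees** record the minimax energy barriers separating
  the minima (over all hypercube paths between two states, the smallest
  achievable path-maximum energy);
* **signatures** are minima whose per-subject energies differ between
  groups at the Bonferroni level α/M, where M pools the minima counts over
  all networks and both groups.

Networks larger than 12 regions are reduced by averaging homologous
left/right regions before binarization (18-region default-mode → 9,
14-region visual → 7), since every stage is exhaustive over 2^N states.

## Worked example

Simulate a two-group study on one 6-region network (8 "young" vs 12 "old"
subjects, 300 volumes each, old-group couplings halved) and run the full
pipeline:

```sh
energylandscape simulate --out demo --seed 7 --n-regions 6 \
    --subjects 8,12 --t-max 300 --effect-scale 0.5
energylandscape pipeline demo --out demo_report.json
```

which prints

```
wrote 20 subjects to demo
M = 4 minima, corrected alpha = 0.0125, 2 significant signature(s); report written to demo_report.json
```

The two group landscapes contribute M = 4 local minima in total, so each
t-test runs at 0.05/4 = 0.0125. The report shows the two flagged states:

```
state  pattern        t          p  significant  mean E (old)  mean E (young)
    1  ------     11.98   5.17e-10         True        -1.094          -2.104
   64  ++++++      9.81   1.21e-08         True        -0.725          -1.536
```

Both signatures are the fully coherent states (all regions inactive /
all active), and the young group — whose generating couplings are twice as
strong — sits at markedly lower energy in both: exactly the "stronger
within-network connectivity in the young group" pattern the method is
designed to expose. The JSON report also carries each group's fitted h and
J, every local minimum with its energy, and provenance hashes;
`energylandscape landscape` exports minima tables and Newick/text
disconnectivity trees for any fitted model.

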