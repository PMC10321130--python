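# Methods

## Overview

The package reduces single-channel EEG segments to small feature vectors
by clustering their amplitude samples, then benchmarks classifiers on the
reduced representation. Everything downstream of the raw segments is
deterministic given (data, config, seed).

## Data model and dialect

A segment is a finite 1-d amplitude series with a sampling rate; the
canonical geometry is 4097 samples at 173.61 Hz (23.6 s). Files are ASCII
with one amplitude per line; the reader tolerates blank lines and decimal
tokens, and the writer emits integers without a decimal point so integer
data round-trips byte-identically. Datasets are assembled from a
`path,label` manifest CSV; all segments in a dataset must share one
length, and duplicate paths are disambiguated by id suffixing.

## Synthetic generator

The generator emulates the two extreme Bonn classes:

- **normal** — a sum of three sinusoids with random frequencies in the
  8–12 Hz band, random phases and amplitudes (0.5–1 × `normal_amp`),
  over AR(1) background noise (lag-1 coefficient 0.6, innovation sd
  scaled so the marginal sd is `noise_sd` = 0.3);
- **ictal** — a periodic ~3 Hz spike-wave train: per cycle a narrow
  Gaussian spike (width = period/20) of amplitude `ictal_amp` = 4 ×
  `normal_amp` with 10% per-cycle jitter, followed by an opposite-sign
  slow half-sine occupying 60% of the cycle, plus the same AR(1) noise.

Defaults (4× amplitude ratio, 3 Hz fundamental, 4097 samples) give the
ictal class the higher amplitude and stronger periodicity that separate
the real ictal and normal subsets. What the generator does **not**
emulate: 1/f spectral background, muscle/ocular artifacts, non-stationary
seizure onset/offset dynamics, inter-subject variability. A green
end-to-end test therefore establishes that the pipeline machinery is
correct and discriminates well-separated classes — not that it matches
accuracies obtainable on clinical recordings.

Per-segment seeds are derived as `SeedSequence(master, spawn_key=(class,
index))`, so a segment's samples do not depend on how many other segments
are generated.

## Clustering

All six algorithms minimize the same hard-assignment objective (SSE for
q = 2); metaheuristic agents encode flattened k×d centroid matrices, so
their solutions are directly comparable with k-means. Shared numerical
choices:

- nearest-centroid ties break toward the lowest cluster index;
- empty clusters in Lloyd iterations are reseeded at the point farthest
  from its assigned centroid;
- metaheuristic positions are clamped to the data bounding box (a
  centroid outside the hull cannot reduce SSE);
- the best-ever solution is archived (elitism), so best-fitness traces
  are non-increasing by construction;
- for 1-d data the SSE of a centroid set is evaluated against sorted
  prefix sums in O(k log n) — exact, and the reason the per-segment
  feature mode is fast.

**k-means / k-median.** Random k-distinct-point initialization; mean
(q = 2) or coordinate-wise median (q = 1) prototype updates; stops when
the assignment repeats. `n_init` restarts keep the best objective.

**Fuzzy c-means.** Memberships z_iq = 1/Σ_h (d_iq/d_hq)^(2/(p−1)),
computed in the equivalent O(nk) inverse-power form; fuzzifier default
p = 2; zero distance takes the one-hot limit. Stops when the objective
changes by less than ξ = 1e−6 or after 300 iterations. The cluster-count
search minimizes the Xie–Beni index (compactness / n × minimal squared
centroid separation) over [2, ⌊√n⌋] by default; ties go to the smaller k.

**Cuckoo search.** 15 nests, 200 generations, discovery probability
p_a = 0.25. Per generation one cuckoo is perturbed by a Mantegna Lévy
step (β = 1.5) whose origin is the best nest or the chosen nest with
equal probability and whose scale is 2% of the search-space span cooling
geometrically (0.98/generation); the candidate greedily replaces a random
nest if fitter; the worst p_a fraction is rebuilt uniformly at random.
The best-seeded, cooling flights matter: a fixed-scale walk from random
nests plateaus 2–3% above the k-means objective on two-blob instances,
while this scheme reaches <0.2%.

**Dragonfly.** Forces per agent: separation Σ(He_j − He_l) over
neighbors within the radius, alignment = mean neighbor velocity, cohesion
= neighbor centroid − position, food attraction toward the best-ever
position, enemy repulsion away from the current worst. The printed enemy
expression in the source material is not dimensionally interpretable and
is implemented as the repulsion mirror of the food term. The
neighborhood radius shrinks linearly from 25% to 5% of the search-space
diagonal; "velocity" is the agent's previous step. Stabilizing choices:
each force weight is multiplied by a fresh U(0,1) draw per agent per
iteration (otherwise the swarm collapses onto the food source in one
step), inertia decays linearly from 0.9 to 0.4, steps are clamped to 25%
of the diagonal, and a neighborless agent takes a Lévy step biased toward
the food source — unless every weight and the inertia are zero, in which
case the update equation yields a zero step and the swarm is static.

**Firefly.** Brightness I = 1/(1 + J_SSE), so lower objective = brighter;
attraction step y ← y + A₀·exp(−λq²)·(y′ − y) + α·ε with A₀ = 1, λ = 1,
α = 0.2 decaying by 0.97/iteration, ε uniform in [−0.5, 0.5] scaled by
the per-dimension box extent. Inside the loop the squared distance in
the exponent is normalized by the search-space diagonal, so λ = 1 yields
usable attraction at any amplitude scale. The brightest firefly performs
a random walk.

**Modified firefly.** Two changes: the attraction scale becomes the
intensity ratio B₀ = J₀′/J₀ of the brighter over the dimmer agent
(singular J₀ = 0 raises), and the brightest agent probes `s` = 10 random
unit directions, moving only along the best strictly improving one and
staying put otherwise — so the population-best objective is
non-increasing at every iteration, not just in the elite archive.

## Features and entropy

Canonical mode clusters each segment's samples (d = 1) into k = 10
clusters and uses the sorted centroids as the feature vector;
classification stays at segment level, where sensitivity and specificity
are well defined. Transpose mode clusters the segments of one class as
points in time-sample space, reproducing the printed
(4097 × 100) → (4097 × 10) matrix reduction.

Entropy defaults follow the Pincus convention: template length m = 2,
tolerance r = 0.2 × series sd, Chebyshev distance; Shannon entropy uses
16 equal-width bins over [min, max] and is reported in bits. Approximate
entropy counts self-inclusive matches (Φ^m − Φ^{m+1}); sample entropy
excludes self-matches and truncates both template sets to n − m so the
two counts compare like with like; a zero match count returns an infinity
sentinel that the report shows as missing and excludes from averages.
The report computes entropies on the concatenated clustered feature
values per (clusterer, class) cell, with the raw-segment alternative one
call away; its Average row is the arithmetic column mean at report
precision (3 decimals by default).

## Classifiers

The registry wires scikit-learn estimators to fixed hyperparameters: MLP
with one 32-unit sigmoid hidden layer trained by SGD (learning rate 0.3,
momentum 0.5, 800 cycles — the stated optimizer name in the source
material conflicts with these SGD-style parameters, and the SGD reading
is implemented); 2-NN with distance-weighted votes so the nearer
neighbor decides ties; Gaussian naive Bayes; linear SVM trained by SGD
(hinge loss, 1000 iterations); polynomial SVM of order 2; RBF SVM with
γ = 2.0; QDA with 1e−3 covariance shrinkage (sorted-centroid features
can be near-collinear); entropy-split decision tree; 100-tree random
forest. Gradient-trained models are wrapped with a feature standardizer
so the fixed learning rates are scale-free. The input layer adapts to
the actual feature count.

Incremental LDA is authored here: per-class counts, means, and the
pooled within-class scatter are updated by Welford rank-1 steps, so
streaming any sample order reproduces batch LDA's discriminant direction
(verified to < 1e−8 angle) and predictions.

The MSE-versus-iterations hyperparameter search trains each (grid value,
iteration cap) cell and records the training MSE of 0/1 predictions; a
grid value qualifies when its last three scheduled MSEs are
non-increasing (converged rather than oscillating or flat), and among
qualifiers the lowest final MSE wins. Learners without an iteration
parameter (KNN, NB, QDA, trees) produce constant columns, making the
iteration axis vacuous but the selection still well defined.

The seizure alarm median-filters a 0/1 window stream (edge replication;
width 1 is the identity) and raises an alarm each time a run of
`alarm_threshold` consecutive positives completes, resetting the run
counter afterwards. The threshold is patient-dependent and exposed as
configuration only; no estimation rule is provided.

## Evaluation

Folds are stratified (both classes in every fold) and fixed by seed, and
the same partition is shared across all classifiers so comparisons are
paired. Aggregation averages per-fold metrics; pooled-count aggregation
is a flag. Metrics are percentages; on balanced folds accuracy equals
(sensitivity + specificity)/2 exactly. Tables are emitted at 5 decimals.

## Known limitations

- The metaheuristic population sizes and iteration counts (15 agents,
  200 iterations) are package defaults; the source material reports none.
- ICA artifact suppression is opt-in and stacks same-class segments as
  pseudo-channels — a construction chosen here for want of a specified
  channel layout; it should not be assumed to match any published
  preprocessing.
- The sample-entropy infinity sentinel makes report cells missing rather
  than imputing; averages over columns with missing cells use the
  remaining entries.
- Synthetic acceptance evidence does not transfer to clinical EEG; see
  the generator section.
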