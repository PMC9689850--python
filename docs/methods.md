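# Methods

This note documents the models, defaults and numerical choices behind
`sodpeeg`, and what its synthetic benchmarks do and do not demonstrate.

## Signal model and preprocessing

Recordings are treated as microvolt-scale multichannel EEG sampled at
256 Hz on a 23-channel bipolar montage. Seizure annotations are half-open
`[start_s, end_s)` intervals. Segmentation uses a sliding 20 s window
with 15 s overlap (5 s stride); a window is labeled *seizure* only when
it lies entirely inside an annotated interval and *seizure-free* only
when it overlaps none, so windows straddling an onset or offset are
discarded — mixed windows would dilute both classes and there is no
principled fractional label for a segment-level classifier.

Band decomposition uses windowed-sinc (Hamming) linear-phase FIR filters
of order 512 (2 s of impulse response), applied forward–backward so the
net phase is exactly zero: the downstream features are geometric
properties of the SODP point cloud, which phase distortion would warp.
δ is realized as a low-pass at 4 Hz; θ/α/β as band-passes at their
edges. The forward–backward pass is computed as FFT convolution with the
autocorrelation kernel `conv(h, reverse(h))` after odd-reflection edge
padding; this is numerically identical to `filtfilt` with the same
padding (maximum observed deviation 4 × 10⁻¹⁶) and roughly two orders of
magnitude faster at these kernel/segment sizes. With order 512 the four
band outputs jointly retain ≈ 94 % of broadband 0–30 Hz power on white
noise; the missing few percent sit in the transition bands at 4, 8, 15
and 30 Hz.

Artifact handling is reduced to an optional amplitude screen (drop
segments whose peak exceeds 8× the median absolute amplitude), off by
default; visual artifact review is out of scope.

## SODP descriptors

All ten descriptors are plain sums or population moments over the SODP
points; none involves fitting or iteration.

* STD1/STD2 are population standard deviations of the point cloud
  projected across/along the `y = x` diagonal; `STD = π·STD1·STD2` is
  the fitted-ellipse area. Population (1/n) rather than sample (1/(n−1))
  normalization: these are descriptors of the realized cloud, not
  estimators of process parameters, and the fixed convention keeps
  results exactly reproducible.
* SAV sums the **cosines** of angles between consecutive position
  vectors, i.e. each term is the dot product over the *product* of
  norms. A rendering of the defining formula with a *sum* of norms in
  the denominator circulates as well; that variant is not
  scale-invariant and is available via `sav(..., denominator="sum")`,
  but the product form matches the feature's name and is the default.
  Pairs containing a zero-length vector have no defined angle and
  contribute 0.
* CTM(ρ) is the fraction of points within a disk of radius ρ times the
  cloud's own radial extent `max √(x²+y²)`, at ρ = 0.3, 0.4, 0.5. The
  radius is per segment and per band, making CTM scale-invariant; the
  alternative (one radius per band fixed across a whole dataset) would
  make the feature depend on the dataset composition and break
  per-segment feature extraction. An all-zero plot has radius 0 and
  CTM = 1.
* SSHD, SDC, SSVL, STA, SCC are the diagonal-distance, radial-distance,
  trajectory-length, triangle-area and centroid-drift sums written in
  their standard forms (shoelace formula for areas; centroids of
  consecutive triples).

Homogeneity under amplitude scaling `a > 0` is checked by tests: SAV and
CTM invariant; SSHD/SDC/SSVL/SCC/STD1/STD2 scale by `a`; STD and STA by
`a²`. Every descriptor is also verified against an independent
term-by-term loop implementation on 1000 random plots at 10⁻¹⁰ relative
tolerance.

Per segment, features are computed per channel and averaged over
channels. The particle encoding carries exactly ten bits per band, so
the classifier must consume one 10-vector per segment per band; the
unweighted channel mean is the simplest aggregate consistent with that
contract.

## Optimizers

All four modes share one driver over real vectors with population 30,
200 iterations and 20 trials by default.

* **PSO**: canonical update `v ← w·v + c1·r1·(pbest−x) + c2·r2·(gbest−x)`
  with constant `w = 0.8`, `c1 = c2 = 2.0`, velocities clamped to
  ±20 % of the bound width, positions clipped to the bounds.
* **AsyLnCPSO**: same update with `c1` falling linearly 2.5→0.5 and `c2`
  rising 0.5→2.5 over the run (the standard time-varying-acceleration
  schedule), shifting the swarm from cognitive exploration to social
  convergence.
* **GA**: tournament selection of size 2; uniform crossover on half of
  the random pairs (`crossover_rate = 0.5`); per-gene Gaussian mutation
  at rate 0.01 with step size annealed linearly from 0.1 to 0.001 of the
  bound width (a conventional annealed real-coded mutation — wide early
  moves for well-hopping, fine late moves for refinement); elitism (the
  best individual always survives). Only crossed-over or mutated
  individuals are re-evaluated, so the GA's extra budget per iteration
  is about `0.5·pop` plus the few individuals hit by mutation.
* **AsyLnCPSO-GA**: per iteration, the scheduled swarm update followed
  by a full GA generation over all particles. The personal-best memory
  is permuted together with tournament winners so each particle keeps
  *its own* history; without this the hybrid's memory becomes incoherent
  and it measurably underperforms the plain swarm.

The global best is tracked across operators, and elitism guarantees the
best-so-far trajectory is monotone in every mode. Non-finite fitness
values are treated as worst-possible (and logged) so the search survives
degenerate inputs such as empty feature masks. A single `numpy`
Generator per run, with per-trial seeds spawned from one `SeedSequence`,
makes every trajectory bit-reproducible and makes cross-mode trial
comparisons paired.

Benchmark validation uses dimension 10 with the standard domains
(Rastrigin ±5.12, Sphere ±100, Rosenbrock ±30, Schwefel ±500; Schwefel
in the shifted form `418.9829·d − Σ x·sin√|x|` with minimum ≈ 0 at
x ≈ 420.97). At this dimension and budget (≈ 9 000 evaluations for the
hybrid) the hybrid dominates on Sphere (≈ 10⁻⁷), Rosenbrock (≈ 5) and
ties the GA on Rastrigin (≈ 7); on the deceptive Schwefel landscape the
GA's recombination of separable coordinates outperforms every
swarm-containing mode. The literature-standard swarm constants used here
make AsyLnCPSO far stronger than plain PSO (its shrinking `c1+c2` sum
lies inside the stability region, plain PSO's does not), so the relative
ranking of the middle modes is sensitive to the exact constants chosen
and should not be over-interpreted.

## Selection fitness

Masks decode from particles by strict thresholding at 0 (a coordinate of
exactly 0 selects nothing, so the all-zero particle is the empty mask,
which scores 0 rather than raising — the search space stays total).

The classifier is Gaussian naive Bayes written in-house (it is part of
the fitness contract: variance floor of 10⁻⁹ × the largest pooled
feature variance, ties broken toward the first label in sorted order),
cross-checked against scikit-learn's implementation in tests. Fitness is
the mean accuracy over stratified 10-fold cross-validation (9:1 split).

Fold assignment is frozen once per experiment: within each class,
samples are sorted lexicographically by their full feature vector,
shuffled once with the experiment seed, and dealt round-robin into ten
folds. Consequences, all covered by tests: fitness is a deterministic
function of the mask (memoizable — mask spaces up to 2⁴⁰ shrink to the
handful of masks actually visited); it is invariant to row permutation
of the table; and the fold split does not depend on which columns a mask
selects, so fitness values are comparable across masks, trials and
optimizer modes. Re-randomizing folds per call would instead turn the
fitness into a noisy objective and make trajectories irreproducible.

## Synthetic data

The generator defines the standard study conditions: 100 seizure + 100
seizure-free segments of 20 s at 256 Hz on 23 channels.

Background is pink noise (power ∝ 1/f) plus band-limited Gaussian
oscillations with relative variances δ 0.8, θ 0.5, α 0.45, β 0.3 —
a δ-dominant resting spectrum. Channels share a common source with
mixing weight 0.7 (inter-channel correlation ≈ 0.5) plus independent
per-channel noise; no head model is attempted. The per-segment RMS is
10 µV jittered log-normally (σ_log = 0.3), emulating slow power drifts.

Seizures add a spike–wave train: biphasic sharp transients
(derivative-of-Gaussian, rise parameter drawn once per segment from
5–25 ms — discharge morphology is stereotyped within a run) each
followed by a slow half-wave, repeating at 2.5 Hz inside "on" periods
drawn with exponential lengths (mean 0.9 s on, duty 0.6). The train is
scaled so the total segment RMS is 4× the background level, itself
jittered log-normally (σ_log = 0.25) so the two classes overlap in any
single amplitude feature and the selection problem is non-trivial.

At these defaults the δ-band features reproduce the qualitative group
structure the pipeline assumes: the seven distance/area descriptors are
higher and all three CTM values lower in the seizure class (the rhythmic
discharge drives SODP radii out toward the plot's own extent, while the
broadband background concentrates radii well inside it), with one-way
ANOVA p ≪ 0.01 at n = 100+100. What passing these benchmarks shows is
that the pipeline's mechanics — filtering, descriptors, fitness, search
— behave as specified; it says nothing about clinical sensitivity or
specificity, inter-patient generalization, or robustness to artifacts,
none of which the generator models.

## Problem sizes used in the automated checks

The test suite exercises the full study scale where it matters (the
100+100-segment pipeline benchmark with 20 trials of both the hybrid and
plain PSO; the four-function optimizer validation at its printed 30 ×
200 × 20 scale) and reduced sizes elsewhere (e.g. 4-channel generator
variants for RMS/spectrum contracts, which do not depend on channel
count; 10-trial permutation-null replicates). The oracle suite runs 1000
random plots; the ANOVA calibration 1000 null replicates.

## Known limitations

* The EDF writer emits minimal 16-bit EDF (one-second records) intended
  for round-tripping synthetic data and fixtures, not for clinical
  archiving.
* CTM uses the per-segment radial extent; results are not comparable
  with implementations that fix the disk radius per dataset.
* The benchmark-function ranking between GA, PSO and AsyLnCPSO depends
  on swarm constants that are not uniquely pinned by the method
  description; only the hybrid-beats-components direction on separable
  smooth functions is robust in our experiments.
* `band_cross_experiment` over all 15 combinations with 20 trials each
  is CPU-minutes of work; the memoized fitness keeps single-band runs
  interactive.
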