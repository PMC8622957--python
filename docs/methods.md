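# Methods

## Signal model and classification rule

A heartbeat is the vector of one R-R interval resampled to n = 128 samples
and normalized to zero mean and unit Euclidean norm.  The working model is
`x ≈ Dα` with `D` an n×m matrix of unit-norm atoms, m > n (overcomplete),
and `α` sparse.  Classification trains one dictionary per class
(NSR, 5 min, …, 30 min before the event) and assigns a beat to
`argmin_c ‖α_c‖₁`, where `α_c` is the error-constrained OMP code of the
beat under class c's dictionary.  The rationale: a dictionary adapted to
the beat's class reaches the reconstruction-error target with few,
moderate coefficients, while a mismatched dictionary needs larger
combinations.

## Orthogonal Matching Pursuit

`omp_code` iterates while the residual energy fraction
`e = ‖r‖₂²/‖x‖₂²` exceeds ε and the support is below the atom budget:

1. select `i = argmax_i |dᵢᵀ r|` over unselected atoms (ties → lowest
   index, for determinism);
2. refit all coefficients by least squares on the selected atoms — kept
   incremental with a re-orthogonalized Gram–Schmidt QR factor, so each
   step costs O(nm) for the correlations plus O(nj) for the update;
3. recompute `r = x − Dα` and `e`.

`e` is an **energy** (squared-norm) ratio.  The loop condition is strict
(`e > ε`): at ε = 1 the empty code already satisfies the constraint, so the
sparsest feasible solution is all-zero.  Termination therefore guarantees
`rel_error ≤ ε` or a full atom budget.  Defaults: ε = 0.05,
`max_atoms = n`.

Two guards handle degenerate geometry.  If the best remaining correlation
is numerically zero (≤ 1e-10·‖r‖ — the residual lies in the orthogonal
complement of every unselected atom, e.g. when the dictionary carries
duplicate atom content), the pursuit stops: no atom can make progress, and
pressing on would select numerically dependent atoms.  If an accepted atom
still fails to enlarge the span (QR diagonal ≤ 1e-10), a rank-deficiency
error naming the offending support is raised; with the stagnation stop in
place this branch is defensively unreachable in practice, since an atom's
correlation with the residual is bounded by its out-of-span component.

Greedy pursuit is *not* exact-recovery-guaranteed on coherent
dictionaries.  Where tests compare OMP against exhaustive least-squares
search, instances are drawn from the regime where recovery is provable
(the exact-recovery condition `max_{i∉S} ‖D_S⁺ dᵢ‖₁ < 1` holds on the
planted support); there, any disagreement is an implementation defect.  On
unconstrained random 8×10 instances OMP matches the oracle ≈ 95% of the
time, which is expected behavior, not error.

## k-SVD

Per iteration: code every training signal with OMP; then for each atom j,
collect the signals whose codes use it, zero row j of their restricted
coefficients, form the residual matrix, and take its rank-1 SVD — the atom
becomes the first left singular vector (sign flipped so its
largest-magnitude entry is positive, for determinism) and its coefficient
row becomes σ₁·v₁ᵀ.  Atoms used by no signal are replaced by the
normalized training signal with the largest current coding residual
(worst-coded first), preventing dead atoms.  Default K = 20 iterations;
between 10 and 20 is the conventional range, and the training history
(total squared coding residual per iteration) is returned so convergence
can be inspected.  Atoms remain unit-norm to 1e-9 after every iteration.

On the planted benchmark (hidden 20×50 dictionary, 1500 three-sparse
signals, coefficients ±[0.1, 1], K = 20) the implementation recovers
82–92% of hidden atoms at |cosine| > 0.99 across seeds; full recovery at
this coherence typically needs 50+ iterations, and atoms sharing energy
with near neighbors converge to rotations within the pair.

## Preprocessing

* **Resampling** — rational polyphase (250 → 128 Hz is up 64 / down 125)
  with a linear-phase Kaiser FIR: 60 dB stopband, transition band 10% of
  the output Nyquist, odd length for integer group delay (compensated by
  the polyphase machinery, so annotations stay aligned; the onset index is
  rescaled by the rate ratio and rounded).  The stopband edge is placed at
  0.85× the output Nyquist (≈54 Hz for a 128 Hz target) rather than at
  Nyquist: diagnostic ECG content sits below ~40 Hz, and this suppresses
  50/60 Hz mains pickup together with genuine aliases (a 60 Hz tone is
  attenuated by ~78 dB, a 5 Hz tone passes within 0.03%).
* **Interval extraction** — half-open windows `[start, start+60 s)` of
  0-based sample indices; for pre-event recordings the window ends m
  minutes before the annotated onset; control windows are drawn uniformly
  with an explicit seed.
* **R-peak detection** — Pan-Tompkins-style: 5–15 Hz linear-phase FIR
  band-pass (delay-compensated), derivative, squaring, 150 ms
  moving-window integration, candidate peaks ≥ 200 ms apart, adaptive
  acceptance at 0.5× the running median of the last 8 accepted peak
  heights (initialized at the 90th percentile of candidate heights), and
  refinement of each fiducial to the raw-signal maximum within ±10
  samples.  On planted beats at 20 dB SNR sensitivity is ≥ 99% within ±3
  samples.
* **Segmentation** — beats run R-to-R (start at one R peak, end one sample
  before the next), matching the R-R interval definition literally;
  R-centered windows would be an equally defensible alternative.  Each
  variable-length slice is linearly interpolated to n = 128 samples, then
  normalized per beat (zero mean, unit norm — unit norm makes OMP
  correlations scale-free).  Slices outside the physiological gate
  [0.25 s, 2.5 s] are dropped and tallied; the gate rejects detector
  glitches without discarding bradycardic beats.

## Experimental protocol

The primary protocol is subject-wise two-fold cross-validation repeated
(default 10×, seeded shuffles): subjects within each class are dealt into
folds, dictionaries are trained on one fold's beats and tested on the
other's, and both directions are scored.  A fixed 55–45% train-test
subject split is available as an alternate mode.  The unit of
classification is the beat; per-interval segment voting is deliberately
not applied.  Class imbalance is left as-is (no reweighting).  Accuracy is
`100·(TP+TN)/total` for the binary scheme and per-class one-vs-rest
correctness for the multi-class scheme; classes absent from the truth are
reported as not-applicable, never zero.

## Parameters

| parameter | default | meaning |
|---|---|---|
| n | 128 | beat length, samples (1 beat ≈ 1 s at 128 Hz) |
| m | 160 | atoms per dictionary; 1.25× overcomplete — the source material never states m, so this is a package choice balancing expressiveness against the few hundred beats available per class per fold |
| ε | 0.05 | OMP residual-energy threshold |
| K | 20 | k-SVD iterations |
| max_atoms | n | OMP support cap (safety bound) |
| folds / repeats | 2 / 10 | cross-validation protocol |
| R-R gate | 0.25–2.5 s | physiological beat-duration bounds |

## Synthetic data

`make_planted_sparse_set` draws a seeded random unit-norm dictionary and
s-sparse signals with supports uniform without replacement and
coefficients uniform on ±[0.1, 1] (magnitudes bounded away from zero so
every planted atom is detectable).

`make_ecg_recording` builds beats from five Gaussian bumps (P, Q, R, S, T)
at fixed beat-phase fractions, amplitudes in mV with R strictly dominant;
R-R intervals are drawn per beat from a Gaussian jitter model around
60/heart-rate; white Gaussian noise is added last.  The class-dependent
morphology shift — T-amplitude gain, S-T phase delay, extra R-R jitter —
caricatures the repolarization/rhythm drift reported before ventricular
fibrillation; for pre-event recordings its strength ramps linearly toward
the synthetic onset.  The generator returns the exact planted R-peak
indices, per-beat interval labels and onset index.

What it does *not* emulate: real PQRST variability across leads and
patients, baseline wander, electrode artifacts, arrhythmic beats, or any
physiologically faithful fibrillation waveform.  Passing the end-to-end
synthetic studies therefore demonstrates that the algorithms and the
pipeline are correct and that the method can learn a morphology difference
of the stated size — not that the published clinical accuracies transfer;
reproducing those requires the original Holter databases, for which the
WFDB reading path is provided.

Desk-scale study sizes (chosen once): the binary end-to-end study uses 6
subjects per class, one 1-minute recording each (~70 beats), 3 repeats of
two-fold CV; the beat-count closure uses 18 control and 20 pre-event
subjects at 71 planted beats per minute, so every 1-minute window contains
exactly 70 R-R intervals.

## Known limitations

* **Minimum-ℓ1 inversion in the one-atom regime.**  For unit-norm beats,
  if *both* class dictionaries can meet the error target with a single
  atom, the coefficient is |cos θ| to the best atom — and the
  worse-matching dictionary then yields the *smaller* coefficient sum, so
  the argmin rule picks the wrong class.  This is intrinsic to the
  criterion: it discriminates only when mismatched dictionaries are forced
  into multi-atom codes whose ℓ1 exceeds the matched one.  The weak-shift
  synthetic regime sits squarely in the inversion zone (accuracy collapses
  below chance); highly stereotyped beat sets with a loose ε are the
  practical risk case.
* Greedy OMP is not globally optimal on coherent dictionaries (see above);
  k-SVD at K = 20 leaves a minority of planted atoms unrecovered.
* The R-peak detector is tuned for single-lead, QRS-dominant morphology at
  128 Hz; it is not an arrhythmia-grade detector.
* Beat-level classification ignores within-interval correlation; subjects
  contribute ~70 statistically dependent beats each, which the
  subject-wise CV split accounts for but per-beat accuracy figures do not.
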