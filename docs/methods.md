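# Methods

## The detection problem

A 30-second single-lead ECG from a consumer smartwatch must be classified
as atrial fibrillation (AF) or not. AF is defined by a completely
irregular ventricular rhythm — RR intervals with no repeating pattern.
The difficulty is the converse class: premature atrial/ventricular
complexes (PAC/PVC), Wenckebach AV block and other arrhythmias are also
irregular, but their irregularity is *patterned*. A screen that stops at
irregularity mislabels them as AF. The algorithm here is deliberately
all-inclusive (no heart-rate window, no quality gate, no inconclusive
verdict) and compensates with a second step that searches the Lorenz
(Poincaré) plot for regular structure.

## Step 1 — irregularity features

**count RR.** `count_rr = #{i : |RR_i − median| ≤ 15 ms} / HR`, with
HR = 60/mean(RR) in bpm. The 15 ms window is absolute (so the statistic is
deliberately not scale-invariant), the comparison inclusive (boundary ties
count), and the median of an even-length list is the mean of the two
central values. Heart-rate normalisation makes a slow, regular rhythm
score higher than a fast one with the same number of matches; the
definition of HR as 60/mean(RR) uses only the detected beats, so a
30-beat, 30 s sinus strip gives the natural 60 bpm. Requires ≥ 5
intervals.

**SVD ratio.** The Lorenz embedding maps n intervals to n−1 points
(RRₙ, RRₙ₊₁). The feature is s₁/s₂ of the singular values of the **raw,
uncentred** (n−1)×2 coordinate matrix. Uncentred is essential: a regular
rhythm puts all points at one spot far from the origin, making the matrix
numerically rank-1 and the ratio explode — which is exactly the
order-of-magnitude contrast (regular ≈ 50–100 vs AF ≈ 5–10) the
threshold exploits. Mean-centring would send regular rhythms toward
ratio ≈ 1 and destroy the contrast. Rank-deficient inputs
(s₂ < 1e−12·s₁) return a finite sentinel (1e6) instead of infinity so
`≤ threshold` comparisons stay well-defined. Requires ≥ 3 points.

A strip is *irregular* iff `count_rr ≤ count_rr_max` **and**
`svd_ratio ≤ svd_ratio_max` (both inclusive). Defaults 0.158 and 13.31
are the validated clinical rule; an alternative count RR cutoff of 0.146
from the threshold-search stage is kept as a documented constant. Strips
with < 5 intervals raise an error rather than silently classifying — the
caller should record a longer strip.

## Step 2 — cluster veto

Irregular strips are searched for clusters with k-means (scikit-learn,
10 seeded restarts, best inertia) for k = k_max…2 (default k_max 4; a
premature-beat rhythm produces at most 4 interval-pair combinations). A
partition is **accepted** only if

1. every cluster has ≥ 2 members (`min_cluster_size`; a single aberrant
   interval must not veto AF);
2. every cluster's radius — the maximum member-to-own-centroid distance —
   is ≤ 0.5 s (`max_cluster_width`);
3. the minimum distance between members of *different* clusters exceeds
   0.4 s (`min_separation`).

`cluster_count` is the largest accepted k, else 1. The verdict is AF iff
the count equals 1. Fewer than 4 points trivially count as one cluster.

**Why separation is an inter-member gap and not a centroid distance.**
This was the one genuinely open design choice, and the geometry decides
it. k-means will happily split a single diffuse AF cloud: for
uniformly distributed intervals on [0.4, 1.2] s the Lorenz cloud is a
square of side 0.8 s, and a 2-means split produces centroids almost
exactly 0.4 s apart with per-cluster radii under 0.5 s — so a
centroid-distance reading of "distance > 0.4" accepts spurious clusters
in the vast majority of AF strips (measured: ~83%). What a contiguous
cloud can never do is split across an *empty margin*: the minimum
member-to-member gap between the halves of a diffuse cloud is on the
order of the nearest-neighbour spacing (~0.1 s), far below 0.4 s, whereas
the discrete clouds of ectopic rhythms are separated by genuinely empty
space. With the gap criterion the measured false-cluster rate on 1000
synthetic AF strips is 0%, while PAC/PVC cluster detection stays at
95–100%. The constants 0.4/0.5 are deliberately wide — the design
accepts occasionally missing clusters (a PVC strip with only one ectopic
event cannot form ≥ 2-member clusters) rather than ever finding clusters
in AF, because step 2 exists solely to remove false positives.

All geometry is in seconds on the RR axes. Increasing `min_separation`
can only decrease the cluster count (monotone safety), and the veto can
only ever flip AF → NOT-AF.

## R-peak detection

The QRS complex concentrates energy near 10–40 Hz. The detector:

1. computes an undecimated (maximal-overlap) discrete wavelet transform
   (`sym4`, PyWavelets `swt` with `norm=True`), keeps the detail levels
   whose dyadic band [fs/2^(j+1), fs/2^j] overlaps 10–40 Hz, zeroes the
   rest, inverts, and squares the reconstruction — a nonnegative QRS
   envelope. Baseline wander (≤ ~0.5 Hz) and T waves fall outside the
   retained bands and are rejected to numerical precision;
2. **pass 1**: envelope peaks above an adaptive threshold (0.25 × rolling
   2 s envelope maximum, floored at 5% of the global maximum) with a
   0.25 s refractory period (240 bpm guard);
3. **pass 2**: every inter-peak gap longer than 1.5 × the running median
   RR is re-searched with the threshold halved, rescuing low-amplitude
   beats;
4. **pass 3**: each detection snaps to the extremum of |raw − local
   median| within ±60 ms — polarity-aware, so negative-dominant
   (ventricular) complexes snap correctly.

All constants are exposed in `PeakConfig`. The detector works at native
rate (≥ 128 Hz, ≥ 2 s of signal); no resampling. Peak times are
shift-equivariant and amplitude-scale invariant by construction. A flat
or energy-free strip returns zero peaks (not an error); downstream
classification requires ≥ 6 peaks.

## Threshold tuning

Candidate cutoff pairs (a, b) define step-1 classifiers
"AF iff count_rr ≤ a and svd_ratio ≤ b". The default grid per axis is
the sorted set of observed feature values plus +∞ — every
threshold-equivalence class is represented, so exhaustive enumeration
provably finds the optimum. The selected pair minimises
√((1−Se)² + (1−Sp)²), the Euclidean distance to the perfect ROC corner
(sensitivity 1, false-positive rate 0); ties break toward the smaller
(count_rr, then svd_ratio) cutoffs for determinism. The cluster-geometry
constants are configuration, not tuned parameters.

## Evaluation

Sensitivity, specificity, PPV, NPV, accuracy and the F2 score
(F2 = 5·PPV·Se/(4·PPV+Se) = 5tp/(5tp+4fn+fp), weighting sensitivity four
times as heavily as precision) are computed from a 2×2 confusion matrix
with AF positive. Zero-denominator ratios are reported as NaN, never 0.
External classifiers may emit "inconclusive"; the scoring convention
counts those as wrong verdicts. Paired classifiers are compared with
McNemar's test on the discordant counts b, c: χ² = (|b−c|−cc)²/(b+c)
with one degree of freedom, cc = 1 only when the continuity correction
is requested (default off, matching the plain discordant-pairs χ²
formulation). Against the exact two-sided binomial(b+c, ½) tail the χ²
p-value agrees within 0.09 absolute wherever the exact p ≤ 0.2, and
within 0.25 for b+c ≥ 10; the statistic itself is exact as a fraction.

## Synthetic data

No public dataset pairs smartwatch strips with expert rhythm labels, so
the generator produces the six rhythm classes with the RR-interval
structure each needs to exercise the pipeline:

| class | model | defaults |
|---|---|---|
| sinus | mean RR + Gaussian jitter + respiratory modulation | 1.0 s, σ 0.02 s, ±0.03 s @ 4 s |
| AF | i.i.d. Uniform(low, high) intervals | 0.4–1.2 s |
| PAC | every k-th beat premature: (k−2) base, coupling, pause | k=3, coupling 0.60, pause 1.40 × RR |
| PVC | same cycle, wide biphasic negative QRS | k=12, RR 0.95 s, coupling 0.42, pause 1.58 |
| AVB | Wenckebach (P:QRS) grouping, dropped beat ≈ 2× base | 4:3, RR 0.9 s, σ 0.01 s |
| SSS | bradycardic base with pauses ≥ 2 s | RR 1.3 s, pause prob 0.08, pauses 2.0–2.8 s |

Choices worth noting:

* The last interval that would cross the strip end is dropped, not
  truncated, so RR statistics carry no artificial short interval.
* AF as i.i.d. uniform is the simplest model of "no lag structure"; a
  uniform cloud is also the *hardest* case for the cluster veto (maximal
  spread), so the 0% false-cluster rate is a conservative reading.
* The PAC/PVC cycle is the steady-state of every-k-th-beat ectopy: the
  pause ends on a sinus beat, so the repeating interval pattern is
  (k−2) base intervals, one coupling, one pause — k=3 is true trigeminy
  (base, coupling, pause) with no consecutive-base pairs. PVC coupling
  0.42 with a full compensatory pause (coupling + pause = 2 cycles) is
  typical ventricular-ectopy timing, and its sparse default rate (~2–3
  PVCs per strip) reproduces the published ordering of the class
  medians: SVD ratio sinus > PVC > AF ≈ PAC, and count RR lowest for AF.
* AVB and SSS use reduced jitter (σ 0.01–0.015 s), reflecting the low
  short-term heart-rate variability of these typically older,
  conduction-impaired patients; this keeps their base rhythm correctly
  classified as regular by count RR despite the low heart rate dividing
  fewer interval matches.
* ECG waveforms are sums of Gaussian bumps (P, Q, R, S, T) per beat; AF
  records carry no P waves, PVC beats get a wide (~120 ms) biphasic
  negative-dominant template with no P wave and a discordant T. Noise and
  baseline wander are additive and never move the ground-truth R times.
  Beats whose R would sit within 100 ms of the strip edge are dropped
  (with their intervals) so every rendered R peak is whole.
* Cohorts spawn per-record seeds from the cohort seed via
  `numpy.random.SeedSequence`, so (n, seed) reproduces records exactly.

What the generator does **not** model: realistic P/QRS/T morphology
(no dynamical ECG model), atrial flutter/junctional rhythms, fibrillatory
f-waves, muscle-artefact noise, electrode drop-out, or beat-to-beat
morphology variation. Passing tests therefore demonstrate the *algorithmic*
behaviour of the pipeline on rhythms with the stated RR structure — not
clinical performance on real smartwatch tracings, whose accuracy can only
be established on clinical data.

## Problem sizes and numerical choices

Test and acceptance runs use 30 s strips at 512 Hz, cohorts of 50 strips
per class (100 per class for threshold training) and 1000 AF strips for
the false-cluster rate — sizes at which every Monte-Carlo margin in the
checks is wide relative to sampling noise. k-means uses 10 seeded
restarts; all tolerances (±20 ms beat matching, 1e−9 relative SVD oracle
agreement, 0.01-percentage-point metric reproduction) are stated at the
point of use in the tests. Degenerate inputs are handled by policy rather
than exception where a value is representable (empty peak list for a flat
strip, NaN for a 0/0 metric, sentinel for a rank-1 SVD), and by explicit
errors where classification would otherwise guess (fewer than 5
intervals, fewer than 6 peaks, non-finite samples).

## Known limitations

* The two printed count RR cutoffs (0.146 from threshold search, 0.158
  in the validated rule) cannot be reconciled from the source material;
  0.158 is the default and both are exposed.
* The cluster-geometry constants (0.4/0.5 s) are taken as seconds on the
  RR axes; if the original constants were in normalised units the
  defaults can be overridden in `ClusterParams`.
* The exact wavelet scales and three-step procedure of the reference
  detector are unpublished; only end-to-end behaviour on synthetic data
  is verifiable.
* PDF/SVG digitisation of proprietary smartwatch exports is out of
  scope; the CSV reader is the interface point for a future adapter.
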