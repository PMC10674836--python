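# irregular-af

Two-step atrial-fibrillation (AF) detection for 30-second single-lead
smartwatch ECG strips.

AF produces a *completely* irregular ventricular rhythm: the RR intervals
(times between successive R peaks) show no repeating pattern. Most other
irregular rhythms — premature atrial/ventricular complexes, higher-degree
AV block — are irregular but contain *regular structure*. Commercial
smartwatch classifiers screen only for irregularity, so these rhythms
become false AF positives, and many strips are rejected as inconclusive.
This package implements an all-inclusive two-step rule that fixes both
problems:

1. **Irregularity screen.** Two statistics are computed from the RR series
   of a strip:

   * `count RR` — the number of intervals within ±15 ms of the strip's
     median RR, divided by the heart rate (HR = 60 / mean RR):

     `count_RR = #{ i : |RR_i − median(RR)| ≤ 0.015 s } / HR`

     Regular rhythms have many near-median intervals (large values); AF
     has almost none.

   * `SVD ratio` — the ratio s₁/s₂ of the two singular values of the raw
     (uncentred) matrix of Lorenz-plot points (RRₙ, RRₙ₊₁). A regular
     rhythm collapses onto one point on the identity diagonal (s₂ → 0,
     ratio → ∞); AF fills the plane (ratio small).

   A strip is *irregular* when both `count_RR ≤ 0.158` and
   `SVD ratio ≤ 13.31` (cutoffs tunable; these defaults are the validated
   clinical rule).

2. **Regularity-within-irregularity veto.** The Lorenz plot of an
   irregular strip is searched for well-separated point clusters with
   constrained k-means (k = 4…2): clusters must be compact (radius
   ≤ 0.5 s), populated (≥ 2 members) and separated by a genuine empty
   margin (> 0.4 s between members of different clusters). Premature
   beats create 3–4 such clusters (base / coupling / pause interval
   combinations); AF forms a single diffuse cloud. The verdict is **AF
   only if the cluster count equals 1** — otherwise the irregularity has
   a regular pattern and the AF call is withdrawn.

Every strip with at least five RR intervals receives a definite AF /
NOT-AF verdict; there is no inconclusive outcome and no heart-rate or
quality exclusion.

The package also provides:

* a **synthetic rhythm/ECG generator** (sinus, AF, PAC, PVC, Wenckebach
  AV block, sick-sinus syndrome) with ground-truth R times, since no
  public smartwatch-ECG dataset with these labels exists;
* a **wavelet R-peak detector** (undecimated wavelet transform, 10–40 Hz
  detail levels, three-pass peak finding with low-amplitude rescue and
  polarity-aware snapping);
* **threshold tuning** by exhaustive 2-D ROC grid search (minimum
  Euclidean distance to the perfect corner);
* **evaluation metrics** (sensitivity, specificity, PPV, NPV, F2,
  accuracy) and paired-classifier comparison via McNemar's χ² test.

## Worked example

```python
import irregular_af as ia

for label in ("af", "pac"):
    rec = ia.simulate_record(label, seed=11)        # 30 s @ 512 Hz
    decision = ia.classify_ecg(rec)                 # peaks -> RR -> rule
    f = decision.features
    print(label, decision.verdict.value, f"count_rr={f.count_rr:.3f}",
          f"svd={f.svd_ratio:.2f}", f"clusters={decision.cluster_count}")
```

prints

```
af AF count_rr=0.052 svd=4.52 clusters=1
pac NOT_AF count_rr=0.082 svd=3.62 clusters=3
```

Both strips pass the irregularity screen (low count RR, low SVD ratio),
but the PAC strip shows three Lorenz clusters — the base, coupling and
pause interval pairs of trigeminal premature beats — so its AF call is
vetoed, while the diffuse AF cloud keeps its AF verdict. The scripts in
`examples/` walk through generation, detection, tuning and evaluation the
same way.

A thin CLI mirrors the library:

```bash
irregular-af simulate --class af --n 50 --seed 42 --out cohort/
irregular-af features cohort/rr.csv --out features.csv
irregular-af classify cohort/rr.csv --rr --out decisions.json
```

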