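# piezoid

Person identification from the cardiac vibration spectrum of a sheet-type
piezoelectric sensor.

A PVDF sheet laid on a chair or bed picks up the tiny body vibrations driven
by the heartbeat (a ballistocardiogram-like signal). The frequency spectrum
of that vibration differs visibly between people: some carry most energy at
the ~1 Hz cardiac fundamental, others carry almost none there and instead
show higher harmonics amplitude-modulated at the heart rate. `piezoid`
turns this observation into a small biometric pipeline for unobtrusive
monitoring settings (e.g. multi-resident elder-care homes, where the system
must know *who* is on the sensor without any wearable).

## Method

For one recording, the pipeline:

1. selects the most stationary 10-s stretch (minimum of the max/median RMS
   ratio over 1-s subwindows — movement artifacts inflate the ratio);
2. band-limits it to 0.6–15 Hz with a zero-phase frequency-domain mask
   (below 0.6 Hz lives respiration, above 15 Hz only noise);
3. computes a Hann periodogram (Δf = 0.1 Hz), smooths it with a 3-bin
   conservative moving average, and normalizes it so ∫P(f) df = 1 over the
   band — all downstream features are therefore independent of sensor gain;
4. extracts two spectral-shape descriptors at the 1/2 and 1/4 *power
   standards* (fractions of the global maximum P*):

   - **number of peak shapes** N = (N₁/₂ + N₁/₄)/2, where N_f counts the
     local maxima exceeding f·P*;
   - **sharpness** S = N / (A₁/₂ + A₁/₄), where A_f is the total area of
     the convex-upward caps cut off by the threshold line f·P*
     (overlapping caps counted once). Tall narrow harmonics ⇒ small caps ⇒
     large S.

5. matches the measurement against enrolled subjects by nearest centroid in
   the z-scored plane (N, r), where r = S − (β₀ + β₁N) is the residual of
   the population regression of sharpness on peak number (the raw pair is
   strongly correlated by construction; the residual carries the
   person-specific part).

A seeded simulator generates realistic recordings — jittered heartbeat
harmonic combs (beat intervals fluctuate within ±100 ms), AM-modulated
harmonics with suppressed fundamentals, respiration, noise, and movement
bursts — and labelled multi-session cohorts for evaluation.

## Worked example

Generate a 4-subject, 3-session synthetic cohort, inspect one recording's
features, and run leave-one-session-out identification:

```
$ piezoid simulate --subjects 4 --sessions 3 --seed 11 --out cohort
wrote 12 recordings to cohort

$ piezoid features cohort/S01_d1.csv --rate 100 --subject S01 --session d1
subject,session,n_peaks,sharpness
S01,d1,1,1.2251968711676635

$ piezoid evaluate cohort
cases,12
top1_accuracy,1
median_intra_distance,0.0932889
median_inter_distance,2.4309
```

Subject S01 shows a single dominant spectral peak (N = 1) with a fairly
broad cap (S ≈ 1.23). Across the cohort every held-out session is matched
to its own subject (top-1 accuracy 1.0), and repeat sessions of the same
person sit ~26× closer to their centroid than to other subjects'
(median intra- vs inter-subject distance).

The same operations are available as a library:

```python
from piezoid import CohortSpec, ProfileDB, analyze, synth_cohort

recordings, truth = synth_cohort(CohortSpec(n_subjects=8, n_sessions=3, seed=7))
db = ProfileDB()
for subject, session, raw in recordings:
    db.enroll(subject, session, analyze(raw).features)
report = db.cross_validate()
print(report.accuracy)
```

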