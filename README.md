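# headkin

Characterization of head-movement patterns from head-worn gyroscopes during
functional mobility tasks — built for movement-analysis and vestibular
researchers comparing patients with bilateral (BV) or unilateral (UV)
vestibulopathy against healthy subjects (HS).

Patients with vestibular loss adopt cautious, "en bloc" head-stabilization
strategies; the functional signature of this is a compressed distribution of
head angular velocity and angular acceleration during everyday tasks
(walking, stairs, carrying a tray, U-turns, ...). `headkin` implements the
full analysis chain from raw 3-axis angular-velocity recordings to
group-level statistics:

1. **Signal conditioning** — trim the first/last 5% of each recording,
   zero-phase 4th-order Butterworth low-pass at 6 Hz, Euclidean vector norm
   across the three axes (rotation-invariant movement intensity), central
   -difference temporal derivative (filtered again) for angular acceleration.
2. **Vestibulogram** — per participant x task, the histogram *mode* of the
   velocity-norm (deg/s, 1 deg/s bins) and acceleration-norm (deg/s², 5
   deg/s² bins) distributions; per group, pooled task modes plus the first
   and third quartiles (Q1, Q3) of the pooled distributions. The rectangle
   (Q3ᵥ − Q1ᵥ) · (Q3ₐ − Q1ₐ)/1000 is the group's interquartile **area**
   (10³·deg²/s³), a one-number summary of movement range.
3. **Mixed-model inference** — per measure, the linear mixed-effects model

       y₍ᵢⱼ₎ = α + αᵢ + β₁·group + β₂·task + β₃·(group × task) + ε₍ᵢⱼ₎

   with a random intercept αᵢ per participant, REML estimation, treatment
   coding against the HS group and Walk task, Huber-White cluster-robust
   standard errors (bias-reduced CR2 by default) clustered by participant,
   and Satterthwaite degrees of freedom. Effects are summarized as
   **Δ-percent**, 100·(β − α)/α, the relative change against the reference
   cell. Pearson (velocity vs acceleration modes) and Spearman (modes vs
   perceived difficulty) correlations complete the analysis.
4. **Synthetic cohorts** — a generator producing band-limited (0.5–5 Hz)
   gyroscope recordings with known per-cell modes, study-shaped groups
   (19 BV / 20 UV / 20 HS, 11 tasks), group scale ordering BV < UV < HS and
   high-frequency sensor noise, so the entire chain is testable end to end
   with known ground truth.

## Worked example

```python
import headkin as hk

config = hk.CohortConfig(seed=42)           # study-shaped synthetic cohort
cohort = hk.generate_cohort(config)
series = [hk.process_recording(r) for r in cohort.recordings.values()]
records = hk.participant_task_modes(series)

for group in hk.Group:
    v = hk.build_vestibulogram(series, group)
    print(f"{group.value}: Q1-Q3 area = {v.iqr_area:.2f} x10^3 deg^2/s^3 "
          f"(Q1 {v.q1_velocity:.1f} deg/s, Q3 {v.q3_velocity:.1f} deg/s)")

table = hk.assemble_observations(records, "angular_velocity")
fit = hk.fit_mixed_model(hk.build_design(table))
result = hk.inference_table(fit, vcov="cr2")
print(result.loc[["Intercept", "group[BV]", "task[UTurn]"],
                 ["estimate", "se", "df", "p", "delta_percent"]].round(3))
```

prints

```
BV: Q1-Q3 area = 1.22 x10^3 deg^2/s^3 (Q1 7.2 deg/s, Q3 15.5 deg/s)
UV: Q1-Q3 area = 1.65 x10^3 deg^2/s^3 (Q1 8.6 deg/s, Q3 18.3 deg/s)
HS: Q1-Q3 area = 3.59 x10^3 deg^2/s^3 (Q1 13.2 deg/s, Q3 27.5 deg/s)
             estimate     se      df    p  delta_percent
term
Intercept      14.650  0.477  19.000  0.0            NaN
group[BV]      -6.466  0.602  36.898  0.0         -144.1
task[UTurn]    43.400  1.636  19.000  0.0          196.2
```

The interquartile areas increase from BV through UV to HS — patients move
their heads through a narrower velocity/acceleration range. The model table
reads: healthy subjects walk with a modal head velocity of ≈14.7 deg/s; BV
patients sit ≈6.5 deg/s below that reference (Δ = −144%), while a U-turn
raises modal velocity by ≈43 deg/s regardless of group.

A command-line interface wraps the same pipeline:

```sh
headkin simulate --out cohort/ --seed 42
headkin report --manifest cohort/manifest.csv --ratings cohort/ratings.csv --out results/
```

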