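# improvsync

Quantifying interpersonal synchronization (IPS) in joint piano improvisation.

Two people share one keyboard: a therapist plays a structured ABA′
accompaniment (a stable bourdon at 80 BPM, a freer and faster B section, a
return to the bourdon), and a participant improvises freely on the white
keys of the upper register. The recording is a standard MIDI file split at
G4; a manual beat annotation supplies the shared pulse. This package turns
such recordings into per-section behavioral features and asks whether
timing behavior alone predicts group membership (patient vs. matched
control) — a workflow relevant to music therapy research and behavioral
phenotyping of interpersonal functioning.

## What it computes

For each participant and section (A, B, B1, B2, A′), fifteen variables:

- **Synchronization** — metrical deviations of each note from the nearest
  eighth-note grid point of the annotated pulse: MD_m, MD_sd (mean/sd of
  |deviation|), LP (lag proportion, the fraction of notes behind the beat),
  and the one-sided statistics MDA_m/MDA_sd (ahead) and MDB_m/MDB_sd
  (behind).
- **Tempo** — TMP_m, TMP_sd from the annotated inter-beat intervals.
- **Rhythmic patterns** — CR_dur, the compression ratio of the quantized
  (ontime, duration) point set under a greedy translational-pattern
  (SIATEC-family) cover; TC_o, the proportion of ontimes covered by repeated
  structure; RS, the modal proportion of inter-onset intervals.
- **Interpersonal imitation** — DN (notes per beat) and AI_mu/AI_min
  (mean/minimum per-beat articulation interaction between the players).

The statistical stage screens variables with Welch t-tests, fits logistic
regressions of diagnosis on selected features (deviances, AIC, Nagelkerke
R², Hosmer–Lemeshow), validates by leave-one-out cross-validation, and
compares against an exact binomial guessing baseline
P(X > k | n, p) = Σ_{j>k} C(n,j) p^j (1−p)^{n−j}. A derived improvement
variable, MD_m_B1 − MD_m_B2, is correlated with attachment and other
questionnaire covariates per group.

Because recordings of this kind are not publicly deposited, the package
includes a synthetic generator producing ABA′ duets (bourdon accompaniment,
white-key participant, group-dependent timing-deviation dynamics across
B1→B2) and full cohorts with known ground truth; see `docs/methods.md`.

## Worked example

```
python analysis/01_simulate_cohort.py     # 16 patients + 12 controls -> scratch/cohort/
python analysis/02_extract_features.py    # 75 features per participant -> results/features.csv
python analysis/03_model_diagnosis.py     # screens, three regressions, LOOCV, baselines
python analysis/04_attachment_correlates.py
```

On the default cohort (seed 0), step 03 prints the metrical-deviation model

```
(A)
Variable             B      SE B       z       P
Intercept        -0.05      1.70   -0.03   0.978
MD_m_B1        -355.44    170.37   -2.09   0.037
MD_m_B2         433.13    164.85    2.63   0.009
Null deviance: 38.24 on 27 degrees of freedom
Residual deviance: 18.93 on 25 degrees of freedom
AIC: 24.93
Nagelkerke R2: 0.67; Hosmer-Lemeshow chi2(8) = 4.87, p = 0.77

model A: LOOCV error 0.14 (24/28 correct)
```

Read: the coefficient on MD_m_B1 is negative and on MD_m_B2 positive, so
what predicts being a patient is *not improving* — deviations that fail to
shrink from B1 to B2. The model classifies 24 of 28 subjects correctly under
leave-one-out cross-validation, far better than guessing
(P(X > 23 | 28, 0.5) < 0.001). The lag-proportion models (B, C) fit worse by
AIC, matching the intended structure of the synthetic cohort. Step 04 then
finds the positive correlation between attachment avoidance and the
improvement variable among patients (r ≈ 0.65 at the default settings) and
no such structure among controls.

The same pipeline runs from the command line (`improvsync simulate`,
`extract`, `model`, `all`) for user-supplied MIDI + annotation data; every
report carries a provenance block with config, seed and versions.

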