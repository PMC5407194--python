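# Methods

## Setting and measurement model

The package analyses one-keyboard piano duets in which a therapist plays an
ABA′ accompaniment — a repeated four-beat bourdon figure at 80 BPM (a low E2
for one beat, then a sustained B2+E3 fifth chord for three beats) in A and
A′, and a freer, faster middle section B — while a participant improvises on
white keys in the upper register. The keyboard is split at G4 (MIDI 67, with
C4 = 60): pitches at or above the split belong to the participant, pitches
below to the therapist. A pitch exactly at the split is assigned to the
participant.

Interpersonal synchronization is measured against a shared pulse. Beat
annotations arrive at the quarter-note (tactus) level, the product of manual
beat tracking; the analysis grid is at the eighth-note level, obtained by
linearly interpolating one point between each pair of annotated beats. Each
participant note is compared with its nearest grid point; the signed
deviation is onset minus grid time, so positive means the note lags behind
the beat. Ties at exact midpoints resolve to the earlier grid point. Notes
before the first or after the last grid point have no two-sided neighbour
and are excluded from deviation statistics (logged).

Section B is bisected into B1 and B2 at its temporal midpoint — elapsed time
between the first B-labelled beat and the first A′-labelled beat — rather
than at the median note, because the construct of interest is change over
the course of the freer interaction. Notes are assigned to sections by onset
in half-open intervals; A′ extends just past the last sounding event.

## The fifteen variables

Per participant and section:

1–7. **MD_m, MD_sd** — mean and sample sd (n−1 denominator throughout) of the
absolute deviations; **LP** — lag proportion, the fraction of notes with
strictly positive signed deviation; **MDA_m/MDA_sd** and **MDB_m/MDB_sd** —
mean/sd of |deviation| restricted to notes ahead of (negative) and behind
(positive) the beat. Exact zeros count in MD_* and the LP denominator but in
neither one-sided set; consequently MD_m = LP·MDB_m + (1−LP)·MDA_m exactly
when no deviation is zero. An empty one-sided set yields a missing value,
never zero. Units are seconds internally and in the feature CSV (the
logistic coefficients of interest are on this scale).

8–9. **TMP_m, TMP_sd** — mean and sd of the local tempo 60/IBI over the
annotated beats in the window. Tempo is a property of the shared pulse, so
it is computed from the annotation, not from participant notes.

10–11. **CR_dur, TC_o** — compression-based structure measures on quantized
point sets: ontime = index of the nearest grid point, duration = sounded
duration over the local eighth length, floored at one unit; duplicate points
collapse (set semantics). Repeated structure is found by a greedy
translational-pattern cover in the SIATEC/COSIATEC family. For every nonzero
difference vector d between points of the remaining set, the maximal
translatable pattern MTP(d) = {p : p + d ∈ set} is a candidate pattern. Its
translator set starts from every vector t with pattern + t inside the set,
then is pruned greedily (translators added in order of new points covered,
ties to the smaller vector, while the ratio covered/(|pattern|+|translators|)
improves). Pruning matters: with maximal translator sets, overlapping
occurrences make strictly periodic sequences incompressible — a periodic
12-point set would have every class at ratio 12/13 — defeating the purpose
of the measure. At each step the class with the best ratio is selected (ties:
larger pattern, then lexicographically smaller pattern, then smaller
translators); selection stops when no class exceeds ratio 1; leftover points
become residual. Encoding cost is Σ(|pattern|+|translators|−1) over selected
classes plus one per residual point. **CR_dur** is |points|/cost of the 2-D
(ontime, duration) set (CR = 1 for empty or incompressible input); **TC_o**
is the proportion of distinct ontimes covered by selected classes of the 1-D
ontime set. The greedy cover's cost is bounded below by the exhaustive
optimum over the same class vocabulary, which the tests verify on small sets.

12. **RS** — rhythmic simplicity: inter-onset intervals are taken between
consecutive *distinct* quantized onsets (chords collapse), and RS is the
modal proportion; ties for the mode resolve to the smaller interval.
Isochronous playing gives RS = 1; all-distinct IOIs give 1/(#IOIs).

13–15. **DN** — participant notes per annotated quarter-note beat in the
window. **AI_mu, AI_min** — articulation interaction: per note, articulation
is sounded duration over the IOI to the next distinct onset, capped at 2
(final notes reuse the last defined IOI); per one-beat window each player's
mean articulation is compared, s_w = 1 − min(1, |a_participant − a_therapist|),
and AI_mu/AI_min are the mean and minimum of s_w over windows where both
players sound. The definition is symmetric under swapping players. The texts
naming DN and AI give no closed formulas, so these per-beat,
absolute-difference operationalizations are this package's own fixed choices
(per-beat rather than per-second density; difference rather than correlation
for articulation).

## Statistical stage

Group membership (patient = 1, control = 0) is modelled by maximum-likelihood
logistic regression (statsmodels GLM, binomial family), complete-case per
model. Reported diagnostics: Wald z and two-sided p per coefficient, null
and residual deviance, AIC, Nagelkerke R²
(= (1 − exp(2(ℓ₀−ℓ₁)/n)) / (1 − exp(2ℓ₀/n))), and the Hosmer–Lemeshow χ²
over g = 10 predicted-probability groups with df = g − 2. Perfect or
quasi-separation is detected from fitted probabilities hugging 0/1 and
flagged rather than silently reported, since separated fits have unbounded
coefficients.

The screening stage is a Welch two-sample t per feature, ranked by raw p;
Bonferroni-adjusted p-values are reported alongside but the primary ranking
is uncorrected, matching the exploratory character of the screen. Stepwise
selection enters the best-screening variable if its p < 0.05 (or starts from
supplied seed terms), then alternates AIC-improving forward steps with
backward removal of terms whose Wald p > 0.10; the path is logged so either
deviance- or Wald-oriented readings of the procedure can be audited.

Validation is leave-one-out cross-validation: refit without each subject,
classify the held-out subject at predicted probability > 0.5 (threshold
fixed at 0.5; non-convergent folds count as misclassified and are logged);
error = misclassified/n. The chance baseline is the exact binomial tail
P(X > k) at p = 0.5 and at the observed prevalence. The derived improvement
variable MD_m_B1 − MD_m_B2 (positive = deviations shrink = improving
synchronization) is screened against questionnaire covariates by per-group
Pearson correlations (df = n − 2), a two-predictor OLS of improvement on
avoidance + anxiety among patients (R², F), a Welch t across groups, and a
paired t restricted to complete matched pairs. Matching does not force a
matched analysis; the paired test is reported alongside, not instead.

## Synthetic data: what it emulates and what it does not

The generator reproduces the paradigm's structure: 80 BPM bourdon bars in
A/A′, a freer B section faster by a configurable proportion (default +15%),
beat annotations taken from the generative pulse, and participant notes on
upper white keys at `density` notes per beat (default 1.5). Participant
onsets sit on the eighth grid plus a signed deviation: behind the beat with
probability `lag_prob`, magnitude |N(lag_bias, dev_sd)| with `dev_sd` per
sub-section (magnitudes clipped at 45% of the local grid spacing so the
nearest grid point is preserved). Group defaults encode the qualitative
group separation under study: control dev_sd 25 ms (B1) → 15 ms (B2),
lag_prob 0.65; patient 25 ms → 27 ms, lag_prob 0.45. The implied mean
absolute deviation is the folded-normal mean, exposed as
`TimingModel.expected_md` for parameter-recovery tests.

Between-subject heterogeneity has a specific shape, chosen to reproduce the
phenomenon that group *levels* overlap while the B1→B2 *change*
discriminates: each subject draws a shared precision factor (lognormal,
sd 0.35) applied to both sub-sections, a B1→B2 ratio jitter (lognormal,
sd 0.20) around the group ratio, and a lag_prob jitter on the logit scale
(sd 0.50). An earlier independent-jitter draft made single-section levels
perfectly separating, which is not how small clinical cohorts behave.

Patient attachment covariates are drawn jointly with each patient's realized
improvement (computed by actually extracting features from the generated
duet) at configured correlations (avoidance +0.68, anxiety −0.55 by
default); Gold-MSI scales, beat perception, depression severity and
medication count are independent draws, and controls' covariates are
independent throughout. Default cohort size is 16 patients and 12 matched
controls. Everything is reproducible from the spec seed: identical seeds
give bit-identical MIDI and tables.

Limitations of the generator, hence of what green tests demonstrate:
deviations are i.i.d. per note — there is no phase correction, drift, or
serial dependence, so the generator cannot probe sensorimotor-adaptation
dynamics; the therapist is metronomically exact; velocity and pedal carry no
signal; B-section content is a placeholder texture, so pattern variables on
synthetic data reflect the sampling process, not musical motifs. Passing
tests show the measurement chain and statistics are correct under these
conditions, not that the clinical effect sizes generalize.

## Numerical and scale choices

Durations at desk scale: duets default to 24 + 48 + 16 beats (≈60 s), which
keeps a full 28-subject cohort extraction (including pattern discovery on
every section) under ~20 s and the complete test suite within a few minutes.
MIDI I/O uses a hand-written SMF type 0/1 codec (note on/off with velocity-0
note-offs, running status, tempo maps; SMPTE division rejected); written
files use division 480 at the nominal tempo, so round-trips preserve times
within one tick (≈1.6 ms at 80 BPM). Same-pitch re-strikes truncate the
earlier note at the later onset. Degenerate inputs fail loudly: empty MIDI,
a silent side of the register split, non-monotone beat times, section
relapses (anything but one contiguous A→B→A′ run), and B sections of zero
duration are all errors, not NaNs.
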