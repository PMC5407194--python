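"""Synthetic ABA′ duets and cohorts with known ground truth.

The generator emulates the recording paradigm: a therapist bourdon
accompaniment at 80 BPM (a low E2 for one beat, then a sustained B2+E3 fifth
chord for three beats, repeating each four-beat bar) in sections A and A′, a
freer and faster B section, and a participant improvising on white keys at or
above the G4 register split.  Participant onsets sit on the eighth-note grid
plus a signed timing deviation: the note falls behind the beat with
probability ``lag_prob`` and its magnitude is |N(lag_bias, dev_sd)| for the
section's deviation spread.  Group defaults encode the study's qualitative
separation: controls tighten from B1 to B2 (dev_sd 25 ms → 15 ms) and lag
more often (LP 0.65), patients do not tighten (25 ms → 27 ms) and lag less
often (LP 0.45).

Deviations are i.i.d. per note — no phase-correction dynamics — which is the
simplest process consistent with the features measured downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .duet_io import BeatAnnotation, DuetRecording, NoteEvent, Player
from .extract import extract_features

WHITE_KEYS_UPPER = (67, 69, 71, 72, 74, 76, 77, 79, 81, 83, 84)  # G4..C6
WHITE_KEYS_LOWER = (40, 41, 43, 45, 47, 48, 50, 52, 53, 55, 57, 59, 60, 62, 64, 65)
BOURDON_BASS = 40          # E2
BOURDON_CHORD = (47, 52)   # B2 + E3 fifth chord

QUARTER_80BPM = 0.75  # seconds per beat at 80 BPM


@dataclass
class TimingModel:
    """Generative timing parameters for one participant group."""

    group: str  # "control" or "patient"
    dev_sd_B1: float
    dev_sd_B2: float
    lag_prob: float
    dev_sd_A: float | None = None  # defaults to dev_sd_B1
    lag_bias: float = 0.0          # seconds added to the deviation magnitude
    density: float = 1.5           # participant notes per quarter-note beat
    accel_B: float = 0.15          # proportional tempo increase in section B
    n_beats: tuple[int, int, int] = (24, 48, 16)  # beats in A, B, Aprime
    seed: int = 0

    def __post_init__(self):
        if self.dev_sd_B1 <= 0 or self.dev_sd_B2 <= 0:
            raise ValueError("deviation spreads must be positive")
        if not 0 <= self.lag_prob <= 1:
            raise ValueError("lag_prob must be a probability")
        if self.dev_sd_A is None:
            self.dev_sd_A = self.dev_sd_B1

    def dev_sd(self, section: str) -> float:
        return {
            "A": self.dev_sd_A, "Aprime": self.dev_sd_A,
            "B1": self.dev_sd_B1, "B2": self.dev_sd_B2,
        }[section]

    def expected_md(self, section: str) -> float:
        """Mean absolute deviation implied by the folded-normal magnitude draw."""
        mu, sd = self.lag_bias, self.dev_sd(section)
        return sd * math.sqrt(2 / math.pi) * math.exp(-(mu**2) / (2 * sd**2)) + mu * (
            1 - 2 * 0.5 * math.erfc(mu / (sd * math.sqrt(2)))
        )


def control_model(seed: int = 0, **overrides) -> TimingModel:
    params = dict(group="control", dev_sd_B1=0.025, dev_sd_B2=0.015, lag_prob=0.65, seed=seed)
    params.update(overrides)
    return TimingModel(**params)


def patient_model(seed: int = 0, **overrides) -> TimingModel:
    params = dict(group="patient", dev_sd_B1=0.025, dev_sd_B2=0.027, lag_prob=0.45, seed=seed)
    params.update(overrides)
    return TimingModel(**params)


def _beat_structure(model: TimingModel) -> BeatAnnotation:
    n_a, n_b, n_ap = model.n_beats
    dt_a = QUARTER_80BPM
    dt_b = QUARTER_80BPM / (1 + model.accel_B)
    dt_ap = QUARTER_80BPM / (1 + model.accel_B / 2)  # A′ returns faster than 80 BPM
    times, labels = [], []
    t = 0.0
    for n, dt, label in ((n_a, dt_a, "A"), (n_b, dt_b, "B"), (n_ap, dt_ap, "Aprime")):
        for _ in range(n):
            times.append(t)
            labels.append(label)
            t += dt
    return BeatAnnotation(beat_times=times, section_labels=labels)


def _therapist_notes(beats: BeatAnnotation, rng: np.random.Generator) -> list[NoteEvent]:
    notes: list[NoteEvent] = []
    times = beats.beat_times
    labels = beats.section_labels
    bar_pos = 0
    for i, (t, label) in enumerate(zip(times, labels)):
        dt = times[i + 1] - times[i] if i + 1 < len(times) else times[i] - times[i - 1]
        if i == 0 or labels[i - 1] != label:
            bar_pos = 0
        if label in ("A", "Aprime"):
            if bar_pos == 0:
                notes.append(NoteEvent(t, t + dt * 0.95, BOURDON_BASS, 70, Player.THERAPIST))
            elif bar_pos == 1:
                for pitch in BOURDON_CHORD:
                    notes.append(NoteEvent(t, t + 3 * dt * 0.95, pitch, 64, Player.THERAPIST))
        else:  # freer B section: one lower-register note per beat, legato-ish
            pitch = int(rng.choice(WHITE_KEYS_LOWER))
            dur = dt * float(rng.uniform(0.7, 1.0))
            notes.append(NoteEvent(t, t + dur, pitch, int(rng.integers(55, 85)), Player.THERAPIST))
        bar_pos = (bar_pos + 1) % 4
    return notes


def simulate_duet(model: TimingModel, recording_id: str = "sim") -> tuple[DuetRecording, BeatAnnotation]:
    """Generate one duet recording plus its beat annotation, reproducibly from the seed."""
    rng = np.random.default_rng(model.seed)
    beats = _beat_structure(model)
    times = np.asarray(beats.beat_times)
    labels = beats.section_labels

    # eighth-note slots (beat + midpoint), skipping the outermost ones so that
    # jittered onsets always stay inside the grid span
    grid = np.empty(2 * len(times) - 1)
    grid[0::2] = times
    grid[1::2] = (times[:-1] + times[1:]) / 2.0
    slot_section = []
    b_times = [t for t, s in zip(times, labels) if s == "B"]
    ap_start = [t for t, s in zip(times, labels) if s == "Aprime"][0]
    b_mid = b_times[0] + (ap_start - b_times[0]) / 2.0
    for k, gt in enumerate(grid):
        sec = labels[min(k // 2, len(labels) - 1)]
        if sec == "B":
            sec = "B1" if gt < b_mid else "B2"
        slot_section.append(sec)

    notes = _therapist_notes(beats, rng)
    p_slot = min(1.0, model.density / 2.0)
    for k in range(1, len(grid) - 1):
        if rng.random() >= p_slot:
            continue
        local = grid[k + 1] - grid[k]
        sign = 1.0 if rng.random() < model.lag_prob else -1.0
        mag = abs(rng.normal(model.lag_bias, model.dev_sd(slot_section[k])))
        mag = min(mag, 0.45 * local)
        onset = grid[k] + sign * mag
        dur = local * float(rng.uniform(0.5, 1.1))
        pitch = int(rng.choice(WHITE_KEYS_UPPER))
        notes.append(NoteEvent(onset, onset + dur, pitch, int(rng.integers(45, 95)), Player.PARTICIPANT))

    duet = DuetRecording(notes=notes, recording_id=recording_id, nominal_tempo=80.0)
    return duet, beats


@dataclass
class CohortSpec:
    """Cohort size, per-group timing models and covariate correlation structure."""

    n_patients: int = 16
    n_controls: int = 12
    control: TimingModel = field(default_factory=control_model)
    patient: TimingModel = field(default_factory=patient_model)
    rho_avoidance: float = 0.68    # with the realized improvement, patients only
    rho_anxiety: float = -0.55
    # Between-subject heterogeneity: subjects differ widely in overall timing
    # precision (a lognormal factor shared by B1 and B2, so group levels
    # overlap), while the group difference lives in the B1->B2 spread ratio.
    subject_precision_jitter: float = 0.35  # lognormal sd of the shared precision factor
    subject_ratio_jitter: float = 0.20      # lognormal sd on the B1->B2 ratio
    subject_lp_jitter: float = 0.50         # logit-scale sd on lag_prob
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 subjects per group")
        for rho in (self.rho_avoidance, self.rho_anxiety):
            if not -1 <= rho <= 1:
                raise ValueError(f"infeasible correlation {rho}")


def _jitter_model(model: TimingModel, rng: np.random.Generator, spec: CohortSpec, seed: int) -> TimingModel:
    logit = math.log(model.lag_prob / (1 - model.lag_prob))
    lp = 1 / (1 + math.exp(-(logit + rng.normal(0, spec.subject_lp_jitter))))
    precision = float(np.exp(rng.normal(0, spec.subject_precision_jitter)))
    ratio = (model.dev_sd_B2 / model.dev_sd_B1) * float(np.exp(rng.normal(0, spec.subject_ratio_jitter)))
    sd_b1 = model.dev_sd_B1 * precision
    return replace(
        model,
        dev_sd_B1=sd_b1,
        dev_sd_B2=sd_b1 * ratio,
        dev_sd_A=None,
        lag_prob=float(np.clip(lp, 0.02, 0.98)),
        seed=seed,
    )


def simulate_cohort(spec: CohortSpec) -> tuple[dict[str, tuple[DuetRecording, BeatAnnotation]], pd.DataFrame]:
    """Generate all duets and the cohort table (group labels + covariates).

    Patient attachment covariates (ECR-R avoidance/anxiety) are drawn jointly
    with each patient's realized improvement MD_m_B1 − MD_m_B2 at the
    configured correlations; all other covariates are independent of playing,
    and controls' covariates are independent throughout.
    """
    rng = np.random.default_rng(spec.seed)
    duets: dict[str, tuple[DuetRecording, BeatAnnotation]] = {}
    rows: list[dict] = []

    improvements: list[float] = []
    for i in range(spec.n_patients):
        sid = f"P{i + 1:02d}"
        model = _jitter_model(spec.patient, rng, spec, seed=int(rng.integers(2**31)))
        duet, beats = simulate_duet(model, recording_id=sid)
        duets[sid] = (duet, beats)
        feats = extract_features(duet, beats, sync_only=True)
        improvements.append(feats["MD_m_B1"] - feats["MD_m_B2"])
        rows.append({"participant_id": sid, "group": 1,
                     "matched_pair": f"pair{i + 1:02d}" if i < spec.n_controls else None})
    for i in range(spec.n_controls):
        sid = f"C{i + 1:02d}"
        model = _jitter_model(spec.control, rng, spec, seed=int(rng.integers(2**31)))
        duet, beats = simulate_duet(model, recording_id=sid)
        duets[sid] = (duet, beats)
        rows.append({"participant_id": sid, "group": 0, "matched_pair": f"pair{i + 1:02d}"})

    table = pd.DataFrame(rows)
    n_p, n_c = spec.n_patients, spec.n_controls

    imp = np.asarray(improvements)
    z = (imp - imp.mean()) / imp.std(ddof=1) if imp.std(ddof=1) > 0 else np.zeros(n_p)
    ra, rx = spec.rho_avoidance, spec.rho_anxiety
    avoid_p = 4.5 + 1.0 * (ra * z + math.sqrt(1 - ra**2) * rng.standard_normal(n_p))
    anx_p = 4.8 + 1.0 * (rx * z + math.sqrt(1 - rx**2) * rng.standard_normal(n_p))

    avoidance = np.concatenate([avoid_p, rng.normal(2.8, 0.9, n_c)])
    anxiety = np.concatenate([anx_p, rng.normal(3.0, 0.9, n_c)])
    table["avoidance"] = np.clip(avoidance, 1, 7)
    table["anxiety"] = np.clip(anxiety, 1, 7)

    n = n_p + n_c
    table["gold_msi_general"] = np.clip(rng.normal(70, 18, n), 18, 126)
    for sub in ("active_engagement", "perceptual_abilities", "musical_training",
                "singing_abilities", "emotions"):
        table[f"gold_msi_{sub}"] = np.clip(rng.normal(30, 8, n), 7, 63)
    table["beat_perception"] = rng.binomial(18, 0.8, n)  # correct of 18 trials
    table["did_severity"] = np.where(table["group"] == 1,
                                     np.clip(rng.normal(30, 10, n), 0, 76), np.nan)
    table["medication_count"] = np.where(table["group"] == 1,
                                         rng.poisson(1.3, n), np.nan).astype(float)
    return duets, table


def write_dataset(out_dir, duets, table: pd.DataFrame) -> None:
    """Write per-subject MIDI + beat CSVs and the cohort table under out_dir."""
    from pathlib import Path

    from .duet_io import write_beats, write_duet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sid, (duet, beats) in duets.items():
        write_duet(out / f"{sid}.mid", duet)
        write_beats(out / f"{sid}_beats.csv", beats)
    table.to_csv(out / "cohort.csv", index=False)
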