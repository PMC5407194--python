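"""Duet recordings and beat annotations: domain types and file I/O.

A duet is recorded on one keyboard with a register split: the therapist plays
the lower register, the participant the upper.  The split point defaults to
G4 (MIDI 67, middle C = C4 = 60), with pitches at or above the split assigned
to the participant.  Beat annotations are the product of manual beat tracking
at the quarter-note (tactus) level and arrive as a CSV sidecar with one row
per beat: time in seconds and a section label among A, B, Aprime.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd

from . import smf

SPLIT_PITCH_G4 = 67
SECTION_ORDER = ("A", "B", "Aprime")


class DuetIOError(ValueError):
    """Raised for unreadable or degenerate duet inputs."""


class Player(str, Enum):
    THERAPIST = "therapist"
    PARTICIPANT = "participant"


@dataclass(frozen=True)
class NoteEvent:
    """One sounded note in performed time (seconds)."""

    onset: float
    offset: float
    pitch: int
    velocity: int
    player: Player

    def __post_init__(self):
        if not self.offset > self.onset:
            raise ValueError(f"offset ({self.offset}) must exceed onset ({self.onset})")
        if not 0 <= self.pitch <= 127:
            raise ValueError(f"pitch {self.pitch} outside 0..127")

    @property
    def duration(self) -> float:
        return self.offset - self.onset


@dataclass
class DuetRecording:
    """All notes of one improvisation, sorted by onset then pitch."""

    notes: list[NoteEvent]
    recording_id: str = ""
    nominal_tempo: float = 80.0

    def __post_init__(self):
        self.notes = sorted(self.notes, key=lambda n: (n.onset, n.pitch))

    def part(self, player: Player) -> list[NoteEvent]:
        return [n for n in self.notes if n.player is player]

    @property
    def last_event_time(self) -> float:
        return max(n.offset for n in self.notes)


@dataclass
class BeatAnnotation:
    """Manually tracked quarter-note beat times with contiguous A→B→Aprime labels."""

    beat_times: list[float]
    section_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        times = list(self.beat_times)
        labels = list(self.section_labels)
        if len(times) != len(labels):
            raise DuetIOError("beat_times and section_labels differ in length")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise DuetIOError("beat times must be strictly increasing")
        runs = [label for i, label in enumerate(labels) if i == 0 or labels[i - 1] != label]
        if tuple(runs) != SECTION_ORDER:
            raise DuetIOError(
                f"section labels must form one contiguous A, B, Aprime run, got runs {runs}"
            )
        self.beat_times = times
        self.section_labels = labels

    def times_for(self, section: str) -> list[float]:
        return [t for t, s in zip(self.beat_times, self.section_labels) if s == section]


def assign_players(
    raw_notes: list[smf.RawNote], split_pitch: int = SPLIT_PITCH_G4
) -> list[NoteEvent]:
    """Register split: pitch >= split_pitch is the participant, below is the therapist."""
    return [
        NoteEvent(
            onset=n.onset,
            offset=n.offset,
            pitch=n.pitch,
            velocity=n.velocity,
            player=Player.PARTICIPANT if n.pitch >= split_pitch else Player.THERAPIST,
        )
        for n in raw_notes
    ]


def read_duet(
    midi_path, split_pitch: int = SPLIT_PITCH_G4, recording_id: str | None = None
) -> DuetRecording:
    """Read an SMF duet and split it into therapist and participant parts.

    Raises DuetIOError if the file is unreadable, empty, or leaves either
    player without a single note (a degenerate recording for this paradigm).
    """
    try:
        raw = smf.read_smf(midi_path)
    except smf.MidiFormatError as exc:
        raise DuetIOError(str(exc)) from exc
    notes = assign_players(raw, split_pitch)
    rid = recording_id if recording_id is not None else Path(midi_path).stem
    duet = DuetRecording(notes=notes, recording_id=rid)
    for player in Player:
        if not duet.part(player):
            raise DuetIOError(
                f"{midi_path}: degenerate recording, no notes on the "
                f"{player.value} side of split pitch {split_pitch}"
            )
    return duet


def write_duet(midi_path, duet: DuetRecording) -> None:
    """Write a duet back to a single-track SMF at its nominal tempo."""
    raw = [smf.RawNote(n.onset, n.offset, n.pitch, n.velocity) for n in duet.notes]
    smf.write_smf(midi_path, raw, bpm=duet.nominal_tempo)


def read_beats(annotation_path) -> BeatAnnotation:
    """Read the beat/section CSV sidecar (columns: time_s, section)."""
    try:
        table = pd.read_csv(annotation_path)
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise DuetIOError(f"cannot read beat annotation {annotation_path}: {exc}") from exc
    required = {"time_s", "section"}
    if not required.issubset(table.columns):
        raise DuetIOError(f"{annotation_path}: beat annotation needs columns {sorted(required)}")
    return BeatAnnotation(
        beat_times=[float(t) for t in table["time_s"]],
        section_labels=[str(s) for s in table["section"]],
    )


def write_beats(annotation_path, beats: BeatAnnotation) -> None:
    pd.DataFrame({"time_s": beats.beat_times, "section": beats.section_labels}).to_csv(
        annotation_path, index=False
    )


def notes_table(duet: DuetRecording) -> pd.DataFrame:
    """Canonical note table (recording_id, player, onset_s, offset_s, pitch, velocity)."""
    return pd.DataFrame(
        {
            "recording_id": duet.recording_id,
            "player": [n.player.value for n in duet.notes],
            "onset_s": [n.onset for n in duet.notes],
            "offset_s": [n.offset for n in duet.notes],
            "pitch": [n.pitch for n in duet.notes],
            "velocity": [n.velocity for n in duet.notes],
        }
    )
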