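import numpy as np
import pytest

from improvsync.duet_io import BeatAnnotation, DuetRecording, NoteEvent, Player


def make_beats(n_a=8, n_b=8, n_ap=8, dt=0.75, start=0.0):
    """Uniform beat annotation with contiguous A, B, Aprime runs."""
    times = [start + i * dt for i in range(n_a + n_b + n_ap)]
    labels = ["A"] * n_a + ["B"] * n_b + ["Aprime"] * n_ap
    return BeatAnnotation(beat_times=times, section_labels=labels)


def participant_note(onset, duration=0.2, pitch=72, velocity=64):
    return NoteEvent(onset, onset + duration, pitch, velocity, Player.PARTICIPANT)


def therapist_note(onset, duration=0.5, pitch=40, velocity=64):
    return NoteEvent(onset, onset + duration, pitch, velocity, Player.THERAPIST)


@pytest.fixture
def beats_80bpm():
    return make_beats()


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def simple_duet():
    """Both players metronomic on the beat; participant legato, therapist legato."""
    notes = []
    for i in range(24):
        t = i * 0.75
        notes.append(therapist_note(t, duration=0.75))
        notes.append(participant_note(t, duration=0.75))
    return DuetRecording(notes=notes, recording_id="simple")
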