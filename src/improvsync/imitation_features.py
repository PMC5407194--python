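"""Interpersonal-imitation variables (MIR variables 13–15).

  DN       note density: participant notes per annotated quarter-note beat
           within a section window.
  AI_mu /  articulation interaction: per one-beat window, each player's mean
  AI_min   articulation (sounded duration / inter-onset interval, capped at
           2) is compared; the window score is
           s_w = 1 − min(1, |a_participant − a_therapist|), and AI_mu / AI_min
           are the mean and minimum of s_w over windows where both players
           sound.  Identical articulation gives 1; articulation differing by
           a full IOI or more gives 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duet_io import DuetRecording, NoteEvent, Player
from .segmentation import EighthGrid

ARTICULATION_CAP = 2.0


class ImitationError(ValueError):
    pass


@dataclass
class ArticulationSeries:
    window_starts: list[float]
    participant: list[float]  # mean articulation per retained window
    therapist: list[float]
    scores: list[float]       # s_w in [0, 1]


def note_density(
    participant_notes: list[NoteEvent],
    window: tuple[float, float],
    beats_in_window: list[float],
) -> float:
    if len(beats_in_window) == 0:
        raise ImitationError("note density needs at least one beat in the window")
    start, end = window
    count = sum(1 for n in participant_notes if start <= n.onset < end)
    return count / len(beats_in_window)


def _articulations(notes: list[NoteEvent]) -> list[tuple[float, float]]:
    """(onset, articulation) per note: duration over the IOI to the next distinct onset.

    The final notes of the stream have no following onset and reuse the last
    defined IOI; if no nonzero IOI exists the stream has a single chord and
    no articulation is defined.
    """
    onsets = sorted({n.onset for n in notes})
    next_onset = {a: b for a, b in zip(onsets, onsets[1:])}
    last_ioi = None
    out: list[tuple[float, float]] = []
    for note in sorted(notes, key=lambda n: n.onset):
        if note.onset in next_onset:
            ioi = next_onset[note.onset] - note.onset
            last_ioi = ioi
        elif last_ioi is not None:
            ioi = last_ioi
        else:
            continue
        out.append((note.onset, min(ARTICULATION_CAP, note.duration / ioi)))
    return out


def articulation_series(
    duet: DuetRecording, beats_in_window: list[float], window: tuple[float, float]
) -> ArticulationSeries:
    """Per one-beat window, both players' mean articulation and the interaction score."""
    start, end = window
    edges = list(beats_in_window) + [end]
    arts = {
        player: _articulations([n for n in duet.part(player) if start <= n.onset < end])
        for player in Player
    }
    series = ArticulationSeries(window_starts=[], participant=[], therapist=[], scores=[])
    for w0, w1 in zip(edges, edges[1:]):
        means = {}
        for player, values in arts.items():
            vals = [a for t, a in values if w0 <= t < w1]
            if vals:
                means[player] = float(np.mean(vals))
        if len(means) < 2:
            continue  # either player silent in this window
        a_p, a_t = means[Player.PARTICIPANT], means[Player.THERAPIST]
        series.window_starts.append(w0)
        series.participant.append(a_p)
        series.therapist.append(a_t)
        series.scores.append(1.0 - min(1.0, abs(a_p - a_t)))
    return series


def articulation_interaction(
    duet: DuetRecording, grid: EighthGrid, window: tuple[float, float],
    beats_in_window: list[float],
) -> tuple[float, float]:
    """(AI_mu, AI_min) over retained one-beat windows; NaN when none is retained."""
    start, end = window
    for player in Player:
        if sum(1 for n in duet.part(player) if start <= n.onset < end) < 2:
            return float("nan"), float("nan")
    series = articulation_series(duet, beats_in_window, window)
    if not series.scores:
        return float("nan"), float("nan")
    return float(np.mean(series.scores)), float(min(series.scores))
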