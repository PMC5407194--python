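"""Section windows and the eighth-note grid.

The accompaniment follows an ABA′ design: a stable bourdon (A), a freer and
faster middle section (B), and a return to the bourdon (A′).  B is bisected
into B1 and B2 at its temporal midpoint so that changes in synchronization
over the freer section can be measured.  Timing deviations are measured
against an eighth-note grid obtained by linear interpolation between the
annotated quarter-note beats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .duet_io import BeatAnnotation

SECTIONS = ("A", "B", "B1", "B2", "Aprime")
_APRIME_EPS = 1e-6


class SegmentationError(ValueError):
    pass


@dataclass(frozen=True)
class SectionWindows:
    """Half-open [start, end) time intervals for A, B, B1, B2, Aprime."""

    windows: dict[str, tuple[float, float]]

    def __getitem__(self, section: str) -> tuple[float, float]:
        return self.windows[section]

    def contains(self, section: str, time: float) -> bool:
        start, end = self.windows[section]
        return start <= time < end


@dataclass
class EighthGrid:
    """Strictly increasing grid times (s) at the eighth-note level with section tags."""

    times: np.ndarray
    sections: list[str]

    def __len__(self) -> int:
        return len(self.times)


def make_sections(beats: BeatAnnotation, last_event_time: float) -> SectionWindows:
    """Build the five section windows from the annotation.

    Each of A, B, Aprime starts at its first annotated beat; Aprime extends
    just past the last sounding event.  B1/B2 split B at its time midpoint.
    """
    for section in ("A", "B", "Aprime"):
        if not beats.times_for(section):
            raise SegmentationError(f"section {section} has no annotated beats")
    a0 = beats.times_for("A")[0]
    b0 = beats.times_for("B")[0]
    ap0 = beats.times_for("Aprime")[0]
    if last_event_time < beats.beat_times[-1]:
        raise SegmentationError("last_event_time precedes the final annotated beat")
    ap_end = last_event_time + _APRIME_EPS
    if not (a0 < b0 < ap0):
        raise SegmentationError("section onsets must be ordered A < B < Aprime")
    if b0 >= ap0:
        raise SegmentationError("section B has zero duration")
    mid = b0 + (ap0 - b0) / 2.0
    return SectionWindows(
        windows={
            "A": (a0, b0),
            "B": (b0, ap0),
            "B1": (b0, mid),
            "B2": (mid, ap0),
            "Aprime": (ap0, ap_end),
        }
    )


def make_eighth_grid(beats: BeatAnnotation) -> EighthGrid:
    """Interpolate one eighth-note grid point between each pair of annotated beats.

    Grid points inherit the section of the beat interval they lie in (the left
    beat's label); the final beat keeps its own label.
    """
    times = np.asarray(beats.beat_times, dtype=float)
    if len(times) < 2:
        raise SegmentationError("need at least 2 beats to build an eighth-note grid")
    mids = (times[:-1] + times[1:]) / 2.0
    grid = np.empty(2 * len(times) - 1)
    grid[0::2] = times
    grid[1::2] = mids
    labels: list[str] = []
    for i in range(len(times) - 1):
        labels.extend([beats.section_labels[i], beats.section_labels[i]])
    labels.append(beats.section_labels[-1])
    return EighthGrid(times=grid, sections=labels)


def nearest_grid_index(grid: EighthGrid, onset: float) -> int:
    """Index of the grid point nearest to onset; exact midpoints resolve earlier."""
    times = grid.times
    j = int(np.searchsorted(times, onset))
    if j == 0:
        return 0
    if j >= len(times):
        return len(times) - 1
    before, after = times[j - 1], times[j]
    # tie (exact midpoint) goes to the earlier grid point
    return j - 1 if onset - before <= after - onset else j
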