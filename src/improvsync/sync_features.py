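"""Interpersonal-synchronization and tempo variables (MIR variables 1–9).

Each participant note is compared with the nearest eighth-note grid point of
the shared pulse.  The signed deviation is onset − nearest grid time, so a
positive value means the note lags behind the beat.  From the deviations of a
section we compute:

  MD_m, MD_sd    mean / sample sd of the absolute deviations (seconds)
  LP             lag proportion: fraction of notes strictly behind the beat
  MDA_m, MDA_sd  mean / sd of |deviation| over notes ahead of the beat
  MDB_m, MDB_sd  mean / sd of |deviation| over notes behind the beat
  TMP_m, TMP_sd  mean / sd of the local tempo 60/IBI from annotated beats

Exact zero deviations count in MD_* and the LP denominator but belong to
neither the ahead nor the behind set.  Undefined statistics (too few notes,
an empty ahead/behind set) are reported as NaN, never as zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .duet_io import NoteEvent
from .segmentation import EighthGrid, nearest_grid_index

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Deviation:
    note: NoteEvent
    grid_index: int
    signed_dev: float

    @property
    def abs_dev(self) -> float:
        return abs(self.signed_dev)


@dataclass
class SyncFeatures:
    MD_m: float
    MD_sd: float
    LP: float
    MDA_m: float
    MDA_sd: float
    MDB_m: float
    MDB_sd: float
    TMP_m: float
    TMP_sd: float
    section: str = ""

    def as_dict(self) -> dict[str, float]:
        return {
            name: getattr(self, name)
            for name in ("MD_m", "MD_sd", "LP", "MDA_m", "MDA_sd", "MDB_m", "MDB_sd", "TMP_m", "TMP_sd")
        }


def deviations(
    participant_notes: list[NoteEvent],
    grid: EighthGrid,
    window: tuple[float, float],
) -> list[Deviation]:
    """Signed deviation of each in-window note from its nearest grid point.

    Notes outside the grid's span have no well-defined nearest neighbour on
    both sides and are excluded (logged), as are notes outside the window.
    """
    start, end = window
    lo, hi = grid.times[0], grid.times[-1]
    out: list[Deviation] = []
    dropped = 0
    for note in participant_notes:
        if not start <= note.onset < end:
            continue
        if note.onset < lo or note.onset > hi:
            dropped += 1
            continue
        j = nearest_grid_index(grid, note.onset)
        out.append(Deviation(note=note, grid_index=j, signed_dev=note.onset - grid.times[j]))
    if dropped:
        log.info("deviations: excluded %d notes outside the grid span", dropped)
    return out


def _mean_sd(values: np.ndarray) -> tuple[float, float]:
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(values.mean())
    sd = float(values.std(ddof=1)) if values.size >= 2 else float("nan")
    return mean, sd


def sync_features(
    devs: list[Deviation], beats_in_window: list[float], section: str = ""
) -> SyncFeatures:
    """Compute variables 1–9 from one section's deviations and annotated beats."""
    signed = np.array([d.signed_dev for d in devs], dtype=float)
    beats = np.asarray(beats_in_window, dtype=float)
    nan = float("nan")

    if signed.size >= 2:
        md_m, md_sd = _mean_sd(np.abs(signed))
        lp = float((signed > 0).sum() / signed.size)
        mda_m, mda_sd = _mean_sd(np.abs(signed[signed < 0]))
        mdb_m, mdb_sd = _mean_sd(signed[signed > 0])
    else:
        md_m = md_sd = lp = mda_m = mda_sd = mdb_m = mdb_sd = nan

    if beats.size >= 2:
        tempo = 60.0 / np.diff(beats)
        tmp_m = float(tempo.mean())
        tmp_sd = float(tempo.std(ddof=1)) if tempo.size >= 2 else nan
    else:
        tmp_m = tmp_sd = nan

    return SyncFeatures(
        MD_m=md_m, MD_sd=md_sd, LP=lp,
        MDA_m=mda_m, MDA_sd=mda_sd, MDB_m=mdb_m, MDB_sd=mdb_sd,
        TMP_m=tmp_m, TMP_sd=tmp_sd, section=section,
    )
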