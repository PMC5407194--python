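"""Per-recording feature extraction: all 15 variables × sections A, B, B1, B2, A′.

Produces one flat row per participant with columns named ``<VAR>_<SECTION>``
(e.g. ``MD_m_B1``, ``LP_B1``, ``CR_dur_Aprime``).  Deviation statistics are in
seconds; tempi in BPM; LP, TC_o, RS, AI in proportions; DN in notes per beat.
"""

from __future__ import annotations

from .duet_io import BeatAnnotation, DuetRecording, Player
from .imitation_features import articulation_interaction, note_density
from .pattern_features import cr_dur, rs, tc_o
from .segmentation import SECTIONS, make_eighth_grid, make_sections
from .sync_features import deviations, sync_features

VARIABLES = (
    "MD_m", "MD_sd", "LP", "MDA_m", "MDA_sd", "MDB_m", "MDB_sd",
    "TMP_m", "TMP_sd", "CR_dur", "TC_o", "RS", "DN", "AI_mu", "AI_min",
)


def feature_columns() -> list[str]:
    return [f"{var}_{sec}" for var in VARIABLES for sec in SECTIONS]


def extract_features(
    duet: DuetRecording, beats: BeatAnnotation, sync_only: bool = False
) -> dict[str, float]:
    """One feature row for the participant of a duet.

    ``sync_only`` restricts to the deviation/lag/tempo variables (1–9), which
    is all the diagnosis models consume, and skips the pattern-discovery and
    articulation passes.
    """
    windows = make_sections(beats, duet.last_event_time)
    grid = make_eighth_grid(beats)
    part_notes = duet.part(Player.PARTICIPANT)

    row: dict[str, float] = {}
    for section in SECTIONS:
        window = windows[section]
        beats_in = [t for t in beats.beat_times if window[0] <= t < window[1]]
        devs = deviations(part_notes, grid, window)
        for name, value in sync_features(devs, beats_in, section).as_dict().items():
            row[f"{name}_{section}"] = value
        if sync_only:
            continue
        in_window = [n for n in part_notes if window[0] <= n.onset < window[1]]
        row[f"CR_dur_{section}"] = cr_dur(in_window, grid)
        row[f"TC_o_{section}"] = tc_o(in_window, grid)
        row[f"RS_{section}"] = rs(in_window, grid)
        row[f"DN_{section}"] = (
            note_density(part_notes, window, beats_in) if beats_in else float("nan")
        )
        ai_mu, ai_min = articulation_interaction(duet, grid, window, beats_in)
        row[f"AI_mu_{section}"] = ai_mu
        row[f"AI_min_{section}"] = ai_min
    return row
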