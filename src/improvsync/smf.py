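"""Minimal Standard MIDI File (SMF type 0/1) reader and writer.

Only the events this project needs are interpreted: note on/off (velocity-0
note-on is treated as note-off, the common dialect) and set-tempo meta events,
which drive the tick→seconds conversion.  All other channel, meta and sysex
events are parsed for length and skipped.  SMPTE time division is rejected.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass


class MidiFormatError(ValueError):
    """Raised when a file is not a readable SMF type 0/1."""


DEFAULT_US_PER_QN = 500_000  # MIDI default: 120 BPM


@dataclass
class RawNote:
    """A paired note with times in seconds (performed time)."""

    onset: float
    offset: float
    pitch: int
    velocity: int


def _read_varlen(data: bytes, pos: int) -> tuple[int, int]:
    value = 0
    while True:
        if pos >= len(data):
            raise MidiFormatError("truncated variable-length quantity")
        byte = data[pos]
        pos += 1
        value = (value << 7) | (byte & 0x7F)
        if not byte & 0x80:
            return value, pos


def _parse_track(data: bytes) -> tuple[list[tuple[int, int, int, int]], list[tuple[int, int]]]:
    """Return (note events, tempo events) at absolute ticks.

    Note events are (tick, kind, pitch, velocity) with kind 1=on, 0=off.
    Tempo events are (tick, microseconds per quarter note).
    """
    pos = 0
    tick = 0
    status = 0
    notes: list[tuple[int, int, int, int]] = []
    tempos: list[tuple[int, int]] = []
    while pos < len(data):
        delta, pos = _read_varlen(data, pos)
        tick += delta
        byte = data[pos]
        if byte & 0x80:
            status = byte
            pos += 1
        elif status == 0:
            raise MidiFormatError("running status with no prior status byte")
        kind = status & 0xF0
        if kind in (0x80, 0x90):
            pitch, vel = data[pos], data[pos + 1]
            pos += 2
            on = 1 if (kind == 0x90 and vel > 0) else 0
            notes.append((tick, on, pitch, vel))
        elif kind in (0xA0, 0xB0, 0xE0):
            pos += 2
        elif kind in (0xC0, 0xD0):
            pos += 1
        elif status == 0xFF:
            meta_type = data[pos]
            length, pos = _read_varlen(data, pos + 1)
            payload = data[pos : pos + length]
            pos += length
            if meta_type == 0x51 and length == 3:
                tempos.append((tick, int.from_bytes(payload, "big")))
            status = 0
        elif status in (0xF0, 0xF7):
            length, pos = _read_varlen(data, pos)
            pos += length
            status = 0
        else:
            raise MidiFormatError(f"unsupported status byte 0x{status:02x}")
    return notes, tempos


def _ticks_to_seconds(ticks: list[int], tempos: list[tuple[int, int]], division: int) -> dict[int, float]:
    """Map each absolute tick to seconds under the piecewise-constant tempo map."""
    tempos = sorted(tempos)
    if not tempos or tempos[0][0] > 0:
        tempos = [(0, DEFAULT_US_PER_QN)] + tempos
    out: dict[int, float] = {}
    seg = 0
    seg_start_s = 0.0
    for tick in sorted(set(ticks)):
        while seg + 1 < len(tempos) and tempos[seg + 1][0] <= tick:
            seg_start_s += (tempos[seg + 1][0] - tempos[seg][0]) * tempos[seg][1] / (division * 1e6)
            seg += 1
        out[tick] = seg_start_s + (tick - tempos[seg][0]) * tempos[seg][1] / (division * 1e6)
    return out


def read_smf(path) -> list[RawNote]:
    """Read an SMF type 0/1 file into paired notes with times in seconds.

    A re-struck pitch (note-on while the same pitch is sounding) truncates the
    earlier note at the later onset.  Notes left open at end of file are closed
    at the final event tick.
    """
    try:
        with open(path, "rb") as fh:
            blob = fh.read()
    except OSError as exc:
        raise MidiFormatError(f"cannot read {path}: {exc}") from exc
    if len(blob) < 14 or blob[:4] != b"MThd":
        raise MidiFormatError(f"{path}: not a Standard MIDI File")
    hlen, fmt, ntrks, division = struct.unpack(">IHHH", blob[4:14])
    if fmt not in (0, 1):
        raise MidiFormatError(f"{path}: SMF format {fmt} not supported")
    if division & 0x8000:
        raise MidiFormatError(f"{path}: SMPTE time division not supported")
    if division == 0:
        raise MidiFormatError(f"{path}: zero ticks-per-quarter division")

    pos = 8 + hlen
    all_notes: list[tuple[int, int, int, int]] = []
    all_tempos: list[tuple[int, int]] = []
    for _ in range(ntrks):
        if pos + 8 > len(blob) or blob[pos : pos + 4] != b"MTrk":
            raise MidiFormatError(f"{path}: malformed track chunk")
        tlen = struct.unpack(">I", blob[pos + 4 : pos + 8])[0]
        notes, tempos = _parse_track(blob[pos + 8 : pos + 8 + tlen])
        all_notes.extend(notes)
        all_tempos.extend(tempos)
        pos += 8 + tlen

    if not all_notes:
        raise MidiFormatError(f"{path}: file contains no notes")

    # stable order: tick, then offs before ons so an off+on at the same tick re-strikes
    all_notes.sort(key=lambda ev: (ev[0], ev[1]))
    ticks = [ev[0] for ev in all_notes]
    t2s = _ticks_to_seconds(ticks, all_tempos, division)

    open_notes: dict[int, tuple[int, int]] = {}  # pitch -> (onset tick, velocity)
    out: list[RawNote] = []
    for tick, on, pitch, vel in all_notes:
        if on:
            if pitch in open_notes:  # re-strike: truncate the earlier note here
                t0, v0 = open_notes.pop(pitch)
                if tick > t0:
                    out.append(RawNote(t2s[t0], t2s[tick], pitch, v0))
            open_notes[pitch] = (tick, vel)
        else:
            if pitch in open_notes:
                t0, v0 = open_notes.pop(pitch)
                if tick > t0:
                    out.append(RawNote(t2s[t0], t2s[tick], pitch, v0))
    last_tick = all_notes[-1][0]
    for pitch, (t0, v0) in open_notes.items():
        if last_tick > t0:
            out.append(RawNote(t2s[t0], t2s[last_tick], pitch, v0))
    out.sort(key=lambda n: (n.onset, n.pitch))
    return out


def _varlen(value: int) -> bytes:
    chunks = [value & 0x7F]
    value >>= 7
    while value:
        chunks.append(0x80 | (value & 0x7F))
        value >>= 7
    return bytes(reversed(chunks))


def write_smf(path, notes: list[RawNote], bpm: float = 120.0, division: int = 480) -> None:
    """Write paired notes (seconds) as a single-track SMF type 0 at a fixed tempo."""
    us_per_qn = round(60e6 / bpm)
    to_tick = lambda s: round(s * division * 1e6 / us_per_qn)
    events: list[tuple[int, int, bytes]] = []  # (tick, sort rank, payload)
    for note in notes:
        on_t, off_t = to_tick(note.onset), to_tick(note.offset)
        if off_t <= on_t:
            off_t = on_t + 1
        events.append((on_t, 1, bytes((0x90, note.pitch, max(1, min(127, note.velocity))))))
        events.append((off_t, 0, bytes((0x80, note.pitch, 0))))
    events.sort(key=lambda ev: (ev[0], ev[1], ev[2]))

    track = bytearray()
    track += _varlen(0) + bytes((0xFF, 0x51, 0x03)) + us_per_qn.to_bytes(3, "big")
    prev = 0
    for tick, _, payload in events:
        track += _varlen(tick - prev) + payload
        prev = tick
    track += _varlen(0) + bytes((0xFF, 0x2F, 0x00))

    with open(path, "wb") as fh:
        fh.write(b"MThd" + struct.pack(">IHHH", 6, 0, 1, division))
        fh.write(b"MTrk" + struct.pack(">I", len(track)) + bytes(track))
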