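"""Rhythmic-pattern variables (MIR variables 10–12).

A participant's playing in a section is quantized to an eighth-note grid and
treated as a point set.  Repeated structure is then found with a greedy
translational-pattern cover in the SIATEC/COSIATEC family: for every nonzero
difference vector d occurring between points of the remaining set, the
maximal translatable pattern MTP(d) = {p : p + d in set} is a candidate
pattern; together with every translator t for which pattern + t stays inside
the set it forms a translational equivalence class (TEC).  At each step the
class maximizing covered_points / (|pattern| + |translators|) is selected and
its covered points removed; selection stops when no class exceeds ratio 1,
and leftovers become residual points costing one unit each.

  CR_dur  compression ratio of the (ontime, duration) point set:
          |points| / encoding cost, where each selected class costs
          |pattern| + |translators| − 1 and each residual point costs 1.
  TC_o    translational coefficient of the ontime set: the proportion of
          distinct ontimes covered by the selected (non-singleton) classes.
  RS      rhythmic simplicity: the modal proportion of the inter-onset
          intervals between consecutive distinct quantized onsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from collections import Counter

from .duet_io import NoteEvent
from .segmentation import EighthGrid, nearest_grid_index

Point = tuple[int, ...]


@dataclass
class QuantizedPointSet:
    """Distinct integer points at eighth-note resolution (1-D ontime or 2-D ontime×duration)."""

    points: frozenset[Point]
    dimensions: int

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class TEClass:
    pattern: tuple[Point, ...]       # sorted, in absolute coordinates
    translators: tuple[Point, ...]   # sorted; includes the zero vector
    covered: frozenset[Point]

    @property
    def cost(self) -> int:
        return len(self.pattern) + len(self.translators) - 1


@dataclass
class PatternCover:
    classes: list[TEClass]
    residual: frozenset[Point]
    n_input: int

    @property
    def encoding_cost(self) -> int:
        return sum(c.cost for c in self.classes) + len(self.residual)

    @property
    def compression_ratio(self) -> float:
        cost = self.encoding_cost
        return self.n_input / cost if cost else 1.0

    @property
    def covered_points(self) -> frozenset[Point]:
        covered: set[Point] = set()
        for cls in self.classes:
            covered |= cls.covered
        return frozenset(covered)


@dataclass
class RhythmProfile:
    iois: list[int]
    modal_ioi: int
    modal_count: int

    @property
    def rs(self) -> float:
        return self.modal_count / len(self.iois)


def quantize(notes: list[NoteEvent], grid: EighthGrid, with_duration: bool = True) -> QuantizedPointSet:
    """Snap notes to grid indices; durations in eighth units floor at 1."""
    points: set[Point] = set()
    times = grid.times
    for note in notes:
        j = nearest_grid_index(grid, note.onset)
        if with_duration:
            # local eighth duration: spacing of the grid interval at the note
            if j + 1 < len(times):
                local = times[j + 1] - times[j]
            else:
                local = times[j] - times[j - 1]
            dur = max(1, round(note.duration / local))
            points.add((j, dur))
        else:
            points.add((j,))
    return QuantizedPointSet(points=frozenset(points), dimensions=2 if with_duration else 1)


def _add(p: Point, d: Point) -> Point:
    return tuple(a + b for a, b in zip(p, d))


def _sub(p: Point, q: Point) -> Point:
    return tuple(a - b for a, b in zip(p, q))


def _prune_translators(pattern: tuple[Point, ...], full: list[Point]) -> tuple[Point, ...]:
    """Greedy translator subset maximizing covered/(|pattern| + |translators|).

    Overlapping occurrences make the maximal translator set self-defeating: a
    strictly periodic sequence has every shift as a translator, so the full
    set costs as much as the points it covers.  Starting from the zero vector,
    translators are added in order of new points covered (ties to the smaller
    vector) while the selection ratio improves.
    """
    zero = (0,) * len(pattern[0])
    chosen = [zero]
    covered = set(pattern)
    candidates = [t for t in full if t != zero]
    while candidates:
        gains = [(len({_add(p, t) for p in pattern} - covered), t) for t in candidates]
        gain, best = max(gains, key=lambda gt: (gt[0], tuple(-c for c in gt[1])))
        k = len(pattern) + len(chosen)
        if gain == 0 or (len(covered) + gain) * k <= len(covered) * (k + 1):
            break
        chosen.append(best)
        covered |= {_add(p, best) for p in pattern}
        candidates.remove(best)
    return tuple(sorted(chosen))


def candidate_classes(remaining: frozenset[Point]) -> list[TEClass]:
    """MTP-derived translational equivalence classes of the remaining set.

    Each nonzero difference vector d yields the pattern MTP(d); its translator
    set is pruned from the maximal one (every t with pattern + t inside the
    set) to the ratio-maximizing subset, which lets periodic structure with
    overlapping occurrences compress.
    """
    pts = sorted(remaining)
    diffs = {_sub(q, p) for p in pts for q in pts if p != q}
    seen: set[tuple] = set()
    classes: list[TEClass] = []
    for d in diffs:
        pattern = tuple(sorted(p for p in pts if _add(p, d) in remaining))
        if len(pattern) < 2:
            continue  # a singleton pattern can never reach ratio > 1
        anchor = pattern[0]
        full = sorted(
            t
            for t in {_sub(r, anchor) for r in pts}
            if all(_add(p, t) in remaining for p in pattern)
        )
        translators = _prune_translators(pattern, full)
        key = (pattern, translators)
        if key in seen:
            continue
        seen.add(key)
        covered = frozenset(_add(p, t) for p in pattern for t in translators)
        classes.append(TEClass(pattern=pattern, translators=translators, covered=covered))
    return classes


def _selection_key(cls: TEClass) -> tuple:
    ratio = len(cls.covered) / (len(cls.pattern) + len(cls.translators))
    # maximize ratio; ties: larger pattern, then lexicographically smaller
    # pattern, then lexicographically smaller translator tuple (determinism)
    return (-ratio, -len(cls.pattern), cls.pattern, cls.translators)


def discover_cover(ps: QuantizedPointSet) -> PatternCover:
    """Greedy iterative TEC cover of a quantized point set (see module docstring)."""
    remaining = set(ps.points)
    selected: list[TEClass] = []
    while len(remaining) >= 4:  # ratio > 1 needs at least 4 covered points
        classes = candidate_classes(frozenset(remaining))
        if not classes:
            break
        best = min(classes, key=_selection_key)
        if len(best.covered) <= len(best.pattern) + len(best.translators):
            break  # no class compresses
        selected.append(best)
        remaining -= best.covered
    return PatternCover(classes=selected, residual=frozenset(remaining), n_input=len(ps.points))


def cr_dur(notes: list[NoteEvent], grid: EighthGrid) -> float:
    """Compression ratio of the 2-D (ontime, duration) point set; NaN below 2 notes."""
    if len(notes) < 2:
        return float("nan")
    return discover_cover(quantize(notes, grid, with_duration=True)).compression_ratio


def tc_o(notes: list[NoteEvent], grid: EighthGrid) -> float:
    """Proportion of distinct ontimes covered by repeated (translatable) structure."""
    if len(notes) < 2:
        return float("nan")
    ps = quantize(notes, grid, with_duration=False)
    if len(ps) < 2:
        return float("nan")
    cover = discover_cover(ps)
    return len(cover.covered_points) / len(ps)


def rhythmic_simplicity(notes: list[NoteEvent], grid: EighthGrid) -> RhythmProfile | None:
    """Modal proportion of inter-onset intervals over distinct quantized onsets.

    Simultaneous notes (chords) collapse to one onset; ties for the modal IOI
    resolve to the smaller interval.  None when fewer than two distinct onsets.
    """
    if len(notes) < 2:
        return None
    onsets = sorted({nearest_grid_index(grid, n.onset) for n in notes})
    if len(onsets) < 2:
        return None
    iois = [b - a for a, b in zip(onsets, onsets[1:])]
    counts = Counter(iois)
    top = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))
    return RhythmProfile(iois=iois, modal_ioi=top[0], modal_count=top[1])


def rs(notes: list[NoteEvent], grid: EighthGrid) -> float:
    profile = rhythmic_simplicity(notes, grid)
    return profile.rs if profile is not None else float("nan")
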