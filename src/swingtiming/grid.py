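"""Triplet-grid classification of swung-eighth performances.

Swung eighths phrase the quarter note as an eighth-note triplet of which
only the first ("base", on the metronome click) and third ("swing", the
offbeat) members are played.  On the canonical 960-tick quarter the three
triplet anchors sit at 0, 320 and 640 ticks; every note is assigned to the
nearest anchor, with a half-open window of one half triplet (160 ticks) on
either side.  Notes landing in the middle-triplet window are *disregarded*:
they are counted but never moved or included in deviation statistics.

A residue exactly 160 ticks past an anchor belongs to the next anchor with
signed offset -160, so offsets always lie in [-160, 160).  Residues in
[800, 960) wrap to the next quarter's base anchor with a negative offset —
a base note played slightly early still counts against its own click.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .midi_io import CANONICAL_TPQ, Performance

__all__ = [
    "NoteClass",
    "GridAssignment",
    "TemporalBin",
    "ClassMeans",
    "EmptyClassError",
    "classify_note",
    "classify_performance",
    "group_bins",
    "compute_class_means",
    "assignments_to_frame",
]

QUARTER = CANONICAL_TPQ  # 960 ticks
TRIPLET = QUARTER // 3  # 320 ticks
HALF_WINDOW = TRIPLET // 2  # 160 ticks

_ANCHORS = (0, TRIPLET, 2 * TRIPLET)  # 0, 320, 640


class NoteClass(str, Enum):
    BASE = "base"
    SWING = "swing"
    DISREGARDED = "disregarded"


_IDX_TO_CLASS = {0: NoteClass.BASE, 1: NoteClass.DISREGARDED, 2: NoteClass.SWING}
_CLASS_TO_ANCHOR = {
    NoteClass.BASE: 0,
    NoteClass.DISREGARDED: TRIPLET,
    NoteClass.SWING: 2 * TRIPLET,
}


class EmptyClassError(ValueError):
    """A performance lacks base or swing notes entirely."""


@dataclass(frozen=True)
class GridAssignment:
    """Grid position of one note: class, quarter index and signed offset.

    Invariant: ``onset = 960*quarter_index + anchor + signed_offset`` with
    ``signed_offset`` in [-160, 160).
    """

    note_index: int
    klass: NoteClass
    quarter_index: int
    anchor: int
    signed_offset: float

    @property
    def anchor_time(self) -> float:
        """Absolute grid-anchor time in ticks (quarter start + anchor)."""
        return QUARTER * self.quarter_index + self.anchor


@dataclass(frozen=True)
class TemporalBin:
    """All notes sharing one (quarter, anchor) slot; chords form one bin.

    The bin's timing is that of its earliest onset — simultaneous chord
    tones do not multiply-count in any statistic.
    """

    quarter_index: int
    klass: NoteClass
    note_indices: Tuple[int, ...]  # sorted by onset; first = earliest
    offset: float  # signed offset of the earliest onset

    @property
    def anchor(self) -> int:
        return _CLASS_TO_ANCHOR[self.klass]

    @property
    def anchor_time(self) -> float:
        return QUARTER * self.quarter_index + self.anchor


@dataclass(frozen=True)
class ClassMeans:
    """Mean base and swing positions of one performance.

    ``b_bar`` is the mean signed offset of base bins from the click
    (negative = ahead of the beat); ``s_bar`` is the mean absolute swing
    position within the quarter, i.e. 640 + mean swing offset.
    """

    b_bar: float
    s_bar: float
    n_base: int
    n_swing: int
    n_disregarded: int

    @property
    def b_offset(self) -> float:
        return self.b_bar

    @property
    def s_offset(self) -> float:
        return self.s_bar - 2 * TRIPLET


def classify_note(onset: float, note_index: int = -1) -> GridAssignment:
    """Assign one onset to its nearest triplet anchor.

    Total over onsets >= 0.  Window arithmetic: with residue r = onset mod
    960, anchor index = floor((r+160)/320); index 3 wraps to the next
    quarter's base.
    """
    if onset < 0:
        raise ValueError(f"onset must be >= 0, got {onset}")
    quarter = int(onset // QUARTER)
    residue = onset - QUARTER * quarter
    idx = int((residue + HALF_WINDOW) // TRIPLET)
    if idx >= 3:  # [800, 960): early note of the next quarter's click
        return GridAssignment(
            note_index=note_index,
            klass=NoteClass.BASE,
            quarter_index=quarter + 1,
            anchor=0,
            signed_offset=residue - QUARTER,
        )
    klass = _IDX_TO_CLASS[idx]
    return GridAssignment(
        note_index=note_index,
        klass=klass,
        quarter_index=quarter,
        anchor=_ANCHORS[idx],
        signed_offset=residue - _ANCHORS[idx],
    )


def classify_performance(perf: Performance) -> List[GridAssignment]:
    """Classify every note of a performance, in note order."""
    return [classify_note(n.onset, i) for i, n in enumerate(perf.notes)]


def group_bins(
    perf: Performance, assignments: Sequence[GridAssignment] | None = None
) -> List[TemporalBin]:
    """Group assignments into temporal bins, earliest onset first.

    Returns bins sorted by anchor time.  Chord tones (several notes in the
    same quarter/anchor slot) collapse into a single bin whose offset is
    the earliest note's offset.
    """
    if assignments is None:
        assignments = classify_performance(perf)
    groups: Dict[Tuple[int, NoteClass], List[GridAssignment]] = {}
    for a in assignments:
        groups.setdefault((a.quarter_index, a.klass), []).append(a)
    bins = []
    for (quarter, klass), members in groups.items():
        members.sort(key=lambda a: (a.signed_offset, a.note_index))
        bins.append(
            TemporalBin(
                quarter_index=quarter,
                klass=klass,
                note_indices=tuple(a.note_index for a in members),
                offset=members[0].signed_offset,
            )
        )
    bins.sort(key=lambda b: b.anchor_time)
    return bins


def compute_class_means(
    perf: Performance, assignments: Sequence[GridAssignment] | None = None
) -> ClassMeans:
    """Mean base/swing positions, one value per temporal bin (chord rule).

    ``b_bar`` is wrap-aware (computed on signed offsets, not raw residues),
    so a recording played consistently a little ahead of the click gets a
    negative mean instead of one polluted by ~960-tick residues.
    """
    if assignments is None:
        assignments = classify_performance(perf)
    bins = group_bins(perf, assignments)
    base = [b.offset for b in bins if b.klass is NoteClass.BASE]
    swing = [b.offset for b in bins if b.klass is NoteClass.SWING]
    if not base or not swing:
        raise EmptyClassError(
            f"performance needs both base and swing notes "
            f"(got {len(base)} base bins, {len(swing)} swing bins)"
        )
    counts = {k: 0 for k in NoteClass}
    for a in assignments:
        counts[a.klass] += 1
    return ClassMeans(
        b_bar=float(np.mean(base)),
        s_bar=float(2 * TRIPLET + np.mean(swing)),
        n_base=counts[NoteClass.BASE],
        n_swing=counts[NoteClass.SWING],
        n_disregarded=counts[NoteClass.DISREGARDED],
    )


def assignments_to_frame(assignments: Sequence[GridAssignment]) -> pd.DataFrame:
    """CSV-ready table: note_index, quarter_index, class, anchor, signed_offset_ticks."""
    return pd.DataFrame(
        {
            "note_index": [a.note_index for a in assignments],
            "quarter_index": [a.quarter_index for a in assignments],
            "class": [a.klass.value for a in assignments],
            "anchor": [a.anchor for a in assignments],
            "signed_offset_ticks": [a.signed_offset for a in assignments],
        }
    )
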