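"""Group fingerprints and their set-algebra comparison.

A group's fingerprint is the set of reference windows in which a peak was
detected in its corrected average spectrum ("called"), or the set of windows
flagged for it in the reference table ("reference"). Groups are compared by
shared windows, windows unique to one group *within the compared set*, and
per-window absence lists.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .errors import ReferenceError_
from .peakcall import DetectedPeak, PeakAssignment
from .reference import PeakWindow

__all__ = [
    "GroupFingerprint",
    "ComparisonReport",
    "build_fingerprint",
    "reference_fingerprint",
    "compare_groups",
    "count_major_peaks",
    "silent_region_audit",
]


@dataclass(frozen=True)
class GroupFingerprint:
    """Window presence set for one group.

    ``source`` records provenance: ``"called"`` (from detected peaks) or
    ``"reference"`` (read from the reference table). ``reference_ids`` is the
    window universe the fingerprint was built against; fingerprints can only
    be compared over the same universe.
    """

    group_id: str
    present_windows: frozenset[str]
    source: str = "called"
    reference_ids: frozenset[str] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "present_windows", frozenset(self.present_windows))
        if self.reference_ids is not None:
            object.__setattr__(self, "reference_ids", frozenset(self.reference_ids))
            extra = self.present_windows - self.reference_ids
            if extra:
                raise ReferenceError_(
                    f"fingerprint of {self.group_id!r} contains windows outside "
                    f"its reference: {sorted(extra)}"
                )


def build_fingerprint(
    assignments: Sequence[PeakAssignment],
    group_id: str,
    windows: Sequence[PeakWindow] | None = None,
) -> GroupFingerprint:
    """Fingerprint from one group's peak assignments (source="called")."""
    present = frozenset(a.window_id for a in assignments if a.window_id is not None)
    ref_ids = frozenset(w.window_id for w in windows) if windows is not None else None
    return GroupFingerprint(
        group_id=group_id, present_windows=present, source="called",
        reference_ids=ref_ids,
    )


def reference_fingerprint(
    group_id: str, windows: Sequence[PeakWindow]
) -> GroupFingerprint:
    """Fingerprint read off the reference table's presence column."""
    known = {g for w in windows for g in w.presence}
    if group_id not in known:
        raise ReferenceError_(f"unknown group {group_id!r} in reference table")
    present = frozenset(
        w.window_id for w in windows if w.presence.get(group_id, False)
    )
    return GroupFingerprint(
        group_id=group_id,
        present_windows=present,
        source="reference",
        reference_ids=frozenset(w.window_id for w in windows),
    )


@dataclass(frozen=True)
class ComparisonReport:
    """Set algebra over a collection of fingerprints.

    ``shared``: windows present in every compared group. ``unique``: per
    group, windows present only in that group within the compared set (empty
    when a single distinct group is compared with itself). ``absent_in``: for
    every window present somewhere, the groups lacking it.
    """

    groups: tuple[str, ...]
    shared: frozenset[str]
    unique: dict[str, frozenset[str]] = field(default_factory=dict)
    absent_in: dict[str, tuple[str, ...]] = field(default_factory=dict)


def compare_groups(fingerprints: Sequence[GroupFingerprint]) -> ComparisonReport:
    """Compare fingerprints built over one reference universe.

    The result is independent of input order. Duplicate fingerprints of the
    same group collapse to one; comparing a fingerprint with itself yields
    ``shared`` equal to its windows and empty unique sets.
    """
    if not fingerprints:
        raise ReferenceError_("need at least one fingerprint to compare")
    universes = {
        fp.reference_ids for fp in fingerprints if fp.reference_ids is not None
    }
    if len(universes) > 1:
        raise ReferenceError_("fingerprints were built over different references")

    by_group: dict[str, frozenset[str]] = {}
    for fp in fingerprints:
        if fp.group_id in by_group and by_group[fp.group_id] != fp.present_windows:
            raise ReferenceError_(
                f"conflicting fingerprints for group {fp.group_id!r}"
            )
        by_group[fp.group_id] = fp.present_windows

    groups = tuple(sorted(by_group))
    sets = [by_group[g] for g in groups]
    shared = frozenset.intersection(*sets)
    if len(groups) == 1:
        unique = {groups[0]: frozenset()}
    else:
        unique = {
            g: by_group[g].difference(*(by_group[h] for h in groups if h != g))
            for g in groups
        }
    union = frozenset().union(*sets)
    absent_in = {
        w: tuple(g for g in groups if w not in by_group[g]) for w in sorted(union)
    }
    return ComparisonReport(
        groups=groups, shared=shared, unique=unique, absent_in=absent_in
    )


def count_major_peaks(fingerprint: GroupFingerprint) -> int:
    """Number of reference windows present — how "major peaks" are tallied."""
    return len(fingerprint.present_windows)


def silent_region_audit(
    assignments: Iterable[PeakAssignment],
    region: tuple[float, float] = (1800.0, 2800.0),
) -> list[DetectedPeak]:
    """Detected peaks falling strictly inside the silent region.

    Endogenous biomolecules give little Raman signal between 1800 and
    2800 cm^-1; any detected peak there (e.g. an alkyne stretch near
    2110 cm^-1) is reported for inspection rather than assigned.
    """
    lo, hi = region
    return [
        a.peak for a in assignments if lo < a.peak.position < hi
    ]
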