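"""The peak-window reference library.

Raman bands of ccfDNA are catalogued as 25 wavenumber windows, each with a
literature assignment (carried as an opaque annotation string) and a
presence/absence flag per study group. The shipped table encodes eleven
study-group columns (healthy male/female serum ccfDNA, MCF12A and MCF7
ccfDNA/gDNA, three breast-cancer treatment groups, T2DM and prediabetic
males) plus a supplementary ``Seq BRCA`` column for the sequential
breast-cancer sampling context, whose 13 reported bands include three windows
flagged in no other group.

Each window carries a *representative* position: the single in-range
assignment wavenumber when the source gives one, otherwise the window
midpoint. Synthetic spectra place their bands at these positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import ReferenceError_

__all__ = [
    "PeakWindow",
    "read_reference",
    "load_reference_windows",
    "reference_group_ids",
    "TABLE_GROUPS",
    "SEQ_BRCA_GROUP",
]

#: The eleven printed study-group columns, in table order.
TABLE_GROUPS: tuple[str, ...] = (
    "Healthy Male ccfDNA",
    "Healthy Female ccfDNA",
    "MCF12A ccfDNA",
    "MCF12A gDNA",
    "MCF7 ccfDNA",
    "MCF7 gDNA",
    "Adj BRCA",
    "Meta BRCA",
    "Neoadj BRCA",
    "T2DM Male ccfDNA",
    "Prediabetic Male ccfDNA",
)

#: Supplementary presence column for the sequential breast-cancer samples.
SEQ_BRCA_GROUP = "Seq BRCA"

_REQUIRED_COLUMNS = (
    "window_id",
    "low_cm1",
    "high_cm1",
    "representative_cm1",
    "assignment",
)


@dataclass(frozen=True)
class PeakWindow:
    """One reference window: bounds, representative position, assignments,
    and a group -> presence mapping."""

    window_id: str
    low: float
    high: float
    representative: float
    assignment_text: str
    presence: Mapping[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.low > self.high:
            raise ReferenceError_(
                f"window {self.window_id}: low {self.low} > high {self.high}"
            )
        if not (self.low <= self.representative <= self.high):
            raise ReferenceError_(
                f"window {self.window_id}: representative "
                f"{self.representative} outside [{self.low}, {self.high}]"
            )

    def contains(self, position: float, tolerance: float = 0.0) -> bool:
        """Closed-interval containment, optionally expanded by *tolerance*."""
        return self.low - tolerance <= position <= self.high + tolerance

    def distance(self, position: float) -> float:
        """Distance from *position* to the window interval (0 if inside)."""
        return max(self.low - position, position - self.high, 0.0)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.low + self.high)


def read_reference(path) -> list[PeakWindow]:
    """Read a peak-window table (TSV) into a list of :class:`PeakWindow`.

    Required columns: window_id, low_cm1, high_cm1, representative_cm1,
    assignment. Every remaining column is interpreted as a group presence
    column with 0/1 entries.
    """
    try:
        frame = pd.read_csv(path, sep="\t", dtype={"window_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ReferenceError_(f"cannot parse reference table {path}: {exc}") from exc
    missing = [c for c in _REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise ReferenceError_(f"reference table missing columns: {missing}")
    if frame.empty:
        raise ReferenceError_(f"reference table {path} contains no windows")
    group_cols = [c for c in frame.columns if c not in _REQUIRED_COLUMNS]
    windows: list[PeakWindow] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        wid = str(row["window_id"])
        if wid in seen:
            raise ReferenceError_(f"duplicate window_id {wid!r}")
        seen.add(wid)
        presence = {g: bool(int(row[g])) for g in group_cols}
        windows.append(
            PeakWindow(
                window_id=wid,
                low=float(row["low_cm1"]),
                high=float(row["high_cm1"]),
                representative=float(row["representative_cm1"]),
                assignment_text=str(row["assignment"]),
                presence=presence,
            )
        )
    return windows


def load_reference_windows() -> list[PeakWindow]:
    """Load the packaged ccfDNA reference window table."""
    with resources.as_file(
        resources.files("ccframan").joinpath("data/reference_windows.tsv")
    ) as path:
        return read_reference(path)


def reference_group_ids(windows: Sequence[PeakWindow]) -> list[str]:
    """Group labels available in a reference table (order-preserving)."""
    out: list[str] = []
    for w in windows:
        for g in w.presence:
            if g not in out:
                out.append(g)
    return out
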