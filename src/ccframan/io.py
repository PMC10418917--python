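"""File formats: two-column spectrum CSV, JCAMP-DX, manifests, fingerprints.

The CSV dialect is fixed (comma-separated, dot decimal, UTF-8, one header
line ``raman_shift_cm-1,intensity``) to avoid locale drift. JCAMP-DX support
is a minimal reader/writer for the ``##XYDATA=(X++(Y..Y))`` form, enough to
round-trip spectra and ingest descending-axis files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError, ParseError, ReferenceError_
from .fingerprint import ComparisonReport, GroupFingerprint
from .peakcall import PeakAssignment
from .reference import read_reference  # re-exported; reference tables are I/O
from .spectrum import AverageSpectrum, RamanSpectrum

__all__ = [
    "read_spectrum",
    "write_spectrum",
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_jcamp",
    "write_jcamp",
    "read_average_csv",
    "write_average_csv",
    "ManifestRecord",
    "Manifest",
    "read_manifest",
    "write_manifest",
    "write_assignments_tsv",
    "fingerprint_to_json",
    "fingerprint_from_json",
    "write_report_tsv",
    "format_report_text",
    "read_reference",
]

logger = logging.getLogger("ccframan")

_CSV_HEADER = ("raman_shift_cm-1", "intensity")


def _finalize_axis(shifts: np.ndarray, intensities: np.ndarray, origin: str):
    if shifts.size and shifts[0] > shifts[-1]:
        logger.info("%s: descending wavenumber axis reversed on load", origin)
        shifts, intensities = shifts[::-1].copy(), intensities[::-1].copy()
    if shifts.size > 1 and np.any(np.diff(shifts) <= 0):
        raise DataError(f"{origin}: axis not strictly monotonic after sorting")
    return shifts, intensities


def read_spectrum_csv(path, **metadata) -> RamanSpectrum:
    """Read a two-column spectrum CSV (header + comma-separated rows)."""
    path = Path(path)
    shifts: list[float] = []
    intensities: list[float] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.strip():
            raise ParseError(f"{path}:1: empty file")
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise ParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                shifts.append(float(parts[0]))
                intensities.append(float(parts[1]))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    x, y = _finalize_axis(np.array(shifts), np.array(intensities), str(path))
    return RamanSpectrum(shifts=x, intensities=y, **metadata)


def write_spectrum_csv(spectrum: RamanSpectrum, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(",".join(_CSV_HEADER) + "\n")
        for x, y in zip(spectrum.shifts, spectrum.intensities):
            fh.write(f"{x:.6f},{y:.12g}\n")


def write_jcamp(spectrum: RamanSpectrum, path, title: str | None = None) -> None:
    """Write a minimal JCAMP-DX file, ``##XYDATA=(X++(Y..Y))`` with one
    abscissa and up to six ordinates per line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    x, y = spectrum.shifts, spectrum.intensities
    deltax = float(x[1] - x[0]) if x.size > 1 else 1.0
    lines = [
        f"##TITLE={title or spectrum.sample_id or 'ccframan spectrum'}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=RAMAN SPECTRUM",
        "##XUNITS=1/CM",
        "##YUNITS=ARBITRARY UNITS",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        f"##FIRSTX={x[0]:.6f}",
        f"##LASTX={x[-1]:.6f}",
        f"##DELTAX={deltax:.6f}",
        f"##NPOINTS={x.size}",
        "##XYDATA=(X++(Y..Y))",
    ]
    for i in range(0, x.size, 6):
        ys = " ".join(f"{v:.12g}" for v in y[i : i + 6])
        lines.append(f"{x[i]:.6f} {ys}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_jcamp(path, **metadata) -> RamanSpectrum:
    """Read a JCAMP-DX spectrum in ``(X++(Y..Y))`` form.

    X and Y factors are applied; a descending axis is reversed on load.
    """
    path = Path(path)
    headers: dict[str, str] = {}
    data_lines: list[tuple[int, str]] = []
    in_data = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                    continue
                headers[key] = value.strip()
                continue
            if in_data:
                data_lines.append((lineno, line))
    if not data_lines:
        raise ParseError(f"{path}: no XYDATA block found")
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    deltax = headers.get("DELTAX")
    if deltax is not None:
        step = float(deltax)
    else:
        try:
            first = float(headers["FIRSTX"])
            last = float(headers["LASTX"])
            npts = int(headers["NPOINTS"])
            step = (last - first) / (npts - 1) if npts > 1 else 1.0
        except KeyError as exc:
            raise ParseError(
                f"{path}: DELTAX or FIRSTX/LASTX/NPOINTS required"
            ) from exc
    shifts: list[float] = []
    intensities: list[float] = []
    for lineno, line in data_lines:
        tokens = line.replace(",", " ").split()
        if len(tokens) < 2:
            raise ParseError(f"{path}:{lineno}: data line needs X and >=1 Y value")
        try:
            x0 = float(tokens[0]) * xfactor
            ys = [float(t) * yfactor for t in tokens[1:]]
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from exc
        for k, yv in enumerate(ys):
            shifts.append(x0 + k * step)
            intensities.append(yv)
    x, y = _finalize_axis(np.array(shifts), np.array(intensities), str(path))
    return RamanSpectrum(shifts=x, intensities=y, **metadata)


def read_spectrum(path, format: str | None = None, **metadata) -> RamanSpectrum:
    """Read a spectrum, dispatching on *format* or the file extension
    (``.jdx``/``.dx`` -> JCAMP-DX, anything else -> CSV)."""
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        return read_spectrum_csv(path, **metadata)
    if format == "jcamp":
        return read_jcamp(path, **metadata)
    raise ParseError(f"unknown spectrum format {format!r}")


def write_spectrum(spectrum: RamanSpectrum, path, format: str | None = None) -> None:
    path = Path(path)
    if format is None:
        format = "jcamp" if path.suffix.lower() in {".jdx", ".dx", ".jcm"} else "csv"
    if format == "csv":
        write_spectrum_csv(spectrum, path)
    elif format == "jcamp":
        write_jcamp(spectrum, path)
    else:
        raise ParseError(f"unknown spectrum format {format!r}")


def write_average_csv(avg: AverageSpectrum, path) -> None:
    """Write an average spectrum as three-column CSV (shift, mean, sd)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {"raman_shift_cm-1": avg.shifts, "mean": avg.mean, "sd": avg.sd}
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# n={avg.n}\tgroup_id={avg.group_id}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def read_average_csv(path) -> AverageSpectrum:
    path = Path(path)
    n, group_id = 1, ""
    with open(path, encoding="utf-8") as fh:
        first = fh.readline()
        if first.startswith("#"):
            for token in first[1:].strip().split("\t"):
                key, _, value = token.partition("=")
                if key == "n":
                    n = int(value)
                elif key == "group_id":
                    group_id = value
            frame = pd.read_csv(fh)
        else:
            fh.seek(0)
            frame = pd.read_csv(fh)
    try:
        return AverageSpectrum(
            shifts=frame["raman_shift_cm-1"].to_numpy(),
            mean=frame["mean"].to_numpy(),
            sd=frame["sd"].to_numpy(),
            n=n,
            group_id=group_id,
        )
    except KeyError as exc:
        raise ParseError(f"{path}: missing column {exc}") from exc


@dataclass(frozen=True)
class ManifestRecord:
    path: Path
    sample_id: str
    group_id: str
    replicate_index: int


@dataclass
class Manifest:
    """Listing of spectrum files with sample/group metadata.

    (sample_id, replicate_index) pairs are unique and every referenced file
    must exist when the manifest is loaded.
    """

    records: list[ManifestRecord]

    def __post_init__(self) -> None:
        seen = set()
        for rec in self.records:
            key = (rec.sample_id, rec.replicate_index)
            if key in seen:
                raise DataError(f"duplicate manifest entry {key}")
            seen.add(key)

    def group_ids(self) -> list[str]:
        out: list[str] = []
        for rec in self.records:
            if rec.group_id not in out:
                out.append(rec.group_id)
        return out

    def load_group(self, group_id: str) -> list[RamanSpectrum]:
        return [
            read_spectrum(
                rec.path,
                sample_id=rec.sample_id,
                group_id=rec.group_id,
                replicate_index=rec.replicate_index,
            )
            for rec in self.records
            if rec.group_id == group_id
        ]


def read_manifest(path) -> Manifest:
    """Read a TSV manifest (columns: file, sample_id, group_id,
    replicate_index); relative file paths resolve against the manifest dir."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t")
    except Exception as exc:
        raise ParseError(f"cannot parse manifest {path}: {exc}") from exc
    required = {"file", "sample_id", "group_id", "replicate_index"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"manifest {path} missing columns: {sorted(missing)}")
    records = []
    for _, row in frame.iterrows():
        p = Path(row["file"])
        if not p.is_absolute():
            p = path.parent / p
        if not p.exists():
            raise DataError(f"manifest references missing file {p}")
        records.append(
            ManifestRecord(
                path=p,
                sample_id=str(row["sample_id"]),
                group_id=str(row["group_id"]),
                replicate_index=int(row["replicate_index"]),
            )
        )
    return Manifest(records=records)


def write_manifest(records: Sequence[ManifestRecord], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "file": [str(r.path) for r in records],
            "sample_id": [r.sample_id for r in records],
            "group_id": [r.group_id for r in records],
            "replicate_index": [r.replicate_index for r in records],
        }
    )
    frame.to_csv(path, sep="\t", index=False)


def write_assignments_tsv(assignments: Sequence[PeakAssignment], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame = pd.DataFrame(
        {
            "position_cm-1": [a.peak.position for a in assignments],
            "height": [a.peak.height for a in assignments],
            "prominence": [a.peak.prominence for a in assignments],
            "fwhm_cm-1": [a.peak.fwhm for a in assignments],
            "window_id": [a.window_id or "unassigned" for a in assignments],
            "distance_cm-1": [a.distance for a in assignments],
        }
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.4f")


def fingerprint_to_json(fingerprint: GroupFingerprint, path=None) -> str:
    payload = {
        "group_id": fingerprint.group_id,
        "present_windows": sorted(fingerprint.present_windows),
        "source": fingerprint.source,
        "reference_ids": (
            sorted(fingerprint.reference_ids)
            if fingerprint.reference_ids is not None
            else None
        ),
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        Path(path).write_text(text + "\n", encoding="utf-8")
    return text


def fingerprint_from_json(path) -> GroupFingerprint:
    try:
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        return GroupFingerprint(
            group_id=payload["group_id"],
            present_windows=frozenset(payload["present_windows"]),
            source=payload.get("source", "called"),
            reference_ids=(
                frozenset(payload["reference_ids"])
                if payload.get("reference_ids") is not None
                else None
            ),
        )
    except (json.JSONDecodeError, KeyError, TypeError) as exc:
        raise ParseError(f"cannot parse fingerprint JSON {path}: {exc}") from exc


def write_report_tsv(report: ComparisonReport, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for w in sorted(report.shared):
        rows.append({"window_id": w, "category": "shared", "detail": "all groups"})
    for g in report.groups:
        for w in sorted(report.unique.get(g, ())):
            rows.append({"window_id": w, "category": "unique", "detail": g})
    for w, absent in report.absent_in.items():
        if absent:
            rows.append(
                {"window_id": w, "category": "absent_in", "detail": ";".join(absent)}
            )
    pd.DataFrame(rows, columns=["window_id", "category", "detail"]).to_csv(
        path, sep="\t", index=False
    )


def format_report_text(report: ComparisonReport) -> str:
    lines = [f"Groups compared: {', '.join(report.groups)}"]
    lines.append(
        f"Shared windows ({len(report.shared)}): "
        + (", ".join(sorted(report.shared)) or "none")
    )
    for g in report.groups:
        uniq = sorted(report.unique.get(g, ()))
        lines.append(f"Unique to {g} ({len(uniq)}): " + (", ".join(uniq) or "none"))
    absentees = {w: a for w, a in report.absent_in.items() if a}
    if absentees:
        lines.append("Absences:")
        for w, absent in absentees.items():
            lines.append(f"  {w} absent in: {', '.join(absent)}")
    return "\n".join(lines)
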