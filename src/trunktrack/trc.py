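"""TRC (Track Row Column) marker-trajectory files, OpenSim dialect.

Tab-delimited text: a three-line header (file type, field names, field
values), a two-line column header (marker labels, then X/Y/Z triplets)
and one row per frame.  Blank coordinate cells mark occluded frames.
Positions are returned in millimetres whatever the file units.
"""
from __future__ import annotations

import numpy as np

from .errors import FormatError, UnknownUnits
from .trial import MarkerTrialSet

_UNIT_SCALE = {"mm": 1.0, "m": 1000.0, "cm": 10.0}


def write_trc(trial: MarkerTrialSet, path) -> None:
    """Write a trial as a TRC file (mm units)."""
    markers = list(trial.markers)
    n = trial.n_frames
    with open(path, "w", newline="") as fh:
        fh.write(f"PathFileType\t4\t(X/Y/Z)\t{path}\n")
        fh.write("DataRate\tCameraRate\tNumFrames\tNumMarkers\tUnits\t"
                 "OrigDataRate\tOrigDataStartFrame\tOrigNumFrames\n")
        fh.write(f"{trial.rate:g}\t{trial.rate:g}\t{n}\t{len(markers)}\tmm\t"
                 f"{trial.rate:g}\t1\t{n}\n")
        fh.write("Frame#\tTime\t" + "\t\t\t".join(markers) + "\t\t\t\n")
        fh.write("\t\t" + "\t".join(
            f"X{i}\tY{i}\tZ{i}" for i in range(1, len(markers) + 1)) + "\n")
        times = trial.time
        for f in range(n):
            cells = [str(f + 1), repr(float(times[f]))]
            for name in markers:
                if trial.occluded[name][f]:
                    cells += ["", "", ""]
                else:
                    cells += [repr(float(v)) for v in trial.positions[name][f]]
            fh.write("\t".join(cells) + "\n")


def read_trc(path, kind: str = "dynamic", subject: str = "S00",
             sex: str | None = None) -> MarkerTrialSet:
    """Read a TRC file into a :class:`MarkerTrialSet` (positions in mm)."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if len(lines) < 6:
        raise FormatError("truncated TRC header", line=len(lines))
    if not lines[0].startswith("PathFileType"):
        raise FormatError("missing PathFileType line", line=1)
    fields = lines[1].split("\t")
    values = lines[2].split("\t")
    header = dict(zip(fields, values))
    try:
        rate = float(header["DataRate"])
        n_frames = int(header["NumFrames"])
        n_markers = int(header["NumMarkers"])
        units = header["Units"].strip().lower()
    except (KeyError, ValueError) as exc:
        raise FormatError(f"bad TRC header: {exc}", line=3) from exc
    if units not in _UNIT_SCALE:
        raise UnknownUnits(f"unknown units {units!r}", line=3)
    scale = _UNIT_SCALE[units]

    labels = [c for c in lines[3].split("\t")[2:] if c.strip()]
    if len(labels) != n_markers:
        raise FormatError(
            f"expected {n_markers} marker labels, found {len(labels)}", line=4)

    data = np.full((n_frames, 3 * n_markers), np.nan)
    row = 0
    for ln, line in enumerate(lines[5:], start=6):
        if not line.strip():
            continue
        if row >= n_frames:
            raise FormatError("more data rows than NumFrames", line=ln)
        cells = line.split("\t")[2:]
        for j in range(3 * n_markers):
            if j < len(cells) and cells[j].strip():
                try:
                    data[row, j] = float(cells[j])
                except ValueError as exc:
                    raise FormatError(f"bad number {cells[j]!r}",
                                      line=ln) from exc
        row += 1
    if row != n_frames:
        raise FormatError(f"expected {n_frames} data rows, found {row}",
                          line=len(lines))
    positions = {
        name: data[:, 3 * i:3 * i + 3] * scale
        for i, name in enumerate(labels)
    }
    return MarkerTrialSet(positions=positions, rate=rate, kind=kind,
                          subject=subject, sex=sex)
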