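"""Minimal C3D reader/writer for labelled 3-D point data.

Supports the common Intel/floating-point dialect: header block, parameter
section (POINT group with LABELS / RATE / UNITS), and per-frame
``x, y, z, residual`` float32 point records.  A negative residual marks an
occluded frame.  Analog channels, integer-scaled data and non-Intel
processor types are out of scope; positions are converted to millimetres.
"""
from __future__ import annotations

import struct

import numpy as np

from .errors import FormatError, UnknownUnits
from .trial import MarkerTrialSet

BLOCK = 512
_PROC_INTEL = 84
_UNIT_SCALE = {"mm": 1.0, "m": 1000.0, "cm": 10.0}


# ---------------------------------------------------------------------------
# writing

def _param_bytes(name: bytes, group_id: int, dtype: int, dims: list[int],
                 data: bytes) -> bytes:
    body = struct.pack("bb", dtype, len(dims))
    body += bytes(dims) + data + b"\x00"  # zero-length description
    head = struct.pack("bb", len(name), group_id) + name
    return head + struct.pack("<h", len(body)) + body


def _group_bytes(name: bytes, group_id: int) -> bytes:
    body = b"\x00"
    head = struct.pack("bb", len(name), -group_id) + name
    return head + struct.pack("<h", len(body)) + body


def write_c3d(trial: MarkerTrialSet, path) -> None:
    """Write a trial as a float-format Intel C3D file (mm units)."""
    markers = list(trial.markers)
    n_frames = trial.n_frames
    n_points = len(markers)

    label_len = max(4, max(len(m) for m in markers))
    labels = b"".join(m.ljust(label_len).encode("ascii") for m in markers)
    params = _group_bytes(b"POINT", 1)
    params += _param_bytes(b"USED", 1, 2, [], struct.pack("<h", n_points))
    params += _param_bytes(b"FRAMES", 1, 2, [], struct.pack("<h", min(n_frames, 32767)))
    params += _param_bytes(b"RATE", 1, 4, [], struct.pack("<f", trial.rate))
    params += _param_bytes(b"SCALE", 1, 4, [], struct.pack("<f", -1.0))
    params += _param_bytes(b"UNITS", 1, -1, [2], b"mm")
    params += _param_bytes(b"LABELS", 1, -1, [label_len, n_points], labels)

    n_param_blocks = -(-(4 + len(params)) // BLOCK)
    data_start = 2 + n_param_blocks  # 1-based block index

    header = bytearray(BLOCK)
    struct.pack_into("BB", header, 0, 2, 0x50)          # param block, magic
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)                # analog per frame
    struct.pack_into("<H", header, 6, 1)                # first frame
    struct.pack_into("<H", header, 8, n_frames)         # last frame
    struct.pack_into("<H", header, 10, 10)              # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)            # scale (float data)
    struct.pack_into("<H", header, 16, data_start)
    struct.pack_into("<H", header, 18, 0)               # analog samples/frame
    struct.pack_into("<f", header, 20, trial.rate)

    param_section = bytearray(n_param_blocks * BLOCK)
    struct.pack_into("BBBB", param_section, 0, 1, 0x50,
                     n_param_blocks, _PROC_INTEL)
    param_section[4:4 + len(params)] = params

    frames = np.zeros((n_frames, n_points, 4), dtype="<f4")
    for i, name in enumerate(markers):
        frames[:, i, :3] = np.nan_to_num(trial.positions[name])
        frames[:, i, 3] = np.where(trial.occluded[name], -1.0, 0.0)

    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(param_section)
        payload = frames.tobytes()
        fh.write(payload)
        pad = (-len(payload)) % BLOCK
        fh.write(b"\x00" * pad)


# ---------------------------------------------------------------------------
# reading

def _parse_parameters(raw: bytes) -> dict:
    """Parse the parameter section into {GROUP: {PARAM: value}}."""
    if len(raw) < 4:
        raise FormatError("truncated C3D parameter section")
    processor = raw[3]
    if processor != _PROC_INTEL:
        raise FormatError(f"unsupported processor type {processor}")
    groups: dict[int, str] = {}
    values: dict[int, dict[str, object]] = {}
    pos = 4
    while pos + 2 <= len(raw):
        n_name = struct.unpack_from("b", raw, pos)[0]
        if n_name == 0:
            break
        group_id = struct.unpack_from("b", raw, pos + 1)[0]
        name = raw[pos + 2:pos + 2 + abs(n_name)].decode("ascii", "replace")
        pos2 = pos + 2 + abs(n_name)
        offset = struct.unpack_from("<h", raw, pos2)[0]
        body_start = pos2 + 2
        if group_id < 0:  # group definition
            groups[-group_id] = name
        else:             # parameter
            dtype = struct.unpack_from("b", raw, body_start)[0]
            ndims = struct.unpack_from("b", raw, body_start + 1)[0]
            dims = list(raw[body_start + 2:body_start + 2 + ndims])
            dstart = body_start + 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            size = {-1: 1, 1: 1, 2: 2, 4: 4}.get(dtype)
            if size is None:
                raise FormatError(f"bad parameter type {dtype}")
            payload = raw[dstart:dstart + count * size]
            if dtype == -1:
                value = payload.decode("ascii", "replace")
                if len(dims) > 1:
                    step = dims[0]
                    value = [value[i * step:(i + 1) * step].strip()
                             for i in range(dims[1])]
                else:
                    value = value.strip()
            else:
                fmt = {1: "b", 2: "<h", 4: "<f"}[dtype]
                value = [struct.unpack_from(fmt, payload, i * size)[0]
                         for i in range(count)]
                value = np.array(value).reshape(dims[::-1] or [1])
            values.setdefault(group_id, {})[name.upper()] = value
        if offset <= 0:
            break
        # offset counts bytes from the end of the offset word to the next entry
        pos = body_start + offset
    return {groups.get(gid, str(gid)): params
            for gid, params in values.items()}


def read_c3d(path, kind: str = "dynamic", subject: str = "S00",
             sex: str | None = None) -> MarkerTrialSet:
    """Read labelled 3-D points from a C3D file (positions in mm)."""
    with open(path, "rb") as fh:
        blob = fh.read()
    if len(blob) < 2 * BLOCK:
        raise FormatError("file too short to be a C3D")
    if blob[1] != 0x50:
        raise FormatError("missing C3D magic byte")
    param_block = blob[0]
    n_points = struct.unpack_from("<H", blob, 2)[0]
    first_frame = struct.unpack_from("<H", blob, 6)[0]
    last_frame = struct.unpack_from("<H", blob, 8)[0]
    scale = struct.unpack_from("<f", blob, 12)[0]
    data_start = struct.unpack_from("<H", blob, 16)[0]
    rate = struct.unpack_from("<f", blob, 20)[0]
    if scale >= 0:
        raise FormatError("integer-scaled C3D data is not supported")
    if n_points == 0:
        raise FormatError("file contains no 3-D points")

    params = _parse_parameters(blob[(param_block - 1) * BLOCK:])
    point = {k.upper(): v for k, v in params.get("POINT", {}).items()}
    labels = point.get("LABELS")
    if not labels or not any(str(l).strip() for l in labels):
        raise FormatError("C3D has no point labels")
    labels = [str(l).strip() for l in labels][:n_points]
    if len(labels) < n_points:
        raise FormatError("fewer labels than points")
    units = str(point.get("UNITS", "mm")).strip().lower()
    if units not in _UNIT_SCALE:
        raise UnknownUnits(f"unknown POINT:UNITS {units!r}")
    if "RATE" in point:
        rate = float(np.ravel(point["RATE"])[0])

    n_frames = last_frame - first_frame + 1
    offset = (data_start - 1) * BLOCK
    need = n_frames * n_points * 4 * 4
    if len(blob) < offset + need:
        raise FormatError("truncated C3D data section")
    frames = np.frombuffer(blob, dtype="<f4", count=n_frames * n_points * 4,
                           offset=offset).reshape(n_frames, n_points, 4)
    unit = _UNIT_SCALE[units]
    positions, occluded = {}, {}
    for i, name in enumerate(labels):
        pos = frames[:, i, :3].astype(float) * unit
        occ = frames[:, i, 3] < 0
        pos[occ] = np.nan
        positions[name] = pos
        occluded[name] = occ
    return MarkerTrialSet(positions=positions, rate=float(rate), kind=kind,
                          subject=subject, sex=sex, occluded=occluded)
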