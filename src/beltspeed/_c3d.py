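"""Minimal C3D motion-capture file codec.

Implements the subset of the C3D standard needed for marker (POINT) data:
512-byte header, parameter section (groups/parameters, Intel byte order),
and the 3D point data section in floating-point or signed-integer storage.
Gaps are encoded with the standard negative-residual convention.

Only Intel (PC) processor-type files are handled; analog channels are
ignored on read and never written.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .exceptions import C3DFormatError

BLOCK = 512
PROC_INTEL = 84  # 83 + 1


@dataclass
class PointData:
    """Raw contents of a C3D file's point section."""

    labels: list[str]
    positions: np.ndarray  # (n_frames, n_points, 3), file units
    residuals: np.ndarray  # (n_frames, n_points), negative = invalid
    frame_rate: float
    first_frame: int  # 1-based, as stored in the file
    units: str
    descriptions: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# parameter-section records


def _param_bytes(name: str, dtype_len: int, dims: list[int], data: bytes) -> bytes:
    name_b = name.encode("ascii")
    body = (
        struct.pack("<b", dtype_len)
        + struct.pack("<B", len(dims))
        + bytes(dims)
        + data
        + b"\x00"  # empty description
    )
    offset = 2 + len(body)
    return (
        struct.pack("<bb", len(name_b), 1)  # group id 1 = POINT
        + name_b
        + struct.pack("<h", offset)
        + body
    )


def _int16_param(name: str, value: int) -> bytes:
    return _param_bytes(name, 2, [], struct.pack("<h", value))


def _float_param(name: str, value: float) -> bytes:
    return _param_bytes(name, 4, [], struct.pack("<f", value))


def _char_param(name: str, text: str) -> bytes:
    raw = text.encode("ascii")
    return _param_bytes(name, -1, [len(raw)], raw)


def _labels_params(labels: list[str]) -> bytes:
    """LABELS plus LABELS2/LABELS3... chunks of at most 255 labels each."""
    width = max(4, max((len(s) for s in labels), default=4))
    if width > 255:
        raise C3DFormatError("marker label longer than 255 characters")
    out = b""
    for chunk_idx in range(0, max(1, (len(labels) + 254) // 255)):
        chunk = labels[chunk_idx * 255 : (chunk_idx + 1) * 255]
        name = "LABELS" if chunk_idx == 0 else f"LABELS{chunk_idx + 1}"
        data = b"".join(s.encode("ascii").ljust(width) for s in chunk)
        out += _param_bytes(name, -1, [width, len(chunk)], data)
    return out


def write_c3d(path, data: PointData) -> None:
    n_frames, n_points, _ = data.positions.shape
    if n_frames < 1:
        raise C3DFormatError("cannot write a capture with zero frames")
    if len(data.labels) != n_points:
        raise C3DFormatError("label count does not match point count")

    # --- parameter section (group POINT, id 1) ---
    group_name = b"POINT"
    group_desc = b""
    group = (
        struct.pack("<bb", len(group_name), -1)
        + group_name
        + struct.pack("<h", 2 + 1 + len(group_desc))
        + struct.pack("<B", len(group_desc))
        + group_desc
    )
    params = (
        group
        + _int16_param("USED", n_points)
        + _int16_param("FRAMES", min(n_frames, 32767))
        + _float_param("RATE", data.frame_rate)
        + _float_param("SCALE", -1.0)  # negative: floating-point storage
        + _char_param("UNITS", data.units)
        + _labels_params(data.labels)
    )
    # DATA_START depends on the parameter section length; reserve its record.
    params_with_ds = _int16_param("DATA_START", 0) + params
    n_param_blocks = (4 + len(params_with_ds) + BLOCK - 1) // BLOCK
    data_start_block = 2 + n_param_blocks  # 1-based block index
    params_with_ds = _int16_param("DATA_START", data_start_block) + params

    param_section = (
        struct.pack("<BBBB", 1, 0x50, n_param_blocks, PROC_INTEL) + params_with_ds
    )
    param_section = param_section.ljust(n_param_blocks * BLOCK, b"\x00")

    # --- header block ---
    header = bytearray(BLOCK)
    struct.pack_into("<BB", header, 0, 2, 0x50)  # parameter block, magic
    struct.pack_into("<H", header, 2, n_points)
    struct.pack_into("<H", header, 4, 0)  # analog measurements per frame
    struct.pack_into("<H", header, 6, data.first_frame)
    struct.pack_into("<H", header, 8, min(data.first_frame + n_frames - 1, 65535))
    struct.pack_into("<H", header, 10, 0)  # max interpolation gap
    struct.pack_into("<f", header, 12, -1.0)  # scale (float storage)
    struct.pack_into("<H", header, 16, data_start_block)
    struct.pack_into("<H", header, 18, 0)  # analog samples per 3D frame
    struct.pack_into("<f", header, 20, data.frame_rate)

    # --- point data: x, y, z, residual as float32 ---
    frame_words = np.empty((n_frames, n_points, 4), dtype="<f4")
    frame_words[:, :, :3] = data.positions
    frame_words[:, :, 3] = data.residuals

    with open(path, "wb") as fh:
        fh.write(bytes(header))
        fh.write(param_section)
        fh.write(frame_words.tobytes())


# ---------------------------------------------------------------------------
# reading


def _parse_params(buf: bytes) -> dict[str, dict[str, tuple]]:
    """Parse the parameter section into {group: {param: (dims, values)}}."""
    if len(buf) < 4:
        raise C3DFormatError("parameter section truncated")
    proc = buf[3]
    if proc != PROC_INTEL:
        raise C3DFormatError(
            f"unsupported processor type {proc} in parameter section "
            "(only Intel/PC byte order is handled)"
        )
    groups_by_id: dict[int, str] = {}
    records: list[tuple[int, str, bytes]] = []  # (group_id, name, body)
    pos = 4
    while pos + 2 <= len(buf):
        nlen = struct.unpack_from("<b", buf, pos)[0]
        if nlen == 0:
            break
        gid = struct.unpack_from("<b", buf, pos + 1)[0]
        name_len = abs(nlen)
        name = buf[pos + 2 : pos + 2 + name_len].decode("ascii", "replace").strip()
        off_pos = pos + 2 + name_len
        if off_pos + 2 > len(buf):
            break
        offset = struct.unpack_from("<h", buf, off_pos)[0]
        body = buf[off_pos + 2 : off_pos + 2 + max(offset - 2, 0)]
        if gid < 0:
            groups_by_id[-gid] = name
        else:
            records.append((gid, name, body))
        if offset <= 0:
            break
        pos = off_pos + offset

    out: dict[str, dict[str, tuple]] = {}
    for gid, name, body in records:
        group = groups_by_id.get(gid, f"GROUP{gid}")
        try:
            dtype_len = struct.unpack_from("<b", body, 0)[0]
            ndims = body[1]
            dims = list(body[2 : 2 + ndims])
            dstart = 2 + ndims
            count = int(np.prod(dims)) if dims else 1
            if dtype_len == -1:
                raw = body[dstart : dstart + count]
                values = raw
            elif dtype_len == 1:
                values = np.frombuffer(body, dtype="<i1", count=count, offset=dstart)
            elif dtype_len == 2:
                values = np.frombuffer(body, dtype="<i2", count=count, offset=dstart)
            elif dtype_len == 4:
                values = np.frombuffer(body, dtype="<f4", count=count, offset=dstart)
            else:
                continue
        except (struct.error, ValueError) as exc:
            raise C3DFormatError(f"malformed parameter {group}:{name}") from exc
        out.setdefault(group, {})[name] = (dims, values)
    return out


def _char_array(dims: list[int], raw: bytes) -> list[str]:
    if len(dims) < 2:
        return [raw.decode("ascii", "replace").strip()]
    width, count = dims[0], int(np.prod(dims[1:]))
    return [
        raw[i * width : (i + 1) * width].decode("ascii", "replace").strip()
        for i in range(count)
    ]


def read_c3d(path) -> PointData:
    with open(path, "rb") as fh:
        raw = fh.read()
    if len(raw) < 2 * BLOCK:
        raise C3DFormatError("file too short to contain a C3D header section")
    if raw[1] != 0x50:
        raise C3DFormatError("missing C3D magic byte in header section")

    param_block = raw[0]
    n_points_hdr = struct.unpack_from("<H", raw, 2)[0]
    first_frame = struct.unpack_from("<H", raw, 6)[0]
    last_frame = struct.unpack_from("<H", raw, 8)[0]
    scale_hdr = struct.unpack_from("<f", raw, 12)[0]
    data_start_hdr = struct.unpack_from("<H", raw, 16)[0]
    rate_hdr = struct.unpack_from("<f", raw, 20)[0]

    pstart = (param_block - 1) * BLOCK
    n_param_blocks = raw[pstart + 2] if len(raw) > pstart + 2 else 0
    pend = pstart + max(n_param_blocks, 1) * BLOCK
    params = _parse_params(raw[pstart:pend])
    point = params.get("POINT", {})

    def scalar(name, default):
        if name not in point:
            return default
        _, values = point[name]
        return type(default)(values[0]) if len(values) else default

    n_points = scalar("USED", n_points_hdr)
    n_frames = scalar("FRAMES", max(last_frame - first_frame + 1, 0))
    rate = scalar("RATE", float(rate_hdr))
    scale = scalar("SCALE", float(scale_hdr))
    data_start = scalar("DATA_START", data_start_hdr)
    units = ""
    if "UNITS" in point:
        units = _char_array(*point["UNITS"])[0]

    labels: list[str] = []
    idx = 1
    while True:
        key = "LABELS" if idx == 1 else f"LABELS{idx}"
        if key not in point:
            break
        labels.extend(_char_array(*point[key]))
        idx += 1
    labels = labels[:n_points]
    labels += [f"*{i + 1}" for i in range(len(labels), n_points)]

    if n_frames < 1:
        raise C3DFormatError("capture declares zero frames in POINT section")
    if n_points < 1:
        return PointData(
            [], np.zeros((n_frames, 0, 3)), np.zeros((n_frames, 0)), rate,
            first_frame, units,
        )

    offset = (data_start - 1) * BLOCK
    if offset + n_frames * n_points * 4 * (4 if scale < 0 else 2) > len(raw):
        raise C3DFormatError("point data section truncated")
    if scale < 0:  # floating-point storage
        words = np.frombuffer(raw, dtype="<f4", count=n_frames * n_points * 4,
                              offset=offset)
        words = words.reshape(n_frames, n_points, 4)
        positions = words[:, :, :3].astype(np.float64)
        residuals = words[:, :, 3].astype(np.float64)
    else:  # signed-integer storage, positions scaled
        words = np.frombuffer(raw, dtype="<i2", count=n_frames * n_points * 4,
                              offset=offset)
        words = words.reshape(n_frames, n_points, 4)
        positions = words[:, :, :3].astype(np.float64) * scale
        residuals = words[:, :, 3].astype(np.float64)
        residuals[residuals > 0] *= scale
    return PointData(labels, positions, residuals, rate, first_frame, units)
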