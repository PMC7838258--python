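"""Reading and writing .c3d motion-capture files.

All format dialect handling lives here: unit conversion to meters, the two
gap-encoding conventions found in vendor exports (negative residual and
all-coordinates-zero), routing of unlabeled points, and the laboratory axis
convention (which lab axis is anteroposterior, mediolateral, vertical, and
the sign of belt travel).

Frames are 0-based internally; the C3D on-disk convention (1-based first
frame) is translated at the file boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import _c3d
from .exceptions import C3DFormatError, ConfigError, EmptyCaptureError

_AXIS_INDEX = {"x": 0, "y": 1, "z": 2}

_UNIT_TO_M = {"mm": 1e-3, "cm": 1e-2, "m": 1.0}


def _parse_axis(spec: str) -> tuple[int, float]:
    """'+y' / 'y' / '-z' -> (column index, sign)."""
    s = spec.strip().lower()
    sign = 1.0
    if s and s[0] in "+-":
        sign = -1.0 if s[0] == "-" else 1.0
        s = s[1:]
    if s not in _AXIS_INDEX:
        raise ConfigError(f"invalid axis specification {spec!r}")
    return _AXIS_INDEX[s], sign


@dataclass(frozen=True)
class AxisConvention:
    """Mapping from lab roles to the file's coordinate axes.

    ``belt_travel_sign`` gives the direction the belt top surface moves
    along the (signed) anteroposterior axis: the default ``-1`` means the
    belt carries the subject backward while they face the +AP direction.
    """

    anteroposterior: str = "+y"
    mediolateral: str = "+x"
    vertical: str = "+z"
    belt_travel_sign: float = -1.0

    def __post_init__(self):
        idxs = {self.ap_index, self.ml_index, self.up_index}
        if len(idxs) != 3:
            raise ConfigError("anteroposterior/mediolateral/vertical axes "
                              "must map to three distinct coordinates")
        if self.belt_travel_sign not in (-1.0, 1.0, -1, 1):
            raise ConfigError("belt_travel_sign must be +1 or -1")

    @property
    def ap_index(self) -> int:
        return _parse_axis(self.anteroposterior)[0]

    @property
    def ap_sign(self) -> float:
        return _parse_axis(self.anteroposterior)[1]

    @property
    def ml_index(self) -> int:
        return _parse_axis(self.mediolateral)[0]

    @property
    def up_index(self) -> int:
        return _parse_axis(self.vertical)[0]

    @property
    def up_sign(self) -> float:
        return _parse_axis(self.vertical)[1]

    def ap_axis_vector(self) -> np.ndarray:
        v = np.zeros(3)
        v[self.ap_index] = self.ap_sign
        return v

    def belt_direction(self) -> np.ndarray:
        """Unit vector along which belt-surface markers travel."""
        return self.belt_travel_sign * self.ap_axis_vector()

    @classmethod
    def from_dict(cls, d: dict) -> "AxisConvention":
        return cls(**{k: d[k] for k in
                      ("anteroposterior", "mediolateral", "vertical",
                       "belt_travel_sign") if k in d})


@dataclass(frozen=True)
class CaptureMeta:
    frame_rate: float
    first_frame: int
    n_frames: int
    position_units: str = "m"
    axis: AxisConvention = field(default_factory=AxisConvention)

    def __post_init__(self):
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be positive")
        if self.n_frames < 1:
            raise EmptyCaptureError("capture must contain at least one frame")
        if self.position_units not in _UNIT_TO_M:
            raise ConfigError(f"unknown position units {self.position_units!r}")

    @property
    def end_frame(self) -> int:
        return self.first_frame + self.n_frames

    def times(self) -> np.ndarray:
        return (np.arange(self.first_frame, self.end_frame)
                - self.first_frame) / self.frame_rate


@dataclass
class Trajectory:
    """One marker's 3D position time series in meters, lab frame.

    ``gap_mask`` is True where the sample is missing/invalid; ``positions``
    at gap frames are meaningless placeholders.
    """

    label: str
    start_frame: int
    positions: np.ndarray  # (n, 3) float64, meters
    gap_mask: np.ndarray  # (n,) bool

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=np.float64)
        self.gap_mask = np.asarray(self.gap_mask, dtype=bool)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValueError("positions must have shape (n, 3)")
        if self.gap_mask.shape != (self.positions.shape[0],):
            raise ValueError("gap_mask length must equal positions length")
        if not (~self.gap_mask).any():
            raise ValueError(f"trajectory {self.label!r} has no valid sample")
        if not np.isfinite(self.positions[~self.gap_mask]).all():
            raise ValueError(f"trajectory {self.label!r} has non-finite "
                             "coordinates at valid frames")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def end_frame(self) -> int:
        return self.start_frame + self.n_frames

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.start_frame, self.end_frame)

    def is_gap_free(self) -> bool:
        return not self.gap_mask.any()


@dataclass
class CaptureSession:
    meta: CaptureMeta
    labeled: dict[str, Trajectory] = field(default_factory=dict)
    unlabeled: list[Trajectory] = field(default_factory=list)

    def __post_init__(self):
        for traj in self.all_trajectories():
            if (traj.start_frame < self.meta.first_frame
                    or traj.end_frame > self.meta.end_frame):
                raise ValueError(
                    f"trajectory {traj.label!r} spans "
                    f"[{traj.start_frame}, {traj.end_frame}) outside capture "
                    f"range [{self.meta.first_frame}, {self.meta.end_frame})")

    def all_trajectories(self):
        yield from self.labeled.values()
        yield from self.unlabeled


def _is_unlabeled(label: str) -> bool:
    return label == "" or label.startswith("*")


def read_capture(path, axis: AxisConvention | None = None, *,
                 zero_is_gap: bool = True) -> CaptureSession:
    """Read a .c3d file into a :class:`CaptureSession` (positions in meters).

    Points flagged invalid by the file (negative residual, or all three
    coordinates exactly zero when ``zero_is_gap``) are marked in each
    trajectory's gap mask.  Points whose label is empty or starts with the
    vendor unlabeled prefix ``*`` go to the unlabeled collection.
    """
    data = _c3d.read_c3d(path)
    units = data.units.strip().lower()
    if not units:
        warnings.warn("POINT:UNITS missing; assuming millimeters",
                      stacklevel=2)
        units = "mm"
    if units not in _UNIT_TO_M:
        raise C3DFormatError(f"unsupported POINT:UNITS value {data.units!r}")
    factor = _UNIT_TO_M[units]

    n_frames = data.positions.shape[0]
    meta = CaptureMeta(frame_rate=data.frame_rate,
                       first_frame=data.first_frame - 1,
                       n_frames=n_frames,
                       axis=axis or AxisConvention())

    labeled: dict[str, Trajectory] = {}
    unlabeled: list[Trajectory] = []
    for col, label in enumerate(data.labels):
        valid = data.residuals[:, col] >= 0
        if zero_is_gap:
            valid &= ~np.all(data.positions[:, col, :] == 0.0, axis=1)
        if not valid.any():
            continue
        idx = np.flatnonzero(valid)
        lo, hi = idx[0], idx[-1] + 1
        traj = Trajectory(label=label,
                          start_frame=meta.first_frame + int(lo),
                          positions=data.positions[lo:hi, col, :] * factor,
                          gap_mask=~valid[lo:hi])
        if _is_unlabeled(label):
            unlabeled.append(traj)
        else:
            if label in labeled:
                raise C3DFormatError(f"duplicate labeled marker {label!r}")
            labeled[label] = traj
    return CaptureSession(meta=meta, labeled=labeled, unlabeled=unlabeled)


def write_capture(session: CaptureSession, path, *, units: str = "mm") -> None:
    """Write a session to a valid .c3d that :func:`read_capture` reproduces.

    Gaps (and frames outside a trajectory's span) are encoded with the
    negative-residual convention.
    """
    if units not in _UNIT_TO_M:
        raise ConfigError(f"unsupported output units {units!r}")
    factor = 1.0 / _UNIT_TO_M[units]
    meta = session.meta
    trajs = list(session.all_trajectories())
    labels = [t.label if t.label else f"*{i + 1}"
              for i, t in enumerate(trajs)]

    n = meta.n_frames
    positions = np.zeros((n, len(trajs), 3), dtype=np.float64)
    residuals = np.full((n, len(trajs)), -1.0)
    for col, traj in enumerate(trajs):
        lo = traj.start_frame - meta.first_frame
        hi = lo + traj.n_frames
        positions[lo:hi, col, :] = traj.positions * factor
        residuals[lo:hi, col] = np.where(traj.gap_mask, -1.0, 0.0)
        # keep gap placeholders from round-tripping as real coordinates
        positions[lo:hi, col, :][traj.gap_mask] = 0.0

    _c3d.write_c3d(path, _c3d.PointData(
        labels=labels, positions=positions, residuals=residuals,
        frame_rate=meta.frame_rate, first_frame=meta.first_frame + 1,
        units=units))


def split_gapped(traj: Trajectory, min_len: int = 1) -> list[Trajectory]:
    """Split a trajectory into maximal contiguous gap-free segments.

    Segments shorter than ``min_len`` frames are discarded; an all-gap
    input yields an empty list.
    """
    if min_len < 1:
        raise ConfigError("min_len must be >= 1")
    valid = ~traj.gap_mask
    out: list[Trajectory] = []
    if not valid.any():
        return out
    # run boundaries of the validity mask
    edges = np.flatnonzero(np.diff(valid.astype(np.int8)))
    starts = np.concatenate(([0], edges + 1))
    ends = np.concatenate((edges + 1, [traj.n_frames]))
    seg_idx = 0
    for lo, hi in zip(starts, ends):
        if not valid[lo]:
            continue
        if hi - lo < min_len:
            continue
        out.append(Trajectory(
            label=f"{traj.label}/{seg_idx}" if traj.gap_mask.any() else traj.label,
            start_frame=traj.start_frame + int(lo),
            positions=traj.positions[lo:hi].copy(),
            gap_mask=np.zeros(hi - lo, dtype=bool)))
        seg_idx += 1
    return out


def interpolate_gaps(traj: Trajectory, frame_rate: float,
                     max_gap_s: float = 0.1) -> Trajectory:
    """Linearly interpolate interior gaps no longer than ``max_gap_s``."""
    if traj.is_gap_free():
        return traj
    valid = ~traj.gap_mask
    idx = np.flatnonzero(valid)
    max_gap = int((np.diff(idx) - 1).max()) if idx.size > 1 else 0
    if max_gap > max_gap_s * frame_rate:
        raise ValueError(
            f"trajectory {traj.label!r} has a gap of {max_gap} frames, "
            f"longer than {max_gap_s} s")
    t = np.arange(traj.n_frames, dtype=float)
    pos = traj.positions.copy()
    for k in range(3):
        pos[:, k] = np.interp(t, t[valid], traj.positions[valid, k])
    return replace(traj, positions=pos,
                   gap_mask=np.zeros(traj.n_frames, dtype=bool))
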