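"""Instantaneous treadmill belt velocity from redundant unlabeled markers.

The estimator chains six stages over the unlabeled marker trajectories of a
capture session:

1. spatial gating — keep only samples inside two user-defined volumes that
   enclose the lateral belt edges;
2. persistence filtering — drop segments visible for fewer than a minimum
   number of consecutive frames (reconstruction flicker);
3. three-frame differentiation — per-marker speed along the belt direction
   from the average displacement over a centered three-frame window;
4. upper-limit outlier rejection — discard samples faster than a fraction
   above the target speed (ghost reflections, mis-reconstructions);
5. per-frame averaging over all surviving markers;
6. zero-phase Butterworth low-pass filtering of the averaged series.

Redundancy over ~10 circulating belt markers makes the estimate robust to
occlusion of any individual marker.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal

from .exceptions import (ConfigError, DegenerateGeometryError,
                         EmptyResultError, GapTooLongError,
                         SeriesTooShortError)
from .io_c3d import AxisConvention, CaptureSession, Trajectory, split_gapped


@dataclass(frozen=True)
class GatingVolume:
    """Axis-aligned box in lab coordinates (meters) enclosing one belt edge."""

    lower: tuple[float, float, float]
    upper: tuple[float, float, float]
    side: str = "left"

    def __post_init__(self):
        lo, hi = np.asarray(self.lower, float), np.asarray(self.upper, float)
        if lo.shape != (3,) or hi.shape != (3,):
            raise ConfigError("gating volume bounds must be 3-vectors")
        if not np.all(lo < hi):
            raise ConfigError(f"gating volume ({self.side}) must have "
                              "min < max on every axis")
        if self.side not in ("left", "right"):
            raise ConfigError("gating volume side must be 'left' or 'right'")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask over points of shape (n, 3)."""
        pts = np.atleast_2d(points)
        lo = np.asarray(self.lower)
        hi = np.asarray(self.upper)
        return np.all((pts >= lo) & (pts <= hi), axis=1)


@dataclass(frozen=True)
class BeltConfig:
    """Parameters of the belt-velocity estimator.

    ``target_speed`` is the speed set on the treadmill control panel (m/s);
    it anchors the outlier limit and all percentage metrics downstream.
    """

    target_speed: float
    volumes: tuple[GatingVolume, GatingVolume]
    min_persistence: int = 20  # frames
    upper_limit_fraction: float = 0.30
    lower_limit_fraction: float | None = None  # off by default
    cutoff_hz: float = 20.0
    filter_order: int = 4
    belt_direction: tuple[float, float, float] | None = None  # None: from axes
    zero_phase: bool = True
    cutoff_correction: bool = False
    max_missing_s: float = 0.1

    def __post_init__(self):
        if self.target_speed <= 0:
            raise ConfigError("target_speed must be positive")
        if self.min_persistence < 3:
            raise ConfigError("min_persistence must be >= 3 frames")
        if self.upper_limit_fraction <= 0:
            raise ConfigError("upper_limit_fraction must be positive")
        if self.cutoff_hz <= 0:
            raise ConfigError("cutoff_hz must be positive")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        if len(self.volumes) != 2:
            raise ConfigError("exactly two gating volumes are required")

    def direction(self, axis: AxisConvention) -> np.ndarray:
        if self.belt_direction is not None:
            d = np.asarray(self.belt_direction, float)
            n = np.linalg.norm(d)
            if n == 0:
                raise ConfigError("belt_direction must be non-zero")
            return d / n
        return axis.belt_direction()


@dataclass
class VelocitySamples:
    """Per-frame speed samples contributed by one belt-marker segment."""

    marker: str
    frames: np.ndarray  # int
    speeds: np.ndarray  # m/s

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.speeds = np.asarray(self.speeds, dtype=np.float64)
        if self.frames.shape != self.speeds.shape:
            raise ValueError("frames and speeds must have equal length")
        if not np.isfinite(self.speeds).all():
            raise ValueError("speed samples must be finite")

    def __len__(self) -> int:
        return self.frames.size


@dataclass
class BeltVelocitySeries:
    """Per-frame belt speed: raw marker average and low-pass-filtered."""

    first_frame: int
    frame_rate: float
    raw: np.ndarray  # NaN where no marker contributed
    filtered: np.ndarray
    n_markers: np.ndarray  # int, per-frame contributing-marker count
    interpolated_mask: np.ndarray  # True where raw was filled before filtering
    edge_margin_frames: int
    config: BeltConfig | None  # None when rebuilt from an exported CSV
    stage_log: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return self.filtered.size

    @property
    def frames(self) -> np.ndarray:
        return np.arange(self.first_frame, self.first_frame + self.n_frames)

    def times(self) -> np.ndarray:
        return (self.frames - self.first_frame) / self.frame_rate

    def interior(self) -> slice:
        """Frame slice unaffected by filter edge transients."""
        m = self.edge_margin_frames
        return slice(m, self.n_frames - m)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": self.frames,
            "time_s": self.times(),
            "raw_mps": self.raw,
            "filtered_mps": self.filtered,
            "n_markers": self.n_markers,
            "interpolated": self.interpolated_mask.astype(int),
        })


@dataclass(frozen=True)
class AlignmentReport:
    """Deviation of the treadmill long axis from the lab AP axis."""

    yaw_deg: float
    inclination_deg: float
    tol_deg: float
    passed: bool

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        return (f"alignment {status}: yaw {self.yaw_deg:.3f} deg, "
                f"inclination {self.inclination_deg:.3f} deg "
                f"(tolerance {self.tol_deg:.3f} deg)")


def check_alignment(front, back, tol_deg: float = 1.0,
                    axis: AxisConvention | None = None) -> AlignmentReport:
    """Check that the front/back treadmill markers lie along the AP axis.

    Yaw is the angle of the front-back line, projected to the horizontal
    plane, against the anteroposterior axis; inclination is its angle out
    of the horizontal plane.  Both are reported in [0, 90] degrees.
    """
    axis = axis or AxisConvention()
    v = np.asarray(front, float) - np.asarray(back, float)
    norm = np.linalg.norm(v)
    if norm < 1e-12:
        raise DegenerateGeometryError("front and back alignment markers "
                                      "coincide")
    ap = abs(v[axis.ap_index])
    ml = abs(v[axis.ml_index])
    up = abs(v[axis.up_index])
    yaw = math.degrees(math.atan2(ml, ap))
    horiz = math.hypot(ap, ml)
    incl = math.degrees(math.atan2(up, horiz))
    return AlignmentReport(yaw_deg=yaw, inclination_deg=incl, tol_deg=tol_deg,
                           passed=(yaw <= tol_deg and incl <= tol_deg))


def gate_by_volume(trajs, volumes) -> list[Trajectory]:
    """Keep only samples inside either gating volume; split at exits.

    Leaving a volume (or a reconstruction gap) splits the trajectory into
    contiguous in-volume segments; trajectories never inside either volume
    are dropped.
    """
    out: list[Trajectory] = []
    for traj in trajs:
        inside = np.zeros(traj.n_frames, dtype=bool)
        for vol in volumes:
            inside |= vol.contains(traj.positions)
        inside &= ~traj.gap_mask
        if not inside.any():
            continue
        gated = replace(traj, gap_mask=~inside)
        out.extend(split_gapped(gated, min_len=1))
    return out


def filter_persistence(segments, min_persistence: int = 20) -> list[Trajectory]:
    """Drop segments visible for fewer than ``min_persistence`` consecutive
    frames (inclusive threshold: exactly ``min_persistence`` is kept)."""
    return [s for s in segments if s.n_frames >= min_persistence]


def marker_velocity(segment: Trajectory, frame_rate: float,
                    belt_direction) -> VelocitySamples:
    """Speed of one belt marker along the belt direction.

    Uses the average displacement over the centered three-frame window
    {i-1, i, i+1}: v(i) = (p(i+1) - p(i-1)) . d * rate / 2.  The first and
    last frame of the segment yield no sample.
    """
    if not segment.is_gap_free():
        raise ValueError("marker_velocity requires a gap-free segment")
    if segment.n_frames < 3:
        raise SeriesTooShortError(
            f"segment {segment.label!r} has {segment.n_frames} frames; "
            "at least 3 contiguous frames are required")
    d = np.asarray(belt_direction, float)
    proj = segment.positions @ d
    speeds = (proj[2:] - proj[:-2]) * (frame_rate / 2.0)
    frames = segment.frames[1:-1]
    return VelocitySamples(marker=segment.label, frames=frames, speeds=speeds)


def reject_outliers(samples: VelocitySamples, v_target: float,
                    upper_limit_fraction: float = 0.30,
                    lower_limit_fraction: float | None = None
                    ) -> VelocitySamples:
    """Remove samples exceeding the speed limits, per sample.

    The upper limit is ``(1 + upper_limit_fraction) * v_target``; samples
    strictly above it are removed, a sample exactly at the limit is kept.
    The optional lower limit ``(1 - lower_limit_fraction) * v_target`` is
    off by default.
    """
    if v_target <= 0:
        raise ConfigError("v_target must be positive")
    keep = samples.speeds <= (1.0 + upper_limit_fraction) * v_target
    if lower_limit_fraction is not None:
        keep &= samples.speeds >= (1.0 - lower_limit_fraction) * v_target
    return VelocitySamples(marker=samples.marker,
                           frames=samples.frames[keep],
                           speeds=samples.speeds[keep])


def aggregate_frames(samples_list, first_frame: int, n_frames: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame mean over all markers' samples and contributing counts.

    Frames with no surviving sample hold NaN in the raw series.
    """
    sums = np.zeros(n_frames)
    counts = np.zeros(n_frames, dtype=np.int64)
    for s in samples_list:
        idx = s.frames - first_frame
        ok = (idx >= 0) & (idx < n_frames)
        np.add.at(sums, idx[ok], s.speeds[ok])
        np.add.at(counts, idx[ok], 1)
    raw = np.full(n_frames, np.nan)
    has = counts > 0
    raw[has] = sums[has] / counts[has]
    return raw, counts


def _design_sos(frame_rate: float, cutoff_hz: float, filter_order: int,
                zero_phase: bool, cutoff_correction: bool):
    nyq = frame_rate / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ConfigError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist="
                          f"{nyq} Hz)")
    if zero_phase:
        if filter_order % 2:
            raise ConfigError("zero-phase filtering needs an even order "
                              "(two passes of order/2)")
        per_pass = filter_order // 2
    else:
        per_pass = filter_order
    fc = cutoff_hz
    if cutoff_correction and zero_phase:
        # classic dual-pass correction so the cascade's -3 dB point lands
        # at the requested cutoff
        fc = cutoff_hz / (2 ** (1 / 2) - 1) ** (1 / (2 * per_pass))
        if fc >= nyq:
            raise ConfigError("corrected cutoff exceeds Nyquist; lower the "
                              "cutoff or disable the correction")
    return signal.butter(per_pass, fc / nyq, output="sos")


def lowpass_series(raw: np.ndarray, frame_rate: float,
                   cutoff_hz: float = 20.0, filter_order: int = 4, *,
                   zero_phase: bool = True, cutoff_correction: bool = False,
                   max_missing_s: float = 0.1
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Low-pass the raw series, interpolating missing frames first.

    Missing (NaN) frames are filled by linear interpolation (edge frames by
    nearest-value extension) and flagged in the returned mask; a missing
    run longer than ``max_missing_s`` aborts.  The filter is a recursive
    Butterworth; with ``zero_phase`` it is applied forward-backward with
    each pass of half the configured order so the cascade meets it.
    """
    raw = np.asarray(raw, dtype=np.float64)
    sos = _design_sos(frame_rate, cutoff_hz, filter_order, zero_phase,
                      cutoff_correction)
    missing = ~np.isfinite(raw)
    if missing.all():
        raise GapTooLongError("series has no valid frames")
    if missing.any():
        run_edges = np.flatnonzero(np.diff(missing.astype(np.int8)))
        starts = np.concatenate(([0], run_edges + 1))
        ends = np.concatenate((run_edges + 1, [raw.size]))
        longest = max((hi - lo for lo, hi in zip(starts, ends)
                       if missing[lo]), default=0)
        if longest > max_missing_s * frame_rate:
            raise GapTooLongError(
                f"{longest} consecutive frames without belt markers "
                f"(limit {max_missing_s} s = "
                f"{max_missing_s * frame_rate:.0f} frames)")
        t = np.arange(raw.size, dtype=float)
        filled = np.interp(t, t[~missing], raw[~missing])
    else:
        filled = raw
    settle = 3 * (2 * sos.shape[0] + 1)
    if filled.size <= 3 * settle:
        raise SeriesTooShortError(
            f"series of {filled.size} frames is too short to filter "
            f"(needs > {3 * settle})")
    if zero_phase:
        filtered = signal.sosfiltfilt(sos, filled)
    else:
        filtered = signal.sosfilt(sos, filled)
    return filtered, missing


def compute_belt_velocity(session: CaptureSession,
                          config: BeltConfig) -> BeltVelocitySeries:
    """Run the full belt-velocity pipeline on a capture session."""
    meta = session.meta
    direction = config.direction(meta.axis)
    log: dict = {"n_unlabeled": len(session.unlabeled)}

    if not session.unlabeled:
        raise EmptyResultError("input", "capture contains no unlabeled "
                               "trajectories")

    gated = gate_by_volume(session.unlabeled, config.volumes)
    log["n_segments_after_gating"] = len(gated)
    if not gated:
        raise EmptyResultError("gating")

    persistent = filter_persistence(gated, config.min_persistence)
    log["n_segments_after_persistence"] = len(persistent)
    if not persistent:
        raise EmptyResultError("persistence")

    samples = [marker_velocity(seg, meta.frame_rate, direction)
               for seg in persistent]
    log["n_samples"] = int(sum(len(s) for s in samples))

    kept = [reject_outliers(s, config.target_speed,
                            config.upper_limit_fraction,
                            config.lower_limit_fraction) for s in samples]
    kept = [s for s in kept if len(s)]
    log["n_samples_after_upper_limit"] = int(sum(len(s) for s in kept))
    if not kept:
        raise EmptyResultError("outlier_rejection")

    raw, counts = aggregate_frames(kept, meta.first_frame, meta.n_frames)
    log["n_frames_with_markers"] = int((counts > 0).sum())

    if np.nanmean(raw) < 0:
        warnings.warn(
            "mean raw belt speed is negative; check the belt_direction / "
            "axis convention configuration", stacklevel=2)

    filtered, interp_mask = lowpass_series(
        raw, meta.frame_rate, config.cutoff_hz, config.filter_order,
        zero_phase=config.zero_phase,
        cutoff_correction=config.cutoff_correction,
        max_missing_s=config.max_missing_s)

    edge_margin = math.ceil(1.5 * meta.frame_rate / config.cutoff_hz)
    return BeltVelocitySeries(
        first_frame=meta.first_frame, frame_rate=meta.frame_rate, raw=raw,
        filtered=filtered, n_markers=counts, interpolated_mask=interp_mask,
        edge_margin_frames=edge_margin, config=config, stage_log=log)
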