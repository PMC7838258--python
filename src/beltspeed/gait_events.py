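"""Kinematic gait-event detection for the right leg.

Two marker-only methods, applied to 6 Hz low-pass-filtered anatomical
trajectories:

* walking — touchdown at the peaks of the anteroposterior heel-minus-pelvis
  distance, toe-off at the peaks of the pelvis-minus-toe distance (the
  pelvis reference is the midpoint of the two posterior superior iliac
  spine markers);
* running — touchdown and toe-off at the peaks of knee extension (minima
  of the knee flexion angle), disambiguated by the rule that the swing
  flexion maximum between cycles is larger than the stance knee-yield
  maximum within a cycle.

Both return paired touchdown/toe-off frames that segment the trial into
gait cycles (right touchdown to next ipsilateral touchdown).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as sps

from .belt_velocity import lowpass_series
from .exceptions import (ConfigError, EventClassificationError,
                         EventPairingError, InsufficientDataError)
from .io_c3d import CaptureMeta, CaptureSession, Trajectory, interpolate_gaps

ROLES = ("psis_left", "psis_right", "trochanter", "condyle", "malleolus",
         "heel", "toe")

#: physiologic bounds on a single stance duration, seconds
STANCE_BOUNDS_S = (0.05, 1.5)


@dataclass
class AnatomicalSet:
    """The seven pelvis/right-leg marker trajectories, gap-free and
    cropped to their common frame range."""

    markers: dict[str, Trajectory]
    frame_rate: float

    def __post_init__(self):
        missing = [r for r in ROLES if r not in self.markers]
        if missing:
            raise ConfigError(
                f"anatomical marker role(s) missing: {', '.join(missing)}")
        trajs = {r: interpolate_gaps(self.markers[r], self.frame_rate)
                 for r in ROLES}
        lo = max(t.start_frame for t in trajs.values())
        hi = min(t.end_frame for t in trajs.values())
        if hi - lo < 3:
            raise InsufficientDataError(
                "anatomical markers share fewer than 3 common frames")
        self.markers = {
            r: replace(t, start_frame=lo,
                       positions=t.positions[lo - t.start_frame:
                                             hi - t.start_frame],
                       gap_mask=np.zeros(hi - lo, dtype=bool))
            for r, t in trajs.items()}

    @property
    def start_frame(self) -> int:
        return self.markers["heel"].start_frame

    @property
    def n_frames(self) -> int:
        return self.markers["heel"].n_frames

    def positions(self, role: str) -> np.ndarray:
        return self.markers[role].positions

    @classmethod
    def from_session(cls, session: CaptureSession,
                     mapping: dict[str, str]) -> "AnatomicalSet":
        """Build from labeled trajectories via a role -> file-label map."""
        markers = {}
        for role in ROLES:
            if role not in mapping:
                raise ConfigError(f"marker mapping lacks role {role!r}")
            label = mapping[role]
            if label not in session.labeled:
                raise ConfigError(
                    f"capture has no labeled marker {label!r} "
                    f"(required for role {role!r})")
            markers[role] = session.labeled[label]
        return cls(markers=markers, frame_rate=session.meta.frame_rate)


@dataclass
class GaitEventSet:
    """Ordered right-leg touchdown/toe-off frames with detection params."""

    gait_type: str  # "walk" or "run"
    frame_rate: float
    touchdowns: np.ndarray
    toeoffs: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.touchdowns = np.asarray(self.touchdowns, dtype=np.int64)
        self.toeoffs = np.asarray(self.toeoffs, dtype=np.int64)
        for name, arr in (("touchdowns", self.touchdowns),
                          ("toeoffs", self.toeoffs)):
            if arr.size > 1 and not (np.diff(arr) > 0).all():
                raise EventPairingError(f"{name} are not strictly increasing")
        lo, hi = STANCE_BOUNDS_S
        for td, to in self.pairs():
            stance_s = (to - td) / self.frame_rate
            if not lo <= stance_s <= hi:
                raise EventPairingError(
                    f"stance of {stance_s:.3f} s at frame {td} outside "
                    f"physiologic bounds [{lo}, {hi}] s")

    def pairs(self) -> list[tuple[int, int]]:
        """(touchdown, matching toe-off) for every stance with a toe-off
        before the next touchdown."""
        out = []
        for i, td in enumerate(self.touchdowns):
            nxt = (self.touchdowns[i + 1] if i + 1 < self.touchdowns.size
                   else np.iinfo(np.int64).max)
            cand = self.toeoffs[(self.toeoffs > td) & (self.toeoffs < nxt)]
            if cand.size == 1:
                out.append((int(td), int(cand[0])))
        return out

    @property
    def n_cycles(self) -> int:
        if self.touchdowns.size < 2:
            return 0
        return len(segment_cycles(self))

    def mean_stance_fraction(self) -> float:
        cycles = segment_cycles(self)
        if not cycles:
            return float("nan")
        return float(np.mean([(to - td) / (nxt - td)
                              for td, to, nxt in cycles]))


def lowpass_markers(aset: AnatomicalSet, frame_rate: float,
                    cutoff_hz: float = 6.0, order: int = 4) -> AnatomicalSet:
    """Zero-phase Butterworth low-pass of every anatomical trajectory."""
    markers = {}
    for role, traj in aset.markers.items():
        pos = np.empty_like(traj.positions)
        for k in range(3):
            pos[:, k], _ = lowpass_series(traj.positions[:, k], frame_rate,
                                          cutoff_hz, order)
        markers[role] = replace(traj, positions=pos)
    return AnatomicalSet(markers=markers, frame_rate=frame_rate)


def dominant_period(x: np.ndarray, frame_rate: float,
                    min_period_s: float = 0.3) -> float:
    """Dominant period (in frames) via the autocorrelation's first
    substantial peak."""
    a = np.asarray(x, float)
    a = a - a.mean()
    ac = np.correlate(a, a, mode="full")[a.size - 1:]
    if ac[0] <= 0:
        raise InsufficientDataError("signal has no variance; cannot "
                                    "determine stride period")
    min_lag = max(int(min_period_s * frame_rate), 2)
    peaks, _ = sps.find_peaks(ac)
    peaks = peaks[(peaks >= min_lag) & (ac[peaks] >= 0.5 * ac[0])]
    if peaks.size == 0:
        raise InsufficientDataError("no periodicity found in signal; "
                                    "cannot determine stride period")
    return float(peaks[0])


def _signed_forward(aset: AnatomicalSet, meta: CaptureMeta) -> np.ndarray:
    """Unit vector the subject faces: opposite the belt travel."""
    return -meta.axis.belt_direction()


def detect_events_walking(aset: AnatomicalSet, meta: CaptureMeta, *,
                          min_separation_frac: float = 0.4,
                          prominence_frac: float = 0.1) -> GaitEventSet:
    """Touchdown/toe-off from pelvis-heel and pelvis-toe distance peaks.

    Touchdowns are local maxima of the forward (heel - pelvis) distance,
    toe-offs local maxima of the forward (pelvis - toe) distance.  Peaks
    are picked with a minimum separation of ``min_separation_frac`` times
    the dominant stride period and a minimum prominence relative to the
    signal's peak-to-peak range.
    """
    fwd = _signed_forward(aset, meta)
    pelvis = 0.5 * (aset.positions("psis_left") + aset.positions("psis_right"))
    s_td = (aset.positions("heel") - pelvis) @ fwd
    s_to = (pelvis - aset.positions("toe")) @ fwd

    period = dominant_period(s_td, aset.frame_rate)
    distance = max(int(min_separation_frac * period), 1)
    tds, _ = sps.find_peaks(s_td, distance=distance,
                            prominence=prominence_frac * np.ptp(s_td))
    tos, _ = sps.find_peaks(s_to, distance=distance,
                            prominence=prominence_frac * np.ptp(s_to))
    if tds.size < 3:
        raise InsufficientDataError(
            f"only {max(tds.size - 1, 0)} walking cycles detected; "
            "at least 2 are required")
    for i in range(tds.size - 1):
        n_between = int(((tos > tds[i]) & (tos < tds[i + 1])).sum())
        if n_between != 1:
            raise EventPairingError(
                f"{n_between} toe-off candidates between touchdowns at "
                f"frames {tds[i]} and {tds[i + 1]} (expected 1)")

    events = GaitEventSet(
        gait_type="walk", frame_rate=aset.frame_rate,
        touchdowns=tds + aset.start_frame, toeoffs=tos + aset.start_frame,
        params={"method": "pelvis-heel/toe distance peaks",
                "min_separation_frac": min_separation_frac,
                "prominence_frac": prominence_frac,
                "stride_period_frames": period})
    frac = events.mean_stance_fraction()
    if not frac > 0.5:
        raise EventPairingError(
            f"detected stance fraction {frac:.2f} is not > 0.5; walking "
            "requires double support — check facing direction or gait mode")
    return events


def knee_flexion_angle(aset: AnatomicalSet) -> np.ndarray:
    """Knee flexion angle (degrees) at the lateral femoral condyle.

    Flexion = 180 deg minus the included angle between the condyle->greater
    trochanter and condyle->lateral malleolus vectors; 0 deg is a fully
    extended (straight) leg.  Degenerate frames give 0 with a warning.
    """
    u = aset.positions("trochanter") - aset.positions("condyle")
    w = aset.positions("malleolus") - aset.positions("condyle")
    nu = np.linalg.norm(u, axis=1)
    nw = np.linalg.norm(w, axis=1)
    degenerate = (nu < 1e-9) | (nw < 1e-9)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate knee-angle "
                      "frame(s); reporting 0 deg flexion there",
                      stacklevel=2)
    cosang = np.einsum("ij,ij->i", u, w) / np.where(degenerate, 1.0, nu * nw)
    included = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    flexion = 180.0 - included
    flexion[degenerate] = 0.0
    return flexion


def detect_events_running(flexion: np.ndarray, meta: CaptureMeta, *,
                          start_frame: int = 0,
                          swing_prominence_frac: float = 0.5,
                          min_prominence_frac: float = 0.1) -> GaitEventSet:
    """Touchdown/toe-off from peak knee extension during running.

    Candidate events are the minima of the flexion angle (extension
    peaks).  Swing flexion maxima (the dominant peaks) delimit cycles:
    between two consecutive swing peaks, the first extension peak is the
    touchdown and the last is the toe-off, with the smaller stance
    knee-yield flexion maximum lying between them.
    """
    flexion = np.asarray(flexion, float)
    rng = np.ptp(flexion)
    if rng < 1e-9:
        raise InsufficientDataError("flexion angle is constant; no "
                                    "extension peaks to detect")
    period = dominant_period(flexion, meta.frame_rate)
    swing, _ = sps.find_peaks(flexion, distance=max(int(0.7 * period), 1),
                              prominence=swing_prominence_frac * rng)
    minima, _ = sps.find_peaks(-flexion,
                               prominence=min_prominence_frac * rng)
    if swing.size < 3:
        raise InsufficientDataError(
            f"only {max(swing.size - 1, 0)} running cycles delimited; "
            "at least 2 are required")

    tds, tos = [], []
    for lo, hi in zip(swing[:-1], swing[1:]):
        between = minima[(minima > lo) & (minima < hi)]
        if between.size < 2:
            raise EventClassificationError(
                int(lo), f"expected touchdown and toe-off extension peaks "
                f"between swing peaks at frames {lo} and {hi}, found "
                f"{between.size}")
        td, to = int(between[0]), int(between[-1])
        stance_seg = flexion[td:to + 1]
        stance_max = float(stance_seg.max())
        if not (flexion[lo] > stance_max and flexion[hi] > stance_max):
            raise EventClassificationError(
                td, "stance knee-yield flexion is not smaller than the "
                "adjacent swing flexion peaks")
        tds.append(td)
        tos.append(to)

    events = GaitEventSet(
        gait_type="run", frame_rate=meta.frame_rate,
        touchdowns=np.asarray(tds) + start_frame,
        toeoffs=np.asarray(tos) + start_frame,
        params={"method": "peak knee extension",
                "swing_prominence_frac": swing_prominence_frac,
                "min_prominence_frac": min_prominence_frac,
                "stride_period_frames": period})
    frac = events.mean_stance_fraction()
    if not frac < 0.5:
        raise EventClassificationError(
            int(events.touchdowns[0]),
            f"detected stance fraction {frac:.2f} is not < 0.5; running "
            "requires a flight phase — check gait mode or input integrity")
    return events


def segment_cycles(events: GaitEventSet) -> list[tuple[int, int, int]]:
    """Gait cycles (TD_i, TO_i, TD_i+1) from consecutive touchdowns.

    A cycle whose intervening toe-off is missing or ambiguous is dropped
    with a warning; trailing incomplete events are discarded.
    """
    tds = events.touchdowns
    if tds.size < 2:
        raise InsufficientDataError("need at least 2 touchdowns to form a "
                                    "gait cycle")
    cycles = []
    for td, nxt in zip(tds[:-1], tds[1:]):
        cand = events.toeoffs[(events.toeoffs > td) & (events.toeoffs < nxt)]
        if cand.size != 1:
            warnings.warn(
                f"cycle at frame {td} dropped: {cand.size} toe-off "
                "candidates", stacklevel=2)
            continue
        cycles.append((int(td), int(cand[0]), int(nxt)))
    return cycles
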