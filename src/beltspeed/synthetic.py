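"""Synthetic motion-capture scenes with known ground truth.

Emulates the measurement setup the belt-velocity method was designed for:
retro-reflective cut-outs spaced along both lateral belt edges so that ten
of them (five per side) are on the top surface at any time, circulating on
a belt loop whose speed fluctuates once per gait cycle, captured with
Gaussian marker noise, random occlusions and optional spurious
reflections.  A simplified pelvis/right-leg marker set is generated with
touchdown/toe-off times known by construction, so every downstream module
can be tested against exact ground truth.

The belt-speed fluctuation is a raised-cosine dip per gait cycle (depth,
center and width relative to stance), the simplest shape matching observed
treadmill belt-speed profiles, plus an optional post-dip overshoot.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .belt_velocity import BeltConfig, GatingVolume
from .exceptions import ConfigError
from .io_c3d import (AxisConvention, CaptureMeta, CaptureSession, Trajectory,
                     write_capture)

_LEG_SEGMENTS = {"thigh_len": 0.45, "shank_len": 0.43, "hip_height": 1.0}


@dataclass(frozen=True)
class BeltSceneConfig:
    """Everything needed to render one synthetic capture, with a seed.

    Defaults reflect the canonical study conditions: 17 s captures at
    250 Hz, ten visible belt markers (five per lateral side), 0.2 mm
    marker noise and a 2 % per-frame occlusion probability.
    """

    target_speed: float = 3.0  # m/s
    # belt geometry (meters)
    loop_length: float = 6.0
    top_length: float = 1.2
    marker_spacing: float = 0.24  # top_length / 5 -> five visible per side
    lateral_offset: float = 0.25
    belt_height: float = 0.0
    # per-cycle speed fluctuation
    dip_depth: float = 0.21  # m/s
    dip_center_frac_stance: float = 0.30
    # the slowdown spans the braking phase and its recovery, which in
    # treadmill belt-speed profiles reaches past mid-stance; drive-train
    # inertia precludes much narrower speed transients
    dip_width_frac_stance: float = 0.70
    overshoot_frac: float = 0.0  # amplitude relative to dip depth
    jitter_sd: float = 0.0  # m/s, broadband speed jitter
    # gait timing
    gait_type: str = "auto"  # "walk" | "run" | "auto" (>= 2.5 m/s -> run)
    cycle_duration: float | None = None  # s; None -> speed-dependent default
    duty_factor: float | None = None  # None -> 0.62 walk / 0.35 run
    first_td_s: float = 0.5
    # capture
    frame_rate: float = 250.0
    duration: float = 17.0
    noise_sd_mm: float = 0.2
    occlusion_p: float = 0.02
    n_spurious_static: int = 0
    n_spurious_fast: int = 0
    fragmentation_p: float = 0.0  # per-frame transit split probability
    seed: int = 0

    def __post_init__(self):
        if self.target_speed <= 0:
            raise ConfigError("target_speed must be positive")
        if not 0 < self.top_length < self.loop_length:
            raise ConfigError("visible top length must be positive and "
                              "shorter than the belt loop")
        if self.marker_spacing <= 0:
            raise ConfigError("marker_spacing must be positive")
        if not 0 <= self.dip_depth < self.target_speed:
            raise ConfigError("dip depth must be in [0, target_speed)")
        if self.dip_depth > 0:
            if not 0 < self.dip_center_frac_stance < 1:
                raise ConfigError("dip center must lie inside stance")
            # an early-centered dip may overlap touchdown; the braking
            # reduction is then measured from the touchdown-frame speed,
            # identically in ground truth and in the estimator
            if not 0 < self.dip_width_frac_stance <= 1.5:
                raise ConfigError("dip width must be in (0, 1.5] stance")
        if self.frame_rate <= 0 or self.duration <= 0:
            raise ConfigError("frame_rate and duration must be positive")
        d = self.resolved_duty()
        if not 0 < d < 1:
            raise ConfigError("duty factor must lie in (0, 1)")
        if self.resolved_gait() == "walk" and d <= 0.5:
            raise ConfigError("walking requires a duty factor > 0.5")
        if self.resolved_gait() == "run" and d >= 0.5:
            raise ConfigError("running requires a duty factor < 0.5")
        if not 0 <= self.occlusion_p < 1:
            raise ConfigError("occlusion_p must be in [0, 1)")

    # --- resolved gait timing -------------------------------------------
    def resolved_gait(self) -> str:
        if self.gait_type != "auto":
            return self.gait_type
        return "run" if self.target_speed >= 2.5 else "walk"

    def resolved_duty(self) -> float:
        if self.duty_factor is not None:
            return self.duty_factor
        return 0.35 if self.resolved_gait() == "run" else 0.62

    def resolved_cycle_duration(self) -> float:
        if self.cycle_duration is not None:
            return self.cycle_duration
        v = self.target_speed
        if self.resolved_gait() == "walk":
            return 1.30 - 0.13 * (v - 1.0)
        return 0.75 - 0.03 * (v - 2.5)

    # --- derived helpers -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate

    def event_times(self) -> tuple[np.ndarray, np.ndarray]:
        """Touchdown and toe-off times (s) covering the capture."""
        T = self.resolved_cycle_duration()
        duty = self.resolved_duty()
        k = np.arange(-2, int(np.ceil(self.duration / T)) + 2)
        tds = self.first_td_s + k * T
        return tds, tds + duty * T

    def default_volumes(self) -> tuple[GatingVolume, GatingVolume]:
        """Gating boxes that snugly enclose the two belt edges."""
        ap = self.top_length / 2 + 0.05
        off, h = self.lateral_offset, self.belt_height
        return (
            GatingVolume(lower=(-off - 0.05, -ap, h - 0.05),
                         upper=(-off + 0.05, ap, h + 0.05), side="left"),
            GatingVolume(lower=(off - 0.05, -ap, h - 0.05),
                         upper=(off + 0.05, ap, h + 0.05), side="right"),
        )

    def belt_config(self, **overrides) -> BeltConfig:
        base = dict(target_speed=self.target_speed,
                    volumes=self.default_volumes())
        base.update(overrides)
        return BeltConfig(**base)

    # --- the prescribed speed profile ------------------------------------
    def speed_profile(self, t: np.ndarray) -> np.ndarray:
        """Deterministic belt speed (m/s) at times ``t`` (jitter excluded)."""
        t = np.asarray(t, float)
        v = np.full(t.shape, self.target_speed)
        if self.dip_depth <= 0:
            return v
        T = self.resolved_cycle_duration()
        stance = self.resolved_duty() * T
        width = self.dip_width_frac_stance * stance
        tds, _ = self.event_times()
        for td in tds:
            center = td + self.dip_center_frac_stance * stance
            v -= _raised_cosine(t, center, width, self.dip_depth)
            if self.overshoot_frac > 0:
                v += _raised_cosine(t, center + width, width,
                                    self.overshoot_frac * self.dip_depth)
        return v


def _raised_cosine(t: np.ndarray, center: float, width: float,
                   amplitude: float) -> np.ndarray:
    out = np.zeros_like(t)
    if width <= 0 or amplitude == 0:
        return out
    m = np.abs(t - center) <= width / 2
    out[m] = amplitude * 0.5 * (1 + np.cos(2 * np.pi * (t[m] - center) / width))
    return out


@dataclass
class GroundTruth:
    """The latent quantities a synthetic scene was rendered from."""

    frame_rate: float
    speed: np.ndarray  # per-frame true belt speed, m/s
    td_times: np.ndarray  # s, touchdowns within the capture
    to_times: np.ndarray
    per_cycle: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    @property
    def td_frames(self) -> np.ndarray:
        return np.round(self.td_times * self.frame_rate).astype(int)

    @property
    def to_frames(self) -> np.ndarray:
        return np.round(self.to_times * self.frame_rate).astype(int)

    def cycles_frames(self) -> list[tuple[int, int, int]]:
        tds, tos = self.td_frames, self.to_frames
        return [(int(tds[i]), int(tos[i]), int(tds[i + 1]))
                for i in range(len(tds) - 1)]

    def summary_means(self) -> dict[str, float]:
        keys = ("avg_tbv_stance_pct", "avg_tbv_cycle_pct",
                "braking_reduction_pct", "min_timing_pct_stance")
        return {k: float(np.mean([c[k] for c in self.per_cycle]))
                for k in keys}

    def to_json(self, path) -> None:
        obj = {"frame_rate": self.frame_rate,
               "speed": self.speed.tolist(),
               "td_times": self.td_times.tolist(),
               "to_times": self.to_times.tolist(),
               "per_cycle": self.per_cycle,
               "config": self.config}
        with open(path, "w") as fh:
            json.dump(obj, fh)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(frame_rate=obj["frame_rate"],
                   speed=np.asarray(obj["speed"]),
                   td_times=np.asarray(obj["td_times"]),
                   to_times=np.asarray(obj["to_times"]),
                   per_cycle=obj["per_cycle"], config=obj["config"])


def _ground_truth(config: BeltSceneConfig, speed: np.ndarray) -> GroundTruth:
    tds_all, tos_all = config.event_times()
    dur = config.duration
    inside = (tds_all >= 0) & (tds_all < dur)
    tds = tds_all[inside]
    tos = tos_all[inside]
    # drop a trailing stance that runs past the capture
    keep = tos < dur
    tds, tos = tds[keep], tos[keep]

    per_cycle = []
    rate = config.frame_rate
    for i in range(len(tds) - 1):
        td_f = int(round(tds[i] * rate))
        to_f = int(round(tos[i] * rate))
        nxt_f = int(round(tds[i + 1] * rate))
        if nxt_f > speed.size:
            break
        stance = speed[td_f:to_f]
        i_min = int(np.argmin(stance))
        per_cycle.append({
            "td_s": float(tds[i]), "to_s": float(tos[i]),
            "next_td_s": float(tds[i + 1]),
            "avg_tbv_stance_pct": float(stance.mean())
            / config.target_speed * 100.0,
            "avg_tbv_cycle_pct": float(speed[td_f:nxt_f].mean())
            / config.target_speed * 100.0,
            "braking_reduction_pct":
                max(float(speed[td_f] - stance.min()), 0.0)
                / config.target_speed * 100.0,
            "min_timing_pct_stance": i_min / (to_f - td_f) * 100.0,
        })
    return GroundTruth(frame_rate=rate, speed=speed,
                       td_times=tds, to_times=tos, per_cycle=per_cycle,
                       config=asdict(config))


def _emit_transits(visible: np.ndarray, positions: np.ndarray,
                   rng: np.random.Generator, config: BeltSceneConfig,
                   counter: list[int]) -> list[Trajectory]:
    """One unlabeled trajectory per contiguous visibility run."""
    out = []
    padded = np.concatenate(([False], visible, [False])).astype(np.int8)
    edges = np.flatnonzero(np.diff(padded))
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo < 2:
            continue
        pos = positions[lo:hi] + rng.normal(
            0.0, config.noise_sd_mm * 1e-3, (hi - lo, 3))
        gaps = rng.random(hi - lo) < config.occlusion_p
        if gaps.all():
            continue
        # vendor-style fragmentation: split a transit into several slots
        cuts = [0]
        if config.fragmentation_p > 0:
            cut_mask = rng.random(hi - lo) < config.fragmentation_p
            cuts += list(np.flatnonzero(cut_mask))
        cuts.append(hi - lo)
        for a, b in zip(cuts[:-1], cuts[1:]):
            if b - a < 2 or gaps[a:b].all():
                continue
            counter[0] += 1
            out.append(Trajectory(label=f"*{counter[0]}",
                                  start_frame=int(lo) + a,
                                  positions=pos[a:b],
                                  gap_mask=gaps[a:b]))
    return out


def simulate_belt(config: BeltSceneConfig
                  ) -> tuple[CaptureSession, GroundTruth]:
    """Render the circulating belt markers and the true speed profile.

    The belt position is the trapezoid-rule integral of the prescribed
    speed; each marker's loop coordinate advances with it modulo the loop
    length and the marker is emitted (as one unlabeled trajectory per
    top-surface transit) only while on the visible top surface.
    """
    rng = np.random.default_rng(config.seed)
    t = config.times()
    speed = config.speed_profile(t)
    if config.jitter_sd > 0:
        from scipy import signal as sps
        sos = sps.butter(2, 10.0 / (config.frame_rate / 2), output="sos")
        jitter = sps.sosfiltfilt(
            sos, rng.normal(0.0, config.jitter_sd, t.size))
        speed = speed + jitter
    # trapezoid-rule belt travel
    s = np.concatenate(([0.0],
                        np.cumsum(0.5 * (speed[1:] + speed[:-1])
                                  / config.frame_rate)))

    n_per_side = int(round(config.loop_length / config.marker_spacing))
    counter = [0]
    unlabeled: list[Trajectory] = []
    for side, (ml, phase) in enumerate(
            ((-config.lateral_offset, 0.0),
             (config.lateral_offset, config.marker_spacing / 2))):
        for j in range(n_per_side):
            x = (j * config.marker_spacing + phase + s) % config.loop_length
            visible = x < config.top_length
            pos = np.empty((t.size, 3))
            pos[:, 0] = ml
            pos[:, 1] = config.top_length / 2 - x  # belt travel: -AP
            pos[:, 2] = config.belt_height
            unlabeled.extend(_emit_transits(visible, pos, rng, config, counter))

    # spurious reflections: static blobs above the belt plane
    for k in range(config.n_spurious_static):
        base = np.array([rng.uniform(-0.4, 0.4), rng.uniform(-0.5, 0.5),
                         config.belt_height + 0.5 + 0.1 * k])
        pos = base + rng.normal(0.0, config.noise_sd_mm * 1e-3, (t.size, 3))
        counter[0] += 1
        unlabeled.append(Trajectory(label=f"*{counter[0]}", start_frame=0,
                                    positions=pos,
                                    gap_mask=np.zeros(t.size, bool)))
    # spurious fast markers: inside the volume but at twice the belt speed
    for k in range(config.n_spurious_fast):
        x = (k * config.loop_length / max(config.n_spurious_fast, 1)
             + 2.0 * s) % config.loop_length
        visible = x < config.top_length
        pos = np.empty((t.size, 3))
        pos[:, 0] = config.lateral_offset * (1 if k % 2 else -1)
        pos[:, 1] = config.top_length / 2 - x
        pos[:, 2] = config.belt_height
        unlabeled.extend(_emit_transits(visible, pos, rng, config, counter))

    meta = CaptureMeta(frame_rate=config.frame_rate, first_frame=0,
                       n_frames=t.size, axis=AxisConvention())
    session = CaptureSession(meta=meta, labeled={}, unlabeled=unlabeled)
    return session, _ground_truth(config, speed)


# ---------------------------------------------------------------------------
# simplified lower-limb kinematics


def _flexion_series(t: np.ndarray, config: BeltSceneConfig) -> np.ndarray:
    """Knee flexion (deg): extension peaks exactly at touchdown/toe-off,
    a stance knee-yield bump in between and a larger swing bump."""
    gait = config.resolved_gait()
    a_st, a_sw = (15.0, 55.0) if gait == "walk" else (25.0, 75.0)
    T = config.resolved_cycle_duration()
    duty = config.resolved_duty()
    tds, tos = config.event_times()
    theta = np.full(t.shape, 8.0)
    for td, to in zip(tds, tos):
        theta += _raised_cosine(t, (td + to) / 2, duty * T, a_st)
        theta += _raised_cosine(t, (to + td + T) / 2, (1 - duty) * T, a_sw)
    return theta


def simulate_gait(config: BeltSceneConfig
                  ) -> tuple[CaptureSession, GroundTruth]:
    """Render the seven pelvis/right-leg markers with known event times.

    By construction the forward heel-minus-pelvis distance peaks exactly
    at touchdowns, the pelvis-minus-toe distance peaks exactly at
    toe-offs, and the knee flexion angle has extension peaks at both
    events with a swing flexion maximum larger than the stance one.
    """
    rng = np.random.default_rng(config.seed + 1)
    t = config.times()
    T = config.resolved_cycle_duration()
    duty = config.resolved_duty()
    t0 = config.first_td_s
    omega = 2 * np.pi / T

    pelvis_ap = 0.01 * np.sin(2 * omega * (t - t0))
    heel_ap = pelvis_ap + 0.35 * np.cos(omega * (t - t0))
    toe_ap = pelvis_ap - 0.30 * np.cos(omega * (t - t0 - duty * T))

    hip_z = _LEG_SEGMENTS["hip_height"]
    phi = 0.40 * np.cos(omega * (t - t0))  # thigh angle, rad, forward +
    theta = np.radians(_flexion_series(t, config))
    psi = phi - theta  # shank angle
    l1, l2 = _LEG_SEGMENTS["thigh_len"], _LEG_SEGMENTS["shank_len"]

    def traj(label, ml, ap, z):
        pos = np.column_stack((np.full(t.size, ml) if np.isscalar(ml) else ml,
                               ap, np.full(t.size, z) if np.isscalar(z) else z))
        pos = pos + rng.normal(0.0, config.noise_sd_mm * 1e-3, pos.shape)
        return Trajectory(label=label, start_frame=0, positions=pos,
                          gap_mask=np.zeros(t.size, bool))

    troch_ap = pelvis_ap + 0.02
    cond_ap = troch_ap + l1 * np.sin(phi)
    cond_z = hip_z - 0.05 - l1 * np.cos(phi)
    mall_ap = cond_ap + l2 * np.sin(psi)
    mall_z = cond_z - l2 * np.cos(psi)

    labeled = {
        "psis_left": traj("psis_left", -0.06, pelvis_ap, hip_z + 0.05),
        "psis_right": traj("psis_right", 0.06, pelvis_ap, hip_z + 0.05),
        "trochanter": traj("trochanter", 0.10, troch_ap, hip_z - 0.05),
        "condyle": traj("condyle", 0.11, cond_ap, cond_z),
        "malleolus": traj("malleolus", 0.10, mall_ap, mall_z),
        "heel": traj("heel", 0.09,
                     heel_ap, 0.03 + 0.05 * (1 - np.cos(omega * (t - t0)))),
        "toe": traj("toe", 0.10, toe_ap,
                    0.02 + 0.05 * (1 - np.cos(omega * (t - t0 - duty * T)))),
    }
    meta = CaptureMeta(frame_rate=config.frame_rate, first_frame=0,
                       n_frames=t.size, axis=AxisConvention())
    session = CaptureSession(meta=meta, labeled=labeled, unlabeled=[])
    return session, _ground_truth(config, config.speed_profile(t))


def simulate_scene(config: BeltSceneConfig
                   ) -> tuple[CaptureSession, GroundTruth]:
    """Belt markers and anatomical markers merged into one session."""
    belt_session, truth = simulate_belt(config)
    gait_session, _ = simulate_gait(config)
    return CaptureSession(meta=belt_session.meta,
                          labeled=gait_session.labeled,
                          unlabeled=belt_session.unlabeled), truth


def make_scene(config: BeltSceneConfig, c3d_path,
               truth_path=None) -> tuple[CaptureSession, GroundTruth]:
    """Write a merged scene to .c3d plus a ground-truth JSON sidecar."""
    session, truth = simulate_scene(config)
    write_capture(session, c3d_path)
    if truth_path is not None:
        truth.to_json(truth_path)
    return session, truth
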