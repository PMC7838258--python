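"""End-to-end orchestration: capture -> belt velocity -> events -> metrics.

Holds the run configuration (parsed from a JSON/YAML file), executes the
stage chain with stage-wise diagnostics, and exports the CSV/JSON/PNG
artifact bundle.  The CLI in :mod:`beltspeed.cli` is a thin wrapper over
this module.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import yaml  # noqa: E402

from .belt_velocity import (BeltConfig, GatingVolume, check_alignment,
                            compute_belt_velocity)
from .exceptions import ConfigError
from .gait_events import (AnatomicalSet, detect_events_running,
                          detect_events_walking, knee_flexion_angle,
                          lowpass_markers, segment_cycles)
from .io_c3d import AxisConvention, read_capture
from .metrics import (cycle_metrics, ensemble_average, metrics_to_frame,
                      summarize_trial, time_normalize)

log = logging.getLogger("beltspeed")

#: target speeds at or above this are treated as running by default (m/s)
RUN_SPEED_THRESHOLD = 2.5

#: default labels the walking/running study protocol used for the
#: anatomical markers; override via the config file's ``marker_map``
DEFAULT_MARKER_MAP = {role: role for role in
                      ("psis_left", "psis_right", "trochanter", "condyle",
                       "malleolus", "heel", "toe")}


def load_config_file(path) -> dict:
    """Parse a JSON or YAML run-configuration file."""
    with open(path) as fh:
        obj = yaml.safe_load(fh)
    if not isinstance(obj, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return obj


def belt_config_from_dict(d: dict, target_speed: float | None = None
                          ) -> BeltConfig:
    vols = d.get("volumes")
    if vols is None:
        raise ConfigError("config must define the two gating 'volumes'")
    volumes = tuple(
        GatingVolume(lower=tuple(vols[side]["lower"]),
                     upper=tuple(vols[side]["upper"]), side=side)
        for side in ("left", "right"))
    kwargs = {k: d[k] for k in
              ("min_persistence", "upper_limit_fraction",
               "lower_limit_fraction", "cutoff_hz", "filter_order",
               "belt_direction", "zero_phase", "cutoff_correction",
               "max_missing_s") if k in d}
    ts = target_speed if target_speed is not None else d.get("target_speed")
    if ts is None:
        raise ConfigError("target_speed missing from config and CLI")
    return BeltConfig(target_speed=float(ts), volumes=volumes, **kwargs)


@dataclass
class RunConfig:
    """Validated configuration of one end-to-end pipeline run."""

    c3d_path: Path
    out_dir: Path
    belt: BeltConfig
    axis: AxisConvention = field(default_factory=AxisConvention)
    marker_map: dict = field(default_factory=lambda: dict(DEFAULT_MARKER_MAP))
    gait_mode: str = "auto"  # walk | run | auto (threshold on target speed)
    run_speed_threshold: float = RUN_SPEED_THRESHOLD
    alignment_markers: tuple[str, str] | None = None  # (front, back) labels
    alignment_tol_deg: float = 1.0
    braking_baseline: str = "touchdown"
    labels: dict = field(default_factory=dict)  # condition labels for summary

    def __post_init__(self):
        self.c3d_path = Path(self.c3d_path)
        self.out_dir = Path(self.out_dir)
        if self.gait_mode not in ("auto", "walk", "run"):
            raise ConfigError("gait_mode must be walk, run or auto")
        if not self.c3d_path.exists():
            raise ConfigError(f"input capture {self.c3d_path} does not exist")

    def resolved_gait_mode(self) -> str:
        if self.gait_mode != "auto":
            return self.gait_mode
        return ("run" if self.belt.target_speed >= self.run_speed_threshold
                else "walk")

    @classmethod
    def from_file(cls, config_path, c3d_path, out_dir,
                  target_speed: float | None = None, **overrides
                  ) -> "RunConfig":
        d = load_config_file(config_path)
        axis = AxisConvention.from_dict(d.get("axis", {}))
        belt = belt_config_from_dict(d, target_speed)
        kwargs = dict(
            c3d_path=c3d_path, out_dir=out_dir, belt=belt, axis=axis,
            marker_map=d.get("marker_map", dict(DEFAULT_MARKER_MAP)),
            gait_mode=d.get("gait_mode", "auto"),
            run_speed_threshold=d.get("run_speed_threshold",
                                      RUN_SPEED_THRESHOLD),
            alignment_tol_deg=d.get("alignment_tol_deg", 1.0),
            braking_baseline=d.get("braking_baseline", "touchdown"),
            labels=d.get("labels", {}))
        if "alignment_markers" in d:
            kwargs["alignment_markers"] = tuple(d["alignment_markers"])
        kwargs.update(overrides)
        return cls(**kwargs)


def _config_header(config: RunConfig) -> str:
    echo = {
        "target_speed": config.belt.target_speed,
        "min_persistence": config.belt.min_persistence,
        "upper_limit_fraction": config.belt.upper_limit_fraction,
        "cutoff_hz": config.belt.cutoff_hz,
        "filter_order": config.belt.filter_order,
        "gait_mode": config.resolved_gait_mode(),
        "braking_baseline": config.braking_baseline,
    }
    return "# beltspeed config: " + json.dumps(echo, sort_keys=True) + "\n"


def _write_csv(df, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_config_header(config))
        df.to_csv(fh, index=False, float_format="%.9g")


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full chain and write the artifact bundle.

    Returns a dict with the in-memory results (series, events, metrics,
    summary, profiles) and the paths written.
    """
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)

    log.info("reading %s", config.c3d_path)
    session = read_capture(config.c3d_path, axis=config.axis)
    log.info("capture: %d frames at %g Hz, %d labeled, %d unlabeled",
             session.meta.n_frames, session.meta.frame_rate,
             len(session.labeled), len(session.unlabeled))

    alignment = None
    if config.alignment_markers is not None:
        front_label, back_label = config.alignment_markers
        try:
            front = session.labeled[front_label]
            back = session.labeled[back_label]
        except KeyError as exc:
            raise ConfigError(f"alignment marker {exc} not in capture")
        alignment = check_alignment(
            front.positions[~front.gap_mask].mean(axis=0),
            back.positions[~back.gap_mask].mean(axis=0),
            config.alignment_tol_deg, axis=config.axis)
        log.info("%s", alignment)
        if not alignment.passed:
            raise ConfigError(f"treadmill alignment check failed: "
                              f"{alignment}")

    series = compute_belt_velocity(session, config.belt)
    for stage, count in series.stage_log.items():
        log.info("belt velocity %s = %d", stage, count)
    _write_csv(series.to_frame(), out / "belt_velocity.csv", config)

    aset = AnatomicalSet.from_session(session, config.marker_map)
    filtered = lowpass_markers(aset, session.meta.frame_rate)
    mode = config.resolved_gait_mode()
    if mode == "walk":
        events = detect_events_walking(filtered, session.meta)
    else:
        flexion = knee_flexion_angle(filtered)
        events = detect_events_running(flexion, session.meta,
                                       start_frame=filtered.start_frame)
    cycles = segment_cycles(events)
    log.info("gait events (%s): %d touchdowns, %d cycles", mode,
             events.touchdowns.size, len(cycles))

    import pandas as pd
    ev_df = pd.DataFrame(
        [{"cycle": i, "td_frame": td, "to_frame": to, "next_td_frame": nxt,
          "td_s": td / series.frame_rate, "to_s": to / series.frame_rate,
          "next_td_s": nxt / series.frame_rate}
         for i, (td, to, nxt) in enumerate(cycles)])
    _write_csv(ev_df, out / "gait_events.csv", config)

    v_target = config.belt.target_speed
    per_cycle = [cycle_metrics(series, cyc, v_target, cycle_index=i,
                               baseline=config.braking_baseline)
                 for i, cyc in enumerate(cycles)]
    _write_csv(metrics_to_frame(per_cycle), out / "cycle_metrics.csv", config)

    summary = summarize_trial(per_cycle, labels=config.labels)
    _write_csv(summary.to_frame(), out / "trial_summary.csv", config)

    profiles = [time_normalize(series, cyc, v_target) for cyc in cycles]
    ensemble = ensemble_average(profiles)
    _write_csv(ensemble.to_frame(), out / "ensemble_profile.csv", config)
    plot_profiles(profiles, out / "ensemble_profile.png")

    report = {
        "input": str(config.c3d_path),
        "stage_log": series.stage_log,
        "gait_mode": mode,
        "n_cycles": len(cycles),
        "alignment": (None if alignment is None else {
            "yaw_deg": alignment.yaw_deg,
            "inclination_deg": alignment.inclination_deg,
            "passed": alignment.passed}),
        "summary_means": summary.means,
        "summary_sds": summary.sds,
        "config": json.loads(_config_header(config)
                             .removeprefix("# beltspeed config: ")),
    }
    with open(out / "run_report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)

    return {"session": session, "series": series, "events": events,
            "cycles": cycles, "metrics": per_cycle, "summary": summary,
            "profiles": profiles, "ensemble": ensemble,
            "alignment": alignment, "out_dir": out}


def plot_profiles(profiles, out_path) -> Path:
    """Mean +/- SD band of normalized belt-speed profiles, with toe-off.

    Axes: % gait cycle vs. % target speed.  The plotted numbers are the
    same as :func:`beltspeed.metrics.ensemble_average` exports.
    """
    profiles = list(profiles)
    ens = ensemble_average(profiles)
    x = np.arange(101)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(x, ens.mean - ens.sd, ens.mean + ens.sd, alpha=0.3,
                    label="±1 SD")
    ax.plot(x, ens.mean, lw=1.5, label=f"mean (n={ens.n_profiles})")
    ax.axvline(ens.toe_off_pct, ls="--", color="k", lw=1, label="toe-off")
    ax.set_xlabel("gait cycle (%)")
    ax.set_ylabel("belt velocity (% target)")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return Path(out_path)
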