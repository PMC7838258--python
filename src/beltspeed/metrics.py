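"""Per-cycle treadmill belt velocity (TBV) metrics and ensemble profiles.

All amplitude metrics are expressed as a percentage of the target speed so
trials at different set speeds are directly comparable:

* average TBV over the stance phase and over the entire gait cycle;
* the reduction of TBV during the braking phase of stance (touchdown level
  minus the stance minimum, by default);
* the relative timing of the stance TBV minimum, in percent of stance
  duration.

Profiles are time-normalized to the gait cycle on the conventional
101-point (0-100 % inclusive) grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .belt_velocity import BeltVelocitySeries
from .exceptions import ConfigError

#: selectable references for the braking-phase reduction
BRAKING_BASELINES = ("touchdown", "target", "pre_td_max")


@dataclass(frozen=True)
class CycleMetrics:
    """Discrete TBV parameters of one gait cycle, in % of target speed."""

    cycle_index: int
    avg_tbv_stance_pct: float
    avg_tbv_cycle_pct: float
    braking_reduction_pct: float  # positive = slowdown; floored at 0
    min_timing_pct_stance: float  # [0, 100]
    stance_s: float
    cycle_s: float
    baseline: str = "touchdown"
    quality_warning: bool = False

    def __post_init__(self):
        if self.stance_s <= 0 or self.cycle_s <= 0:
            raise ValueError("stance and cycle durations must be positive")
        if not 0.0 <= self.min_timing_pct_stance <= 100.0:
            raise ValueError("min timing must lie in [0, 100] % of stance")
        if self.braking_reduction_pct < 0:
            raise ValueError("braking reduction is floored at 0")

    METRIC_NAMES = ("avg_tbv_stance_pct", "avg_tbv_cycle_pct",
                    "braking_reduction_pct", "min_timing_pct_stance")


@dataclass(frozen=True)
class NormalizedProfile:
    """TBV in % of target over the 101-point normalized gait cycle."""

    values: np.ndarray  # (101,)
    toe_off_pct: float

    def __post_init__(self):
        object.__setattr__(self, "values",
                           np.asarray(self.values, dtype=np.float64))
        if self.values.shape != (101,):
            raise ValueError("normalized profile must have 101 samples")
        if not 0.0 < self.toe_off_pct < 100.0:
            raise ValueError("toe-off must fall strictly inside the cycle")


@dataclass(frozen=True)
class EnsembleProfile:
    mean: np.ndarray
    sd: np.ndarray
    toe_off_pct: float
    n_profiles: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pct_cycle": np.arange(101),
                             "mean_pct_target": self.mean,
                             "sd_pct_target": self.sd})


@dataclass
class TrialSummary:
    """Per-trial mean and SD of each cycle metric, with condition labels."""

    means: dict[str, float]
    sds: dict[str, float]
    n_cycles: int
    labels: dict = field(default_factory=dict)
    single_cycle: bool = False

    def to_frame(self) -> pd.DataFrame:
        row = dict(self.labels)
        row["n_cycles"] = self.n_cycles
        for k in CycleMetrics.METRIC_NAMES:
            row[f"{k}_mean"] = self.means[k]
            row[f"{k}_sd"] = self.sds[k]
        return pd.DataFrame([row])


def _cycle_slices(series: BeltVelocitySeries, cycle) -> tuple[int, int, int]:
    td, to, nxt = (int(c) for c in cycle)
    if not td < to < nxt:
        raise ValueError(f"cycle frames must satisfy TD < TO < nextTD, got "
                         f"{cycle}")
    lo, hi = series.first_frame, series.first_frame + series.n_frames
    if td < lo or nxt > hi:
        raise IndexError(f"cycle [{td}, {nxt}] outside series range "
                         f"[{lo}, {hi})")
    return td - series.first_frame, to - series.first_frame, nxt - series.first_frame


def cycle_metrics(series: BeltVelocitySeries, cycle, v_target: float, *,
                  cycle_index: int = 0,
                  baseline: str = "touchdown") -> CycleMetrics:
    """Discrete TBV parameters for one (TD, TO, nextTD) cycle.

    Stance and cycle intervals are half-open ([TD, TO) and [TD, nextTD)).
    The braking reduction is measured from the configured ``baseline``
    ("touchdown" = TBV at touchdown, "target", or "pre_td_max" = maximum
    TBV in the 10 % of cycle preceding touchdown) down to the stance
    minimum, floored at 0.
    """
    if v_target <= 0:
        raise ConfigError("v_target must be positive")
    if baseline not in BRAKING_BASELINES:
        raise ConfigError(f"unknown braking baseline {baseline!r}; "
                          f"choose from {BRAKING_BASELINES}")
    i_td, i_to, i_nxt = _cycle_slices(series, cycle)
    v = series.filtered

    stance = v[i_td:i_to]
    full = v[i_td:i_nxt]
    i_min = int(np.argmin(stance))
    v_min = float(stance[i_min])

    if baseline == "touchdown":
        ref = float(v[i_td])
    elif baseline == "target":
        ref = v_target
    else:  # pre_td_max
        w = max(int(round(0.1 * (i_nxt - i_td))), 1)
        ref = float(v[max(i_td - w, 0):i_td + 1].max())

    interp_frac = float(series.interpolated_mask[i_td:i_nxt].mean())
    quality = interp_frac > 0.20
    if quality:
        warnings.warn(f"cycle {cycle_index}: {interp_frac:.0%} of frames "
                      "were interpolated before filtering", stacklevel=2)

    return CycleMetrics(
        cycle_index=cycle_index,
        avg_tbv_stance_pct=float(stance.mean()) / v_target * 100.0,
        avg_tbv_cycle_pct=float(full.mean()) / v_target * 100.0,
        braking_reduction_pct=max(ref - v_min, 0.0) / v_target * 100.0,
        min_timing_pct_stance=i_min / (i_to - i_td) * 100.0,
        stance_s=(i_to - i_td) / series.frame_rate,
        cycle_s=(i_nxt - i_td) / series.frame_rate,
        baseline=baseline,
        quality_warning=quality)


def time_normalize(series: BeltVelocitySeries, cycle,
                   v_target: float) -> NormalizedProfile:
    """Resample one cycle to the 101-point normalized grid (% of target).

    Linear interpolation of the filtered series from touchdown (0 %) to
    the next ipsilateral touchdown (100 %); toe-off is marked at its
    relative position within the cycle.
    """
    if v_target <= 0:
        raise ConfigError("v_target must be positive")
    i_td, i_to, i_nxt = _cycle_slices(series, cycle)
    u = np.linspace(0.0, 1.0, 101)
    t = i_td + u * (i_nxt - i_td)
    values = np.interp(t, np.arange(series.n_frames), series.filtered)
    return NormalizedProfile(values=values / v_target * 100.0,
                             toe_off_pct=(i_to - i_td) / (i_nxt - i_td) * 100.0)


def ensemble_average(profiles, ddof: int = 1) -> EnsembleProfile:
    """Pointwise mean and SD over normalized profiles (sample SD default)."""
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    arr = np.stack([p.values for p in profiles])
    if len(profiles) > ddof:
        sd = arr.std(axis=0, ddof=ddof)
    else:
        sd = np.zeros(101)
    return EnsembleProfile(
        mean=arr.mean(axis=0), sd=sd,
        toe_off_pct=float(np.mean([p.toe_off_pct for p in profiles])),
        n_profiles=len(profiles))


def summarize_trial(metrics, labels: dict | None = None,
                    ddof: int = 1) -> TrialSummary:
    """Mean and sample SD of each metric over a trial's gait cycles.

    A single-cycle trial reports SD 0 with the ``single_cycle`` flag set;
    fewer than ten cycles triggers a warning (trials are expected to span
    at least ten cycles).
    """
    metrics = list(metrics)
    if not metrics:
        raise ValueError("cannot summarize an empty cycle list")
    if len(metrics) < 10:
        warnings.warn(f"only {len(metrics)} gait cycles in trial; at least "
                      "10 are expected for stable summaries", stacklevel=2)
    means, sds = {}, {}
    for name in CycleMetrics.METRIC_NAMES:
        vals = np.array([getattr(m, name) for m in metrics], dtype=float)
        means[name] = float(vals.mean())
        sds[name] = float(vals.std(ddof=ddof)) if vals.size > ddof else 0.0
    return TrialSummary(means=means, sds=sds, n_cycles=len(metrics),
                        labels=dict(labels or {}),
                        single_cycle=len(metrics) == 1)


def metrics_to_frame(metrics) -> pd.DataFrame:
    rows = []
    for m in metrics:
        rows.append({"cycle": m.cycle_index,
                     **{k: getattr(m, k) for k in CycleMetrics.METRIC_NAMES},
                     "stance_s": m.stance_s, "cycle_s": m.cycle_s,
                     "baseline": m.baseline,
                     "quality_warning": int(m.quality_warning)})
    return pd.DataFrame(rows)
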