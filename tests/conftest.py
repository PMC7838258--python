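import numpy as np
import pytest

from beltspeed.synthetic import BeltSceneConfig, simulate_belt, simulate_gait


def match_events(detected, truth, tol_frames, keep_range=None):
    """Assert every true event has a detected partner within tolerance;
    return the worst absolute error in frames.

    ``keep_range=(lo, hi)`` restricts the truth events considered, so
    cycles clipped by the capture boundary (where any low-pass filter has
    an edge transient) are not demanded of the detector.
    """
    detected = np.asarray(detected)
    truth = np.asarray(truth)
    if keep_range is not None:
        lo, hi = keep_range
        truth = truth[(truth >= lo) & (truth <= hi)]
    assert detected.size > 0 and truth.size > 0
    errs = []
    for t in truth:
        errs.append(np.abs(detected - t).min())
    worst = int(max(errs))
    assert worst <= tol_frames, (
        f"worst event error {worst} frames exceeds {tol_frames}")
    return worst


@pytest.fixture(scope="session")
def clean_belt_scene():
    """Noise-free constant-speed belt scene: 10 visible markers, 3 m/s."""
    cfg = BeltSceneConfig(target_speed=3.0, dip_depth=0.0, noise_sd_mm=0.0,
                          occlusion_p=0.0, duration=5.0, seed=11)
    session, truth = simulate_belt(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def dip_belt_scene():
    """Noisy belt scene with a per-cycle raised-cosine slowdown."""
    cfg = BeltSceneConfig(target_speed=3.0, dip_depth=0.18, duration=8.0,
                          seed=7)
    session, truth = simulate_belt(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def walking_scene():
    cfg = BeltSceneConfig(target_speed=1.5, duration=17.0, seed=3)
    session, truth = simulate_gait(cfg)
    return cfg, session, truth


@pytest.fixture(scope="session")
def running_scene():
    cfg = BeltSceneConfig(target_speed=3.5, duration=17.0, seed=3)
    session, truth = simulate_gait(cfg)
    return cfg, session, truth
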