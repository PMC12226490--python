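import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make `oracles` importable

from socialdist import (
    ArenaCalibration,
    SessionMeta,
    PoseTrack,
    SimConfig,
    apply_p_cutoff,
    simulate_session,
    to_mm,
)

FIXTURES = Path(__file__).parent / "fixtures"


@pytest.fixture
def calibration():
    return ArenaCalibration()


@pytest.fixture
def meta():
    return SessionMeta(session_id="test", strain="CBA", sex="F", age_months=3.0)


@pytest.fixture
def sim_track():
    """A short simulated session (px) with its ground truth."""
    cfg = SimConfig(seed=42, n_frames=2000)
    return simulate_session(cfg)


@pytest.fixture
def filtered_mm(sim_track):
    """The same session filtered at the default cutoff and calibrated to mm."""
    track, _ = sim_track
    return to_mm(apply_p_cutoff(track, 0.6))


def make_track(xy, likelihood, meta_obj=None, calibration_obj=None, units="px"):
    """Build a PoseTrack from explicit arrays (test helper)."""
    meta_obj = meta_obj or SessionMeta(
        session_id="manual", strain="BTBR", sex="M", age_months=4.0
    )
    calibration_obj = calibration_obj or ArenaCalibration()
    return PoseTrack(
        meta=meta_obj,
        calibration=calibration_obj,
        xy=np.asarray(xy, float),
        likelihood=np.asarray(likelihood, float),
        units=units,
    )


def random_small_track(rng, n_frames=40, reject_p=0.25):
    """Random mm-space filtered track for oracle-equivalence checks."""
    xy = rng.uniform(0, 300, size=(n_frames, 2, 5, 2))
    lk = rng.uniform(0, 1, size=(n_frames, 2, 5))
    # Plant some hard rejections/missing labels.
    missing = rng.random(lk.shape) < 0.05
    lk[missing] = np.nan
    xy[missing] = np.nan
    track = make_track(xy, lk, units="mm")
    return apply_p_cutoff(track, reject_p)  # uniform likelihoods: ~reject_p rejected
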