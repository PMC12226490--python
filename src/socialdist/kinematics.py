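"""Centroids, locomotion rates and epoch-wise social distance.

The centroid of an animal in a frame is the unweighted mean of its
accepted body-part labels (optionally restricted to a subset: all five
parts, tail excluded, or ears only).  Social distance is the Euclidean
distance between the two animals' centroids, summarised per 30-s epoch as
a mean and a median; the session grand mean is the mean of epoch means and
the grand median the median of epoch medians.  Locomotion is the mean
frame-to-frame centroid displacement expressed per second, with no
interpolation across invalid frames.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import BODY_PARTS, FilteredPoseTrack

logger = logging.getLogger(__name__)

#: Body-part index subsets available for centroid computation.
PART_SUBSETS: dict[str, tuple[int, ...]] = {
    "all": tuple(range(len(BODY_PARTS))),
    "no_tail": tuple(
        i for i, p in enumerate(BODY_PARTS) if p not in ("tail_base", "tail_end")
    ),
    "ears_only": tuple(i for i, p in enumerate(BODY_PARTS) if p.endswith("_ear")),
}


@dataclass
class CentroidSeries:
    """Per-frame centroid of one animal (mm); NaN rows are invalid frames."""

    xy: np.ndarray  # (n_frames, 2), NaN where invalid
    n_parts_used: np.ndarray  # (n_frames,)
    part_subset: str
    fps: float
    animal_id: str = ""

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def valid(self) -> np.ndarray:
        return np.isfinite(self.xy).all(axis=1)


@dataclass
class EpochDistanceSeries:
    """Epoch-wise social-distance summary for one session.

    Epoch statistics are computed only over frames where both centroids
    are valid; epochs with no such frame carry NaN and are excluded from
    the grand aggregation.
    """

    session_id: str
    epoch_length_s: float
    mean_mm: np.ndarray  # (n_epochs,)
    median_mm: np.ndarray  # (n_epochs,)
    n_valid_frames: np.ndarray  # (n_epochs,)
    fps: float

    @property
    def n_epochs(self) -> int:
        return len(self.mean_mm)

    @property
    def grand_mean_mm(self) -> float:
        """Mean of epoch means (the per-cage session summary)."""
        return float(np.nanmean(self.mean_mm))

    @property
    def grand_median_mm(self) -> float:
        """Median of epoch medians."""
        return float(np.nanmedian(self.median_mm))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "mean_mm": self.mean_mm,
                "median_mm": self.median_mm,
                "n_valid": self.n_valid_frames,
            }
        )


@dataclass
class LocomotionSummary:
    """Mean centroid displacement rate of one animal (mm/s)."""

    animal_id: str
    rate_mm_s: float
    n_valid_frame_pairs: int
    defined: bool = True


def compute_centroids(
    track: FilteredPoseTrack, part_subset: str = "all", min_parts: int = 1
) -> tuple[CentroidSeries, CentroidSeries]:
    """Per-frame centroids of both animals from accepted labels.

    The centroid is the unweighted mean of the accepted labels within the
    chosen subset; a frame is invalid when fewer than ``min_parts`` labels
    survive.  Requires the track to be in mm.
    """
    if track.units != "mm":
        raise ValueError("track must be calibrated to mm before computing centroids")
    if part_subset not in PART_SUBSETS:
        raise ValueError(f"part_subset must be one of {sorted(PART_SUBSETS)}")
    if min_parts < 1:
        raise ValueError("min_parts must be >= 1")
    idx = list(PART_SUBSETS[part_subset])
    sub_xy = track.xy[:, :, idx, :]  # (F, 2, k, 2)
    sub_ok = track.accepted[:, :, idx]  # (F, 2, k)
    n_used = sub_ok.sum(axis=2)  # (F, 2)
    w = sub_ok[..., None].astype(float)
    with np.errstate(invalid="ignore"):
        centroid = np.where(
            n_used[..., None] >= min_parts,
            np.nansum(sub_xy * w, axis=2) / np.maximum(n_used, 1)[..., None],
            np.nan,
        )
    out = []
    for a in range(2):
        out.append(
            CentroidSeries(
                xy=centroid[:, a, :],
                n_parts_used=n_used[:, a],
                part_subset=part_subset,
                fps=track.calibration.fps,
                animal_id=track.meta.animal_ids[a],
            )
        )
    return out[0], out[1]


def frame_distances(c1: CentroidSeries, c2: CentroidSeries) -> np.ndarray:
    """Frame-wise inter-centroid Euclidean distance; NaN where either is invalid."""
    if c1.n_frames != c2.n_frames:
        raise ValueError("centroid series must share frame indexing")
    d = c1.xy - c2.xy
    return np.hypot(d[:, 0], d[:, 1])


def social_distance_epochs(
    c1: CentroidSeries,
    c2: CentroidSeries,
    epoch_length_s: float = 30.0,
    session_id: str = "",
) -> EpochDistanceSeries:
    """Mean and median inter-centroid distance in consecutive fixed-length epochs.

    A 60-min 30-fps session yields 120 epochs of 900 frames.  A trailing
    partial epoch is dropped with a warning.
    """
    if c1.fps != c2.fps:
        raise ValueError("centroid series must share fps")
    frames_per_epoch = int(round(epoch_length_s * c1.fps))
    if frames_per_epoch < 1:
        raise ValueError("epoch_length_s too small for this frame rate")
    dist = frame_distances(c1, c2)
    n_epochs = len(dist) // frames_per_epoch
    leftover = len(dist) - n_epochs * frames_per_epoch
    if leftover:
        logger.warning(
            "dropping trailing partial epoch of %d frames (session %s)",
            leftover,
            session_id,
        )
    dist = dist[: n_epochs * frames_per_epoch].reshape(n_epochs, frames_per_epoch)
    n_valid = np.isfinite(dist).sum(axis=1)
    import warnings

    with warnings.catch_warnings():
        # all-NaN epochs legitimately yield NaN statistics
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(dist, axis=1)
        median = np.nanmedian(dist, axis=1)
    if np.any(n_valid == 0):
        logger.warning(
            "%d epoch(s) with zero mutually valid frames excluded from grand "
            "aggregation (session %s)",
            int((n_valid == 0).sum()),
            session_id,
        )
    return EpochDistanceSeries(
        session_id=session_id,
        epoch_length_s=epoch_length_s,
        mean_mm=mean,
        median_mm=median,
        n_valid_frames=n_valid,
        fps=c1.fps,
    )


def locomotion_rate(c: CentroidSeries, fps: float | None = None) -> LocomotionSummary:
    """Mean frame-to-frame centroid displacement x fps, in mm/s.

    Only consecutive pairs of valid frames contribute; pairs spanning an
    invalid frame are excluded (no interpolation), so the rate reflects
    observed motion only.
    """
    fps = c.fps if fps is None else fps
    step = np.diff(c.xy, axis=0)
    d = np.hypot(step[:, 0], step[:, 1])
    ok = np.isfinite(d)
    n_pairs = int(ok.sum())
    if n_pairs == 0:
        return LocomotionSummary(c.animal_id, float("nan"), 0, defined=False)
    return LocomotionSummary(c.animal_id, float(d[ok].mean() * fps), n_pairs)


def time_binned_distance(e: EpochDistanceSeries, bin_minutes: float = 20.0) -> pd.DataFrame:
    """Aggregate epoch statistics into consecutive time bins.

    A 60-min session at 30-s epochs binned in 20-min blocks yields 3 bins
    of 40 epochs.  Per-bin aggregation mirrors the session rule: mean of
    epoch means, median of epoch medians.  ``bin_minutes`` must divide the
    session length exactly.
    """
    epochs_per_bin = bin_minutes * 60.0 / e.epoch_length_s
    if abs(epochs_per_bin - round(epochs_per_bin)) > 1e-9:
        raise ValueError("bin_minutes must be an integer number of epochs")
    epochs_per_bin = int(round(epochs_per_bin))
    if e.n_epochs % epochs_per_bin != 0:
        raise ValueError(
            f"bin of {epochs_per_bin} epochs does not divide {e.n_epochs} epochs"
        )
    n_bins = e.n_epochs // epochs_per_bin
    mean = e.mean_mm.reshape(n_bins, epochs_per_bin)
    median = e.median_mm.reshape(n_bins, epochs_per_bin)
    with np.errstate(invalid="ignore"):
        rows = {
            "bin": np.arange(n_bins),
            "start_min": np.arange(n_bins) * bin_minutes,
            "mean_mm": np.nanmean(mean, axis=1),
            "median_mm": np.nanmedian(median, axis=1),
            "n_epochs": np.isfinite(mean).sum(axis=1),
        }
    return pd.DataFrame(rows)
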