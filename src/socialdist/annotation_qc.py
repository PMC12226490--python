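"""Annotation quality control for likelihood-filtered pose tracks.

Two complementary views of label rejection:

- per body part, the percentage of frames in which that animal's label was
  rejected (sub-cutoff or absent) — the per-session rejection table;
- the mean number of rejected labels per frame (pooled over both animals,
  0..10) as a function of inter-animal distance, in half-open 5-mm bins —
  a check that tracking quality does not covary pathologically with the
  very quantity being measured.

Frames whose inter-centroid distance is undefined cannot be binned; they
are excluded from the distance curve (and counted) but still contribute to
the per-part percentages, each view keeping its own natural denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import BODY_PARTS, FilteredPoseTrack


@dataclass
class RejectionProfile:
    """Session-level rejection summary."""

    per_part_pct: pd.DataFrame  # index: animal_id, columns: body parts, values: %
    mean_rejected_per_frame: float  # pooled over both animals
    binned: pd.DataFrame  # columns: bin_lower_mm, mean_rejected, n_frames
    n_unbinned_frames: int  # frames with undefined distance


def rejection_by_part(track: FilteredPoseTrack) -> pd.DataFrame:
    """Percentage of frames with a rejected label, per animal and body part."""
    pct = 100.0 * track.rejected.mean(axis=0)  # (2, 5)
    return pd.DataFrame(pct, index=list(track.meta.animal_ids), columns=list(BODY_PARTS))


def rejection_vs_distance(
    track: FilteredPoseTrack, distances: np.ndarray, bin_mm: float = 5.0
) -> RejectionProfile:
    """Mean rejected labels per frame in half-open distance bins [k·w, (k+1)·w).

    ``distances`` is the per-frame inter-centroid distance (mm), NaN where
    undefined.  A distance exactly on a bin edge belongs to the bin that
    starts there.
    """
    if bin_mm <= 0:
        raise ValueError("bin_mm must be > 0")
    distances = np.asarray(distances, dtype=float)
    if len(distances) != track.n_frames:
        raise ValueError("distances must align with track frames")
    counts = track.rejected_per_frame()
    ok = np.isfinite(distances)
    n_unbinned = int((~ok).sum())
    if not ok.any():
        import warnings

        warnings.warn("all frame distances are undefined; empty rejection profile")
        binned = pd.DataFrame(columns=["bin_lower_mm", "mean_rejected", "n_frames"])
    else:
        bins = np.floor(distances[ok] / bin_mm).astype(int)
        df = pd.DataFrame({"bin": bins, "count": counts[ok]})
        agg = df.groupby("bin")["count"].agg(["mean", "size"]).reset_index()
        binned = pd.DataFrame(
            {
                "bin_lower_mm": agg["bin"] * bin_mm,
                "mean_rejected": agg["mean"],
                "n_frames": agg["size"],
            }
        )
    return RejectionProfile(
        per_part_pct=rejection_by_part(track),
        mean_rejected_per_frame=float(counts.mean()),
        binned=binned,
        n_unbinned_frames=n_unbinned,
    )
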