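"""Head/Body/Tail reduction and the interaction-symmetry statistic.

Five body-part labels per animal are reduced to three regions: the head
(mean of the accepted nose and ear labels), the tail (mean of the accepted
tail base and tail end), and the body.  The body region defaults to the
all-label centroid — the same point used for social distance — since no
dedicated trunk label exists in the five-point scheme; a head/tail-base
midpoint alternative is available.

For a session, the 3x3 matrix ``S`` holds the mean distance between each
region of animal 1 (rows) and each region of animal 2 (columns), averaged
over the frames in which both regions are valid.  Its symmetry ratio,

    ``||S - S^T||_F / ||S||_F``

(Frobenius norms), is 0 for a perfectly balanced socio-spatial arrangement
and grows toward sqrt(2) with increasing directional imbalance (e.g. one
animal persistently keeping its head near the other's tail).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import BODY_PARTS, FilteredPoseTrack

REGIONS = ("head", "body", "tail")

_HEAD_IDX = tuple(i for i, p in enumerate(BODY_PARTS) if p in ("nose", "left_ear", "right_ear"))
_TAIL_IDX = tuple(i for i, p in enumerate(BODY_PARTS) if p in ("tail_base", "tail_end"))
_ALL_IDX = tuple(range(len(BODY_PARTS)))


@dataclass
class HBTMatrix:
    """Inter-animal head/body/tail mean-distance matrix with symmetry ratio."""

    session_id: str
    S: np.ndarray  # (3, 3) mm; rows = animal-1 regions, cols = animal-2 regions
    n_valid_frames: np.ndarray  # (3, 3) ints
    symmetry_ratio: float

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, ri in enumerate(REGIONS):
            for j, rj in enumerate(REGIONS):
                rows.append(
                    {
                        "session_id": self.session_id,
                        "cell": f"{ri[0].upper()}{rj[0].upper()}",
                        "mean_distance_mm": self.S[i, j],
                        "n_valid_frames": int(self.n_valid_frames[i, j]),
                    }
                )
        df = pd.DataFrame(rows)
        df["symmetry_ratio"] = self.symmetry_ratio
        return df


def _subset_mean(track: FilteredPoseTrack, idx: tuple[int, ...]) -> np.ndarray:
    """Mean of accepted labels in the subset, (F, 2, 2); NaN when none accepted."""
    xy = track.xy[:, :, list(idx), :]
    ok = track.accepted[:, :, list(idx)]
    n = ok.sum(axis=2)
    w = ok[..., None].astype(float)
    with np.errstate(invalid="ignore"):
        return np.where(
            n[..., None] >= 1, np.nansum(xy * w, axis=2) / np.maximum(n, 1)[..., None], np.nan
        )


def reduce_to_hbt(track: FilteredPoseTrack, body_mode: str = "centroid") -> np.ndarray:
    """Per-frame head/body/tail points for both animals, (F, 2, 3, 2) in mm.

    ``body_mode='centroid'`` (default) takes the body as the mean of all
    accepted labels; ``'head_tailbase_mid'`` takes the midpoint of the head
    region and the accepted tail-base label.  A region is NaN in a frame
    when none of its constituent labels is accepted.
    """
    if track.units != "mm":
        raise ValueError("track must be calibrated to mm before HBT reduction")
    head = _subset_mean(track, _HEAD_IDX)
    tail = _subset_mean(track, _TAIL_IDX)
    if body_mode == "centroid":
        body = _subset_mean(track, _ALL_IDX)
    elif body_mode == "head_tailbase_mid":
        tail_base = _subset_mean(track, (BODY_PARTS.index("tail_base"),))
        body = 0.5 * (head + tail_base)
    else:
        raise ValueError("body_mode must be 'centroid' or 'head_tailbase_mid'")
    return np.stack([head, body, tail], axis=2)


def hbt_matrix(
    regions1: np.ndarray, regions2: np.ndarray, session_id: str = ""
) -> HBTMatrix:
    """Session HBT matrix from per-frame region points of the two animals.

    ``regions1``/``regions2`` are (F, 3, 2) arrays (head, body, tail rows).
    Each cell averages over its own set of frames where both regions are
    valid; a cell with no valid frame makes the matrix (and the symmetry
    ratio) undefined, which is an error.
    """
    regions1 = np.asarray(regions1, dtype=float)
    regions2 = np.asarray(regions2, dtype=float)
    if regions1.shape != regions2.shape or regions1.ndim != 3 or regions1.shape[1:] != (3, 2):
        raise ValueError("regions must be (n_frames, 3, 2) arrays with shared indexing")
    diff = regions1[:, :, None, :] - regions2[:, None, :, :]  # (F, 3, 3, 2)
    dist = np.hypot(diff[..., 0], diff[..., 1])
    valid = np.isfinite(dist)
    n = valid.sum(axis=0)
    if np.any(n == 0):
        empty = [(REGIONS[i], REGIONS[j]) for i, j in zip(*np.nonzero(n == 0))]
        raise ValueError(f"HBT cell(s) with zero valid frames: {empty}")
    with np.errstate(invalid="ignore"):
        S = np.nansum(np.where(valid, dist, 0.0), axis=0) / n
    return HBTMatrix(
        session_id=session_id, S=S, n_valid_frames=n, symmetry_ratio=symmetry_ratio(S)
    )


def symmetry_ratio(S: np.ndarray) -> float:
    """``||S - S^T||_F / ||S||_F`` for a complete 3x3 distance matrix.

    0 for symmetric S; bounded by sqrt(2) for entrywise non-negative S.
    Undefined (error) for the zero matrix.
    """
    S = np.asarray(S, dtype=float)
    if S.shape != (3, 3):
        raise ValueError(f"S must be 3x3, got {S.shape}")
    if not np.all(np.isfinite(S)):
        raise ValueError("S must be complete (finite entries)")
    denom = float(np.linalg.norm(S))
    if denom == 0.0:
        raise ValueError("symmetry ratio undefined for the zero matrix")
    return float(np.linalg.norm(S - S.T) / denom)
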