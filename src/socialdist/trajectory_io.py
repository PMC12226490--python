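"""Reading, writing and filtering DeepLabCut multi-animal pose tracks.

The on-disk format is the DeepLabCut (DLC) multi-animal CSV dialect: four
header rows (``scorer`` / ``individuals`` / ``bodyparts`` / ``coords``), a
leading integer frame-index column, and one ``(x, y, likelihood)`` triplet
per individual per body part.  Coordinates are pixels until
:func:`to_mm` applies the arena calibration.

In memory a track is dense NumPy storage: ``xy`` with shape
``(n_frames, n_animals, n_parts, 2)`` and ``likelihood`` with shape
``(n_frames, n_animals, n_parts)``; missing labels are NaN.  Filtering by
the DLC likelihood cutoff (``p-cutoff``) never touches geometry — it only
adds a boolean acceptance mask, so the raw track remains inspectable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

#: Canonical body-part order: head labels first, then tail labels.
BODY_PARTS: tuple[str, ...] = ("nose", "left_ear", "right_ear", "tail_base", "tail_end")

STRAINS = ("BTBR", "CBA")
SEXES = ("M", "F")


class DLCFormatError(ValueError):
    """Raised when a file does not conform to the multi-animal DLC CSV dialect."""


@dataclass(frozen=True)
class ArenaCalibration:
    """Pixel-to-millimetre scale and frame rate of a recording arena.

    Parameters
    ----------
    mm_per_pixel
        Arena scale in mm per pixel (0.68 for the reference arena).
    fps
        Video frame rate in frames per second.
    image_width, image_height
        Frame dimensions in pixels.
    """

    mm_per_pixel: float = 0.68
    fps: float = 30.0
    image_width: int = 480
    image_height: int = 270

    def __post_init__(self) -> None:
        if not self.mm_per_pixel > 0:
            raise ValueError(f"mm_per_pixel must be > 0, got {self.mm_per_pixel}")
        if not self.fps > 0:
            raise ValueError(f"fps must be > 0, got {self.fps}")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ValueError("image dimensions must be positive")

    def px_to_mm(self, value_px):
        """Convert a length (or array of lengths) from pixels to millimetres."""
        return np.asarray(value_px, dtype=float) * self.mm_per_pixel


@dataclass(frozen=True)
class SessionMeta:
    """Metadata for one 2-animal recording session."""

    session_id: str
    strain: str
    sex: str
    age_months: float
    animal_ids: tuple[str, str] = ("M1", "M2")

    def __post_init__(self) -> None:
        if self.strain not in STRAINS:
            raise ValueError(f"strain must be one of {STRAINS}, got {self.strain!r}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if not self.age_months > 0:
            raise ValueError(f"age_months must be > 0, got {self.age_months}")
        if len(self.animal_ids) != 2:
            raise ValueError("exactly two animal_ids are required")
        object.__setattr__(self, "animal_ids", tuple(self.animal_ids))


@dataclass
class PoseTrack:
    """Dense per-frame, per-animal, per-body-part labels for one session.

    ``xy[f, a, p]`` is the (x, y) position of body part ``p`` of animal
    ``a`` in frame ``f``; ``likelihood[f, a, p]`` the DLC confidence.
    Missing labels are NaN in both arrays.  ``units`` is ``"px"`` or
    ``"mm"`` and guards against double calibration.
    """

    meta: SessionMeta
    calibration: ArenaCalibration
    xy: np.ndarray
    likelihood: np.ndarray
    units: str = "px"

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float)
        self.likelihood = np.asarray(self.likelihood, dtype=float)
        n_parts = len(BODY_PARTS)
        if self.xy.ndim != 4 or self.xy.shape[1:] != (2, n_parts, 2):
            raise ValueError(
                f"xy must have shape (n_frames, 2, {n_parts}, 2), got {self.xy.shape}"
            )
        if self.likelihood.shape != self.xy.shape[:3]:
            raise ValueError(
                f"likelihood shape {self.likelihood.shape} does not match xy {self.xy.shape[:3]}"
            )
        lk = self.likelihood[np.isfinite(self.likelihood)]
        if lk.size and (lk.min() < 0 or lk.max() > 1):
            raise ValueError("likelihood values must lie in [0, 1]")
        if np.any(np.isinf(self.xy)):
            raise ValueError("coordinates must be finite where present")
        if self.units not in ("px", "mm"):
            raise ValueError(f"units must be 'px' or 'mm', got {self.units!r}")

    @property
    def n_frames(self) -> int:
        return self.xy.shape[0]

    @property
    def present(self) -> np.ndarray:
        """Boolean (n_frames, 2, n_parts): label present in the file."""
        return np.isfinite(self.likelihood)


@dataclass
class FilteredPoseTrack(PoseTrack):
    """A :class:`PoseTrack` plus the p-cutoff acceptance mask.

    A label is *accepted* iff it is present and its likelihood is at least
    ``p_cutoff`` (the threshold value itself is accepted).  Geometry is
    untouched; rejected labels keep their coordinates.
    """

    p_cutoff: float = 0.6
    accepted: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        super().__post_init__()
        if not 0.0 <= self.p_cutoff <= 1.0:
            raise ValueError(f"p_cutoff must lie in [0, 1], got {self.p_cutoff}")
        if self.accepted is None:
            with np.errstate(invalid="ignore"):
                self.accepted = np.where(
                    np.isfinite(self.likelihood), self.likelihood >= self.p_cutoff, False
                )
        self.accepted = np.asarray(self.accepted, dtype=bool)
        if self.accepted.shape != self.likelihood.shape:
            raise ValueError("accepted mask shape must match likelihood shape")

    @property
    def rejected(self) -> np.ndarray:
        """Boolean mask of unusable labels (sub-cutoff or absent from the file)."""
        return ~self.accepted

    def rejected_per_frame(self) -> np.ndarray:
        """Number of unusable labels per frame, pooled over both animals (0..10)."""
        return self.rejected.reshape(self.n_frames, -1).sum(axis=1)


def apply_p_cutoff(track: PoseTrack, p_cutoff: float = 0.6) -> FilteredPoseTrack:
    """Mark every label below the likelihood cutoff as rejected.

    The threshold is inclusive: likelihood exactly equal to ``p_cutoff`` is
    accepted, matching the cutoff's role as a minimum confidence.  Missing
    labels are rejected.  Idempotent and monotone in ``p_cutoff``.
    """
    if not 0.0 <= p_cutoff <= 1.0:
        raise ValueError(f"p_cutoff must lie in [0, 1], got {p_cutoff}")
    return FilteredPoseTrack(
        meta=track.meta,
        calibration=track.calibration,
        xy=track.xy.copy(),
        likelihood=track.likelihood.copy(),
        units=track.units,
        p_cutoff=p_cutoff,
    )


def to_mm(track: FilteredPoseTrack) -> FilteredPoseTrack:
    """Convert coordinates from pixels to millimetres using the calibration.

    Raises ``ValueError`` if the track is already in mm (double conversion
    would silently corrupt every downstream distance).
    """
    if track.units == "mm":
        raise ValueError("track is already in mm; refusing to convert twice")
    return FilteredPoseTrack(
        meta=track.meta,
        calibration=track.calibration,
        xy=track.xy * track.calibration.mm_per_pixel,
        likelihood=track.likelihood.copy(),
        units="mm",
        p_cutoff=track.p_cutoff,
        accepted=track.accepted.copy(),
    )


# ---------------------------------------------------------------------------
# DLC multi-animal CSV dialect
# ---------------------------------------------------------------------------

_HEADER_ROWS = ("scorer", "individuals", "bodyparts", "coords")


def read_dlc_csv(
    path: str | Path, meta: SessionMeta, calibration: ArenaCalibration
) -> PoseTrack:
    """Read a multi-animal DLC CSV into a :class:`PoseTrack`.

    Animals in the file are mapped onto ``meta.animal_ids`` in header
    order.  Empty or unparseable cells become missing labels; the frame is
    retained.  Frame indices must be unique and gap-free.
    """
    path = Path(path)
    with open(path) as fh:
        header_lines = [fh.readline().rstrip("\n") for _ in range(4)]
    for i, (line, expected) in enumerate(zip(header_lines, _HEADER_ROWS)):
        first = line.split(",", 1)[0].strip() if line else ""
        if first != expected:
            raise DLCFormatError(
                f"header row {i + 1} must start with {expected!r}, got {first!r} "
                f"(file {path.name})"
            )
    df = pd.read_csv(path, header=[0, 1, 2, 3], index_col=0)
    if df.columns.nlevels != 4:
        raise DLCFormatError("expected 4 header rows (scorer/individuals/bodyparts/coords)")

    individuals: list[str] = []
    for ind in df.columns.get_level_values(1):
        if ind not in individuals:
            individuals.append(ind)
    if len(individuals) != 2:
        raise DLCFormatError(f"expected exactly 2 individuals, found {individuals}")

    parts_in_file = set(df.columns.get_level_values(2))
    unknown = parts_in_file - set(BODY_PARTS)
    if unknown:
        raise DLCFormatError(
            f"unknown body part(s) {sorted(unknown)}; expected {list(BODY_PARTS)}"
        )

    frame_index = df.index.to_numpy()
    if len(frame_index) and pd.Index(frame_index).has_duplicates:
        raise DLCFormatError("duplicate frame indices in data rows")
    if len(frame_index) > 1 and np.any(np.diff(frame_index.astype(int)) != 1):
        raise DLCFormatError("frame index must be strictly increasing and gap-free")

    n_frames = len(df)
    n_parts = len(BODY_PARTS)
    xy = np.full((n_frames, 2, n_parts, 2), np.nan)
    likelihood = np.full((n_frames, 2, n_parts), np.nan)
    for a, ind in enumerate(individuals):
        for p, part in enumerate(BODY_PARTS):
            try:
                sub = df.xs((ind, part), axis=1, level=(1, 2))
            except KeyError:
                continue
            coords = list(sub.columns.get_level_values(-1))
            if not {"x", "y", "likelihood"} <= set(coords):
                raise DLCFormatError(
                    f"body part {part!r} of {ind!r} is missing an (x, y, likelihood) triplet"
                )
            x = pd.to_numeric(sub.xs("x", axis=1, level=-1).iloc[:, 0], errors="coerce")
            y = pd.to_numeric(sub.xs("y", axis=1, level=-1).iloc[:, 0], errors="coerce")
            lk = pd.to_numeric(
                sub.xs("likelihood", axis=1, level=-1).iloc[:, 0], errors="coerce"
            )
            ok = x.notna() & y.notna() & lk.notna()
            xy[ok.to_numpy(), a, p, 0] = x[ok]
            xy[ok.to_numpy(), a, p, 1] = y[ok]
            likelihood[ok.to_numpy(), a, p] = lk[ok].clip(0.0, 1.0)

    return PoseTrack(meta=meta, calibration=calibration, xy=xy, likelihood=likelihood)


def write_dlc_csv(track: PoseTrack, path: str | Path, scorer: str = "socialdist") -> Path:
    """Write a track in the 4-header-row multi-animal DLC CSV dialect.

    ``read_dlc_csv(write_dlc_csv(t))`` reproduces ``t`` exactly (values are
    written with full float repr); missing labels become empty cells.
    """
    path = Path(path)
    columns = pd.MultiIndex.from_tuples(
        [
            (scorer, ind, part, coord)
            for ind in track.meta.animal_ids
            for part in BODY_PARTS
            for coord in ("x", "y", "likelihood")
        ],
        names=list(_HEADER_ROWS),
    )
    n_parts = len(BODY_PARTS)
    data = np.empty((track.n_frames, 2 * n_parts * 3))
    for a in range(2):
        for p in range(n_parts):
            base = (a * n_parts + p) * 3
            data[:, base] = track.xy[:, a, p, 0]
            data[:, base + 1] = track.xy[:, a, p, 1]
            data[:, base + 2] = track.likelihood[:, a, p]
    df = pd.DataFrame(data, columns=columns, index=pd.RangeIndex(track.n_frames))
    df.to_csv(path, index_label=None)
    return path


# ---------------------------------------------------------------------------
# Session metadata sidecar (YAML)
# ---------------------------------------------------------------------------


def write_session_meta(
    meta: SessionMeta, calibration: ArenaCalibration, path: str | Path
) -> Path:
    path = Path(path)
    payload = {
        **dataclasses.asdict(meta),
        "animal_ids": list(meta.animal_ids),
        "mm_per_pixel": calibration.mm_per_pixel,
        "fps": calibration.fps,
        "image_width": calibration.image_width,
        "image_height": calibration.image_height,
    }
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_session_meta(path: str | Path) -> tuple[SessionMeta, ArenaCalibration]:
    payload = yaml.safe_load(Path(path).read_text())
    meta = SessionMeta(
        session_id=str(payload["session_id"]),
        strain=payload["strain"],
        sex=payload["sex"],
        age_months=float(payload["age_months"]),
        animal_ids=tuple(payload.get("animal_ids", ("M1", "M2"))),
    )
    calibration = ArenaCalibration(
        mm_per_pixel=float(payload["mm_per_pixel"]),
        fps=float(payload["fps"]),
        image_width=int(payload.get("image_width", 480)),
        image_height=int(payload.get("image_height", 270)),
    )
    return meta, calibration
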