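"""Localization-table IO, per-molecule merging, drift correction and slicing.

A localization table is the raw currency of single-molecule localization
microscopy: one row per detected signal with its frame, 3D position (nm) and
localization uncertainty (the fitted sigma in the focal plane, nm).  Two CSV
dialects are supported: a ``minimal`` canonical one (``frame,x,y,z,accuracy``)
and a ThunderSTORM-compatible one (headers such as ``"x [nm]"`` and
``"uncertainty [nm]"``).

Repeated detections of one molecule are merged when they fall in the same
camera pixel (160 nm square by default) in consecutive frames.  Slow stage
drift between z stacks is estimated from 2D-histogram cross-correlation or a
fiducial cluster and subtracted per stack.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .core import Box, PointPattern

__all__ = [
    "Localization",
    "LocalizationTable",
    "DriftTrack",
    "ParseError",
    "read_localizations",
    "write_localizations",
    "merge_consecutive",
    "estimate_drift",
    "apply_drift",
    "slice_z",
]

DIALECTS = ("minimal", "thunderstorm")
MINIMAL_COLUMNS = ("frame", "x", "y", "z", "accuracy")


class ParseError(ValueError):
    """A row-level failure while parsing a localization file."""


class Localization(NamedTuple):
    frame: int
    x: float
    y: float
    z: float
    accuracy: float


@dataclass
class LocalizationTable:
    """Per-signal localization records with ROI metadata.

    ``frames`` need not be sorted; sorting is an operation, not an invariant.
    ``n_rejected`` counts input rows dropped for missing coordinates or
    non-positive accuracy during parsing.
    """

    frames: np.ndarray
    xyz: np.ndarray
    accuracy: np.ndarray
    roi: Box
    camera_pixel_nm: float = 160.0
    n_rejected: int = 0

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64).reshape(-1)
        self.xyz = np.asarray(self.xyz, dtype=float).reshape(-1, 3)
        self.accuracy = np.asarray(self.accuracy, dtype=float).reshape(-1)
        n = len(self.frames)
        if self.xyz.shape[0] != n or self.accuracy.shape[0] != n:
            raise ValueError("frames, xyz and accuracy must have equal lengths")
        if n:
            if not np.all(np.isfinite(self.xyz)):
                raise ValueError("coordinates must be finite")
            if np.any(self.frames < 0):
                raise ValueError("frames must be >= 0")
            if np.any(self.accuracy <= 0) or not np.all(np.isfinite(self.accuracy)):
                raise ValueError("accuracy must be finite and > 0")
        if self.camera_pixel_nm <= 0:
            raise ValueError("camera_pixel_nm must be > 0")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def records(self) -> list[Localization]:
        return [
            Localization(int(f), *map(float, p), float(a))
            for f, p, a in zip(self.frames, self.xyz, self.accuracy)
        ]

    @classmethod
    def from_arrays(
        cls,
        frames,
        xyz,
        accuracy,
        roi: Box | None = None,
        camera_pixel_nm: float = 160.0,
        n_rejected: int = 0,
    ) -> "LocalizationTable":
        xyz = np.asarray(xyz, dtype=float).reshape(-1, 3)
        if roi is None:
            roi = Box.from_points(xyz)
        return cls(frames, xyz, accuracy, roi, camera_pixel_nm, n_rejected)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frames,
                "x": self.xyz[:, 0],
                "y": self.xyz[:, 1],
                "z": self.xyz[:, 2],
                "accuracy": self.accuracy,
            }
        )


def _map_thunderstorm_columns(columns) -> dict:
    mapping = {}
    for col in columns:
        key = str(col).strip().strip('"').lower()
        if key == "frame":
            mapping[col] = "frame"
        elif key == "x [nm]" or key.startswith("x ["):
            mapping[col] = "x"
        elif key == "y [nm]" or key.startswith("y ["):
            mapping[col] = "y"
        elif key == "z [nm]" or key.startswith("z ["):
            mapping[col] = "z"
        elif "uncertainty" in key:
            mapping[col] = "accuracy"
    return mapping


def read_localizations(path, dialect: str = "minimal") -> LocalizationTable:
    """Read a localization CSV into a table, normalizing units to nm.

    Rows with missing coordinates or non-positive accuracy are dropped and
    counted in ``table.n_rejected``.  A non-numeric value in a required
    column raises :class:`ParseError` naming the offending line.
    Lines starting with ``#`` are treated as comments.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    df = pd.read_csv(path, comment="#", skip_blank_lines=True)
    if dialect == "thunderstorm":
        mapping = _map_thunderstorm_columns(df.columns)
        df = df.rename(columns=mapping)
    else:
        df = df.rename(columns={c: str(c).strip() for c in df.columns})
    for col in ("frame", "x", "y", "accuracy"):
        if col not in df.columns:
            raise ParseError(f"{path}: required column {col!r} not found "
                             f"(dialect {dialect!r})")
    if "z" not in df.columns:
        df["z"] = 0.0  # 2D table: z defaults to the focal plane

    numeric = {}
    for col in MINIMAL_COLUMNS:
        raw = df[col]
        coerced = pd.to_numeric(raw, errors="coerce")
        bad = coerced.isna() & raw.notna() & (raw.astype(str).str.strip() != "")
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"{path}: non-numeric value {raw[row]!r} in column {col!r} "
                f"on data line {row + 2}"
            )
        numeric[col] = coerced
    data = pd.DataFrame(numeric)
    ok = data[["x", "y", "z"]].notna().all(axis=1) & (data["accuracy"] > 0)
    n_rejected = int((~ok).sum())
    data = data[ok]
    if len(data) == 0:
        raise ParseError(f"{path}: no valid localization rows")
    return LocalizationTable.from_arrays(
        data["frame"].to_numpy(),
        data[["x", "y", "z"]].to_numpy(),
        data["accuracy"].to_numpy(),
        n_rejected=n_rejected,
    )


def write_localizations(
    table: LocalizationTable, path, dialect: str = "minimal", comments=()
) -> None:
    """Write a table as CSV (coordinates at 0.01 nm precision)."""
    if dialect != "minimal":
        raise ValueError("only the 'minimal' dialect is written")
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        fh.write(",".join(MINIMAL_COLUMNS) + "\n")
        for f, (x, y, z), a in zip(table.frames, table.xyz, table.accuracy):
            fh.write(f"{int(f)},{x:.2f},{y:.2f},{z:.2f},{a:.2f}\n")


def merge_consecutive(
    table: LocalizationTable, pixel_nm: float | None = None
) -> LocalizationTable:
    """Merge repeated per-frame detections of one molecule.

    Maximal runs of records in consecutive frames (gap of exactly 1 continues
    a run) whose (x, y) fall in the same ``pixel_nm`` grid cell — anchored at
    the ROI minimum corner — are replaced by a single record: the inverse-
    variance weighted mean position (z averaged with the same weights), the
    quadrature-combined accuracy σ = (Σ σ_k⁻²)^(−1/2), and the first frame of
    the run.
    """
    pix = table.camera_pixel_nm if pixel_nm is None else pixel_nm
    if pix <= 0:
        raise ValueError("pixel_nm must be > 0")
    n = len(table)
    if n == 0:
        return replace(table)
    cells = np.floor((table.xyz[:, :2] - table.roi.lo[:2]) / pix).astype(np.int64)
    order = np.lexsort((table.frames, cells[:, 1], cells[:, 0]))
    frames = table.frames[order]
    xyz = table.xyz[order]
    acc = table.accuracy[order]
    c = cells[order]

    out_frames, out_xyz, out_acc = [], [], []
    start = 0
    for i in range(1, n + 1):
        same_cell = i < n and c[i, 0] == c[start, 0] and c[i, 1] == c[start, 1]
        if same_cell and frames[i] - frames[i - 1] <= 1:
            continue
        w = 1.0 / acc[start:i] ** 2
        out_frames.append(frames[start])
        out_xyz.append(np.average(xyz[start:i], axis=0, weights=w))
        out_acc.append(1.0 / np.sqrt(w.sum()))
        start = i
    frames_a = np.array(out_frames)
    order2 = np.argsort(frames_a, kind="stable")
    return LocalizationTable(
        frames_a[order2],
        np.array(out_xyz)[order2],
        np.array(out_acc)[order2],
        table.roi,
        table.camera_pixel_nm,
        table.n_rejected,
    )


@dataclass
class DriftTrack:
    """Per-z-stack xy displacement relative to the first stack (nm)."""

    stack_starts: np.ndarray  # (n_stacks,) first frame of each stack, ascending
    shifts: np.ndarray  # (n_stacks, 2) xy drift of each stack vs stack 0

    def __post_init__(self) -> None:
        self.stack_starts = np.asarray(self.stack_starts, dtype=np.int64).reshape(-1)
        self.shifts = np.asarray(self.shifts, dtype=float).reshape(-1, 2)
        if len(self.stack_starts) != len(self.shifts):
            raise ValueError("one shift vector per stack is required")
        if len(self.stack_starts) == 0:
            raise ValueError("a drift track needs at least one stack")
        if np.any(np.diff(self.stack_starts) <= 0):
            raise ValueError("stack_starts must be strictly increasing")
        if not np.allclose(self.shifts[0], 0.0):
            raise ValueError("the first stack's drift vector must be zero")

    @classmethod
    def zero(cls, stack_starts) -> "DriftTrack":
        starts = np.asarray(stack_starts, dtype=np.int64).reshape(-1)
        return cls(starts, np.zeros((len(starts), 2)))

    def negated(self) -> "DriftTrack":
        return DriftTrack(self.stack_starts, -self.shifts)

    def stack_of(self, frames: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(self.stack_starts, frames, side="right") - 1
        if np.any(idx < 0):
            bad = int(np.asarray(frames).reshape(-1)[np.argmax(idx < 0)])
            raise ValueError(
                f"frame {bad} precedes the first stack covered by the drift track"
            )
        return idx


def _parabolic_offset(m1: float, m0: float, p1: float) -> float:
    denom = m1 - 2.0 * m0 + p1
    if denom == 0.0:
        return 0.0
    return 0.5 * (m1 - p1) / denom


def _xcorr_shift(h_ref: np.ndarray, h: np.ndarray, bin_nm: float) -> np.ndarray:
    """Shift of ``h`` relative to ``h_ref`` from the cross-correlation peak,
    with parabolic sub-bin refinement along each axis."""
    corr = fftconvolve(h, h_ref[::-1, ::-1], mode="full")
    peak = np.unravel_index(np.argmax(corr), corr.shape)
    shift_bins = np.array(peak, dtype=float) - (np.array(h_ref.shape) - 1)
    for axis in range(2):
        i = peak[axis]
        if 0 < i < corr.shape[axis] - 1:
            sl = list(peak)
            sl[axis] = slice(i - 1, i + 2)
            tri = corr[tuple(sl)]
            shift_bins[axis] += _parabolic_offset(tri[0], tri[1], tri[2])
    return shift_bins * bin_nm


def estimate_drift(
    table: LocalizationTable,
    stack_starts,
    method: str = "autocorrelation",
    bin_nm: float = 20.0,
    fiducial_xy=None,
    fiducial_radius: float = 250.0,
) -> DriftTrack:
    """Estimate per-stack xy drift relative to the first stack.

    ``autocorrelation``: each stack is rendered as a 2D histogram (20 nm bins
    over the ROI) and registered to the first stack by the cross-correlation
    peak with parabolic sub-bin refinement.  ``fiducial``: the centroid of
    signals within ``fiducial_radius`` of a user-marked bright cluster at
    ``fiducial_xy`` is tracked per stack.
    """
    if method not in ("autocorrelation", "fiducial"):
        raise ValueError(f"unknown drift method {method!r}")
    starts = np.asarray(stack_starts, dtype=np.int64).reshape(-1)
    if len(starts) < 2:
        warnings.warn("fewer than 2 stacks: drift cannot be estimated, returning zero")
        return DriftTrack.zero(starts if len(starts) else [0])
    track = DriftTrack.zero(starts)
    idx = track.stack_of(table.frames)
    groups = [np.nonzero(idx == k)[0] for k in range(len(starts))]
    for k, g in enumerate(groups):
        if len(g) == 0:
            raise ValueError(f"stack {k} (frames from {starts[k]}) has no localizations")

    shifts = np.zeros((len(starts), 2))
    if method == "autocorrelation":
        lo, hi = table.roi.lo[:2], table.roi.hi[:2]
        nbins = np.maximum(np.ceil((hi - lo) / bin_nm).astype(int), 1)
        edges = [np.linspace(lo[a], lo[a] + nbins[a] * bin_nm, nbins[a] + 1) for a in (0, 1)]
        hists = [
            np.histogram2d(table.xyz[g, 0], table.xyz[g, 1], bins=edges)[0]
            for g in groups
        ]
        for k in range(1, len(starts)):
            shifts[k] = _xcorr_shift(hists[0], hists[k], bin_nm)
    else:
        if fiducial_xy is None:
            raise ValueError("method 'fiducial' requires fiducial_xy")
        center = np.asarray(fiducial_xy, dtype=float).reshape(2)
        centroids = []
        for k, g in enumerate(groups):
            d = np.linalg.norm(table.xyz[g, :2] - center, axis=1)
            near = g[d <= fiducial_radius]
            if len(near) == 0:
                raise ValueError(
                    f"stack {k}: no signals within {fiducial_radius} nm of the fiducial"
                )
            centroids.append(table.xyz[near, :2].mean(axis=0))
        for k in range(1, len(starts)):
            shifts[k] = centroids[k] - centroids[0]
    return DriftTrack(starts, shifts)


def apply_drift(table: LocalizationTable, track: DriftTrack) -> LocalizationTable:
    """Subtract each record's per-stack drift vector from its xy position."""
    idx = track.stack_of(table.frames)
    xyz = table.xyz.copy()
    xyz[:, :2] -= track.shifts[idx]
    return LocalizationTable(
        table.frames.copy(),
        xyz,
        table.accuracy.copy(),
        table.roi,
        table.camera_pixel_nm,
        table.n_rejected,
    )


def slice_z(
    table: LocalizationTable, center_z: float, thickness: float = 60.0
) -> PointPattern:
    """Signals with z in the half-open slab ``[center_z − t/2, center_z + t/2)``.

    Disjoint slices tiling the z range therefore partition the table.  The
    induced box keeps the ROI's xy bounds and the slab's z bounds.
    """
    if thickness <= 0:
        raise ValueError("thickness must be > 0")
    half = thickness / 2.0
    z = table.xyz[:, 2]
    mask = (z >= center_z - half) & (z < center_z + half)
    box = Box(
        np.array([table.roi.lo[0], table.roi.lo[1], center_z - half]),
        np.array([table.roi.hi[0], table.roi.hi[1], center_z + half]),
    )
    return PointPattern(table.xyz[mask], box)
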