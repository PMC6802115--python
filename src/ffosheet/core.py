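"""Shared geometric primitives: axis-aligned boxes and 3D point patterns.

All coordinates are continuous nanometres.  Binning and slicing operations
throughout the package treat intervals as half-open ``[lo, hi)``; containment
checks against a :class:`Box` are closed on the upper bound so that a box
inferred from data bounds still contains its extremal points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Box", "PointPattern"]


@dataclass(frozen=True)
class Box:
    """Axis-aligned 3D bounding box in nm."""

    lo: np.ndarray
    hi: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lo, dtype=float).reshape(3)
        hi = np.asarray(self.hi, dtype=float).reshape(3)
        if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
            raise ValueError("box bounds must be finite")
        if np.any(hi <= lo):
            raise ValueError("box must be nondegenerate (hi > lo on every axis)")
        object.__setattr__(self, "lo", lo)
        object.__setattr__(self, "hi", hi)

    @classmethod
    def from_extent(cls, extent, lo=(0.0, 0.0, 0.0)) -> "Box":
        lo = np.asarray(lo, dtype=float).reshape(3)
        extent = np.asarray(extent, dtype=float).reshape(3)
        return cls(lo, lo + extent)

    @classmethod
    def from_points(cls, points: np.ndarray, pad_degenerate: float = 0.5) -> "Box":
        """Tight box around ``points``; degenerate axes are padded symmetrically."""
        points = np.asarray(points, dtype=float).reshape(-1, 3)
        if points.size == 0:
            raise ValueError("cannot infer a box from an empty point set")
        lo = points.min(axis=0)
        hi = points.max(axis=0)
        flat = hi <= lo
        lo = np.where(flat, lo - pad_degenerate, lo)
        hi = np.where(flat, hi + pad_degenerate, hi)
        return cls(lo, hi)

    @property
    def extent(self) -> np.ndarray:
        return self.hi - self.lo

    @property
    def center(self) -> np.ndarray:
        return 0.5 * (self.lo + self.hi)

    @property
    def volume(self) -> float:
        return float(np.prod(self.extent))

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points inside the box (closed bounds)."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((p >= self.lo) & (p <= self.hi), axis=1)

    def translated(self, shift) -> "Box":
        shift = np.asarray(shift, dtype=float).reshape(3)
        return Box(self.lo + shift, self.hi + shift)


@dataclass
class PointPattern:
    """A bag of 3D coordinates (nm) with its bounding box.

    ``labels`` optionally tags each point with a category (e.g. ``"sheet"``
    vs ``"free"`` for the sheet simulator's ground truth).
    """

    coords: np.ndarray
    box: Box
    labels: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(coords)):
            raise ValueError("pattern coordinates must be finite")
        self.coords = coords
        if self.labels is not None:
            labels = np.asarray(self.labels)
            if labels.shape[0] != coords.shape[0]:
                raise ValueError("labels must have one entry per point")
            self.labels = labels

    def __len__(self) -> int:
        return self.coords.shape[0]

    @property
    def n(self) -> int:
        return len(self)

    def subset(self, mask: np.ndarray) -> "PointPattern":
        labels = None if self.labels is None else self.labels[mask]
        return PointPattern(self.coords[mask], self.box, labels)

    def translated(self, shift) -> "PointPattern":
        shift = np.asarray(shift, dtype=float).reshape(3)
        return PointPattern(self.coords + shift, self.box.translated(shift), self.labels)
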