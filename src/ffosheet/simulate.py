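"""Ground-truth simulators for GAS7 label patterns on membranes.

Three generative hypotheses are modelled for the spatial arrangement of
labelled GAS7 molecules:

* complete spatial randomness (CSR) — independent uniform points;
* randomly placed dimers — pairs of labels a fixed distance apart, with the
  pair axis uniform in the membrane (xy) plane;
* FFO sheets — flat filamentous oligomers (FFOs): strings of dimers at a
  fixed axial spacing with the dimer long axis tilted from the filament
  axis, packed laterally in parallel (or antiparallel) into a planar sheet
  patch, with the remaining molecules as free random dimers.

Observation is emulated by independent Bernoulli detection thinning followed
by Gaussian localization noise whose axial (z) sigma is a fixed multiple of
the focal-plane sigma.  A separate generator renders a noise-free striation
image of a sheet patch for Fourier periodicity analysis.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import ndimage

from .core import Box, PointPattern

__all__ = [
    "SheetModelParams",
    "simulate_csr",
    "simulate_dimer_field",
    "simulate_ffo",
    "filament_width",
    "simulate_sheet",
    "thin_detection",
    "add_localization_noise",
    "render_striation_image",
]


@dataclass
class SheetModelParams:
    """Geometric and observation constants of the sheet model.

    Defaults are the crystal-derived geometry and the observation model used
    throughout the package: label pairs 11 nm apart within a dimer, dimers
    strung at 5 nm axial spacing with a 40° tilt (dimer length 22 nm, so the
    filament envelope is 22·sin 40° ≈ 14 nm wide, which also sets the lateral
    filament packing), 40% of molecules in sheets, 10% label detection, and
    20 nm focal-plane localization accuracy with 2× the deviation in z.
    """

    dimer_label_distance: float = 11.0
    intra_filament_spacing: float = 5.0
    tilt_deg: float = 40.0
    dimer_length: float = 22.0
    filament_lateral_spacing: float = 14.0
    sheet_fraction: float = 0.4
    detection_prob: float = 0.1
    accuracy_xy: float = 20.0
    z_accuracy_factor: float = 2.0
    alignment: str = "parallel"

    def __post_init__(self) -> None:
        for name in (
            "dimer_label_distance",
            "intra_filament_spacing",
            "dimer_length",
            "filament_lateral_spacing",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 < self.tilt_deg <= 90.0:
            raise ValueError("tilt_deg must be in (0, 90]")
        for name in ("sheet_fraction", "detection_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.accuracy_xy < 0 or self.z_accuracy_factor < 0:
            raise ValueError("accuracies must be non-negative")
        if self.alignment not in ("parallel", "antiparallel"):
            raise ValueError("alignment must be 'parallel' or 'antiparallel'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SheetModelParams":
        return cls(**d)


def filament_width(params: SheetModelParams) -> float:
    """Perpendicular envelope width of one filament, nm.

    A dimer of length L tilted by angle t from the filament axis projects
    L·sin(t) perpendicular to the axis; with the default 22 nm length and 40°
    tilt this is ≈14.1 nm, consistent with the crystal-lattice filament width.
    """
    return params.dimer_length * math.sin(math.radians(params.tilt_deg))


def simulate_csr(n: int, box: Box, seed=None) -> PointPattern:
    """``n`` independent uniform points in ``box`` (complete spatial randomness)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    coords = box.lo + rng.random((n, 3)) * box.extent
    return PointPattern(coords, box)


def _dimer_labels(centers: np.ndarray, directions: np.ndarray, distance: float) -> np.ndarray:
    """Two labels per dimer at centre ± (distance/2)·direction, interleaved."""
    half = 0.5 * distance * directions
    out = np.empty((2 * len(centers), 3))
    out[0::2] = centers + half
    out[1::2] = centers - half
    return out


def simulate_dimer_field(
    n_dimers: int, box: Box, params: SheetModelParams, seed=None
) -> PointPattern:
    """Randomly placed dimers: label pairs a fixed distance apart.

    Dimer centres are uniform in the box; the pair axis is uniform in the
    membrane (xy) plane.  No detection thinning or localization noise is
    applied here.  Labels of dimer ``k`` occupy rows ``2k`` and ``2k+1``.
    """
    if n_dimers < 0:
        raise ValueError("n_dimers must be >= 0")
    rng = np.random.default_rng(seed)
    centers = box.lo + rng.random((n_dimers, 3)) * box.extent
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n_dimers)
    directions = np.column_stack([np.cos(phi), np.sin(phi), np.zeros(n_dimers)])
    coords = _dimer_labels(centers, directions, params.dimer_label_distance)
    return PointPattern(coords, box)


def simulate_ffo(
    n_dimers: int, origin, axis_direction, params: SheetModelParams
) -> PointPattern:
    """One flat filamentous oligomer: a string of dimers along an in-plane axis.

    Dimer centres sit at ``origin + k·spacing·axis`` (k = 0..n−1); each
    dimer's label pair lies along a direction tilted by ``tilt_deg`` from the
    filament axis, within the sheet (xy) plane.
    """
    if n_dimers < 1:
        raise ValueError("n_dimers must be >= 1")
    origin = np.asarray(origin, dtype=float).reshape(3)
    axis = np.asarray(axis_direction, dtype=float).reshape(-1)
    if axis.size == 2:
        axis = np.array([axis[0], axis[1], 0.0])
    norm = math.hypot(axis[0], axis[1])
    if norm == 0.0:
        raise ValueError("axis_direction must have nonzero in-plane length")
    angle = math.atan2(axis[1], axis[0])
    u = np.array([math.cos(angle), math.sin(angle), 0.0])
    tilt = math.radians(params.tilt_deg)
    tdir = np.array([math.cos(angle + tilt), math.sin(angle + tilt), 0.0])
    k = np.arange(n_dimers)[:, None]
    centers = origin + k * params.intra_filament_spacing * u
    directions = np.broadcast_to(tdir, (n_dimers, 3))
    coords = _dimer_labels(centers, directions, params.dimer_label_distance)
    pad = params.dimer_length
    box = Box(coords.min(axis=0) - pad, coords.max(axis=0) + pad)
    return PointPattern(coords, box)


def _sheet_patch_layout(n_sheet_dimers: int, params: SheetModelParams) -> tuple[int, int]:
    """Number of filaments and dimers per filament for a roughly square patch."""
    s = params.intra_filament_spacing
    lat = params.filament_lateral_spacing
    n_fil = max(1, int(math.ceil(math.sqrt(n_sheet_dimers * s / lat))))
    n_per = int(math.ceil(n_sheet_dimers / n_fil))
    return n_fil, n_per


def simulate_sheet(
    n_labels_total: int, box: Box, params: SheetModelParams, seed=None
) -> PointPattern:
    """A planar FFO-sheet patch plus free random dimers.

    ``sheet_fraction`` of the labels (rounded to whole dimers) form one patch
    of laterally packed parallel filaments at mid-z of the box; the remainder
    are random dimers in the 3D box.  Points carry labels ``"sheet"`` or
    ``"free"``.  ``alignment="antiparallel"`` flips the axis of alternate
    filaments.
    """
    if n_labels_total < 0 or n_labels_total % 2:
        raise ValueError("n_labels_total must be a non-negative even number")
    rng_free = np.random.default_rng(seed)
    n_dimers_total = n_labels_total // 2
    n_sheet = int(round(params.sheet_fraction * n_dimers_total))
    n_free = n_dimers_total - n_sheet

    parts: list[np.ndarray] = []
    tags: list[np.ndarray] = []
    if n_sheet:
        s = params.intra_filament_spacing
        lat = params.filament_lateral_spacing
        n_fil, n_per = _sheet_patch_layout(n_sheet, params)
        width_x = (n_per - 1) * s
        width_y = (n_fil - 1) * lat
        pad = params.dimer_label_distance
        if width_x + 2 * pad > box.extent[0] or width_y + 2 * pad > box.extent[1]:
            raise ValueError(
                f"sheet patch ({width_x:.0f} x {width_y:.0f} nm plus label margins) "
                "does not fit in the box; use a larger box or fewer sheet labels"
            )
        c = box.center
        placed = 0
        for j in range(n_fil):
            take = min(n_per, n_sheet - placed)
            if take <= 0:
                break
            y = c[1] - width_y / 2.0 + j * lat
            flip = params.alignment == "antiparallel" and j % 2 == 1
            if flip:
                origin = (c[0] + width_x / 2.0, y, c[2])
                axis = (-1.0, 0.0)
            else:
                origin = (c[0] - width_x / 2.0, y, c[2])
                axis = (1.0, 0.0)
            ffo = simulate_ffo(take, origin, axis, params)
            parts.append(ffo.coords)
            placed += take
        tags.append(np.full(2 * n_sheet, "sheet"))
    if n_free:
        free = simulate_dimer_field(n_free, box, params, rng_free)
        parts.append(free.coords)
        tags.append(np.full(2 * n_free, "free"))

    if parts:
        coords = np.concatenate(parts)
        labels = np.concatenate(tags)
    else:
        coords = np.empty((0, 3))
        labels = np.empty((0,), dtype="<U5")
    return PointPattern(coords, box, labels)


def thin_detection(pattern: PointPattern, p: float, seed=None) -> PointPattern:
    """Keep each label independently with probability ``p`` (detection thinning)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random(len(pattern)) < p
    return pattern.subset(mask)


def add_localization_noise(
    pattern: PointPattern, params: SheetModelParams, seed=None
) -> PointPattern:
    """Independent Gaussian localization error per label.

    σ_x = σ_y = ``accuracy_xy``; σ_z = ``z_accuracy_factor · accuracy_xy``.
    Points displaced outside the box are kept — ROI selection is a separate,
    downstream step.
    """
    rng = np.random.default_rng(seed)
    sigma = np.array(
        [
            params.accuracy_xy,
            params.accuracy_xy,
            params.z_accuracy_factor * params.accuracy_xy,
        ]
    )
    if np.all(sigma == 0.0):
        return PointPattern(pattern.coords.copy(), pattern.box, pattern.labels)
    noise = rng.normal(size=pattern.coords.shape) * sigma
    return PointPattern(pattern.coords + noise, pattern.box, pattern.labels)


def render_striation_image(
    params: SheetModelParams,
    image_size: int = 512,
    pixel_size: float = 0.5,
    n_dimers: int | None = None,
) -> np.ndarray:
    """Noise-free intensity image of a sheet patch's striations.

    The micrograph stand-in represents each dimer row of the lattice as a
    uniform ridge of density perpendicular to the filament axis (EM contrast
    integrates protein mass along the dimer, so the dominant repeat is the
    dimer-row pitch).  Ridges repeat along the filament axis (image x) at
    ``intra_filament_spacing`` and are splatted with a sub-pixel Gaussian of
    σ = 1 px.  ``n_dimers=None`` fills the field; ``n_dimers=0`` returns an
    all-zero image (empty patch).
    """
    if pixel_size <= 0:
        raise ValueError("pixel_size must be > 0")
    if pixel_size > params.intra_filament_spacing / 2.0:
        raise ValueError(
            "pixel_size violates Nyquist sampling for the requested striation "
            f"pitch ({params.intra_filament_spacing} nm): need <= "
            f"{params.intra_filament_spacing / 2.0} nm/px"
        )
    s = params.intra_filament_spacing
    width_nm = image_size * pixel_size
    margin = 0.1 * width_nm
    if n_dimers is None:
        n_dimers = max(0, int(math.floor((width_nm - 2.0 * margin) / s)) + 1)
    img = np.zeros((image_size, image_size), dtype=float)
    if n_dimers == 0:
        return img.astype(np.float32)
    comb_width = (n_dimers - 1) * s
    x0 = (width_nm - comb_width) / 2.0
    row_lo = int(round(margin / pixel_size))
    row_hi = image_size - row_lo
    for k in range(n_dimers):
        x = x0 + k * s
        c = x / pixel_size - 0.5  # pixel centres at (i + 0.5) * pixel_size
        i0 = int(math.floor(c))
        w1 = c - i0
        if 0 <= i0 < image_size:
            img[row_lo:row_hi, i0] += 1.0 - w1
        if 0 <= i0 + 1 < image_size:
            img[row_lo:row_hi, i0 + 1] += w1
    img = ndimage.gaussian_filter(img, sigma=1.0)
    return img.astype(np.float32)
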