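"""3D binary masks on a physical voxel grid and contour agreement metrics.

Masks live on a regular anisotropic grid indexed (slice, row, column); the
physical coordinate of voxel index ``(i, j, k)`` is ``origin + index * spacing``
(voxel-centre convention, all distances in millimetres).  Agreement between a
gold-standard contour and a submitted contour is quantified by

* the Sorensen-Dice similarity index ``DSI = 2 |A ∩ B| / (|A| + |B|)``,
  a volume-overlap measure in [0, 1] (1 = identical occupancy), and
* the (percentile) Hausdorff distance: the largest minimal distance between
  the two boundary point sets, optionally replaced by a distance order
  statistic (e.g. the 95th percentile) to suppress single-voxel outliers.

Both metrics require the two masks to be co-registered; resampling to a
common grid is an explicit I/O-layer step, never implicit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .errors import EmptyStructureError, GridMismatchError, UndefinedMetricError

__all__ = [
    "Mask3D",
    "SurfacePointSet",
    "AgreementResult",
    "HausdorffResult",
    "compute_dsi",
    "extract_surface",
    "directed_percentile_hd",
    "compute_hd",
    "compare_masks",
]

#: 6-connected structuring element (face neighbours only).
_SIX_CONN = ndimage.generate_binary_structure(3, 1)


def _as_triple(v) -> tuple[float, float, float]:
    t = tuple(float(x) for x in v)
    if len(t) != 3:
        raise ValueError(f"expected a length-3 sequence, got {v!r}")
    return t  # type: ignore[return-value]


@dataclass
class Mask3D:
    """Boolean occupancy on a physical voxel grid.

    Parameters
    ----------
    data
        Boolean array of shape ``(n_slices, n_rows, n_cols)``.
    spacing
        Millimetres per voxel along each axis, same order as ``data``.
    origin
        Physical coordinate (mm) of the centre of voxel ``(0, 0, 0)``.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("mask data must be 3-dimensional")
        if self.data.dtype != bool:
            self.data = self.data.astype(bool)
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    # -- grid geometry -----------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.data))

    @property
    def volume_cc(self) -> float:
        return self.n_voxels * self.voxel_volume_mm3 / 1000.0

    @property
    def is_empty(self) -> bool:
        return not bool(self.data.any())

    def same_grid(self, other: "GridLike") -> bool:
        return (
            self.shape == tuple(other.shape)
            and np.allclose(self.spacing, other.spacing, rtol=0.0, atol=1e-9)
            and np.allclose(self.origin, other.origin, rtol=0.0, atol=1e-9)
        )

    def require_same_grid(self, other: "GridLike") -> None:
        if not self.same_grid(other):
            raise GridMismatchError(
                f"grids differ: shape {self.shape} vs {tuple(other.shape)}, "
                f"spacing {self.spacing} vs {tuple(other.spacing)}, "
                f"origin {self.origin} vs {tuple(other.origin)}"
            )

    def with_data(self, data: np.ndarray) -> "Mask3D":
        """New mask on the same grid with different occupancy."""
        return Mask3D(data, self.spacing, self.origin)

    def indices_to_physical(self, idx: np.ndarray) -> np.ndarray:
        """Map an ``(n, 3)`` array of voxel indices to physical mm coordinates."""
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * np.asarray(self.spacing)


GridLike = Mask3D  # anything exposing shape/spacing/origin; DoseGrid duck-types


@dataclass
class SurfacePointSet:
    """Physical-coordinate centres (mm) of a mask's boundary voxels."""

    points: np.ndarray  # (n, 3) float, mm
    source_mask_id: str = ""

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return self.points.shape[0]


class HausdorffResult(NamedTuple):
    hd: float
    directed_ab: float
    directed_ba: float


@dataclass
class AgreementResult:
    """Per-structure agreement between a submission and the gold standard."""

    structure_name: str
    dsi: float
    hd: float
    hd_percentile: float
    directed_hd_ab: float
    directed_hd_ba: float
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.dsi <= 1.0 + 1e-12):
            raise ValueError(f"DSI out of [0, 1]: {self.dsi}")
        if self.hd < 0:
            raise ValueError(f"negative Hausdorff distance: {self.hd}")


def compute_dsi(a: Mask3D, b: Mask3D) -> float:
    """Sorensen-Dice similarity index ``2 |A ∩ B| / (|A| + |B|)``.

    Symmetric in its arguments; 1 iff the occupancies are identical, 0 for
    disjoint masks.  Raises :class:`UndefinedMetricError` when both masks are
    empty (the metric has no value there; an absent contour is a review
    deviation, not a number).
    """
    a.require_same_grid(b)
    na, nb = a.n_voxels, b.n_voxels
    if na == 0 and nb == 0:
        raise UndefinedMetricError("DSI undefined: both masks are empty")
    inter = int(np.count_nonzero(a.data & b.data))
    return 2.0 * inter / (na + nb)


def extract_surface(m: Mask3D, mask_id: str = "") -> SurfacePointSet:
    """Boundary voxel centres: occupied voxels with a 6-connected free neighbour.

    Voxels on the grid border count as boundary (the out-of-grid side is
    treated as unoccupied).  A single-voxel mask yields exactly one point.
    """
    if m.is_empty:
        raise EmptyStructureError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(m.data, structure=_SIX_CONN, border_value=0)
    surface = m.data & ~interior
    idx = np.argwhere(surface)
    return SurfacePointSet(m.indices_to_physical(idx), mask_id)


def _nearest_rank(values: np.ndarray, p: float) -> float:
    """Nearest-rank percentile: smallest v with >= p% of values <= v."""
    v = np.sort(np.asarray(values, dtype=float))
    n = v.size
    k = int(math.ceil(p * n / 100.0))
    k = min(max(k, 1), n)
    return float(v[k - 1])


def directed_percentile_hd(src: SurfacePointSet, dst: SurfacePointSet, p: float = 100.0) -> float:
    """Directed percentile Hausdorff distance in millimetres.

    For every point of ``src`` take the minimum Euclidean distance to ``dst``
    and return the p-th nearest-rank percentile of those distances; ``p=100``
    is the classical directed Hausdorff distance (the maximum).
    """
    if len(src) == 0 or len(dst) == 0:
        raise EmptyStructureError("directed HD requires two non-empty point sets")
    if not (0.0 < p <= 100.0):
        raise ValueError(f"percentile must be in (0, 100], got {p}")
    dists, _ = cKDTree(dst.points).query(src.points, k=1)
    return _nearest_rank(dists, p)


def compute_hd(a: Mask3D, b: Mask3D, p: float = 95.0) -> HausdorffResult:
    """Symmetric percentile Hausdorff distance between two co-registered masks.

    ``hd = max(directed(A→B, p), directed(B→A, p))``; zero for identical
    masks ("perfect superimposition").
    """
    a.require_same_grid(b)
    sa = extract_surface(a, "a")
    sb = extract_surface(b, "b")
    ab = directed_percentile_hd(sa, sb, p)
    ba = directed_percentile_hd(sb, sa, p)
    return HausdorffResult(max(ab, ba), ab, ba)


def compare_masks(
    gold: Mask3D,
    submission: Mask3D,
    structure_name: str = "",
    hd_percentile: float = 95.0,
) -> AgreementResult:
    """Full agreement record (DSI + percentile HD) for one structure."""
    dsi = compute_dsi(gold, submission)
    hd = compute_hd(gold, submission, hd_percentile)
    return AgreementResult(
        structure_name=structure_name,
        dsi=dsi,
        hd=hd.hd,
        hd_percentile=hd_percentile,
        directed_hd_ab=hd.directed_ab,
        directed_hd_ba=hd.directed_ba,
    )
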