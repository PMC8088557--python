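"""Dose grids, cumulative DVHs and protocol dose metrics.

The protocol constrains structures through four dose-volume metrics:

* ``Dmean`` — volume-weighted mean structure dose (Gy),
* ``Dmax``  — maximum voxel dose (distinct from the near-maximum D2%),
* ``D x %`` near-maximum (``DnearMax``) — minimum dose received by the
  hottest x% of the structure volume (D2% in the protocol),
* ``D x %`` coverage (``Dcoverage``) — minimum dose received by x% of the
  volume (D95% in the protocol).

Both percentile metrics are the inverse cumulative DVH at volume fraction
x/100, evaluated with linear interpolation between voxel order statistics;
for equal-volume voxels this is the (100 − x)-th percentile of the voxel
doses.  Masks and doses are integrated at voxel level (no partial-volume
weighting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ConfigError, EmptyStructureError, GeometryError
from .geometry import Mask3D, _as_triple

__all__ = [
    "DoseGrid",
    "DVH",
    "DoseMetricSpec",
    "resample_dose",
    "compute_dvh",
    "dose_metric",
    "structure_dose_metric",
]

log = logging.getLogger(__name__)


@dataclass
class DoseGrid:
    """Scalar absorbed dose (Gy, non-negative) on a voxel grid."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("dose data must be 3-dimensional")
        if np.any(self.data < 0):
            raise ValueError("dose values must be non-negative")
        self.spacing = _as_triple(self.spacing)
        self.origin = _as_triple(self.origin)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    shape = Mask3D.shape
    voxel_volume_mm3 = Mask3D.voxel_volume_mm3
    same_grid = Mask3D.same_grid
    require_same_grid = Mask3D.require_same_grid

    def with_data(self, data: np.ndarray) -> "DoseGrid":
        return DoseGrid(data, self.spacing, self.origin)


@dataclass
class DVH:
    """Cumulative dose-volume histogram for one structure.

    ``volume_fraction[i]`` is the fraction of the structure volume receiving
    at least ``dose_axis[i]`` Gy; it starts at 1 and is non-increasing,
    reaching 0 beyond the maximum structure dose.
    """

    structure_name: str
    dose_axis: np.ndarray
    volume_fraction: np.ndarray
    total_volume_cc: float

    def __post_init__(self) -> None:
        self.dose_axis = np.asarray(self.dose_axis, dtype=float)
        self.volume_fraction = np.asarray(self.volume_fraction, dtype=float)
        if self.dose_axis.shape != self.volume_fraction.shape:
            raise ValueError("dose_axis and volume_fraction must align")
        if np.any(np.diff(self.volume_fraction) > 1e-12):
            raise ValueError("cumulative DVH must be non-increasing")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"dose_Gy": self.dose_axis, "volume_fraction": self.volume_fraction}
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


_KINDS = ("Dmean", "Dmax", "DnearMax", "Dcoverage")


@dataclass(frozen=True)
class DoseMetricSpec:
    """One protocol dose metric: kind plus the percent-volume parameter.

    ``DnearMax(2)`` is the protocol's "D2%", ``Dcoverage(95)`` its "D95%".
    """

    kind: str
    x: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigError(f"unknown dose metric kind {self.kind!r}")
        if self.kind in ("DnearMax", "Dcoverage"):
            if self.x is None or not (0.0 < self.x < 100.0):
                raise ConfigError(f"{self.kind} needs a percent volume in (0, 100), got {self.x}")
        elif self.x is not None:
            raise ConfigError(f"{self.kind} takes no percent-volume parameter")

    @classmethod
    def parse(cls, label: str) -> "DoseMetricSpec":
        """Parse protocol shorthand: ``Dmean``, ``Dmax``, ``D2%``, ``D95%``.

        ``Dx%`` with x <= 50 is read as a near-maximum metric, larger x as a
        coverage metric — matching protocol usage (D2% near-max, D95%
        coverage).
        """
        s = label.strip()
        if s == "Dmean":
            return cls("Dmean")
        if s == "Dmax":
            return cls("Dmax")
        if s.startswith("D") and s.endswith("%"):
            x = float(s[1:-1])
            return cls("DnearMax" if x <= 50 else "Dcoverage", x)
        raise ConfigError(f"cannot parse dose metric label {label!r}")

    @property
    def label(self) -> str:
        if self.kind == "Dmean":
            return "Dmean"
        if self.kind == "Dmax":
            return "Dmax"
        x = self.x
        sx = f"{x:g}"
        return f"D{sx}%"


def resample_dose(d: DoseGrid, target) -> DoseGrid:
    """Trilinearly interpolate a dose grid onto another grid's voxel centres.

    Target voxel centres outside the dose grid's physical extent receive
    0 Gy (with a logged warning); grids with no spatial overlap raise
    :class:`GeometryError`.  A no-op (bitwise equal) when the grids already
    match.
    """
    if d.same_grid(target):
        return d.with_data(d.data.copy())
    # physical extents (outer voxel faces)
    for ax in range(3):
        d_lo = d.origin[ax] - 0.5 * d.spacing[ax]
        d_hi = d.origin[ax] + (d.shape[ax] - 0.5) * d.spacing[ax]
        t_lo = target.origin[ax] - 0.5 * target.spacing[ax]
        t_hi = target.origin[ax] + (target.shape[ax] - 0.5) * target.spacing[ax]
        if t_hi <= d_lo or t_lo >= d_hi:
            raise GeometryError(f"dose and target grids do not overlap along axis {ax}")
    axes = [
        (np.asarray(target.origin[ax]) + np.arange(target.shape[ax]) * target.spacing[ax]
         - d.origin[ax]) / d.spacing[ax]
        for ax in range(3)
    ]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    outside = np.zeros(ii.shape, dtype=bool)
    for ax, cont in enumerate((ii, jj, kk)):
        outside |= (cont < 0) | (cont > d.shape[ax] - 1)
    if outside.any():
        log.warning(
            "resample_dose: %d target voxels lie outside the dose extent; set to 0 Gy",
            int(outside.sum()),
        )
    out = ndimage.map_coordinates(d.data, [ii, jj, kk], order=1, mode="constant", cval=0.0)
    out[outside] = 0.0
    return DoseGrid(out, target.spacing, target.origin)


def _structure_doses(d: DoseGrid, m: Mask3D) -> np.ndarray:
    m.require_same_grid(d)
    if m.is_empty:
        raise EmptyStructureError("structure mask is empty")
    return d.data[m.data]


def compute_dvh(d: DoseGrid, m: Mask3D, bin_width: float = 0.5) -> DVH:
    """Cumulative DVH of the doses inside a mask (equal-volume voxels)."""
    if bin_width <= 0:
        raise ConfigError("DVH bin width must be positive")
    doses = np.sort(_structure_doses(d, m))
    n = doses.size
    top = float(doses[-1])
    n_bins = int(np.floor(top / bin_width)) + 2
    axis = np.arange(n_bins) * bin_width
    # fraction of voxels with dose >= edge
    frac = (n - np.searchsorted(doses, axis, side="left")) / n
    return DVH(
        structure_name=getattr(m, "name", ""),
        dose_axis=axis,
        volume_fraction=frac,
        total_volume_cc=m.volume_cc,
    )


def dose_metric(voxel_doses: Union[np.ndarray, "DVHInput"], spec: DoseMetricSpec) -> float:
    """Evaluate a dose metric on a structure's voxel dose list (Gy).

    ``DnearMax(x)`` and ``Dcoverage(x)`` are the (100 − x)-th percentile of
    the voxel doses with linear interpolation between order statistics.
    """
    doses = np.asarray(voxel_doses, dtype=float).ravel()
    if doses.size == 0:
        raise EmptyStructureError("dose metric of an empty structure")
    if spec.kind == "Dmean":
        return float(doses.mean())
    if spec.kind == "Dmax":
        return float(doses.max())
    return float(np.percentile(doses, 100.0 - spec.x))


DVHInput = np.ndarray


def structure_dose_metric(d: DoseGrid, m: Mask3D, spec: DoseMetricSpec) -> float:
    """Convenience wrapper: extract the voxel doses of ``m`` then evaluate."""
    return dose_metric(_structure_doses(d, m), spec)
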