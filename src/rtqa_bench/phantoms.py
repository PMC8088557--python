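"""Synthetic head-and-neck benchmark phantoms, perturbed submissions and
analytic dose fields.

The benchmark case the pipeline emulates has no public imaging data, so every
stage is exercised on geometric phantoms: parametric solids (ellipsoids for
glands, tubes along the slice axis for the spinal-cord PRV / esophagus /
larynx, curved shells for the pharyngeal constrictors and the mandible
horseshoe, boxes for the target volumes) voxelised by a voxel-centre-inside
test on a 2 mm grid.  Closed-form volumes and distances make every metric
oracle-checkable.

Institutional submissions are controlled perturbations of the gold standard,
emulating the error taxonomy seen in benchmark reviews: over/under-contouring
(dilate/erode), systematic shifts (translate), cranio-caudal boundary errors
on elongated organs (crop/extend_longitudinal — the error mode a percentile
Hausdorff distance is most sensitive to), ragged boundaries (seeded surface
noise) and missing structures (omit).

The default cohort reproduces the study conditions of a 35-institution
head-and-neck benchmark: 23 institutions fail their first submission, with 76
unacceptable deviations in total — 40 OAR delineation, 27 target delineation
(19 prophylactic + 8 therapeutic PTV) and 9 planning — and round counts with
median 2, range 1–4.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy import ndimage

from .dosimetry import DoseGrid
from .errors import ConfigError, GeometryError
from .geometry import Mask3D
from .qa_rules import RoundInput

__all__ = [
    "StructureRecipe",
    "PhantomSpec",
    "PerturbationSpec",
    "DosePrescription",
    "RoundScript",
    "Cohort",
    "default_head_neck_spec",
    "make_phantom",
    "perturb_structure",
    "make_dose",
    "add_hotspot",
    "default_schedule",
    "make_cohort",
    "DELINEATION_DEVIATION_COUNTS",
    "DEVIATION_MODES",
]

# ---------------------------------------------------------------------------
# phantom specification and voxelisation
# ---------------------------------------------------------------------------

_RECIPE_KINDS = ("ellipsoid", "tube", "shell_arc", "box", "union")


@dataclass(frozen=True)
class StructureRecipe:
    """One parametric solid. Coordinates/sizes in physical mm, (z, y, x) order.

    kinds:
      ellipsoid: center=(z,y,x), radii=(rz,ry,rx)
      tube:      axis along z; center=(y,x), radius, z_range=(lo,hi)
      shell_arc: half-annulus along z; center=(y,x), r_inner, r_outer,
                 z_range, half='posterior' (y >= cy) or 'anterior' (y <= cy)
      box:       lo=(z,y,x), hi=(z,y,x)
      union:     parts=[StructureRecipe, ...]
    """

    kind: str
    params: tuple  # frozen key/value pairs
    role: str = "oar"  # target | oar

    def __post_init__(self) -> None:
        if self.kind not in _RECIPE_KINDS:
            raise ConfigError(f"unknown recipe kind {self.kind!r}")
        if self.role not in ("target", "oar"):
            raise ConfigError(f"role must be target/oar, got {self.role!r}")

    @classmethod
    def make(cls, kind: str, role: str = "oar", **params) -> "StructureRecipe":
        return cls(kind, tuple(sorted(params.items())), role)

    @property
    def p(self) -> dict:
        return dict(self.params)


@dataclass
class PhantomSpec:
    """Grid geometry plus named structure recipes for one benchmark case."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    structures: dict[str, StructureRecipe]
    containments: list[tuple[str, str]] = field(default_factory=list)  # (inner, outer)


def _physical_axes(spec: PhantomSpec):
    return [
        spec.origin[ax] + np.arange(spec.shape[ax]) * spec.spacing[ax]
        for ax in range(3)
    ]


def _voxelise(recipe: StructureRecipe, zz, yy, xx) -> np.ndarray:
    p = recipe.p
    if recipe.kind == "ellipsoid":
        cz, cy, cx = p["center"]
        rz, ry, rx = p["radii"]
        return ((zz - cz) / rz) ** 2 + ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if recipe.kind == "tube":
        cy, cx = p["center"]
        lo, hi = p["z_range"]
        return ((yy - cy) ** 2 + (xx - cx) ** 2 <= p["radius"] ** 2) & (zz >= lo) & (zz <= hi)
    if recipe.kind == "shell_arc":
        cy, cx = p["center"]
        lo, hi = p["z_range"]
        r2 = (yy - cy) ** 2 + (xx - cx) ** 2
        ring = (r2 >= p["r_inner"] ** 2) & (r2 <= p["r_outer"] ** 2)
        half = (yy >= cy) if p["half"] == "posterior" else (yy <= cy)
        return ring & half & (zz >= lo) & (zz <= hi)
    if recipe.kind == "box":
        lo, hi = p["lo"], p["hi"]
        return (
            (zz >= lo[0]) & (zz <= hi[0])
            & (yy >= lo[1]) & (yy <= hi[1])
            & (xx >= lo[2]) & (xx <= hi[2])
        )
    # union
    shape = np.broadcast_shapes(zz.shape, yy.shape, xx.shape)
    out = np.zeros(shape, dtype=bool)
    for part in p["parts"]:
        out |= _voxelise(part, zz, yy, xx)
    return out


def _recipe_within_grid(recipe: StructureRecipe, spec: PhantomSpec) -> bool:
    """Cheap bound check: the solid's bounding box must touch the grid."""
    axes = _physical_axes(spec)
    lo = [a[0] - 0.5 * s for a, s in zip(axes, spec.spacing)]
    hi = [a[-1] + 0.5 * s for a, s in zip(axes, spec.spacing)]
    p = recipe.p
    if recipe.kind == "ellipsoid":
        bb_lo = [c - r for c, r in zip(p["center"], p["radii"])]
        bb_hi = [c + r for c, r in zip(p["center"], p["radii"])]
    elif recipe.kind == "tube":
        cy, cx = p["center"]
        r = p["radius"]
        bb_lo = [p["z_range"][0], cy - r, cx - r]
        bb_hi = [p["z_range"][1], cy + r, cx + r]
    elif recipe.kind == "shell_arc":
        cy, cx = p["center"]
        r = p["r_outer"]
        bb_lo = [p["z_range"][0], cy - r, cx - r]
        bb_hi = [p["z_range"][1], cy + r, cx + r]
    elif recipe.kind == "box":
        bb_lo, bb_hi = list(p["lo"]), list(p["hi"])
    else:
        return all(_recipe_within_grid(part, spec) for part in p["parts"])
    return all(bl >= l and bh <= h for bl, bh, l, h in zip(bb_lo, bb_hi, lo, hi))


def make_phantom(spec: PhantomSpec, seed: int = 0) -> dict[str, Mask3D]:
    """Voxelise every structure of a phantom spec (deterministic given spec).

    Raises :class:`GeometryError` if a recipe leaves the grid or voxelises to
    an empty mask, and checks declared containments voxelwise.
    """
    del seed  # deterministic solids; kept for interface symmetry
    axes = _physical_axes(spec)
    zz = axes[0][:, None, None]
    yy = axes[1][None, :, None]
    xx = axes[2][None, None, :]
    masks: dict[str, Mask3D] = {}
    for name, recipe in spec.structures.items():
        if not _recipe_within_grid(recipe, spec):
            raise GeometryError(f"recipe for {name!r} leaves the grid")
        data = _voxelise(recipe, zz, yy, xx)
        if not data.any():
            raise GeometryError(f"recipe for {name!r} voxelises to an empty mask")
        masks[name] = Mask3D(data, spec.spacing, spec.origin)
    for inner, outer in spec.containments:
        if np.any(masks[inner].data & ~masks[outer].data):
            raise GeometryError(f"containment violated: {inner} ⊄ {outer}")
    return masks


def default_head_neck_spec() -> PhantomSpec:
    """The bundled EORTC 1420-like benchmark phantom (15 structures).

    Layout on a 2 mm isotropic 100×80×80 grid (200×160×160 mm, z = cranio-
    caudal): an ipsilateral therapeutic PTV nested inside a larger
    prophylactic PTV; elongated midline swallowing structures (esophagus,
    constrictor shell, larynx tubes) hugging or flanking the target; compact
    glands (parotids, submandibular, thyroid wings) at lateral/caudal
    stand-off; mandible horseshoe and oral-cavity box cranially; cord and
    brainstem PRV tubes posteriorly.  Shapes are metric test-beds, not
    anatomy.
    """
    R = StructureRecipe.make
    tptv = R("ellipsoid", role="target", center=(100.0, 70.0, 100.0), radii=(20.0, 15.0, 15.0))
    structures = {
        "therapeutic_ptv": tptv,
        "prophylactic_ptv": R(
            "union", role="target",
            parts=(R("box", lo=(60.0, 45.0, 75.0), hi=(140.0, 95.0, 125.0)), tptv),
        ),
        "brainstem_prv": R("tube", center=(110.0, 80.0), radius=8.0, z_range=(155.0, 190.0)),
        "spinal_cord_prv": R("tube", center=(126.0, 80.0), radius=6.0, z_range=(10.0, 140.0)),
        "cervical_esophagus": R("tube", center=(95.0, 80.0), radius=5.0, z_range=(10.0, 60.0)),
        "cricopharyngeal_inlet": R("tube", center=(90.0, 80.0), radius=6.0, z_range=(60.0, 72.0)),
        "pharyngeal_constrictors": R(
            "shell_arc", center=(104.0, 80.0), r_inner=8.0, r_outer=12.0,
            z_range=(70.0, 130.0), half="posterior",
        ),
        "glottis": R("tube", center=(75.0, 80.0), radius=7.0, z_range=(30.0, 44.0)),
        "supraglottic_larynx": R("tube", center=(78.0, 80.0), radius=8.0, z_range=(46.0, 62.0)),
        "thyroid": R(
            "union",
            parts=(
                R("ellipsoid", center=(45.0, 80.0, 64.0), radii=(12.0, 8.0, 7.0)),
                R("ellipsoid", center=(45.0, 80.0, 96.0), radii=(12.0, 8.0, 7.0)),
            ),
        ),
        "mandible": R(
            "shell_arc", center=(60.0, 80.0), r_inner=28.0, r_outer=36.0,
            z_range=(150.0, 170.0), half="anterior",
        ),
        "extended_oral_cavity": R("box", lo=(125.0, 35.0, 55.0), hi=(160.0, 70.0, 105.0)),
        "ipsilateral_parotid": R("ellipsoid", center=(150.0, 75.0, 125.0), radii=(15.0, 12.0, 10.0)),
        "contralateral_parotid": R("ellipsoid", center=(150.0, 75.0, 35.0), radii=(15.0, 12.0, 10.0)),
        "contralateral_submandibular": R("ellipsoid", center=(115.0, 65.0, 38.0), radii=(10.0, 8.0, 7.0)),
    }
    return PhantomSpec(
        shape=(100, 80, 80),
        spacing=(2.0, 2.0, 2.0),
        origin=(0.0, 0.0, 0.0),
        structures=structures,
        containments=[("therapeutic_ptv", "prophylactic_ptv")],
    )


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------

_MODES = (
    "dilate", "erode", "translate", "crop_longitudinal",
    "extend_longitudinal", "boundary_noise", "omit_structure",
)


@dataclass(frozen=True)
class PerturbationSpec:
    """One controlled contouring error.

    ``magnitude`` is in millimetres (dilate/erode radius, translation length,
    longitudinal crop/extension) except for ``boundary_noise``, where it is
    the flip probability of a boundary-adjacent voxel; ``omit_structure``
    ignores it.  ``direction`` orients a translation (unit vector, (z,y,x)).
    """

    mode: str
    magnitude: float = 0.0
    seed: int = 0
    direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ConfigError(f"unknown perturbation mode {self.mode!r}")
        if self.magnitude < 0:
            raise ConfigError("perturbation magnitude must be >= 0")


def _ball(spacing: Sequence[float], radius_mm: float) -> np.ndarray:
    """Boolean spherical structuring element in physical mm."""
    n = [int(np.floor(radius_mm / s)) for s in spacing]
    z = np.arange(-n[0], n[0] + 1)[:, None, None] * spacing[0]
    y = np.arange(-n[1], n[1] + 1)[None, :, None] * spacing[1]
    x = np.arange(-n[2], n[2] + 1)[None, None, :] * spacing[2]
    return z**2 + y**2 + x**2 <= radius_mm**2 + 1e-9


def _shift(data: np.ndarray, shift_voxels: Sequence[int]) -> np.ndarray:
    out = np.zeros_like(data)
    src = []
    dst = []
    for ax, s in enumerate(shift_voxels):
        n = data.shape[ax]
        if abs(s) >= n:
            return out
        if s >= 0:
            src.append(slice(0, n - s))
            dst.append(slice(s, n))
        else:
            src.append(slice(-s, n))
            dst.append(slice(0, n + s))
    out[tuple(dst)] = data[tuple(src)]
    return out


def perturb_structure(gold: Mask3D, p: PerturbationSpec) -> Mask3D:
    """Apply one controlled perturbation to a gold-standard mask.

    Magnitude 0 is the identity for every mode except ``omit_structure``.
    Erosion may legally empty the mask (gross under-contouring); the caller
    sees the empty result and treats it as an absent structure.
    """
    if p.mode == "omit_structure":
        return gold.with_data(np.zeros(gold.shape, dtype=bool))
    if gold.is_empty:
        raise ConfigError("cannot perturb an empty gold mask")
    if p.magnitude == 0:
        return gold.with_data(gold.data.copy())

    if p.mode in ("dilate", "erode"):
        ball = _ball(gold.spacing, p.magnitude)
        op = ndimage.binary_dilation if p.mode == "dilate" else ndimage.binary_erosion
        return gold.with_data(op(gold.data, structure=ball))

    if p.mode == "translate":
        d = np.asarray(p.direction, dtype=float)
        norm = np.linalg.norm(d)
        if norm == 0:
            raise ConfigError("translate needs a non-zero direction")
        vec_mm = d / norm * p.magnitude
        shift = [int(round(v / s)) for v, s in zip(vec_mm, gold.spacing)]
        return gold.with_data(_shift(gold.data, shift))

    if p.mode in ("crop_longitudinal", "extend_longitudinal"):
        k = int(round(p.magnitude / gold.spacing[0]))
        if k == 0:
            return gold.with_data(gold.data.copy())
        occ = np.flatnonzero(gold.data.any(axis=(1, 2)))
        top = occ[-1]  # cranial end
        data = gold.data.copy()
        if p.mode == "crop_longitudinal":
            data[max(top - k + 1, 0):top + 1] = False
        else:
            template = gold.data[top]
            data[top + 1:min(top + 1 + k, gold.shape[0])] = template
        return gold.with_data(data)

    # boundary_noise
    prob = min(p.magnitude, 1.0)
    rng = np.random.default_rng(p.seed)
    interior = ndimage.binary_erosion(gold.data, border_value=0)
    surface = gold.data & ~interior
    ring = ndimage.binary_dilation(gold.data) & ~gold.data
    flips = (surface | ring) & (rng.random(gold.shape) < prob)
    return gold.with_data(gold.data ^ flips)


# ---------------------------------------------------------------------------
# analytic dose
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DosePrescription:
    """SIB prescription: therapeutic and elective dose levels plus a simple
    planner model (dose margin around the PTVs, exponential falloff)."""

    therapeutic_gy: float = 66.0
    elective_gy: float = 54.45
    falloff_mm: float = 8.0
    margin_mm: float = 5.0
    therapeutic_name: str = "therapeutic_ptv"
    prophylactic_name: str = "prophylactic_ptv"


def make_dose(
    structures: Mapping[str, Mask3D],
    prescription: DosePrescription = DosePrescription(),
) -> DoseGrid:
    """Analytic benchmark dose: prescription inside the (margin-expanded)
    therapeutic PTV, elective dose inside the prophylactic PTV, exponential
    falloff with distance outside.  Deterministic.
    """
    try:
        tptv = structures[prescription.therapeutic_name]
        pptv = structures[prescription.prophylactic_name]
    except KeyError as exc:
        raise ConfigError(f"prescription references missing PTV: {exc}") from exc
    margin = prescription.margin_mm
    spacing = tptv.spacing
    t_region = ndimage.binary_dilation(tptv.data, structure=_ball(spacing, margin)) if margin else tptv.data
    p_region = ndimage.binary_dilation(pptv.data, structure=_ball(spacing, margin)) if margin else pptv.data
    p_region = p_region | t_region
    dist = ndimage.distance_transform_edt(~p_region, sampling=spacing)
    dose = prescription.elective_gy * np.exp(-dist / prescription.falloff_mm)
    dose[t_region] = prescription.therapeutic_gy
    return DoseGrid(dose, tptv.spacing, tptv.origin)


def add_hotspot(
    dose: DoseGrid, center_mm: Sequence[float], radius_mm: float, peak_gy: float
) -> DoseGrid:
    """Raise the dose to ``peak_gy`` inside a sphere — a scripted planning error."""
    axes = [
        dose.origin[ax] + np.arange(dose.shape[ax]) * dose.spacing[ax] - center_mm[ax]
        for ax in range(3)
    ]
    r2 = axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2 + axes[2][None, None, :] ** 2
    data = dose.data.copy()
    inside = r2 <= radius_mm**2
    data[inside] = np.maximum(data[inside], peak_gy)
    return dose.with_data(data)


# ---------------------------------------------------------------------------
# cohort scripting
# ---------------------------------------------------------------------------

#: Per-structure unacceptable delineation deviation counts of the emulated
#: study (40 OAR + 27 target = 67; planning adds 9 for 76 in total).
DELINEATION_DEVIATION_COUNTS: dict[str, int] = {
    "prophylactic_ptv": 19,
    "pharyngeal_constrictors": 8,
    "therapeutic_ptv": 8,
    "mandible": 6,
    "cricopharyngeal_inlet": 5,
    "extended_oral_cavity": 5,
    "cervical_esophagus": 4,
    "brainstem_prv": 3,
    "glottis": 3,
    "spinal_cord_prv": 3,
    "supraglottic_larynx": 2,
    "contralateral_submandibular": 1,
}

N_PLANNING_DEVIATIONS = 9

#: Scripted error per structure, chosen so each trips exactly one review
#: criterion: longitudinal crops violate the HD threshold while leaving DSI
#: high (elongated organs), generous dilations violate the DSI threshold
#: while staying under the HD limit, and one structure is omitted entirely.
DEVIATION_MODES: dict[str, tuple[str, float]] = {
    "prophylactic_ptv": ("dilate", 10.0),
    "pharyngeal_constrictors": ("crop_longitudinal", 20.0),
    "therapeutic_ptv": ("dilate", 10.0),
    "mandible": ("dilate", 8.0),
    "cricopharyngeal_inlet": ("dilate", 10.0),
    "extended_oral_cavity": ("dilate", 10.0),
    "cervical_esophagus": ("crop_longitudinal", 18.0),
    "brainstem_prv": ("dilate", 8.0),
    "glottis": ("dilate", 10.0),
    "spinal_cord_prv": ("crop_longitudinal", 25.0),
    "supraglottic_larynx": ("dilate", 10.0),
    "contralateral_submandibular": ("omit_structure", 0.0),
}


@dataclass(frozen=True)
class RoundScript:
    """What one institution gets wrong in one scripted round."""

    bad_structures: tuple[str, ...] = ()
    include_dose: bool = False
    planning_bad: bool = False


def _allocate(counts: Mapping[str, int], capacities: list[int]) -> list[list[str]]:
    """Distribute structure deviation slots over institutions.

    Greedy: structures in descending count order, each occurrence to the
    institution with the most remaining capacity that does not already hold
    that structure.  Deterministic; raises if infeasible.
    """
    remaining = list(capacities)
    assigned: list[list[str]] = [[] for _ in capacities]
    for name in sorted(counts, key=lambda n: (-counts[n], n)):
        for _ in range(counts[name]):
            order = sorted(
                range(len(capacities)),
                key=lambda i: (-remaining[i], i),
            )
            for i in order:
                if remaining[i] > 0 and name not in assigned[i]:
                    assigned[i].append(name)
                    remaining[i] -= 1
                    break
            else:
                raise ConfigError(f"cannot place deviation slot for {name!r}")
    if any(remaining):
        raise ConfigError("unfilled deviation capacity in schedule")
    return assigned


def default_schedule(n_institutions: int = 35) -> list[list[RoundScript]]:
    """The scripted study schedule: who fails what, in which round.

    For the default 35 institutions: 12 clean single-round institutions;
    3 planning-only failures (2 rounds); 5 institutions with first-round
    delineation failures followed by a planning failure (3 rounds); one
    institution that introduces a new delineation error on resubmission and
    then fails planning (4 rounds); 14 institutions with first-round
    delineation failures only (2 rounds).  Other cohort sizes reuse the same
    35-institution pattern cyclically (counts then scale with n).
    """
    pattern = _schedule_35()
    if n_institutions == 35:
        return pattern
    return [pattern[i % 35] for i in range(n_institutions)]


def _schedule_35() -> list[list[RoundScript]]:
    # institutions 0-11 clean; 12-14 planning-only; 15-19 delineation+planning
    # (3 rounds); 20 the 4-round institution; 21-34 delineation-only.
    capacities = []
    delin_insts = []  # indices 15..34 except 20 handled separately
    for i in range(15, 35):
        if i == 20:
            continue
        delin_insts.append(i)
        capacities.append(4 if i in (15, 16, 17, 18, 19, 21, 22, 23) else 3)
    counts = dict(DELINEATION_DEVIATION_COUNTS)
    # the 4-round institution carries two single-structure failing rounds
    special = ["prophylactic_ptv", "therapeutic_ptv"]
    for s in special:
        counts[s] -= 1
    assigned = _allocate(counts, capacities)
    by_inst = dict(zip(delin_insts, assigned))

    schedule: list[list[RoundScript]] = []
    for i in range(35):
        if i < 12:
            schedule.append([RoundScript(include_dose=True)])
        elif i < 15:  # planning-only
            schedule.append(
                [
                    RoundScript(include_dose=True, planning_bad=True),
                    RoundScript(include_dose=True),
                ]
            )
        elif i == 20:  # two-stage delineation failure, then planning
            schedule.append(
                [
                    RoundScript(bad_structures=(special[0],)),
                    RoundScript(bad_structures=(special[1],)),
                    RoundScript(include_dose=True, planning_bad=True),
                    RoundScript(include_dose=True),
                ]
            )
        elif i < 20:  # delineation then planning (3 rounds)
            schedule.append(
                [
                    RoundScript(bad_structures=tuple(by_inst[i])),
                    RoundScript(include_dose=True, planning_bad=True),
                    RoundScript(include_dose=True),
                ]
            )
        else:  # delineation-only (2 rounds)
            schedule.append(
                [
                    RoundScript(bad_structures=tuple(by_inst[i])),
                    RoundScript(include_dose=True),
                ]
            )
    return schedule


@dataclass
class Cohort:
    """A fully materialised synthetic benchmark input set."""

    gold: dict[str, Mask3D]
    submissions: dict[str, list[RoundInput]]
    schedule: list[list[RoundScript]]
    prescription: DosePrescription
    seed: int


def _substream(seed: int, *keys) -> np.random.Generator:
    """Seeded substream keyed by institution/structure/round identifiers."""
    ints = [int(seed) % (2**31)]
    for k in keys:
        if isinstance(k, str):
            ints.append(zlib.crc32(k.encode()) % (2**31))
        else:
            ints.append(int(k) % (2**31))
    return np.random.default_rng(ints)


def make_cohort(
    n_institutions: int = 35,
    schedule: Optional[list[list[RoundScript]]] = None,
    seed: int = 0,
    spec: Optional[PhantomSpec] = None,
    prescription: DosePrescription = DosePrescription(),
) -> Cohort:
    """Generate a reproducible scripted benchmark cohort.

    Every institution contours with its own mild seeded boundary noise
    (flip probability 0.05–0.15, well inside the review thresholds); scripted
    bad structures replace the noise version in the scripted round with the
    structure's deviation-mode perturbation (magnitude jittered upward by as
    much as 25%); planning-bad rounds carry the clean analytic plan plus a
    hotspot on the spinal-cord PRV.  Identical seeds give identical cohorts.
    """
    spec = spec or default_head_neck_spec()
    schedule = schedule if schedule is not None else default_schedule(n_institutions)
    if len(schedule) != n_institutions:
        raise ConfigError("schedule length must match n_institutions")
    gold = make_phantom(spec)
    cord_center = _cord_hotspot_center(spec)

    submissions: dict[str, list[RoundInput]] = {}
    for idx in range(n_institutions):
        inst = f"INST-{idx + 1:02d}"
        noise_p = 0.05 + 0.10 * float(_substream(seed, inst, "style").random())
        final_contours = {
            name: perturb_structure(
                mask,
                PerturbationSpec(
                    "boundary_noise", noise_p,
                    seed=int(_substream(seed, inst, name, "noise").integers(2**31)),
                ),
            )
            for name, mask in gold.items()
        }
        falloff = prescription.falloff_mm * float(
            np.clip(1.0 + 0.05 * _substream(seed, inst, "plan").standard_normal(), 0.95, 1.05)
        )
        inst_rx = DosePrescription(
            therapeutic_gy=prescription.therapeutic_gy,
            elective_gy=prescription.elective_gy,
            falloff_mm=falloff,
            margin_mm=prescription.margin_mm,
            therapeutic_name=prescription.therapeutic_name,
            prophylactic_name=prescription.prophylactic_name,
        )
        clean_dose = None
        rounds: list[RoundInput] = []
        for script in schedule[idx]:
            structures = dict(final_contours)
            for name in script.bad_structures:
                mode, base_mag = DEVIATION_MODES[name]
                jitter = 1.0 + 0.25 * float(_substream(seed, inst, name, "dev").random())
                structures[name] = perturb_structure(
                    gold[name], PerturbationSpec(mode, base_mag * jitter)
                )
            dose = None
            if script.include_dose:
                if clean_dose is None:
                    clean_dose = make_dose(gold, inst_rx)
                dose = clean_dose
                if script.planning_bad:
                    dose = add_hotspot(clean_dose, cord_center, radius_mm=8.0, peak_gy=45.0)
            rounds.append(RoundInput(structures=structures, dose=dose))
        submissions[inst] = rounds
    return Cohort(gold, submissions, schedule, prescription, seed)


def _cord_hotspot_center(spec: PhantomSpec) -> tuple[float, float, float]:
    recipe = spec.structures.get("spinal_cord_prv")
    if recipe is None or recipe.kind != "tube":
        raise ConfigError("default planning deviation needs a spinal_cord_prv tube")
    p = recipe.p
    cy, cx = p["center"]
    z_lo, z_hi = p["z_range"]
    return (0.5 * (z_lo + z_hi), cy, cx)
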