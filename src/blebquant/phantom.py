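"""Synthetic orbital phantoms and simulated patient cohorts.

A phantom stands in for an MRI segmentation of an eye carrying a
glaucoma drainage implant: a spherical globe, a curved silicone plate
conforming to the sclera (a spherical-shell patch with fenestration
holes), an inner fluid bleb between globe and plate, and an outer bleb
on top of the plate.  Fibrotic strands growing through the fenestrations
are modelled by extending the inner bleb through the holes, so the two
blebs touch there by design; with ``merged=True`` the bleb shells are
additionally extended past the plate rim until they touch at the edges,
mimicking the "plate floating inside one large bleb" configuration.

Every phantom carries its ground truth: component volumes counted from
the generated voxels (exact by construction) and the analytic maximum
surface-to-surface extent of the complex along the plate axis, which is
what the height measurement estimates.

The cohort simulator draws per-patient morphometry from log-normal
volume distributions parameterized by group median and interquartile
range, with height following a cube-root link — volumes scale like a
length cubed — plus Gaussian noise, and clinical covariates drawn per
group.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .errors import MissingComponentError, ParameterError, SizingError
from .surface import COMPONENTS, LabelVolume, TriangleMesh, extract_surface

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "CohortSimSpec",
    "make_phantom",
    "phantom_to_meshes",
    "random_phantom_spec",
    "simulate_cohort",
]

_Z75 = 0.6744897501960817  # 75th percentile of the standard normal

#: Angular scale factor applied to the bleb patch when blebs merge past the rim.
_MERGE_SCALE = 1.25


# --------------------------------------------------------------------------
# specs and ground truth
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Geometry of one synthetic orbit.

    Lengths in mm, angles in degrees.  The globe sits at the grid center;
    the plate patch axis points ``plate_offset_angle`` away from the grid
    +z axis (rotated about y).  Defaults follow the imaging setup the
    pipeline targets: globe radius 11.5 mm and 0.4 mm reconstruction
    voxels.
    """

    globe_radius: float = 11.5
    plate_extent: Tuple[float, float, float] = (18.0, 18.0, 1.0)  # width, length, thickness
    plate_offset_angle: float = 0.0
    inner_bleb_thickness: float = 2.5
    outer_bleb_thickness: float = 1.5
    fenestration_count: int = 4
    fenestration_radius: float = 0.6
    merged: bool = False
    voxel_spacing: float = 0.4
    grid_shape: Tuple[int, int, int] = (96, 96, 96)
    seed: int = 0

    def __post_init__(self) -> None:
        lengths = (self.globe_radius, *self.plate_extent, self.inner_bleb_thickness,
                   self.outer_bleb_thickness, self.voxel_spacing)
        if any(v <= 0 for v in lengths):
            raise ParameterError("all phantom lengths must be positive")
        if self.fenestration_count < 0:
            raise ParameterError("fenestration_count must be >= 0")
        if self.fenestration_count > 0 and self.fenestration_radius <= 0:
            raise ParameterError("fenestration_radius must be positive")
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ParameterError("grid_shape must be 3 integers >= 8")
        need = self.outer_radius + 2.0  # complex plus 2 mm margin
        for ax, n in enumerate(self.grid_shape):
            half = (int(n) - 1) / 2 * self.voxel_spacing
            if half < need:
                raise SizingError(
                    f"grid axis {ax} spans ±{half:.1f} mm but the phantom needs "
                    f"±{need:.1f} mm (complex radius + 2 mm margin)"
                )

    # derived radii of the concentric construction
    @property
    def inner_radius(self) -> float:
        """Outer radius of the inner bleb = inner radius of the plate."""
        return self.globe_radius + self.inner_bleb_thickness

    @property
    def plate_outer_radius(self) -> float:
        return self.inner_radius + self.plate_extent[2]

    @property
    def outer_radius(self) -> float:
        """Outer radius of the outer bleb (full complex extent)."""
        return self.plate_outer_radius + self.outer_bleb_thickness

    @property
    def patch_half_angles(self) -> Tuple[float, float]:
        """Angular half-extents (radians) of the plate patch (width, length)."""
        r_mid = self.inner_radius + self.plate_extent[2] / 2
        return (self.plate_extent[0] / 2 / r_mid, self.plate_extent[1] / 2 / r_mid)


@dataclass
class PhantomGroundTruth:
    """Construction-derived truth for one phantom (volumes mm³, height mm)."""

    volume_inner: float
    volume_outer: float
    volume_plate: float
    volume_total: float
    height: float
    merged: bool
    height_apex: float = 0.0
    globe_center: Tuple[float, float, float] = (0.0, 0.0, 0.0)
    fenestration_axes: Tuple[Tuple[float, float, float], ...] = ()
    fenestration_radius: float = 0.0

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


# --------------------------------------------------------------------------
# phantom construction
# --------------------------------------------------------------------------


def _patch_frame(offset_deg: float) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Orthonormal frame (axis, e_u, e_v) of the plate patch."""
    t = np.deg2rad(offset_deg)
    axis = np.array([np.sin(t), 0.0, np.cos(t)])
    e_u = np.array([np.cos(t), 0.0, -np.sin(t)])
    e_v = np.array([0.0, 1.0, 0.0])
    return axis, e_u, e_v


def _fenestration_dirs(spec: PhantomSpec) -> np.ndarray:
    """Unit radial axes of the fenestration cylinders (k, 3)."""
    axis, e_u, e_v = _patch_frame(spec.plate_offset_angle)
    aw, al = spec.patch_half_angles
    if spec.fenestration_count == 0:
        return np.zeros((0, 3))
    theta = 2 * np.pi * np.arange(spec.fenestration_count) / spec.fenestration_count
    bu = 0.5 * aw * np.cos(theta)
    bv = 0.5 * al * np.sin(theta)
    dirs = (np.outer(np.cos(np.hypot(bu, bv)), axis)
            + np.outer(np.sin(bu), e_u) + np.outer(np.sin(bv), e_v))
    return dirs / np.linalg.norm(dirs, axis=1, keepdims=True)


def make_phantom(spec: PhantomSpec) -> Tuple[LabelVolume, PhantomGroundTruth]:
    """Generate the label map and ground truth for one phantom.

    The construction is deterministic and purely analytic (no noise):
    a voxel's label is decided by its center's radius from the globe
    center and its angular position relative to the plate patch axis.
    """
    h = spec.voxel_spacing
    shape = tuple(int(n) for n in spec.grid_shape)
    center = np.zeros(3)
    axes = [(np.arange(n, dtype=np.float32) - (n - 1) / 2) * h for n in shape]
    origin = tuple(float(a[0]) for a in axes)

    R0, R1 = spec.globe_radius, spec.inner_radius
    R2, R3 = spec.plate_outer_radius, spec.outer_radius
    aw, al = spec.patch_half_angles
    scale = _MERGE_SCALE if spec.merged else 1.0

    r2grid = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
              + axes[2][None, None, :] ** 2)
    vox = np.zeros(shape, dtype=np.int16)
    lm = dict(COMPONENTS)
    vox[r2grid <= R0 * R0] = lm["globe"]

    # the complex lives in the spherical shell (R0, R3]; restrict the
    # angular computations to those voxels (a small fraction of the grid)
    shell = np.argwhere((r2grid > R0 * R0) & (r2grid <= R3 * R3))
    del r2grid
    pts = (shell * h + np.array(origin, dtype=np.float32)).astype(np.float32)
    axis, e_u, e_v = _patch_frame(spec.plate_offset_angle)
    px = pts @ axis.astype(np.float32)
    pu = pts @ e_u.astype(np.float32)
    pv = pts @ e_v.astype(np.float32)
    r = np.linalg.norm(pts, axis=1)

    with np.errstate(invalid="ignore", divide="ignore"):
        ell = (np.arctan2(pu, px) / aw) ** 2 + (np.arctan2(pv, px) / al) ** 2
    ell[px <= 0] = np.inf
    in_plate_patch = ell <= 1.0
    in_bleb_patch = ell <= scale * scale

    lab = np.zeros(len(shell), dtype=np.int16)
    inner_shell = (r <= R1) & in_bleb_patch
    lab[inner_shell] = lm["inner_bleb"]
    plate_band = (r > R1) & (r <= R2)
    lab[plate_band & in_plate_patch] = lm["plate"]
    outer_shell = (r > R2) & in_bleb_patch
    lab[outer_shell] = lm["outer_bleb"]

    # fenestration holes: remove plate, grow an inner-bleb strand through
    fen_dirs = _fenestration_dirs(spec)
    for d in fen_dirs:
        proj = pts @ d.astype(np.float32)
        dist2 = np.maximum(r * r - proj * proj, 0.0)
        cyl = (dist2 <= spec.fenestration_radius ** 2) & (proj > 0) & plate_band
        lab[cyl] = lm["inner_bleb"]

    if spec.merged:
        # past the plate rim the blebs meet: fill the plate-thickness band
        rim = plate_band & in_bleb_patch & ~in_plate_patch
        r_mid = (R1 + R2) / 2
        lab[rim & (r <= r_mid)] = lm["inner_bleb"]
        lab[rim & (r > r_mid)] = lm["outer_bleb"]

    keep = lab > 0
    vox[tuple(shell[keep].T)] = lab[keep]
    vol = LabelVolume(vox, (h, h, h), origin=origin, label_map=lm)

    voxv = float(h ** 3)
    v_inner = float(np.count_nonzero(vox == lm["inner_bleb"])) * voxv
    v_outer = float(np.count_nonzero(vox == lm["outer_bleb"])) * voxv
    v_plate = float(np.count_nonzero(vox == lm["plate"])) * voxv
    gt = PhantomGroundTruth(
        volume_inner=v_inner,
        volume_outer=v_outer,
        volume_plate=v_plate,
        volume_total=v_inner + v_outer + v_plate,
        height=_analytic_max_span(spec),
        merged=spec.merged,
        height_apex=R3 - R0,
        globe_center=tuple(center),
        fenestration_axes=tuple(tuple(float(x) for x in d) for d in fen_dirs),
        fenestration_radius=spec.fenestration_radius if len(fen_dirs) else 0.0,
    )
    return vol, gt


def _analytic_max_span(spec: PhantomSpec, n_d: int = 2000, n_phi: int = 73) -> float:
    """Largest outer-to-inner surface extent along the patch axis.

    For a column at lateral offset ``d`` from the patch axis, the top of
    the outer bleb lies on the sphere of radius R3 and the bottom of the
    inner bleb on the globe sphere (or on the patch cone once the column
    leaves the globe cap), so the extent is available in closed form;
    the maximum over columns is found numerically on a fine grid.
    """
    R0, R1, R3 = spec.globe_radius, spec.inner_radius, spec.outer_radius
    aw, al = spec.patch_half_angles
    scale = _MERGE_SCALE if spec.merged else 1.0
    best = 0.0
    for phi in np.linspace(0, np.pi / 2, n_phi):
        inv2 = (np.cos(phi) / (scale * aw)) ** 2 + (np.sin(phi) / (scale * al)) ** 2
        ab = 1.0 / np.sqrt(inv2)  # effective bleb half-angle along this azimuth
        d_hi = min(R1 * np.sin(ab), R3 * np.sin(ab))
        d = np.linspace(0, d_hi * 0.999999, n_d)
        z_top = np.sqrt(np.maximum(R3 * R3 - d * d, 0.0))
        z_bot = np.where(
            d <= R0 * np.sin(ab),
            np.sqrt(np.maximum(R0 * R0 - d * d, 0.0)),
            d / np.tan(ab),
        )
        best = max(best, float(np.max(z_top - z_bot)))
    return best


def phantom_to_meshes(vol: LabelVolume) -> Dict[str, TriangleMesh]:
    """Extract one closed surface per phantom component.

    Raises
    ------
    MissingComponentError
        if any of the four components is absent from the label map.
    """
    meshes: Dict[str, TriangleMesh] = {}
    for comp in ("globe", "plate", "inner_bleb", "outer_bleb"):
        if not vol.mask(comp).any():
            raise MissingComponentError(f"phantom is missing component '{comp}'")
        meshes[comp] = extract_surface(vol, comp, largest_only=True)
    return meshes


def random_phantom_spec(seed: int, merged_probability: float = 0.2,
                        spacing: float = 0.4) -> PhantomSpec:
    """Draw a plausibly varied phantom geometry (for recovery studies).

    Globe radius, bleb thicknesses, plate extent and patch orientation
    vary over anatomically reasonable ranges; the grid is sized to fit
    the sampled geometry with the required 2 mm margin.  ``spacing``
    sets the generation voxel size (recovery studies match it to the
    analysis resolution so construction quantization does not dominate).
    """
    rng = np.random.default_rng(seed)
    globe = rng.uniform(10.5, 12.5)
    t_in = rng.uniform(1.5, 3.5)
    t_out = rng.uniform(1.0, 2.5)
    t_plate = rng.uniform(0.8, 1.2)
    extent = rng.uniform(14.0, 20.0)
    r3 = globe + t_in + t_plate + t_out
    n = int(np.ceil(2 * (r3 + 2.2) / spacing)) | 1  # odd: voxel center at origin
    return PhantomSpec(
        globe_radius=round(globe, 2),
        plate_extent=(round(extent, 1), round(extent * rng.uniform(0.8, 1.0), 1), round(t_plate, 2)),
        plate_offset_angle=round(rng.uniform(0.0, 30.0), 1),
        inner_bleb_thickness=round(t_in, 2),
        outer_bleb_thickness=round(t_out, 2),
        merged=bool(rng.random() < merged_probability),
        voxel_spacing=spacing,
        grid_shape=(n, n, n),
        seed=seed,
    )


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------


@dataclass
class CohortSimSpec:
    """Parameters of the two-group cohort simulator.

    Defaults reproduce the study population this pipeline targets:
    12 diplopia vs 18 control patients, log-normal complex volumes with
    the groups' median/IQR, and group-specific visual-field and duction
    restriction distributions.  Tuples are (diplopia, control).
    """

    n_diplopia: int = 12
    n_control: int = 18
    volume_median_by_group: Tuple[float, float] = (1023.3, 804.6)
    volume_iqr_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (875.7, 1750.5), (755.1, 923.4))
    height_median_by_group: Tuple[float, float] = (5.3, 4.6)
    md_distribution_by_group: Tuple[Tuple[float, float], Tuple[float, float]] = (
        (-6.9, 4.5), (-12.17, 4.5))
    restriction_probability_by_group: Tuple[float, float] = (10 / 12, 6 / 18)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_diplopia < 1 or self.n_control < 1:
            raise ParameterError("group sizes must be >= 1")
        for m in self.volume_median_by_group + self.height_median_by_group:
            if m <= 0:
                raise ParameterError("medians must be positive")
        for lo, hi in self.volume_iqr_by_group:
            if lo <= 0 or hi <= 0:
                raise ParameterError("IQR bounds must be positive")
            if lo >= hi:
                raise ParameterError(f"infeasible IQR: lower {lo} >= upper {hi}")
        for p in self.restriction_probability_by_group:
            if not 0 <= p <= 1:
                raise ParameterError("restriction probabilities must lie in [0, 1]")


# group-specific covariate parameters (diplopia, control): plain conventions
# chosen to mirror the target population's baseline table.
_AGE = ((66.5, 9.0), (67.8, 7.4))
_IOP = {
    "iop_pre": ((21.9, 7.3), (20.4, 5.0)),
    "iop_6wk": ((17.7, 8.1), (15.5, 7.7)),
    "iop_3mo": ((17.1, 5.3), (16.8, 6.7)),
    "iop_mri": ((13.4, 4.0), (11.3, 2.3)),
}
_MD_FELLOW = ((-3.0, 3.0), (-3.5, 3.0))
_P_MALE = (7 / 12, 10 / 18)
_P_OD = (4 / 12, 12 / 18)
_P_FREE_PLATE = (7 / 12, 8 / 18)
_TIME_SURGERY = ((3.6, 1.4), (5.3, 2.9))
_P_MERGED = (4 / 12, 2 / 18)
_P_STRANDS = (0.75, 0.88)
_P_EXTRA_FLUID = (1 / 12, 8 / 18)
_INNER_FRACTION = (0.68, 0.56)  # inner bleb share of the non-plate volume
_PLATE_VOLUME = (280.0, 25.0)   # mm³, implant plate is the same device in all eyes
_HEIGHT_NOISE_SD = 0.3          # mm


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Draw a per-patient cohort table with the spec's group structure.

    Total complex volume is log-normal with ``exp(mu)`` at the group
    median and ``sigma`` solving the interquartile ratio,
    ``sigma = ln(q3/q1) / (2 z_0.75)``; height follows the cube-root
    link calibrated so the group's median volume maps to its median
    height.  The same seed always yields the identical table.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g, (label, n) in enumerate((("diplopia", spec.n_diplopia), ("control", spec.n_control))):
        med = spec.volume_median_by_group[g]
        q1, q3 = spec.volume_iqr_by_group[g]
        sigma = np.log(q3 / q1) / (2 * _Z75)
        total = rng.lognormal(np.log(med), sigma, n)

        plate = np.clip(rng.normal(*_PLATE_VOLUME, n), 150.0, 0.5 * total)
        rest = total - plate
        f = _INNER_FRACTION[g]
        frac = rng.beta(f * 12, (1 - f) * 12, n)
        inner = rest * frac
        outer = rest - inner

        c = spec.height_median_by_group[g] / med ** (1 / 3)
        height = np.maximum(c * total ** (1 / 3) + rng.normal(0, _HEIGHT_NOISE_SD, n), 1.0)

        restricted = rng.random(n) < spec.restriction_probability_by_group[g]
        restriction_total = np.where(
            restricted,
            np.maximum(10.0, 15.0 + 25.0 * (total - med) / med + rng.normal(0, 10.0, n)),
            0.0,
        )
        md_loc, md_scale = spec.md_distribution_by_group[g]
        frames.append(pd.DataFrame({
            "id": [f"sim{g}{i:03d}" for i in range(n)],
            "diplopia": bool(g == 0),
            "eye": np.where(rng.random(n) < _P_OD[g], "OD", "OS"),
            "age": np.clip(rng.normal(*_AGE[g], n), 40, 90).round(1),
            "sex": np.where(rng.random(n) < _P_MALE[g], "M", "F"),
            "volume_inner": inner.round(1),
            "volume_outer": outer.round(1),
            "volume_plate": plate.round(1),
            "volume_total": (inner.round(1) + outer.round(1) + plate.round(1)),
            "height": height.round(2),
            "merged": rng.random(n) < _P_MERGED[g],
            "md_study": rng.normal(md_loc, md_scale, n).round(1),
            "md_fellow": rng.normal(*_MD_FELLOW[g], n).round(1),
            "iop_pre": np.clip(rng.normal(*_IOP["iop_pre"][g], n), 5, None).round(0),
            "iop_6wk": np.clip(rng.normal(*_IOP["iop_6wk"][g], n), 5, None).round(0),
            "iop_3mo": np.clip(rng.normal(*_IOP["iop_3mo"][g], n), 5, None).round(0),
            "iop_mri": np.clip(rng.normal(*_IOP["iop_mri"][g], n), 5, None).round(0),
            "restricted": restricted,
            "restriction_total": restriction_total.round(0),
            "strands_visible": rng.random(n) < _P_STRANDS[g],
            "extra_fluid": rng.random(n) < _P_EXTRA_FLUID[g],
            "surgical_technique": np.where(rng.random(n) < _P_FREE_PLATE[g], "free", "sutured"),
            "time_since_surgery": np.clip(rng.normal(*_TIME_SURGERY[g], n), 1.5, 12).round(1),
        }))
    cohort = pd.concat(frames, ignore_index=True)
    cohort["large_bleb"] = cohort["volume_total"] > 1100.0
    return cohort
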