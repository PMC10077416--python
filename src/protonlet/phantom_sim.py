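"""Analytical water phantom and proton-beam simulator.

Produces per-beam physical-dose and dose-averaged-LET voxel grids with the
structure of Monte-Carlo scored grids, without particle transport: the
phantom is uniform water inside the body contour, depth is the geometric
path length from the body surface along the beam axis, and each energy
layer contributes a parametric pristine Bragg curve.

Depth dose is a pseudo-Bortfeld shape: a slowly rising power-law plateau
(∝ 1/(R − z)^0.23) blended into a Gaussian peak at the residual range R,
with a Gaussian distal falloff whose width is the range-straggling sigma.
Depth LET starts at a plateau value (~1–2 keV/μm), rises as
1/(R − z + softening) toward the end of range and is capped — reproducing
the sharp distal LET enhancement that drives variable-RBE effects.

Spread-out Bragg peaks are built by non-negative least squares on the layer
weights to flatten the summed depth dose across the target depth interval.
Energy layers of one beam are combined with the same dose-weighted LET
mixing rule used for combining beams (see :mod:`protonlet.let_ops`).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage
from scipy.optimize import nnls

from . import let_ops
from .grids import StructureMask, VoxelGrid
from .rbe_models import FractionationScheme

__all__ = [
    "DepthCurveParams",
    "BeamSpec",
    "Phantom",
    "PlanDose",
    "pristine_peak_dose",
    "pristine_peak_let",
    "build_sobp",
    "plan_beam",
    "compute_beam_dose_let",
    "assemble_plan",
    "build_phantom",
]

#: exponent of the proximal power-law fluence/stopping rise
_PLATEAU_EXPONENT = 0.23


@dataclass(frozen=True)
class DepthCurveParams:
    """Parameters of the pristine depth-dose and depth-LET curves.

    plateau_dose
        Entrance dose relative to the Bragg-peak maximum (unitless).
    peak_width_mm
        Proximal width of the peak region; also used as the power-law
        softening so the plateau stays finite at the peak.
    straggling_sigma_mm
        Sigma of the Gaussian distal falloff (range straggling).
    let_plateau
        Dose-averaged LET in the entrance plateau [keV/μm].
    let_scale
        Strength of the 1/(R−z) LET rise [keV/μm·mm].
    let_softening_mm
        Softening length keeping the LET finite at z = R.
    let_cap
        Upper clip for LET [keV/μm]; also the value held beyond the range.
    """

    plateau_dose: float = 0.36
    peak_width_mm: float = 6.0
    straggling_sigma_mm: float = 3.0
    let_plateau: float = 1.2
    let_scale: float = 20.0
    let_softening_mm: float = 2.0
    let_cap: float = 15.0

    def __post_init__(self) -> None:
        if self.let_plateau < 0:
            raise ValueError("let_plateau must be >= 0")
        if self.let_cap <= self.let_plateau:
            raise ValueError("let_cap must exceed let_plateau")
        if self.straggling_sigma_mm <= 0:
            raise ValueError("straggling_sigma_mm must be positive")
        if self.peak_width_mm <= 0 or self.let_softening_mm <= 0:
            raise ValueError("peak_width_mm and let_softening_mm must be positive")
        if not 0 < self.plateau_dose < 1:
            raise ValueError("plateau_dose is relative to the peak and must be in (0, 1)")


@dataclass
class BeamSpec:
    """One treatment field: gantry angle, energy layers and aperture.

    ``angle_deg`` is the gantry angle in the axial plane with 0° anterior;
    the beam travels from the source through the isocenter (no couch kick).
    ``layer_ranges`` are residual ranges in mm water, strictly increasing;
    ``layer_weights`` are the non-negative SOBP weights.
    """

    angle_deg: float
    layer_ranges: np.ndarray
    layer_weights: np.ndarray
    aperture_margin_mm: float = 12.0
    penumbra_sigma_mm: float = 5.0

    def __post_init__(self) -> None:
        self.angle_deg = float(self.angle_deg) % 360.0
        self.layer_ranges = np.asarray(self.layer_ranges, dtype=np.float64)
        self.layer_weights = np.asarray(self.layer_weights, dtype=np.float64)
        if self.layer_ranges.ndim != 1 or self.layer_ranges.size == 0:
            raise ValueError("layer_ranges must be a non-empty 1-D sequence")
        if np.any(np.diff(self.layer_ranges) <= 0):
            raise ValueError("layer_ranges must be strictly increasing")
        if self.layer_weights.shape != self.layer_ranges.shape:
            raise ValueError("layer_weights must match layer_ranges")
        if np.any(self.layer_weights < 0):
            raise ValueError("layer_weights must be non-negative")


@dataclass
class Phantom:
    """Synthetic water phantom: body contour, CTV and named OAR masks."""

    grid_shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    body_mask: np.ndarray
    ctv_mask: np.ndarray
    oar_masks: dict[str, StructureMask] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.body_mask = np.asarray(self.body_mask, dtype=bool)
        self.ctv_mask = np.asarray(self.ctv_mask, dtype=bool)
        if self.body_mask.shape != tuple(self.grid_shape):
            raise ValueError("body_mask shape does not match grid_shape")
        if np.any(self.ctv_mask & ~self.body_mask):
            raise ValueError("ctv_mask must lie inside body_mask")
        for name, sm in self.oar_masks.items():
            if np.any(sm.mask & ~self.body_mask):
                raise ValueError(f"OAR {name!r} must lie inside body_mask")

    @property
    def voxel_volume_cc(self) -> float:
        return math.prod(self.spacing) / 1000.0

    def structure(self, name: str) -> StructureMask:
        """Mask for ``name``; ``body`` and ``ctv`` resolve to those masks."""
        if name == "body":
            return StructureMask("body", self.body_mask, self.spacing)
        if name == "ctv":
            return StructureMask("ctv", self.ctv_mask, self.spacing)
        return self.oar_masks[name]

    def structure_names(self) -> list[str]:
        return ["body", "ctv", *self.oar_masks.keys()]

    def empty_grid(self, quantity: str = "dose_Gy") -> VoxelGrid:
        return VoxelGrid(np.zeros(self.grid_shape), self.spacing, self.origin, quantity)


@dataclass
class PlanDose:
    """Per-beam dose and LET grids of one plan plus the prescription."""

    beams: list[BeamSpec]
    beam_doses: list[VoxelGrid]
    beam_lets: list[VoxelGrid]
    prescription: FractionationScheme

    def composite_dose(self) -> VoxelGrid:
        """Sum of the per-beam physical-dose grids."""
        total = np.zeros(self.beam_doses[0].shape)
        for g in self.beam_doses:
            total += g.values
        return self.beam_doses[0].like(total, provenance="composite")

    def mixed_let(self) -> VoxelGrid:
        """Relative-dose-weighted composite LET (unthresholded)."""
        return let_ops.mix_let(list(zip(self.beam_doses, self.beam_lets)))


# ---------------------------------------------------------------------------
# pristine curves


def _validate_depth(depth, range_R: float) -> np.ndarray:
    z = np.asarray(depth, dtype=np.float64)
    if np.any(z < 0):
        raise ValueError("depth must be non-negative")
    if range_R <= 0:
        raise ValueError("range_R must be positive")
    return z


def pristine_peak_dose(depth, range_R: float, p: DepthCurveParams = DepthCurveParams()):
    """Relative dose of a pristine Bragg peak at water depth ``depth`` mm.

    Normalised to 1 at the peak (z = R): a power-law plateau blended into a
    Gaussian peak proximally, a Gaussian of the straggling sigma distally.
    """
    z = _validate_depth(depth, range_R)
    w = p.peak_width_mm
    sigma_peak = 0.5 * w
    plateau = p.plateau_dose * ((range_R + w) / (np.clip(range_R - z, 0.0, None) + w)) ** _PLATEAU_EXPONENT
    plateau = np.minimum(plateau, 0.98)
    blend = np.exp(-0.5 * ((range_R - z) / sigma_peak) ** 2)
    proximal = plateau * (1.0 - blend) + blend
    distal = np.exp(-0.5 * ((z - range_R) / p.straggling_sigma_mm) ** 2)
    out = np.where(z <= range_R, proximal, distal)
    return out if out.ndim else float(out)


def pristine_peak_let(depth, range_R: float, p: DepthCurveParams = DepthCurveParams()):
    """Dose-averaged LET [keV/μm] of a pristine peak at depth ``depth`` mm.

    Anchored to ``let_plateau`` at the surface, rising as
    1/(R − z + softening) toward the end of range, clipped at ``let_cap``
    and held there beyond the range where only the straggling tail of the
    dose remains.
    """
    z = _validate_depth(depth, range_R)
    zc = np.minimum(z, range_R)
    soft = p.let_softening_mm
    base = p.let_plateau + p.let_scale * (1.0 / (range_R - zc + soft) - 1.0 / (range_R + soft))
    out = np.where(z <= range_R, np.minimum(base, p.let_cap), p.let_cap)
    return out if out.ndim else float(out)


def build_sobp(
    target_interval: tuple[float, float],
    layer_ranges: Sequence[float],
    p: DepthCurveParams = DepthCurveParams(),
    ripple_tol: float = 0.03,
    grid_step_mm: float = 0.5,
) -> np.ndarray:
    """Non-negative layer weights flattening the summed dose over a depth interval.

    Solves ``min ||A w − 1||`` with w ≥ 0 where A holds the pristine curves
    sampled on a fine depth grid across ``target_interval``.  Warns (and
    still returns the best-achievable weights) when the residual ripple
    max/min exceeds ``1 + ripple_tol``.
    """
    a, b = float(target_interval[0]), float(target_interval[1])
    ranges = np.asarray(layer_ranges, dtype=np.float64)
    if a > b:
        raise ValueError("target interval must have a <= b")
    if a < ranges.min() - p.peak_width_mm or b > ranges.max() + p.peak_width_mm:
        raise ValueError("target interval is not covered by the layer ranges")
    zs = np.arange(a, b + 1e-9, grid_step_mm)
    if zs.size == 0:
        zs = np.array([a])
    A = np.stack([pristine_peak_dose(zs, R, p) for R in ranges], axis=1)
    weights, _ = nnls(A, np.ones(zs.size))
    profile = A @ weights
    lo = float(profile.min())
    ripple = float(profile.max()) / lo if lo > 0 else np.inf
    if ripple > 1.0 + ripple_tol:
        warnings.warn(
            f"SOBP flatness not achievable: ripple {ripple:.3f} over target "
            f"[{a:.1f}, {b:.1f}] mm; returning best-fit weights",
            stacklevel=2,
        )
    return weights


# ---------------------------------------------------------------------------
# beam geometry


def beam_direction(angle_deg: float) -> tuple[float, float]:
    """Unit travel direction (ux, uy) in the axial plane; 0° enters anteriorly."""
    g = math.radians(angle_deg % 360.0)
    return math.sin(g), math.cos(g)


@dataclass
class _BeamFrame:
    """Per-voxel depth and ray indexing for one beam through a phantom."""

    depth: np.ndarray        # mm from body entry along the beam; <0 before entry
    sbin: np.ndarray         # (nx, ny) lateral ray-bin index
    nbins: int
    ds: float                # lateral bin width, mm


def _beam_frame(phantom: Phantom, angle_deg: float) -> _BeamFrame:
    nx, ny, nz = phantom.grid_shape
    sx, sy, sz = phantom.spacing
    ux, uy = beam_direction(angle_deg)
    xs = phantom.origin[0] + (np.arange(nx) + 0.5) * sx
    ys = phantom.origin[1] + (np.arange(ny) + 0.5) * sy
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    T = X * ux + Y * uy                       # along-beam coordinate
    S = -X * uy + Y * ux                      # lateral coordinate
    ds = min(sx, sy)
    sbin = np.round(S / ds).astype(np.int64)
    sbin -= sbin.min()
    nbins = int(sbin.max()) + 1

    # entry T per (lateral bin, z-slice): minimum T over body voxels on the ray
    entry = np.full(nbins * nz, np.inf)
    body = phantom.body_mask
    ix, iy, iz = np.nonzero(body)
    np.minimum.at(entry, sbin[ix, iy] * nz + iz, T[ix, iy])
    entry = entry.reshape(nbins, nz)

    depth = T[:, :, None] - entry[sbin, :]    # (nx, ny, nz); NaN/inf off-body rays
    depth = np.where(np.isfinite(depth), depth, -1.0)
    return _BeamFrame(depth=depth, sbin=sbin, nbins=nbins, ds=ds)


def _lateral_profile(phantom: Phantom, beam: BeamSpec, frame: _BeamFrame) -> np.ndarray:
    """Aperture × penumbra weight per voxel: smoothed projected-CTV box."""
    nz = phantom.grid_shape[2]
    sz = phantom.spacing[2]
    footprint = np.zeros((frame.nbins, nz), dtype=bool)
    ix, iy, iz = np.nonzero(phantom.ctv_mask)
    footprint[frame.sbin[ix, iy], iz] = True
    if not footprint.any():
        raise ValueError("CTV does not project into the beam's lateral frame")

    m_s = max(1, round(beam.aperture_margin_mm / frame.ds))
    m_z = max(1, round(beam.aperture_margin_mm / sz))
    aperture = ndimage.binary_dilation(footprint, structure=np.ones((2 * m_s + 1, 2 * m_z + 1)))
    sig_s = beam.penumbra_sigma_mm / frame.ds
    sig_z = beam.penumbra_sigma_mm / sz
    lateral = ndimage.gaussian_filter(aperture.astype(np.float64), sigma=(sig_s, sig_z),
                                      mode="constant")
    # hard cutoff at aperture + 3 penumbra sigma
    c_s = m_s + max(1, round(3 * beam.penumbra_sigma_mm / frame.ds))
    c_z = m_z + max(1, round(3 * beam.penumbra_sigma_mm / sz))
    cutoff = ndimage.binary_dilation(footprint, structure=np.ones((2 * c_s + 1, 2 * c_z + 1)))
    lateral[~cutoff] = 0.0
    return lateral[frame.sbin, :]             # (nx, ny, nz)


def compute_beam_dose_let(
    phantom: Phantom,
    beam: BeamSpec,
    p: DepthCurveParams = DepthCurveParams(),
) -> tuple[VoxelGrid, VoxelGrid]:
    """Per-beam dose [Gy, unnormalised] and dose-averaged-LET [keV/μm] grids.

    Voxel dose is the SOBP sum of weighted pristine curves at the voxel's
    water-equivalent depth times the lateral aperture/penumbra profile;
    voxel LET is the dose-weighted mix of the pristine layer LETs.  Voxels
    outside the body, before the entry surface, or beyond the aperture plus
    three penumbra sigmas receive zero dose (and LET 0 by convention).
    """
    frame = _beam_frame(phantom, beam.angle_deg)
    depth = np.clip(frame.depth, 0.0, None)
    inside = phantom.body_mask & (frame.depth >= 0)

    def layer_pairs():
        for R, w in zip(beam.layer_ranges, beam.layer_weights):
            if w <= 0:
                continue
            yield w * pristine_peak_dose(depth, R, p), pristine_peak_let(depth, R, p)

    pairs = list(layer_pairs())
    if not pairs:
        raise ValueError("beam has no positive layer weights")
    sobp_dose = np.zeros_like(depth)
    for d_k, _ in pairs:
        sobp_dose += d_k
    let = let_ops.mix_let_arrays(pairs)

    dose = sobp_dose * _lateral_profile(phantom, beam, frame)
    dose[~inside] = 0.0
    if not np.any(dose > 0):
        raise ValueError(f"beam at {beam.angle_deg}° does not deposit dose in the phantom")
    let = np.where(dose > 0, let, 0.0)

    geom = dict(spacing=phantom.spacing, origin=phantom.origin)
    tag = f"beam@{beam.angle_deg:g}deg"
    return (
        VoxelGrid(dose, quantity="dose_Gy", provenance=tag, **geom),
        VoxelGrid(let, quantity="let_keVum", provenance=tag, **geom),
    )


def plan_beam(
    phantom: Phantom,
    angle_deg: float,
    p: DepthCurveParams = DepthCurveParams(),
    layer_spacing_mm: float = 3.0,
    range_margin_mm: float = 3.0,
    aperture_margin_mm: float = 12.0,
    penumbra_sigma_mm: float = 5.0,
) -> BeamSpec:
    """Design a field at ``angle_deg``: layers spanning the CTV depth extent.

    The SOBP target interval is the CTV's depth range along this beam,
    expanded by ``range_margin_mm`` proximally and distally, with layers
    every ``layer_spacing_mm`` and weights from :func:`build_sobp`.
    """
    frame = _beam_frame(phantom, angle_deg)
    ctv_depth = frame.depth[phantom.ctv_mask]
    if ctv_depth.size == 0 or np.all(ctv_depth < 0):
        raise ValueError("CTV is not traversed by this beam")
    a = max(float(ctv_depth.min()) - range_margin_mm, layer_spacing_mm)
    b = float(ctv_depth.max()) + range_margin_mm
    ranges = np.arange(a, b + layer_spacing_mm, layer_spacing_mm)
    weights = build_sobp((a, b), ranges, p)
    return BeamSpec(angle_deg, ranges, weights, aperture_margin_mm, penumbra_sigma_mm)


def assemble_plan(
    phantom: Phantom,
    beams: Sequence[BeamSpec],
    prescription: FractionationScheme | Mapping[str, float],
    p: DepthCurveParams = DepthCurveParams(),
) -> PlanDose:
    """Compute all per-beam grids and normalise the plan to the prescription.

    One global factor rescales every beam so the median composite physical
    dose over the CTV equals the prescription total dose; the per-beam dose
    split is preserved.  (The normalisation statistic is a convention; the
    median is insensitive to penumbra and SOBP-edge voxels.)
    """
    if isinstance(prescription, Mapping):
        prescription = FractionationScheme(
            float(prescription["total_dose"]), int(prescription["n_fractions"])
        )
    if len(beams) < 1:
        raise ValueError("a plan needs at least one beam")
    doses, lets = [], []
    for beam in beams:
        d, l = compute_beam_dose_let(phantom, beam, p)
        doses.append(d)
        lets.append(l)
    composite = np.zeros(phantom.grid_shape)
    for d in doses:
        composite += d.values
    median_ctv = float(np.median(composite[phantom.ctv_mask]))
    if median_ctv <= 0:
        raise ValueError("CTV receives no dose; cannot normalise the plan")
    factor = prescription.total_dose / median_ctv
    doses = [d.like(d.values * factor) for d in doses]
    return PlanDose(list(beams), doses, lets, prescription)


# ---------------------------------------------------------------------------
# phantom construction


def _ellipsoid(coords, center, semi_axes) -> np.ndarray:
    X, Y, Z = coords
    cx, cy, cz = center
    ax, ay, az = semi_axes
    return ((X - cx) / ax) ** 2 + ((Y - cy) / ay) ** 2 + ((Z - cz) / az) ** 2 <= 1.0


def _cylinder(coords, center_xy, radius) -> np.ndarray:
    X, Y, _ = coords
    cx, cy = center_xy
    return (X - cx) ** 2 + (Y - cy) ** 2 <= radius ** 2


def build_phantom(config: Mapping) -> Phantom:
    """Build the phantom from a geometry config (see the default study YAML).

    The default geometry is a mediastinal arrangement: an elliptical body
    cross-section, an anterior-mediastinal CTV, a heart posterior to it
    with a small left-atrium-like substructure abutting the CTV's
    posterior (distal, for anterior beams) surface plus a deliberately
    sub-0.1-cc coronary-artery-like structure, two lungs, spinal cord and
    esophagus.  All structures are clipped to the body; heart excludes the
    CTV and esophagus; lungs exclude heart and CTV.
    """
    grid = config["grid"]
    shape = tuple(int(n) for n in grid["shape"])
    spacing = tuple(float(s) for s in grid["spacing_mm"])
    origin = tuple(-n * s / 2.0 for n, s in zip(shape, spacing))
    axes = [origin[a] + (np.arange(shape[a]) + 0.5) * spacing[a] for a in range(3)]
    coords = np.meshgrid(*axes, indexing="ij")

    geo = config["phantom"]

    def ell(name):
        g = geo[name]
        return _ellipsoid(coords, g["center"], g["semi_axes"])

    def cyl(name):
        g = geo[name]
        return _cylinder(coords, g["center"], g["radius"])

    body = ell("body")
    ctv = ell("ctv") & body
    esophagus = cyl("esophagus") & body & ~ctv
    heart_full = ell("heart")
    heart = heart_full & body & ~ctv & ~esophagus
    left_atrium = ell("left_atrium") & heart
    lmca = ell("lmca") & heart if "lmca" in geo else np.zeros(shape, bool)
    lung_left = ell("lung_left") & body & ~heart_full & ~ctv
    lung_right = ell("lung_right") & body & ~heart_full & ~ctv
    spinal_cord = cyl("spinal_cord") & body

    oars = {
        name: StructureMask(name, mask, spacing)
        for name, mask in [
            ("heart", heart),
            ("left_atrium", left_atrium),
            ("lmca", lmca),
            ("lung_left", lung_left),
            ("lung_right", lung_right),
            ("spinal_cord", spinal_cord),
            ("esophagus", esophagus),
        ]
        if mask.any() or name == "lmca"
    }
    return Phantom(shape, spacing, origin, body, ctv, oars)
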