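"""Structure-level comparison metrics: DVHs, near-maximum values, Vx,
coverage, Δdose maps, threshold volumes and high-dose/high-LET overlap.

All metrics operate on a :class:`~protonlet.grids.VoxelGrid` restricted to a
:class:`~protonlet.grids.StructureMask`.  Voxels carrying the exclusion
sentinel (NaN) — LET or variable-RBE values below the dose threshold — are
omitted from every statistic; physical-dose grids contain no sentinels, so
dose metrics automatically use the full structure.

Near-maximum values are reported as D(v): the lowest value received by the
hottest ``v`` cc of a structure (0.1 cc by convention).  A structure smaller
than the requested hot volume raises :class:`StructureTooSmallError` rather
than extrapolating — small cardiac substructures genuinely cannot support a
0.1 cc statistic on a 2 mm grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import StructureMask, VoxelGrid, require_congruent

__all__ = [
    "DVHCurve",
    "StructureTooSmallError",
    "dvh",
    "d_volume",
    "mean_in_mask",
    "v_dose",
    "coverage_check",
    "delta_dose_map",
    "volume_above",
    "overlap_volume",
]


class StructureTooSmallError(ValueError):
    """Structure cannot support the requested statistic."""


@dataclass
class DVHCurve:
    """Cumulative dose-volume histogram.

    ``dose_axis`` is ascending (Gy, Gy(RBE) or keV/μm); ``volume_axis`` is
    the percentage of the structure's evaluable volume receiving at least
    that dose, hence non-increasing with 100% at dose 0.
    """

    dose_axis: np.ndarray
    volume_axis: np.ndarray

    def volume_at(self, dose: float) -> float:
        """Volume % receiving at least ``dose``, linearly interpolated."""
        return float(np.interp(dose, self.dose_axis, self.volume_axis))


def _structure_values(grid: VoxelGrid, mask: StructureMask, drop_excluded: bool = True):
    require_congruent(grid, mask)
    if mask.n_voxels == 0:
        raise StructureTooSmallError(f"structure {mask.name!r} is empty")
    vals = grid.values[mask.mask]
    if drop_excluded:
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            raise StructureTooSmallError(
                f"structure {mask.name!r} has no evaluable voxels for {grid.quantity}"
            )
    return vals


def dvh(grid: VoxelGrid, mask: StructureMask, n_bins: int = 200,
        dose_max: float | None = None) -> DVHCurve:
    """Cumulative DVH of ``grid`` over ``mask`` on ``n_bins + 1`` dose points.

    Excluded-sentinel voxels are omitted (relevant for LET and vRBE grids);
    pass ``dose_max`` to put several curves on a common axis.
    """
    vals = np.sort(_structure_values(grid, mask))
    hi = float(dose_max) if dose_max is not None else float(vals[-1]) * 1.001 + 1e-12
    edges = np.linspace(0.0, hi, n_bins + 1)
    # fraction of voxels with value >= edge
    above = vals.size - np.searchsorted(vals, edges, side="left")
    return DVHCurve(edges, 100.0 * above / vals.size)


def d_volume(grid: VoxelGrid, mask: StructureMask, volume_cc: float = 0.1,
             interpolate: bool = True) -> float:
    """Lowest value in the hottest ``volume_cc`` of the structure (D0.1cc).

    Structure voxels are sorted descending; the value at cumulative volume
    ``volume_cc`` is returned, linearly interpolated between the bracketing
    voxels (or, with ``interpolate=False``, the value of the voxel whose
    cumulative volume first reaches it).
    """
    if volume_cc <= 0:
        raise ValueError("volume_cc must be positive")
    vals = _structure_values(grid, mask)
    vv = mask.voxel_volume_cc
    total = vals.size * vv
    if total < volume_cc:
        raise StructureTooSmallError(
            f"structure {mask.name!r} ({total:.4f} cc evaluable) is too small "
            f"for a {volume_cc:g} cc near-maximum"
        )
    ordered = np.sort(vals)[::-1]
    cum = vv * np.arange(1, ordered.size + 1)
    if interpolate:
        return float(np.interp(volume_cc, cum, ordered))
    return float(ordered[int(np.searchsorted(cum, volume_cc - 1e-12))])


def mean_in_mask(grid: VoxelGrid, mask: StructureMask) -> float:
    """Arithmetic mean over the structure's evaluable voxels."""
    return float(_structure_values(grid, mask).mean())


def v_dose(grid: VoxelGrid, mask: StructureMask, threshold: float) -> float:
    """Percentage of the structure volume receiving at least ``threshold``.

    The denominator is the full structure volume; sentinel voxels count as
    not reaching the threshold.
    """
    require_congruent(grid, mask)
    if mask.n_voxels == 0:
        raise StructureTooSmallError(f"structure {mask.name!r} is empty")
    vals = grid.values[mask.mask]
    with np.errstate(invalid="ignore"):
        hit = np.sum(vals >= threshold)
    return 100.0 * float(hit) / vals.size


def coverage_check(dose: VoxelGrid, ctv_mask: StructureMask,
                   prescription: float) -> dict:
    """Clinical coverage criterion: D98% of the CTV ≥ 95% of prescription.

    D98% is the dose exceeded by 98% of the CTV volume, i.e. the
    near-minimum :func:`d_volume` at 98% of the structure volume.
    """
    vol98 = 0.98 * ctv_mask.volume_cc
    d98 = d_volume(dose, ctv_mask, vol98)
    return {"d98": d98, "pass": bool(d98 >= 0.95 * prescription)}


def delta_dose_map(vrbe_dose: VoxelGrid, fixed_dose: VoxelGrid,
                   included: np.ndarray | None = None) -> VoxelGrid:
    """Voxel-wise vRBE-weighted minus fixed-RBE-weighted dose [Gy(RBE)].

    Where either input carries the sentinel — or ``included`` marks a voxel
    as outside the evaluable volume — the output is the sentinel.
    """
    require_congruent(vrbe_dose, fixed_dose)
    delta = vrbe_dose.values - fixed_dose.values
    if included is not None:
        delta = np.where(included, delta, np.nan)
    return vrbe_dose.like(delta, quantity="delta_Gy_rbe", provenance="delta_dose_map")


def volume_above(delta: VoxelGrid, threshold: float = 3.0,
                 mask: StructureMask | None = None) -> float:
    """Volume [cc] with ``delta ≥ threshold``, optionally within a structure."""
    sel = delta.values >= threshold
    if mask is not None:
        require_congruent(delta, mask)
        sel = sel & mask.mask
    return float(np.count_nonzero(sel)) * delta.voxel_volume_cc


def overlap_volume(
    dose: VoxelGrid,
    let: VoxelGrid,
    dose_fraction: float = 0.8,
    let_threshold: float = 6.0,
    body_mask: np.ndarray | None = None,
    structures: dict[str, StructureMask] | None = None,
) -> dict:
    """Overlap of the high-dose region with the high-LET region.

    Returns the volume [cc] of voxels with dose ≥ ``dose_fraction`` of the
    (body-restricted) maximum AND LET ≥ ``let_threshold``, plus the names of
    any supplied structures the overlap intersects.
    """
    require_congruent(dose, let)
    ref = dose.values[body_mask] if body_mask is not None else dose.values
    dmax = float(ref.max()) if ref.size else 0.0
    with np.errstate(invalid="ignore"):
        sel = (dose.values >= dose_fraction * dmax) & (let.values >= let_threshold)
    if body_mask is not None:
        sel &= body_mask
    components = []
    if structures:
        components = [name for name, sm in structures.items() if np.any(sel & sm.mask)]
    return {
        "volume_cc": float(np.count_nonzero(sel)) * dose.voxel_volume_cc,
        "component_structures": components,
    }
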