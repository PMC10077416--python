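"""Combining per-beam dose-averaged LET grids and dose thresholding.

For a plan with several beams, the composite dose-averaged LET in a voxel is
the mean of the per-beam LET values weighted by each beam's relative dose
contribution to that voxel:

    L = Σ_b d_b L_b / Σ_b d_b

Voxels receiving no dose from any beam have no defined LET and are set to
the exclusion sentinel (NaN).  Because voxels far from any beam contain very
few particles, LET (and everything derived from it) is only evaluated where
the total physical dose reaches a fraction (default 5%) of the plan maximum;
:func:`threshold_let` applies that rule.

The same dose-weighted mixing is used inside the beam simulator to combine
energy layers, so synthetic generation and analysis share one code path.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .grids import SENTINEL, GeometryError, VoxelGrid, require_congruent

__all__ = ["BeamGridSet", "mix_let", "mix_let_arrays", "threshold_let"]


@dataclass
class BeamGridSet:
    """Per-beam (dose, LET) grid pairs with congruent geometry."""

    beams: Sequence[tuple[VoxelGrid, VoxelGrid]]

    def __post_init__(self) -> None:
        if len(self.beams) < 1:
            raise ValueError("BeamGridSet needs at least one beam")
        ref = self.beams[0][0]
        for dose, let in self.beams:
            require_congruent(ref, dose, let)
            if np.any(dose.values < 0) or np.any(let.values < 0):
                raise ValueError("per-beam dose and LET grids must be non-negative")


def mix_let_arrays(pairs: Iterable[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
    """Dose-weighted LET mean over raw ``(dose, let)`` array pairs.

    Zero-dose components contribute nothing (their LET value is ignored even
    if undefined).  Voxels with zero total dose get :data:`SENTINEL`.
    """
    pairs = list(pairs)
    if len(pairs) == 1:
        # single component: identity on the LET values where dose > 0
        dose = np.asarray(pairs[0][0], dtype=np.float64)
        let = np.asarray(pairs[0][1], dtype=np.float64)
        return np.where(dose > 0, let, SENTINEL)
    num = None
    den = None
    for dose, let in pairs:
        dose = np.asarray(dose, dtype=np.float64)
        contrib = np.where(dose > 0, dose * np.asarray(let, dtype=np.float64), 0.0)
        if num is None:
            num = contrib.copy()
            den = dose.copy()
        else:
            num += contrib
            den += dose
    if num is None:
        raise ValueError("no (dose, LET) pairs to mix")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[~(den > 0)] = SENTINEL
    return out


def mix_let(beam_set: BeamGridSet | Sequence[tuple[VoxelGrid, VoxelGrid]]) -> VoxelGrid:
    """Combine per-beam LET grids into one composite LET grid.

    Implements the relative-dose weighting rule ``L = Σ d_b L_b / Σ d_b``
    per voxel; voxels with zero dose from every beam carry the sentinel.
    """
    if not isinstance(beam_set, BeamGridSet):
        beam_set = BeamGridSet(list(beam_set))
    ref_dose = beam_set.beams[0][0]
    mixed = mix_let_arrays((d.values, l.values) for d, l in beam_set.beams)
    return ref_dose.like(mixed, quantity="let_keVum", provenance="mix_let")


def threshold_let(
    let: VoxelGrid,
    total_dose: VoxelGrid,
    fraction: float = 0.05,
    body_mask: np.ndarray | None = None,
) -> VoxelGrid:
    """Exclude LET voxels where the composite dose is below ``fraction`` of max.

    The anchoring maximum is the composite-plan physical-dose maximum, taken
    within ``body_mask`` when one is supplied and over the whole grid
    otherwise.  Excluded voxels are set to the sentinel; the operation is
    idempotent.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    require_congruent(let, total_dose)
    dose = total_dose.values
    ref = dose[body_mask] if body_mask is not None else dose
    ref_max = float(ref.max()) if ref.size else 0.0
    out = let.values.copy()
    if ref_max <= 0:
        warnings.warn("all-zero dose grid: every LET voxel excluded", stacklevel=2)
        out[:] = SENTINEL
    else:
        out[dose < fraction * ref_max] = SENTINEL
    return let.like(out, provenance=f"threshold_let(fraction={fraction})")
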