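"""Proton RBE models: the clinical constant 1.1 and the McNamara LQ model.

The McNamara phenomenological model expresses the proton RBE as a function
of dose per fraction d [Gy], dose-averaged LET [keV/μm] and the tissue's
photon (α/β)ₓ [Gy]:

    RBEmax = c1 + c2 · LETd / (α/β)ₓ
    RBEmin = c3 − c4 · √(α/β)ₓ · LETd
    RBE    = 1/(2d) · [ √( (α/β)ₓ² + 4d(α/β)ₓ·RBEmax + 4d²·RBEmin² ) − (α/β)ₓ ]

with fitted coefficients c1 = 0.99064, c2 = 0.35605 Gy·μm/keV,
c3 = 1.1012, c4 = 0.0038703 Gy^(−1/2)·μm/keV.  RBEmax and RBEmin are the
asymptotic RBE at vanishing and very large dose per fraction.  Setting
RBEmax = RBEmin = c collapses the square root to (α/β + 2cd) and the model
returns exactly c for every dose — the fixed-RBE setting is the degenerate
point of the variable model.

RBEmin is floored at 0: at LET far beyond the model's fitted range the
linear RBEmin term would go negative and clamping is preferable to a NaN
from the square root.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import VoxelGrid, require_congruent

__all__ = [
    "RBEParameters",
    "FractionationScheme",
    "rbe_max",
    "rbe_min",
    "mcnamara_rbe",
    "vrbe_weighted_dose",
]


@dataclass(frozen=True)
class RBEParameters:
    """α/β and McNamara coefficients; ``fixed_rbe`` bypasses the model.

    ``alpha_beta`` is the photon (α/β)ₓ in Gy (2 Gy is typical for
    late-responding normal tissue).  When ``fixed_rbe`` is set the variable
    coefficients are ignored and every voxel gets that constant RBE.
    """

    alpha_beta: float = 2.0
    c1: float = 0.99064
    c2: float = 0.35605
    c3: float = 1.1012
    c4: float = 0.0038703
    fixed_rbe: float | None = None

    def __post_init__(self) -> None:
        if self.alpha_beta <= 0:
            raise ValueError(f"alpha_beta must be positive, got {self.alpha_beta}")


@dataclass(frozen=True)
class FractionationScheme:
    """Prescription: total dose [Gy] delivered in ``n_fractions`` fractions."""

    total_dose: float
    n_fractions: int

    def __post_init__(self) -> None:
        if self.total_dose <= 0:
            raise ValueError("total_dose must be positive")
        if int(self.n_fractions) < 1:
            raise ValueError("n_fractions must be >= 1")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


def _check_let(let_d) -> np.ndarray:
    let_d = np.asarray(let_d, dtype=np.float64)
    if np.any(let_d[np.isfinite(let_d)] < 0):
        raise ValueError("LET must be non-negative")
    return let_d


def rbe_max(let_d, params: RBEParameters = RBEParameters()):
    """Low-dose-limit RBE: ``c1 + c2 · LETd / (α/β)``."""
    let_d = _check_let(let_d)
    out = params.c1 + params.c2 * let_d / params.alpha_beta
    return out if out.ndim else float(out)


def rbe_min(let_d, params: RBEParameters = RBEParameters()):
    """High-dose-limit RBE: ``c3 − c4 · √(α/β) · LETd``, floored at 0."""
    let_d = _check_let(let_d)
    out = np.maximum(params.c3 - params.c4 * np.sqrt(params.alpha_beta) * let_d, 0.0)
    return out if out.ndim else float(out)


def mcnamara_rbe(dose_per_fraction, let_d, params: RBEParameters = RBEParameters()):
    """Variable RBE at dose per fraction d [Gy] and dose-averaged LET [keV/μm].

    Returns ``params.fixed_rbe`` unconditionally when that is set.  The
    d → 0 limit is not evaluated: callers must threshold zero-dose voxels
    beforehand.
    """
    d = np.asarray(dose_per_fraction, dtype=np.float64)
    let_d = _check_let(let_d)
    if params.fixed_rbe is not None:
        out = np.full(np.broadcast_shapes(d.shape, let_d.shape), float(params.fixed_rbe))
        return out if out.ndim else float(params.fixed_rbe)
    if np.any(d <= 0):
        raise ValueError("dose_per_fraction must be strictly positive")
    ab = params.alpha_beta
    rmax = params.c1 + params.c2 * let_d / ab
    rmin = np.maximum(params.c3 - params.c4 * np.sqrt(ab) * let_d, 0.0)
    disc = ab * ab + 4.0 * d * ab * rmax + 4.0 * d * d * rmin * rmin
    out = (np.sqrt(disc) - ab) / (2.0 * d)
    return out if out.ndim else float(out)


def vrbe_weighted_dose(
    total_dose: VoxelGrid,
    let_d: VoxelGrid,
    scheme: FractionationScheme,
    params: RBEParameters = RBEParameters(),
) -> tuple[VoxelGrid, np.ndarray]:
    """RBE-weighted dose grid [Gy(RBE)] and the mask of evaluable voxels.

    The dose per fraction in each voxel is that voxel's total dose divided
    by the fraction count (uniform fractionation).  Voxels whose LET is the
    exclusion sentinel, or that receive no dose, produce 0 and are flagged
    excluded in the returned boolean mask; downstream Δdose metrics treat
    them as outside the evaluable volume.
    """
    require_congruent(total_dose, let_d)
    dose = total_dose.values
    let = let_d.values
    included = np.isfinite(let) & (dose > 0)
    out = np.zeros_like(dose)
    if params.fixed_rbe is not None:
        out[included] = float(params.fixed_rbe) * dose[included]
    elif included.any():
        d_fx = dose[included] / scheme.n_fractions
        out[included] = dose[included] * mcnamara_rbe(d_fx, let[included], params)
    grid = total_dose.like(
        out,
        quantity="dose_Gy_rbe",
        provenance=(
            f"vrbe(fixed={params.fixed_rbe})" if params.fixed_rbe is not None
            else f"vrbe(mcnamara, alpha_beta={params.alpha_beta})"
        ),
    )
    return grid, included
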