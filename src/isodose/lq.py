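"""Linear-quadratic biologically effective dose (BED) and fraction conversions.

Under the linear-quadratic survival model, a fractionated scheme delivering a
total dose ``n*d`` in ``n`` equal fractions of ``d`` Gy has biologically
effective dose

    BED = n * d * (1 + d / (alpha/beta)).

Two schemes with equal BED are iso-effective, which makes BED the natural
currency both for converting a fractionated plan into an equivalent
single-fraction dose (BNCT is delivered in a single session, so cross-modality
comparison happens on the single-fraction scale) and for summing plans that
are delivered sequentially with full sublethal-damage repair in between.

The inverse map, the single-fraction dose with a given BED, is the positive
root of ``D * (1 + D/(alpha/beta)) = BED``:

    D = (alpha/beta)/2 * (-1 + sqrt(1 + 4*BED/(alpha/beta))).

Clinical carbon-ion practice uses alpha/beta = 2 Gy for these conversions;
the tumour-control model of :mod:`isodose.tcp` was built on data converted at
alpha/beta = 10 Gy.  Both are plain parameters here, never hard-coded
downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, GridError

#: alpha/beta used for clinical fractionation conversions (normal tissue & CIRT).
ALPHA_BETA_CLINICAL = 2.0
#: alpha/beta of the tumour-control model's source-data convention.
ALPHA_BETA_TUMOUR_MODEL = 10.0


@dataclass(frozen=True)
class FractionationScheme:
    """A fractionation scheme: ``n_fractions`` equal fractions totalling
    ``total_dose`` Gy on a photon-equivalent scale, with tissue ``alpha_beta``."""

    n_fractions: int
    total_dose: float
    alpha_beta: float = ALPHA_BETA_CLINICAL

    def __post_init__(self):
        if int(self.n_fractions) < 1:
            raise ValueError(f"n_fractions must be a positive integer, got {self.n_fractions}")
        if self.total_dose < 0:
            raise ValueError(f"total_dose must be non-negative, got {self.total_dose}")
        if not self.alpha_beta > 0:
            raise ValueError(f"alpha_beta must be > 0, got {self.alpha_beta}")

    @property
    def dose_per_fraction(self) -> float:
        return self.total_dose / self.n_fractions


def bed(scheme: FractionationScheme) -> float:
    """BED [Gy] of a fractionation scheme: ``n*d*(1 + d/(alpha/beta))``."""
    d = scheme.dose_per_fraction
    return scheme.total_dose * (1.0 + d / scheme.alpha_beta)


def bed_values(total_dose, n_fractions: int, alpha_beta: float):
    """Vectorized BED for per-voxel total doses delivered in ``n_fractions``."""
    if not alpha_beta > 0:
        raise ValueError(f"alpha_beta must be > 0, got {alpha_beta}")
    total_dose = np.asarray(total_dose, dtype=np.float64)
    d = total_dose / n_fractions
    return total_dose * (1.0 + d / alpha_beta)


def sf_equivalent(bed_value, alpha_beta: float):
    """Single-fraction dose [Gy] with the given BED (positive quadratic root).

    Accepts scalars or arrays; the map is the exact inverse of :func:`bed`
    at ``n_fractions = 1`` and is strictly increasing in ``bed_value``.
    """
    if not alpha_beta > 0:
        raise ValueError(f"alpha_beta must be > 0, got {alpha_beta}")
    b = np.asarray(bed_value, dtype=np.float64)
    if np.any(b < 0):
        raise ValueError("BED must be non-negative")
    out = 0.5 * alpha_beta * (-1.0 + np.sqrt(1.0 + 4.0 * b / alpha_beta))
    return float(out) if np.isscalar(bed_value) else out


def grid_to_single_fraction(grid: DoseGrid, n_fractions: int, alpha_beta: float) -> DoseGrid:
    """Convert a total-dose photon-equivalent grid to its single-fraction
    equivalent, voxel by voxel.

    Every voxel is assumed to receive all ``n_fractions`` fractions with
    per-fraction dose ``D(x)/n``; the per-voxel map is strictly increasing,
    so dose order statistics (D2, D98, ...) commute with the conversion.
    """
    if grid.units == "Gy_IsoE_C12_BED":
        raise GridError("grid is already on the single-fraction (BED-converted) scale")
    if grid.units not in ("Gy_IsoE_C12", "Gy_IsoE_BNCT"):
        raise GridError(
            f"single-fraction conversion needs a total photon-equivalent grid, got units {grid.units!r}"
        )
    converted = sf_equivalent(bed_values(grid.values, n_fractions, alpha_beta), alpha_beta)
    units = "Gy_IsoE_C12_BED" if grid.units == "Gy_IsoE_C12" else grid.units
    meta = dict(grid.meta)
    meta["sf_conversion"] = {"n_fractions": int(n_fractions), "alpha_beta": float(alpha_beta)}
    return DoseGrid(converted, grid.voxel_size, units, meta)
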