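"""Voxelwise combination of photon-equivalent plans on the BED scale.

Two plans delivered sequentially (e.g. a carbon-ion series and a BNCT
session) are summed per voxel by adding their biologically effective doses
and mapping the total back to a single-fraction dose:

    D_combined(x) = SF( BED_A(x) + BED_B(x) ),

where each plan's BED uses its own fraction number.  The operation is
commutative and associative, a zero plan is the identity (up to the
single-fraction conversion of the other plan), and in the limit
alpha/beta -> infinity it degenerates to the plain sum of physical doses.

For healthy tissue the emulated protocol assumes complete recovery between
irradiations, so normal-tissue reporting sums the single-fraction
isoeffective doses linearly instead (:func:`combine_healthy_linear`).  Which
rule a pipeline applies to which ROI is explicit configuration, never
implicit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import DoseGrid, GridError, LatticeMismatchError
from .lq import FractionationScheme, bed_values, sf_equivalent

_SF_UNITS = ("Gy_IsoE_BNCT", "Gy_IsoE_C12_BED")


@dataclass
class PlanComponent:
    """One modality's contribution: a photon-equivalent total-dose grid plus
    its fractionation scheme (n = 1 for a BNCT session)."""

    grid: DoseGrid
    scheme: FractionationScheme
    modality: str = ""

    def __post_init__(self):
        if self.grid.units == "Gy_IsoE_C12_BED" and self.scheme.n_fractions != 1:
            raise GridError(
                "grid already on the single-fraction scale but scheme has n_fractions > 1"
            )

    def bed_per_voxel(self) -> np.ndarray:
        """Per-voxel BED with this plan's own fraction number."""
        return bed_values(self.grid.values, self.scheme.n_fractions, self.scheme.alpha_beta)


def _combined_units(units_a: str, units_b: str) -> str:
    if units_a == units_b == "Gy_IsoE_BNCT":
        return "Gy_IsoE_BNCT"
    return "Gy_IsoE_C12_BED"


def combine(plan_a: PlanComponent, plan_b: PlanComponent, alpha_beta: float) -> DoseGrid:
    """BED-space sum of two plans as a single-fraction isoeffective grid.

    Commutative; combining with an all-zero plan returns the other plan
    converted to its single-fraction equivalent.  The result's ``meta``
    records both provenances.
    """
    if not plan_a.grid.same_lattice(plan_b.grid):
        raise LatticeMismatchError("plans are not on one lattice")
    if not alpha_beta > 0:
        raise ValueError("alpha_beta must be > 0")
    total_bed = plan_a.bed_per_voxel() + plan_b.bed_per_voxel()
    values = sf_equivalent(total_bed, alpha_beta)
    meta = {
        "combined_from": sorted(
            [
                f"{plan_a.modality or plan_a.grid.units}/n={plan_a.scheme.n_fractions}",
                f"{plan_b.modality or plan_b.grid.units}/n={plan_b.scheme.n_fractions}",
            ]
        ),
        "rule": "BED sum",
        "alpha_beta": float(alpha_beta),
    }
    return DoseGrid(values, plan_a.grid.voxel_size, _combined_units(plan_a.grid.units, plan_b.grid.units), meta)


def combine_healthy_linear(plan_a_sf: DoseGrid, plan_b_sf: DoseGrid) -> DoseGrid:
    """Linear voxelwise sum of two single-fraction isoeffective grids.

    The normal-tissue reporting rule under the complete-recovery assumption.
    Units are preserved when equal; a cross-modality sum carries the
    composite single-fraction tag with both provenances in ``meta``.
    """
    if not plan_a_sf.same_lattice(plan_b_sf):
        raise LatticeMismatchError("grids are not on one lattice")
    for g in (plan_a_sf, plan_b_sf):
        if g.units not in _SF_UNITS:
            raise GridError(f"linear combination needs single-fraction IsoE grids, got {g.units!r}")
    meta = {
        "combined_from": sorted([plan_a_sf.units, plan_b_sf.units]),
        "rule": "linear sum (complete recovery)",
    }
    return DoseGrid(
        plan_a_sf.values + plan_b_sf.values,
        plan_a_sf.voxel_size,
        _combined_units(plan_a_sf.units, plan_b_sf.units),
        meta,
    )
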