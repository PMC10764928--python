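"""DVHs, dose percentiles (D2/D98), homogeneity index and ROI summaries.

D_x is the dose received by at least x% of a structure's volume.  The default
rule is the discrete at-least rule on the voxel sample (no interpolation):
D_x is the largest sampled dose ``d`` with ``count(doses >= d)/n >= x/100``.
An interpolated variant is available for figure work; all table mirroring
uses the discrete rule.

The homogeneity index is HI = (D2 - D98) / Dmean: zero for perfectly uniform
dose, and invariant under uniform dose scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np

from .grid import DoseGrid, ROIMask, extract_roi_doses


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram: volume fraction receiving >= dose."""

    dose_edges: np.ndarray
    volume_fraction: np.ndarray

    def to_csv(self, path) -> None:
        """Write as two-column CSV (dose_Gy, volume_fraction)."""
        arr = np.column_stack([self.dose_edges, self.volume_fraction])
        np.savetxt(path, arr, fmt="%.6g", delimiter=",", header="dose_Gy,volume_fraction", comments="")


@dataclass(frozen=True)
class DoseSummary:
    """Near-to-min (D98), mean and near-to-max (D2) of an ROI dose sample."""

    near_to_min: float
    mean: float
    near_to_max: float
    units: str = "Gy_absorbed"


def _as_sample(doses) -> np.ndarray:
    d = np.asarray(doses, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("dose sample is empty")
    return d


def dvh_cumulative(doses, bin_width: float = 0.1) -> DVH:
    """Cumulative DVH on edges 0, w, 2w, ... past the max dose.

    The fraction at edge ``e`` is ``count(d >= e)/n``; it starts at 1.0 at
    dose 0, is non-increasing, and is 0 beyond the maximum dose.
    """
    d = _as_sample(doses)
    if not bin_width > 0:
        raise ValueError("bin_width must be positive")
    n_edges = int(np.floor(d.max() / bin_width)) + 2
    edges = np.arange(n_edges) * bin_width
    frac = (d[None, :] >= edges[:, None]).mean(axis=1) if d.size * n_edges < 5_000_000 else None
    if frac is None:  # memory-light path for very large samples
        sorted_d = np.sort(d)
        frac = 1.0 - np.searchsorted(sorted_d, edges, side="left") / d.size
    return DVH(edges, np.asarray(frac, dtype=np.float64))


def d_at_least(doses, x: float, interpolate: bool = False) -> float:
    """D_x: the dose received by at least x% of the volume (discrete rule).

    Discrete rule: the k-th largest sampled dose with ``k = ceil(n*x/100)``,
    i.e. the largest dose d in the sample such that at least x% of voxels
    receive >= d.  ``interpolate=True`` returns the linearly interpolated
    (100-x)th percentile instead.
    """
    d = _as_sample(doses)
    if not (0 < x <= 100):
        raise ValueError(f"x must be in (0, 100], got {x}")
    if interpolate:
        return float(np.percentile(d, 100.0 - x))
    k = ceil(d.size * x / 100.0)
    return float(np.sort(d)[::-1][k - 1])


def homogeneity_index(d2: float, d98: float, dmean: float) -> float:
    """HI = (D2 - D98) / Dmean; 0 iff the dose is uniform (D2 = D98)."""
    if not dmean > 0:
        raise ValueError("mean dose must be positive")
    if d2 < d98:
        raise ValueError(f"D2 ({d2}) must be >= D98 ({d98})")
    return (d2 - d98) / dmean


def summarize_roi(grid: DoseGrid, mask: ROIMask) -> DoseSummary:
    """D98 / mean / D2 of the grid restricted to the mask."""
    d = extract_roi_doses(grid, mask)
    return DoseSummary(
        near_to_min=d_at_least(d, 98.0),
        mean=float(d.mean()),
        near_to_max=d_at_least(d, 2.0),
        units=grid.units,
    )


def summary_hi(summary: DoseSummary) -> float:
    """Homogeneity index straight from a D98/mean/D2 summary."""
    return homogeneity_index(summary.near_to_max, summary.near_to_min, summary.mean)


def quartile_box(doses) -> tuple[float, float, float, float]:
    """(q1, median, q3, mean) with linearly interpolated quartiles (type-7)."""
    d = _as_sample(doses)
    q1, med, q3 = np.percentile(d, [25.0, 50.0, 75.0])
    return float(q1), float(med), float(q3), float(d.mean())
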