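"""Tumour control probability for uniform and non-uniform single-fraction dose.

The model is Poisson-type with an explicit volume effect.  For a uniform
single-fraction photon dose ``D`` to a tumour of volume ``v`` (cm^3),

    TCP(v, D) = exp(-c1 * v**c2 * S(D)),          S(D) = exp(-alpha*D - beta*D**2),

with ``c1`` and ``c2`` modulating the volume effect and ``S`` the
linear-quadratic surviving fraction.  The default parameters carry a
published head-and-neck fit (about 100 stereotactic-body-radiotherapy
patients, doses converted to single fractions at alpha/beta = 10 Gy):

    c1 = 2.4 [1.1, 3.7],  c2 = 0.12 [0, 0.26],  alpha = 0.022 [0.016, 0.028] /Gy

(brackets: 68% confidence intervals).  ``beta`` is not part of the printed
fit; the default ties it to alpha through the construction convention,
``beta = alpha / 10``.

Non-uniform dose uses the equivalent-subvolume generalization: the tumour is
a parallel arrangement of subvolumes and the survival entering the uniform
formula is the generalized (power) mean of exponent ``1/c2`` of the per-voxel
survivals,

    TCP_T = exp(-c1 * v**c2 * ( mean_x S(D(x))**(1/c2) )**c2 ).

With c2 ~ 0.1 the exponent 1/c2 is large: ``S**(1/c2)`` underflows double
precision for typical doses, so the mean is formed in log space with a
log-sum-exp construction, and for c2 below 1e-6 a dedicated branch returns
the analytic limit (the power mean tends to ``max_x S(D(x))``: cold-spot
domination).

Confidence intervals on TCP are propagated by Monte Carlo: independent
uniform sampling of (c1, c2, alpha) within their 68% bounds with beta tied
to alpha, reporting the 16th/84th percentiles of the sampled TCP.  The
scheme, sample count and seed are recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

#: c2 below this is computed as the analytic c2 -> 0+ limit (cold-spot dominated).
C2_LIMIT_BRANCH = 1e-6

#: Published 68% confidence bounds of the head-and-neck fit.
DEFAULT_CI68 = {
    "c1": (1.1, 3.7),
    "c2": (0.0, 0.26),
    "alpha": (0.016, 0.028),
}


@dataclass(frozen=True)
class TCPParameters:
    """Parameters of the volume-effect TCP model.

    ``beta_ratio`` is the alpha/beta ratio [Gy] tying beta to alpha
    (``beta = alpha / beta_ratio``); used both for the central value and when
    sampling alpha in CI propagation.  An explicit ``beta`` overrides it.
    """

    c1: float = 2.4
    c2: float = 0.12
    alpha: float = 0.022
    beta: float | None = None
    beta_ratio: float = 10.0
    ci68: dict = field(default_factory=lambda: dict(DEFAULT_CI68))

    def __post_init__(self):
        if self.c1 < 0 or self.c2 < 0 or self.alpha < 0:
            raise ValueError("c1, c2 and alpha must be non-negative")
        if self.beta is not None and self.beta < 0:
            raise ValueError("beta must be non-negative")
        if not self.beta_ratio > 0:
            raise ValueError("beta_ratio must be > 0")
        for name, (lo, hi) in self.ci68.items():
            centre = getattr(self, name)
            if not (lo <= centre <= hi):
                raise ValueError(f"ci68 bounds for {name} do not bracket the central value")

    @property
    def beta_value(self) -> float:
        return self.alpha / self.beta_ratio if self.beta is None else self.beta


@dataclass(frozen=True)
class TCPResult:
    """A TCP with a propagated 68% interval.

    ``flagged`` marks the (Monte-Carlo-tolerable) case of the central value
    falling outside the sampled percentile interval.
    """

    tcp: float
    ci68: tuple[float, float]
    n_samples: int
    seed: int
    flagged: bool = False


def survival(dose, alpha: float, beta: float):
    """LQ surviving fraction ``exp(-alpha*D - beta*D**2)``; scalar or array."""
    d = np.asarray(dose, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-(alpha * d + beta * d * d))
    return float(out) if np.isscalar(dose) else out


def _log_survival(dose, alpha, beta):
    d = np.asarray(dose, dtype=np.float64)
    return -(alpha * d + beta * d * d)


def tcp_uniform(volume: float, dose: float, params: TCPParameters | None = None) -> float:
    """TCP of a uniform single-fraction photon dose to a tumour of ``volume`` cm^3."""
    params = params or TCPParameters()
    if not volume > 0:
        raise ValueError(f"tumour volume must be positive, got {volume}")
    s = survival(float(dose), params.alpha, params.beta_value)
    return float(np.exp(-params.c1 * volume**params.c2 * s))


def _generalized_mean_log_survival(log_s: np.ndarray, c2: float) -> float:
    """log of the exponent-1/c2 power mean of survivals, given log-survivals."""
    if c2 < C2_LIMIT_BRANCH:
        # power mean -> max survival (the coldest voxel dominates)
        return float(np.max(log_s))
    n = log_s.size
    return float(c2 * (logsumexp(log_s / c2) - np.log(n)))


def tcp_nonuniform(doses, voxel_volume: float, params: TCPParameters | None = None) -> float:
    """TCP of a non-uniform single-fraction dose list (equivalent-subvolume model).

    ``doses`` is the per-voxel dose over the tumour ROI and ``voxel_volume``
    the volume of one voxel in cm^3; the ROI volume is ``n * voxel_volume``.
    Reduces exactly to :func:`tcp_uniform` on constant dose lists.
    """
    params = params or TCPParameters()
    d = np.asarray(doses, dtype=np.float64).ravel()
    if d.size == 0:
        raise ValueError("dose list is empty")
    if not voxel_volume > 0:
        raise ValueError("voxel_volume must be positive")
    if params.c2 < 0:
        raise ValueError("c2 must be non-negative")
    v = d.size * voxel_volume
    log_s = _log_survival(d, params.alpha, params.beta_value)
    log_mean = _generalized_mean_log_survival(log_s, params.c2)
    return float(np.exp(-params.c1 * v**params.c2 * np.exp(log_mean)))


def _sampled_tcp(d, voxel_volume, c1, c2, alpha, beta_ratio):
    """Vectorized TCP over parameter samples (c1, c2, alpha are 1-D arrays)."""
    v = d.size * voxel_volume
    beta = alpha / beta_ratio
    log_s = -(alpha[:, None] * d[None, :] + beta[:, None] * d[None, :] ** 2)
    out = np.empty(c1.size)
    small = c2 < C2_LIMIT_BRANCH
    if np.any(small):
        # c2 -> 0+: v**c2 -> 1 and the power mean -> max survival
        out[small] = np.exp(-c1[small] * np.exp(np.max(log_s[small], axis=1)))
    big = ~small
    if np.any(big):
        c2b = c2[big]
        lse = logsumexp(log_s[big] / c2b[:, None], axis=1)
        log_mean = c2b * (lse - np.log(d.size))
        out[big] = np.exp(-c1[big] * v**c2b * np.exp(log_mean))
    return out


def tcp_ci(
    doses,
    voxel_volume: float,
    params: TCPParameters | None = None,
    n_samples: int = 10_000,
    seed: int = 0,
) -> TCPResult:
    """Central TCP with a Monte-Carlo 68% interval from the parameter bounds.

    (c1, c2, alpha) are sampled independently and uniformly within their 68%
    bounds, beta tied to alpha by ``params.beta_ratio``; the interval is the
    16th/84th percentile of the sampled TCPs.  Deterministic under ``seed``.
    """
    params = params or TCPParameters()
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    for key in ("c1", "c2", "alpha"):
        if key not in params.ci68:
            raise ValueError(f"ci68 bounds missing for {key!r}")
    d = np.asarray(doses, dtype=np.float64).ravel()
    central = tcp_nonuniform(d, voxel_volume, params)
    rng = np.random.default_rng(seed)
    c1 = rng.uniform(*params.ci68["c1"], n_samples)
    c2 = rng.uniform(*params.ci68["c2"], n_samples)
    alpha = rng.uniform(*params.ci68["alpha"], n_samples)
    samples = _sampled_tcp(d, voxel_volume, c1, c2, alpha, params.beta_ratio)
    lo, hi = np.percentile(samples, [16.0, 84.0])
    flagged = not (lo <= central <= hi)
    return TCPResult(central, (float(lo), float(hi)), int(n_samples), int(seed), flagged)
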