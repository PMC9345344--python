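"""Mean-squared-displacement curves and the two classical MSD fits.

The MSD at lag τ is the mean of |x(t+τ) − x(t)|² over all tracks and all
(overlapping) start times t.  Each lag keeps the count of averaged squared
displacements; both fits weight residuals by these counts, so long lags —
averaged over few pairs — carry proportionally less weight.

Two models are fitted by weighted nonlinear least squares:

* power law  MSD = k·t^α, where α = 1 is pure diffusion, α = 2 uniform
  linear motion, and intermediate values superdiffusion;
* the Fürth persistent-random-walk model
  MSD = 2S²P·[t − P·(1 − e^(−t/P))], with root-mean-squared speed S
  (μm/min) and persistence time P (min).  For t ≪ P the model is ballistic
  (MSD ≈ S²t²); for t ≫ P it is diffusive with slope 2S²P.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .tracks import TrackSet

__all__ = [
    "MSDCurve",
    "PowerLawFit",
    "FurthFit",
    "FitError",
    "msd_curve",
    "fit_power_law",
    "fit_furth",
    "furth_model",
]


class FitError(RuntimeError):
    """A nonlinear fit failed to converge; carries diagnostics."""


@dataclass
class MSDCurve:
    """MSD per lag with the number of averaged squared displacements."""

    lags: np.ndarray  # minutes, strictly increasing, multiples of Δt
    msd: np.ndarray  # μm²
    counts: np.ndarray  # squared displacements averaged per lag

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if np.any(self.counts < 1):
            raise ValueError("every retained lag needs count >= 1")
        if np.any(self.msd < 0):
            raise ValueError("msd must be >= 0")

    def __len__(self) -> int:
        return len(self.lags)


@dataclass
class PowerLawFit:
    k: float  # μm²/min^α
    k_se: float
    alpha: float  # diffusion exponent
    alpha_se: float


@dataclass
class FurthFit:
    S: float  # μm/min, root mean squared speed
    S_se: float
    P: float  # minutes, persistence time
    P_se: float

    @property
    def asymptotic_slope(self) -> float:
        """Long-time diffusive slope 2S²P (μm²/min)."""
        return 2.0 * self.S * self.S * self.P


def msd_curve(ts: TrackSet) -> MSDCurve:
    """Build the MSD curve of a resampled TrackSet.

    Squared displacements are collected for every lag τ = m·Δt between Δt
    and the longest path duration, over all tracks and all overlapping
    start positions, then averaged per lag.
    """
    dt = ts.interval
    sums: dict[int, float] = {}
    counts: dict[int, int] = {}
    any_steps = False
    for tr in ts:
        n = tr.n_samples
        if n < 2:
            continue
        any_steps = True
        for m in range(1, n):
            diff = tr.xy[m:] - tr.xy[:-m]
            sq = np.einsum("ij,ij->i", diff, diff)
            sums[m] = sums.get(m, 0.0) + float(sq.sum())
            counts[m] = counts.get(m, 0) + len(sq)
    if not any_steps:
        raise ValueError("no track has >= 2 samples; cannot build an MSD curve")
    ms = sorted(sums)
    lags = np.array([m * dt for m in ms])
    msd = np.array([sums[m] / counts[m] for m in ms])
    cnt = np.array([counts[m] for m in ms])
    return MSDCurve(lags=lags, msd=msd, counts=cnt)


def _weighted_fit(model, curve: MSDCurve, p0, bounds, name: str, maxfev=10000):
    """curve_fit with weights proportional to per-lag counts, with restarts."""
    # weight w_i ∝ counts_i in the χ² objective  <=>  sigma_i = 1/sqrt(counts_i)
    sigma = 1.0 / np.sqrt(curve.counts.astype(float))
    rng = np.random.default_rng(0)
    p0 = np.asarray(p0, dtype=float)
    last_exc = None
    for attempt in range(6):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.3, 3.0, size=len(p0))
        start = np.clip(start, bounds[0], bounds[1])
        try:
            popt, pcov = curve_fit(
                model,
                curve.lags,
                curve.msd,
                p0=start,
                sigma=sigma,
                absolute_sigma=False,
                bounds=bounds,
                maxfev=maxfev,
            )
            se = np.sqrt(np.diag(pcov))
            return popt, se
        except (RuntimeError, ValueError) as exc:  # non-convergence
            last_exc = exc
    raise FitError(
        f"{name} fit did not converge after restarts "
        f"(n_lags={len(curve)}, last error: {last_exc})"
    )


def fit_power_law(curve: MSDCurve) -> PowerLawFit:
    """Weighted NLS fit of MSD = k·t^α.

    Fitted on the original scale (not log-log) so the count weighting acts
    on the MSD values themselves.  Standard errors come from the
    residual-variance-scaled covariance of the fit.
    """
    if len(curve) < 3:
        raise ValueError("power-law fit needs >= 3 lags")

    def model(t, k, alpha):
        return k * np.power(t, alpha)

    k0 = max(curve.msd[0] / curve.lags[0], 1e-12)
    popt, se = _weighted_fit(
        model,
        curve,
        p0=(k0, 1.0),
        bounds=([1e-300, -10.0], [np.inf, 10.0]),
        name="power-law",
    )
    return PowerLawFit(k=popt[0], k_se=se[0], alpha=popt[1], alpha_se=se[1])


def furth_model(t, S, P):
    """Fürth persistent-random-walk MSD: 2S²P·[t − P·(1 − e^(−t/P))]."""
    t = np.asarray(t, dtype=float)
    return 2.0 * S * S * P * (t - P * (1.0 - np.exp(-t / P)))


def fit_furth(curve: MSDCurve, max_lags: int | None = 5) -> FurthFit:
    """Weighted NLS fit of the Fürth model; S and P constrained positive.

    By default only the first ``max_lags`` lags are fitted (200 min at the
    standard 40-min interval).  The persistence time is identified by the
    curvature of the MSD at short lags (t of order P); at long lags the
    model is asymptotically linear and, whenever the data carry any
    ballistic component (e.g. a directional drift, whose MSD grows as t²),
    an unrestricted fit chases that tail and P degenerates towards the
    ballistic regime.  Pass ``max_lags=None`` to fit the full curve, e.g.
    for parameter-recovery checks on data generated from the model itself.
    """
    if max_lags is not None and max_lags < 3:
        raise ValueError("max_lags must be >= 3 (or None for all lags)")
    if max_lags is not None and len(curve) > max_lags:
        curve = MSDCurve(
            lags=curve.lags[:max_lags],
            msd=curve.msd[:max_lags],
            counts=curve.counts[:max_lags],
        )
    if len(curve) < 3:
        raise ValueError("Fürth fit needs >= 3 lags")
    dt = curve.lags[0]
    S0 = max(math.sqrt(curve.msd[0]) / dt, 1e-9)
    P0 = dt
    popt, se = _weighted_fit(
        furth_model,
        curve,
        p0=(S0, P0),
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        name="Fürth",
    )
    return FurthFit(S=popt[0], S_se=se[0], P=popt[1], P_se=se[1])
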