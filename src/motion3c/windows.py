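"""Windowed time-course analysis and the time-vs-vector persistence relation.

Two complementary views of the same statistics:

* :func:`windowed_analysis` slides an overlapping window (default 4 h,
  stepped by one 40-min interval) along the experiment and runs the
  three-component decomposition inside each window, tracking how average
  displacement, random module and the normalised persistence and bias
  modules evolve — e.g. the decay of the bias as a wound closes.

* :func:`persistence_relation` compares, across datasets, persistence
  expressed as a time (Fürth P, normalised by the interval Δt) with
  persistence expressed as a vector module (decomposed p, normalised by
  the mean random module).  Across unbiased populations the two follow a
  no-intercept quadratic y = a·x² with a ≈ 2; biased populations sit
  systematically above the curve because the Fürth P absorbs the bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .decompose import decompose
from .msd import fit_furth, msd_curve
from .tracks import Track, TrackSet, steps as extract_steps

__all__ = [
    "WindowRecord",
    "WindowSeries",
    "PersistenceRelationFit",
    "windowed_analysis",
    "fit_quadratic_no_intercept",
    "persistence_relation",
]

logger = logging.getLogger(__name__)


@dataclass
class WindowRecord:
    t_start: float  # minutes
    avg_distance: float  # mean displacement length, μm per interval
    r_mean: float  # mean random module, μm
    p_norm: float  # persistence module / random module
    b_norm: float  # bias module / random module
    n_steps: int
    delta: Optional[float] = None  # degrees, if an expected direction was given


@dataclass
class WindowSeries:
    window: float  # minutes
    step: float  # minutes
    records: list

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "t_start": r.t_start,
                    "avg_distance_um": r.avg_distance,
                    "r_mean_um": r.r_mean,
                    "p_norm": r.p_norm,
                    "b_norm": r.b_norm,
                    "n_steps": r.n_steps,
                    "delta_deg": r.delta,
                }
                for r in self.records
            ]
        )


@dataclass
class PersistenceRelationFit:
    a: float  # quadratic coefficient
    a_se: float
    r_squared: float
    points: np.ndarray  # (n, 2): x = p/r_mean, y = P/Δt
    degenerate: bool = False  # all x ≈ 0: coefficient not identifiable


def _clip_trackset(ts: TrackSet, t0: float, t1: float) -> TrackSet:
    """Restrict every track to samples with t0 <= time <= t1."""
    kept = []
    for tr in ts:
        mask = (tr.times >= t0) & (tr.times <= t1)
        if not mask.any():
            continue
        idx = np.flatnonzero(mask)
        kept.append(
            Track(
                id=tr.id,
                frames=tr.frames[idx],
                times=tr.times[idx],
                xy=tr.xy[idx],
                origin=tr.origin,
                destiny=tr.destiny,
                meta={c: [v[i] for i in idx] for c, v in tr.meta.items()},
            )
        )
    return TrackSet(tracks=kept, interval=ts.interval)


def windowed_analysis(
    ts: TrackSet,
    window: float = 240.0,
    step: float = 40.0,
    expected_direction: Optional[float] = None,
    min_steps: int = 30,
) -> WindowSeries:
    """Decompose a TrackSet inside overlapping time windows.

    A window starting at t covers samples with t <= time <= t + window (a
    240-min window at 40-min sampling spans 7 samples, hence 6 steps per
    uninterrupted track).  Windows whose clipped data yield fewer than
    ``min_steps`` regression steps are omitted with a logged warning
    rather than reported with uninformative errors.
    """
    dt = ts.interval
    for name, value in (("window", window), ("step", step)):
        ratio = value / dt
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError(f"{name} must be a positive multiple of the interval")
    t_min = min(float(tr.times[0]) for tr in ts)
    t_max = max(float(tr.times[-1]) for tr in ts)
    records = []
    t = t_min
    while t + window <= t_max + 1e-9:
        sub = _clip_trackset(ts, t, t + window)
        try:
            res = decompose(sub, expected_direction=expected_direction)
        except ValueError:
            res = None
        if res is None or res.n_steps_used < min_steps:
            n = 0 if res is None else res.n_steps_used
            logger.warning(
                "window [%g, %g): only %d usable steps (< %d), omitted",
                t,
                t + window,
                n,
                min_steps,
            )
            t += step
            continue
        step_list = extract_steps(sub)
        avg_distance = float(np.mean([s.length for s in step_list]))
        records.append(
            WindowRecord(
                t_start=t,
                avg_distance=avg_distance,
                r_mean=res.r_mean,
                p_norm=res.p / res.r_mean if res.r_mean > 0 else np.nan,
                b_norm=res.b / res.r_mean if res.r_mean > 0 else np.nan,
                n_steps=res.n_steps_used,
                delta=res.delta,
            )
        )
        t += step
    return WindowSeries(window=window, step=step, records=records)


def fit_quadratic_no_intercept(x: np.ndarray, y: np.ndarray):
    """Least-squares fit of y = a·x² with no intercept or linear term.

    Closed form a = Σx²y / Σx⁴.  R² is computed against the zero-function
    baseline (R² = 1 − Σ(y − a·x²)² / Σy²), the consistent choice for a
    no-intercept model.  Returns (a, a_se, r_squared).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x4 = float(np.sum(x**4))
    if x4 <= 0.0:
        raise ValueError("all x are zero: coefficient not identifiable")
    a = float(np.sum(x * x * y)) / x4
    resid = y - a * x * x
    dof = max(len(x) - 1, 1)
    sigma2 = float(resid @ resid) / dof
    a_se = float(np.sqrt(sigma2 / x4))
    ss_tot = float(y @ y)
    r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else np.nan
    return a, a_se, r2


def persistence_relation(datasets: Sequence[TrackSet]) -> PersistenceRelationFit:
    """Fit y = a·x² across datasets, x = p/r_mean and y = Fürth P/Δt.

    One point per dataset.  The no-intercept quadratic has the closed-form
    least-squares solution a = Σx²y / Σx⁴; the standard error uses the
    residual variance with n − 1 degrees of freedom, and R² is computed
    against the zero-function baseline, R² = 1 − Σ(y − a·x²)² / Σy²,
    consistent with a model that has no intercept.
    """
    if len(datasets) < 2:
        raise ValueError("persistence_relation needs >= 2 datasets")
    xs, ys = [], []
    for ts in datasets:
        res = decompose(ts)
        fit = fit_furth(msd_curve(ts))
        xs.append(res.p / res.r_mean if res.r_mean > 0 else np.nan)
        ys.append(fit.P / ts.interval)
    x = np.asarray(xs)
    y = np.asarray(ys)
    points = np.column_stack([x, y])
    if float(np.sum(x**4)) < 1e-12:
        logger.warning("all normalised persistence modules ~ 0: fit degenerate")
        return PersistenceRelationFit(
            a=np.nan, a_se=np.nan, r_squared=np.nan, points=points, degenerate=True
        )
    a, a_se, r2 = fit_quadratic_no_intercept(x, y)
    return PersistenceRelationFit(a=a, a_se=a_se, r_squared=r2, points=points)
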