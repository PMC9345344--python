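"""Three-component decomposition of observed displacements.

The central procedure of the package.  Each observed displacement d over
one analysis interval is modelled as the vector sum

    d = b·û(β) + p·û(previous displacement) + r

of a constant bias of module b along direction β, a persistence vector of
module p along the previous displacement, and a random residual r.
Projected on the bias direction, the displacement obeys

    d_b = b + p·cos(α)

where α is the angle between the previous displacement and the bias
direction: persistence contributes fully when the previous step pointed
along the bias (α = 0) and negatively when it pointed against it.  This is
linear in (b, p) with regressor cos(α), so b and p are estimated by
ordinary least squares over all steps that have a defined predecessor
direction.

The pipeline (:func:`decompose`):

1. :func:`raw_bias` — β from the mean of *all* displacement vectors;
2. :func:`directional_samples` — (d_b, α) per step with a predecessor;
3. :func:`fit_bias_persistence` — OLS of d_b on cos(α);
4. :func:`extract_random` — per-step residual vectors and their mean
   module, the natural normaliser for b and p.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .tracks import Step, TrackSet, steps as extract_steps, wrap_angle

__all__ = [
    "RawBias",
    "DirectionalSample",
    "DecompositionResult",
    "raw_bias",
    "directional_samples",
    "fit_bias_persistence",
    "extract_random",
    "delta_angle",
    "decompose",
]


@dataclass
class RawBias:
    """Mean displacement vector: the naive bias estimate before decomposition."""

    vector: np.ndarray  # μm per interval
    module: float  # |vector|
    beta: float  # direction, radians in (-π, π]
    degenerate: bool = False  # true when the mean vector is (numerically) zero


@dataclass
class DirectionalSample:
    """One step's projection on the bias direction and its α angle."""

    d_b: float  # μm
    alpha_angle: float  # radians in (-π, π]


@dataclass
class DecompositionResult:
    b: float  # bias module, μm per interval (unconstrained sign)
    b_se: float
    beta: float  # bias direction, radians
    p: float  # persistence module, μm per interval (unconstrained sign)
    p_se: float
    random_vectors: np.ndarray  # (n_steps_used, 2), μm
    r_mean: float  # mean random module, μm
    n_steps_used: int
    raw: RawBias = None
    delta: Optional[float] = None  # degrees vs expected direction, if given


def raw_bias(step_list: Sequence[Step]) -> RawBias:
    """Average all displacement vectors (all tracks, all times).

    The direction β of the resulting vector seeds the decomposition.  A
    zero mean vector (e.g. perfectly cancelling steps) is flagged
    degenerate and β set to 0.
    """
    if len(step_list) == 0:
        raise ValueError("raw_bias needs at least one step")
    vec = np.mean([s.d for s in step_list], axis=0)
    module = float(np.hypot(vec[0], vec[1]))
    if module == 0.0:
        return RawBias(vector=vec, module=0.0, beta=0.0, degenerate=True)
    return RawBias(
        vector=vec, module=module, beta=float(math.atan2(vec[1], vec[0]))
    )


def directional_samples(
    step_list: Sequence[Step], beta: float
) -> list[DirectionalSample]:
    """Project each step on the bias direction and compute its α angle.

    d_b = |d|·cos(θ_d − β) is the signed length of the displacement along
    the bias direction; α = θ_prev − β (wrapped to (-π, π]) is the angle of
    the previous displacement relative to the bias.  Steps without a
    defined predecessor direction are excluded.
    """
    u = np.array([math.cos(beta), math.sin(beta)])
    out = []
    for s in step_list:
        if s.prev_dir is None:
            continue
        d_b = float(s.d @ u)
        theta_prev = math.atan2(s.prev_dir[1], s.prev_dir[0])
        out.append(
            DirectionalSample(d_b=d_b, alpha_angle=wrap_angle(theta_prev - beta))
        )
    return out


def fit_bias_persistence(
    samples: Sequence[DirectionalSample],
) -> tuple[float, float, float, float]:
    """OLS fit of d_b = b + p·cos(α); returns (b, b_se, p, p_se).

    Both parameters are unconstrained in sign: with near-zero true
    persistence, sampling noise legitimately produces small negative
    estimates.  Standard errors use the usual OLS covariance with residual
    variance (n − 2 degrees of freedom).
    """
    n = len(samples)
    if n < 3:
        raise ValueError("need >= 3 directional samples")
    y = np.array([s.d_b for s in samples])
    c = np.cos([s.alpha_angle for s in samples])
    X = np.column_stack([np.ones(n), c])
    # rank check: cos(α) must take at least two distinct values
    if np.ptp(c) < 1e-12:
        raise ValueError("rank-deficient design: all cos(α) values identical")
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    dof = n - 2
    sigma2 = float(resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    return float(coef[0]), float(se[0]), float(coef[1]), float(se[1])


def extract_random(
    step_list: Sequence[Step], b: float, beta: float, p: float
) -> tuple[np.ndarray, float]:
    """Strip bias and persistence from each step to recover random vectors.

    For every step with a defined predecessor direction,
    r = d − b·û(β) − p·û(prev_dir).  By construction the reconstruction
    identity d = b·û(β) + p·û(prev_dir) + r holds exactly.  Returns the
    array of random vectors and their mean module.
    """
    u_b = np.array([math.cos(beta), math.sin(beta)])
    vecs = []
    for s in step_list:
        if s.prev_dir is None:
            continue
        vecs.append(s.d - b * u_b - p * s.prev_dir)
    if not vecs:
        return np.empty((0, 2)), 0.0
    arr = np.array(vecs)
    r_mean = float(np.mean(np.hypot(arr[:, 0], arr[:, 1])))
    return arr, r_mean


def delta_angle(beta: float, expected_direction: float) -> float:
    """Minimal absolute angle (degrees, in [0, 180]) between the estimated
    bias direction and an externally expected migration direction.

    Both arguments are radians.  For a wound-healing assay the expected
    direction is perpendicular to the wound, towards the empty space.
    """
    diff = abs(wrap_angle(beta - expected_direction))
    return math.degrees(diff)


def decompose(
    ts: TrackSet, expected_direction: Optional[float] = None
) -> DecompositionResult:
    """Run the full decomposition pipeline on a resampled TrackSet.

    β is estimated once for the whole analysed window from all steps; the
    regression and the random-vector extraction use only steps with a
    defined predecessor direction.  If ``expected_direction`` (radians) is
    given, the δ angle against it is reported; it is left undefined when
    the raw bias is degenerate.
    """
    step_list = extract_steps(ts)
    rb = raw_bias(step_list)
    samples = directional_samples(step_list, rb.beta)
    b, b_se, p, p_se = fit_bias_persistence(samples)
    random_vectors, r_mean = extract_random(step_list, b, rb.beta, p)
    delta = None
    if expected_direction is not None and not rb.degenerate:
        delta = delta_angle(rb.beta, expected_direction)
    return DecompositionResult(
        b=b,
        b_se=b_se,
        beta=rb.beta,
        p=p,
        p_se=p_se,
        random_vectors=random_vectors,
        r_mean=r_mean,
        n_steps_used=len(samples),
        raw=rb,
        delta=delta,
    )
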