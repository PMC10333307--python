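"""Poincare-ball (gyrovector) primitives.

The ball of curvature ``c > 0`` is the open set ``{x : sqrt(c) ||x|| < 1}``
with conformal metric factor ``lambda_p = 2 / (1 - c ||p||^2)``.  ``c = 0`` is
handled everywhere as an explicit Euclidean branch (never as a small-c limit),
because zero curvature is a first-class model configuration.

All operations are batched over arbitrary leading dimensions; the coordinate
axis is the last one.  They accept either plain numpy arrays or
:class:`hyperseg.nn.Tensor`, in which case they are differentiable.

Numerical guards
----------------
* ``EPS_BALL = 1e-5``  — containment margin used by :func:`project_to_ball`.
* ``ATANH_MAX = 1 - 1e-7`` — clamp on arguments of ``arctanh``.
* ``EPS_NORM = 1e-15`` — below this, divisions by a vector norm are skipped
  and the operand is returned unchanged (the exact limit of the formulas).
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F

__all__ = [
    "EPS_BALL", "ATANH_MAX", "EPS_NORM",
    "check_curvature", "conformal_factor", "mobius_add", "mobius_scalar_mul",
    "ball_distance", "exp_map", "exp_map0", "project_to_ball",
]

EPS_BALL = 1e-5
ATANH_MAX = 1.0 - 1e-7
EPS_NORM = 1e-15


def _data(x) -> np.ndarray:
    return x.data if F.is_tensor(x) else np.asarray(x)


def check_curvature(c) -> float:
    c = float(c)
    if c < 0 or not np.isfinite(c):
        raise ValueError(f"curvature must be a finite non-negative real, got {c}")
    return c


def _check_same_dim(u, v):
    du, dv = _data(u), _data(v)
    if du.shape[-1] != dv.shape[-1]:
        raise ValueError(
            f"dimension mismatch: {du.shape[-1]} vs {dv.shape[-1]}")


def conformal_factor(p, c):
    """``lambda_p = 2 / (1 - c ||p||^2)``; equals 2 at the origin or for c=0.

    The same quantity appears as the metric factor and in the exponential
    map; it diverges at the ball boundary, so points must be strictly
    interior.
    """
    c = check_curvature(c)
    if c == 0.0:
        sq = _data(p)
        return np.full(sq.shape[:-1], 2.0) if not F.is_tensor(p) else \
            F.sum_last(p * 0.0, keepdims=False) + 2.0
    sq = F.sum_last(p * p, keepdims=False)
    if np.any(c * _data(sq) >= 1.0):
        raise ValueError("point outside the closed ball: c * ||p||^2 >= 1")
    return 2.0 / (1.0 - c * sq)


def mobius_add(u, v, c, *, project: bool = True):
    """Mobius addition ``u (+)_c v`` — the gyrovector analogue of ``u + v``.

    Non-commutative and non-associative for c > 0; exactly ``u + v`` at c=0.
    The result is re-projected into the open ball unless ``project=False``.
    """
    c = check_curvature(c)
    _check_same_dim(u, v)
    if c == 0.0:
        return u + v
    uv = F.sum_last(u * v)
    u2 = F.sum_last(u * u)
    v2 = F.sum_last(v * v)
    num = (1.0 + 2.0 * c * uv + c * v2) * u + (1.0 - c * u2) * v
    den = 1.0 + 2.0 * c * uv + c * c * u2 * v2
    out = num / den
    return project_to_ball(out, c) if project else out


def mobius_scalar_mul(r, u, c):
    """Mobius scalar multiplication ``r (x)_c u``; ``r * u`` at c=0."""
    c = check_curvature(c)
    r = float(r)
    if c == 0.0:
        return r * u
    sc = np.sqrt(c)
    norm = F.norm_last(u * 1.0, eps=EPS_NORM)
    arg = F.clip(sc * norm, None, ATANH_MAX)
    scaled = F.tanh(r * F.arctanh(arg)) / (sc * norm) * u
    small = _data(norm) <= EPS_NORM
    if np.any(small):
        scaled = F.where(small, u * 0.0, scaled)
    return project_to_ball(scaled, c)


def ball_distance(u, v, c):
    """Geodesic distance ``(2/sqrt(c)) * arctanh(sqrt(c) ||(-u) (+)_c v||)``.

    At c=0 this returns ``2 ||u - v||`` — the exact limit (the factor 2 is the
    conformal factor at zero curvature).  Symmetric, zero iff ``u == v``.
    """
    c = check_curvature(c)
    _check_same_dim(u, v)
    if c == 0.0:
        return 2.0 * F.norm_last(v - u, keepdims=False)
    w = mobius_add(-1.0 * u, v, c, project=False)
    sc = np.sqrt(c)
    arg = sc * F.norm_last(w, keepdims=False)
    if np.any(_data(arg) >= 1.0 + 1e-9):
        raise ValueError("arctanh argument >= 1: points escaped the ball")
    return (2.0 / sc) * F.arctanh(F.clip(arg, None, ATANH_MAX))


def exp_map(p, v, c):
    """Exponential map at ``p``: lifts tangent vector ``v`` onto the ball.

    ``exp_p(v) = p (+)_c ( tanh(sqrt(c) * lambda_p * ||v|| / 2) * v /
    (sqrt(c) * ||v||) )``; returns ``p`` when ``||v||`` underflows and
    ``p + v`` on the Euclidean branch.
    """
    c = check_curvature(c)
    _check_same_dim(p, v)
    if c == 0.0:
        return p + v
    sc = np.sqrt(c)
    norm = F.norm_last(v * 1.0, eps=EPS_NORM)
    lam = conformal_factor(p, c)
    lam = lam.reshape(_data(lam).shape + (1,)) if F.is_tensor(lam) else \
        np.asarray(lam)[..., None]
    second = F.tanh(sc * lam * norm / 2.0) * v / (sc * norm)
    small = _data(norm) <= EPS_NORM
    if np.any(small):
        second = F.where(small, v * 0.0, second)
    return mobius_add(p, second, c)


def exp_map0(v, c):
    """Exponential map at the origin: ``tanh(sqrt(c)||v||) * v/(sqrt(c)||v||)``.

    This is the lift used on every pixel feature; at c=0 it is the identity.
    The output norm is strictly below the ball radius ``1/sqrt(c)``.
    """
    c = check_curvature(c)
    if c == 0.0:
        return v
    sc = np.sqrt(c)
    norm = F.norm_last(v * 1.0, eps=EPS_NORM)
    out = F.tanh(sc * norm) * v / (sc * norm)
    small = _data(norm) <= EPS_NORM
    if np.any(small):
        out = F.where(small, v * 1.0, out)
    # tanh saturates to 1.0 in floating point for huge inputs; re-project so
    # the result is strictly interior, as for every ball-valued operation
    return project_to_ball(out, c)


def project_to_ball(x, c, eps: float = EPS_BALL):
    """Rescale ``x`` to norm ``(1 - eps)/sqrt(c)`` whenever it falls outside.

    Interior points pass through unchanged (bitwise).  No-op at c=0.
    """
    c = check_curvature(c)
    if c == 0.0:
        return x
    if not (0.0 < eps <= 1e-2):
        raise ValueError("eps must lie in (0, 1e-2]")
    norm = F.norm_last(x * 1.0, eps=EPS_NORM)
    limit = (1.0 - eps) / np.sqrt(c)
    outside = _data(norm) > limit
    if not np.any(outside):
        return x
    scaled = x * (limit / norm)
    return F.where(outside, scaled, x)
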