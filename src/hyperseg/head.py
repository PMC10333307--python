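"""Hyperbolic multinomial logistic regression over per-pixel embeddings.

Euclidean pixel features ``f(X)_ij`` are lifted into the Poincare ball with
the exponential map at the origin; each class ``y`` owns a *gyroplane* — a
hyperbolic hyperplane parameterized by an offset point ``p_y`` in the ball
and a tangent normal ``a_y`` — and the class logit is a scaled signed
hyperbolic distance from the lifted pixel to that gyroplane.

The naive logit requires the Mobius sum ``p_y (+)_c z_ij`` for every
(pixel, class) pair, an ``O(pixels * classes * n)`` intermediate.  Both the
inner product ``<p (+)_c z, a>`` and the squared norm ``||p (+)_c z||^2``
are bilinear in ``p`` and ``z`` given two scalars::

    p (+)_c z = A p + B z,
    A = (1 + 2c<p,z> + c||z||^2) / den,   B = (1 - c||p||^2) / den,
    den = 1 + 2c<p,z> + c^2 ||p||^2 ||z||^2,

so every quantity follows from the three scalar reductions ``<p,z>``,
``||p||^2`` and ``||z||^2`` — the per-pair memory drops to
``O(pixels * classes)``.  That rewrite is the centrepiece of this module and
is cross-checked against the materialized Mobius sum in the test suite.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import geometry as geo
from .nn import functional as F
from .nn.modules import Module
from .nn.tensor import Parameter

__all__ = [
    "rewrite_coefficients", "gyro_inner", "gyro_sq_norm",
    "gyroplane_distance", "hyperbolic_logits", "segmentation_loss",
    "GyroplaneBank", "RiemannianSGD", "rsgd_step",
    "BOUNDARY_EPS", "NORMAL_FLOOR",
]

BOUNDARY_EPS = 1e-7     # 1 - c||p(+)z||^2 below this counts as "on boundary"
NORMAL_FLOOR = 1e-12    # a gyroplane normal below this norm is degenerate


def _rewrite_from_reductions(pz, p2, z2, c):
    """A, B of the Mobius rewrite from the three scalar reductions."""
    den = 1.0 + 2.0 * c * pz + (c * c) * p2 * z2
    dd = den.data if F.is_tensor(den) else np.asarray(den)
    if np.any(dd <= 0.0):
        raise ValueError("rewrite denominator <= 0: ball containment violated")
    A = (1.0 + 2.0 * c * pz + c * z2) / den
    B = (1.0 - c * p2) / den
    return A, B


def rewrite_coefficients(p, z, c):
    """Scalars ``(A, B)`` with ``p (+)_c z = A p + B z`` (elementwise batch).

    At c=0 both coefficients are exactly 1.
    """
    c = geo.check_curvature(c)
    if c == 0.0:
        one = F.sum_last(p * 0.0 + z * 0.0, keepdims=False) + 1.0
        return one, one * 1.0
    pz = F.sum_last(p * z, keepdims=False)
    p2 = F.sum_last(p * p, keepdims=False)
    z2 = F.sum_last(z * z, keepdims=False)
    return _rewrite_from_reductions(pz, p2, z2, c)


def gyro_inner(p, z, a, c):
    """``<p (+)_c z, a>`` without materializing the Mobius sum."""
    A, B = rewrite_coefficients(p, z, c)
    pa = F.sum_last(p * a, keepdims=False)
    za = F.sum_last(z * a, keepdims=False)
    return A * pa + B * za


def gyro_sq_norm(p, z, c):
    """``||p (+)_c z||^2`` from the rewrite: ``A^2 p2 + 2AB <p,z> + B^2 z2``."""
    c = geo.check_curvature(c)
    pz = F.sum_last(p * z, keepdims=False)
    p2 = F.sum_last(p * p, keepdims=False)
    z2 = F.sum_last(z * z, keepdims=False)
    if c == 0.0:
        return p2 + 2.0 * pz + z2
    A, B = _rewrite_from_reductions(pz, p2, z2, c)
    return A * A * p2 + 2.0 * A * B * pz + B * B * z2


def gyroplane_distance(z, p, a, c):
    """Signed hyperbolic distance from ``z`` to the gyroplane ``(p, a)``.

    ``(1/sqrt(c)) * asinh( 2 sqrt(c) <p (+)_c z, a> /
    ((1 - c ||p (+)_c z||^2) ||a||) )``.  The sign of the inner product is
    retained so the value discriminates the two sides of the gyroplane; it is
    invariant to positive rescaling of ``a``.
    """
    c = geo.check_curvature(c)
    if c == 0.0:
        raise ValueError("gyroplane_distance requires c > 0; "
                         "use the Euclidean logit branch at c = 0")
    an = np.linalg.norm(np.atleast_1d(
        a.data if F.is_tensor(a) else np.asarray(a)), axis=-1)
    if np.any(an <= NORMAL_FLOOR):
        raise ValueError("gyroplane normal has (near) zero norm")
    inner = gyro_inner(p, z, a, c)
    sqn = gyro_sq_norm(p, z, c)
    denom = 1.0 - c * sqn
    dd = denom.data if F.is_tensor(denom) else np.asarray(denom)
    if np.any(dd <= BOUNDARY_EPS):
        raise ValueError("point effectively on the ball boundary")
    norm_a = F.norm_last(a * 1.0, keepdims=False)
    sc = np.sqrt(c)
    return (1.0 / sc) * F.arcsinh(2.0 * sc * inner / (denom * norm_a))


def hyperbolic_logits(features, bank: "GyroplaneBank", shape_log=None):
    """Per-pixel class logits from Euclidean features of shape ``(..., n)``.

    Lifts features with ``exp_0``, then computes
    ``zeta_y(z) = (lambda_{p_y} ||a_y|| / sqrt(c)) * asinh(arg)`` with the
    rewrite reductions; the scale makes the c -> 0 limit equal the Euclidean
    multinomial-logistic logit ``4 <z - p_y, a_y>``, which is also the exact
    branch taken at c = 0.

    ``shape_log``, if a list, receives the shapes of every allocated
    per-(pixel, class) intermediate — used to audit that memory scales as
    pixels x classes, never pixels x classes x n.
    """
    c = bank.curvature
    if F.is_tensor(features):
        p = bank.offsets * -1.0 if bank.negate_offset else bank.offsets * 1.0
        a = bank.normals
    else:  # pure-numpy inference path: detach parameters
        p = -bank.offsets.data if bank.negate_offset else bank.offsets.data
        a = bank.normals.data
    lead = features.shape[:-1]
    n = features.shape[-1]
    m = int(np.prod(lead)) if lead else 1
    f = features.reshape((m, n)) if F.is_tensor(features) else \
        np.asarray(features).reshape(m, n)
    if c != 0.0 and bank.max_feature_norm is not None:
        # clipped lift: capping ||f|| keeps z off the ball shell, where the
        # conformal blow-up saturates tanh and starves the gradient — the
        # standard cure for vanishing gradients in hyperbolic classifiers
        r = bank.max_feature_norm
        fn = F.norm_last(f * 1.0, eps=geo.EPS_NORM)
        fd = fn.data if F.is_tensor(fn) else fn
        if np.any(fd > r):
            f = F.where(fd > r, f * (r / fn), f)
    # containment margin keeps the 1 - c ||p (+) z||^2 denominators away
    # from zero for arbitrarily large pre-lift features
    z = geo.project_to_ball(geo.exp_map0(f, c), c)

    def log(*arrs):
        if shape_log is not None:
            for arr in arrs:
                shape_log.append(tuple(
                    arr.data.shape if F.is_tensor(arr) else np.shape(arr)))

    pT = p.swapaxes(-1, -2) if F.is_tensor(p) else np.swapaxes(p, -1, -2)
    aT = a.swapaxes(-1, -2) if F.is_tensor(a) else np.swapaxes(a, -1, -2)
    za = z @ aT                                    # (m, C)
    pa = F.sum_last(p * a, keepdims=False)         # (C,)
    if c == 0.0:
        # exact c -> 0 limit of the gyroplane logit under the active offset
        # convention: 4 <z + p_eff, a>, i.e. 4 <z - p, a> when the offset is
        # negated (the default)
        zeta = 4.0 * (za + pa)
        log(za, zeta)
    else:
        pz = z @ pT                                # (m, C)
        z2 = F.sum_last(z * z)                     # (m, 1)
        p2 = F.sum_last(p * p, keepdims=False)     # (C,)
        A, B = _rewrite_from_reductions(pz, p2, z2, c)
        inner = A * pa + B * za
        sqn = A * A * p2 + 2.0 * A * B * pz + B * B * z2
        # re-projection of the implicit Mobius sum: cap its squared norm at
        # the containment margin, as for any other ball-valued result
        sqn = F.clip(sqn, None, (1.0 - geo.EPS_BALL) ** 2 / c)
        denom = 1.0 - c * sqn
        norm_a = F.norm_last(a * 1.0, keepdims=False)   # (C,)
        lam = 2.0 / (1.0 - c * p2)
        sc = np.sqrt(c)
        arg = 2.0 * sc * inner / (denom * norm_a)
        zeta = (lam * norm_a / sc) * F.arcsinh(arg)
        log(pz, A, B, inner, sqn, denom, arg, zeta)
    return zeta.reshape(lead + (bank.num_classes,))


def segmentation_loss(logits, labels, ignore_index: int = 255):
    """Mean softmax cross-entropy over non-ignored pixels.

    ``logits``: tensor/array of shape ``(..., C)``; ``labels``: integer array
    of the leading shape with values in ``{0..C-1}`` or ``ignore_index``.
    """
    labels = np.asarray(labels)
    C = logits.shape[-1]
    m = int(np.prod(labels.shape)) if labels.shape else 1
    flat = logits.reshape((m, C))
    lab = labels.reshape(m)
    valid = lab != ignore_index
    nv = int(valid.sum())
    if nv == 0:
        raise ValueError("all pixels carry the ignore label")
    if lab[valid].min() < 0 or lab[valid].max() >= C:
        raise ValueError("labels out of range")
    rows = np.nonzero(valid)[0]
    if F.is_tensor(flat):
        logp = F.log_softmax(flat, axis=-1)
        picked = logp[(rows, lab[rows])]
        return -picked.sum() * (1.0 / nv)
    logp = flat - flat.max(axis=-1, keepdims=True)
    logp = logp - np.log(np.exp(logp).sum(axis=-1, keepdims=True))
    return float(-logp[rows, lab[rows]].mean())


class GyroplaneBank(Module):
    """One gyroplane (offset ``p_y``, tangent normal ``a_y``) per class.

    Offsets start at the ball origin so initial logits coincide with a
    Euclidean linear classifier; normals start as a small isotropic Gaussian.

    ``negate_offset`` chooses between the two sign conventions for the
    gyroplane condition — ``<(-p) (+)_c z, a> = 0`` (default) or the literal
    ``<p (+)_c z, a> = 0``.  They differ only by the reparameterization
    ``p -> -p`` of the learned offset; the default is the one whose c -> 0
    limit is the familiar Euclidean logit ``4 <z - p, a>``.
    """

    def __init__(self, num_classes: int, dim: int, curvature: float,
                 rng: np.random.Generator, init_std: float = 0.01,
                 negate_offset: bool = True,
                 max_feature_norm: float | None = 3.0):
        if num_classes < 2:
            raise ValueError("need at least two classes")
        self.num_classes = num_classes
        self.dim = dim
        self.curvature = geo.check_curvature(curvature)
        self.negate_offset = bool(negate_offset)
        self.max_feature_norm = max_feature_norm
        self.offsets = Parameter(np.zeros((num_classes, dim)))
        self.normals = Parameter(rng.normal(0.0, init_std, (num_classes, dim)))
        self._rng = rng
        self._revive_normals()

    def _revive_normals(self):
        norms = np.linalg.norm(self.normals.data, axis=-1)
        dead = norms < NORMAL_FLOOR
        if np.any(dead):
            self.normals.data[dead] = self._rng.normal(
                0.0, 0.01, (int(dead.sum()), self.dim))

    def forward(self, features, shape_log=None):
        return hyperbolic_logits(features, self, shape_log=shape_log)


class RiemannianSGD:
    """RSGD for the gyroplane bank.

    Offsets live on the ball: the Euclidean gradient is rescaled by the
    inverse metric, ``g / lambda_p^2``, and applied through the exponential
    map at the current offset, then re-projected.  At c=0 this is plain SGD
    with the constant metric factor ``(2)^2 = 4``, i.e. ``p - lr * g / 4``.
    Normals are tangent-space parameters and take a plain SGD step.
    Non-finite gradients skip that parameter with a warning.

    Two stabilizers guard against the boundary trap of ball optimization
    (a gradient spike flings an offset toward the shell, where the inverse
    metric makes every subsequent step vanishingly small and the conformal
    factor inflates the logits): the per-row tangent step is capped at
    ``max_step``, and offsets are kept at scaled norm <= ``offset_bound``,
    bounding the conformal factor at about 2 / (1 - offset_bound^2).
    """

    def __init__(self, bank: GyroplaneBank, max_step: float = 0.1,
                 offset_bound: float = 0.9):
        self.bank = bank
        self.max_step = max_step
        self.offset_bound = offset_bound

    def zero_grad(self):
        self.bank.zero_grad()

    def step(self, lr: float):
        if lr <= 0:
            raise ValueError("lr must be positive")
        bank, c = self.bank, self.bank.curvature
        g = bank.offsets.grad
        if g is not None:
            if not np.all(np.isfinite(g)):
                warnings.warn("non-finite gradient on gyroplane offsets; "
                              "skipping update", RuntimeWarning)
            else:
                p = bank.offsets.data
                if c == 0.0:
                    bank.offsets.data = p - lr * g / 4.0
                else:
                    lam = 2.0 / (1.0 - c * (p * p).sum(-1, keepdims=True))
                    step = -lr * g / (lam * lam)
                    sn = np.linalg.norm(step, axis=-1, keepdims=True)
                    big = sn > self.max_step
                    step = np.where(
                        big, step * (self.max_step / np.maximum(sn, 1e-300)),
                        step)
                    new = geo.project_to_ball(geo.exp_map(p, step, c), c)
                    norm = np.linalg.norm(new, axis=-1, keepdims=True)
                    limit = self.offset_bound / np.sqrt(c)
                    out = norm > limit
                    bank.offsets.data = np.where(
                        out, new * (limit / np.maximum(norm, 1e-300)), new)
        ga = bank.normals.grad
        if ga is not None:
            if not np.all(np.isfinite(ga)):
                warnings.warn("non-finite gradient on gyroplane normals; "
                              "skipping update", RuntimeWarning)
            else:
                bank.normals.data = bank.normals.data - lr * ga
        bank._revive_normals()


def rsgd_step(bank: GyroplaneBank, lr: float) -> GyroplaneBank:
    """Single functional RSGD step using gradients stored on the bank."""
    RiemannianSGD(bank).step(lr)
    return bank
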