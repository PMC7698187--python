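"""Gaussian membership layer and weighted fuzzy logic neurons.

The first layer turns each feature value into a Gaussian membership degree.
The second layer aggregates the per-feature memberships of one rule with a
fuzzy logic neuron: classical AND (t-norm) and OR (t-conorm) neurons, plus
uninorm (interior identity element g), nullnorm (interior absorbing element
u) and a composed uninull operator that behaves as one uninorm below a knot
``beta`` and as another above it.  Before aggregation every membership is
passed through a relevancy transformation so that a feature with weight 0
contributes the aggregator's neutral value and a feature with weight 1
contributes its raw membership.

Default norms are the product t-norm and the probabilistic-sum t-conorm;
min/max are available.  Folds run left-to-right in feature order — the base
t-norms/t-conorms are associative so AND/OR are order-free, while uninorm
folds are order-dependent in the mixed region and feature order is the
documented contract.

All aggregators accept scalars or equal-shape arrays (evaluated
elementwise), which lets a whole layer of same-kind neurons be activated in
one vectorised fold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "NormPair",
    "PRODUCT_PROBSUM",
    "MIN_MAX",
    "GaussianSet",
    "LogicNeuron",
    "gaussian_membership",
    "uninorm",
    "nullnorm",
    "uninullnorm",
    "relevancy_transform",
    "neuron_activation",
    "layer_activations",
    "layer_activations_fast",
]

NEURON_KINDS = ("AND", "OR", "UNI", "NULL", "UNINULL")


@dataclass(frozen=True)
class NormPair:
    """A t-norm / t-conorm pair (commutative, associative, monotone)."""

    tnorm: Callable
    tconorm: Callable


PRODUCT_PROBSUM = NormPair(tnorm=lambda x, y: x * y,
                           tconorm=lambda x, y: x + y - x * y)
MIN_MAX = NormPair(tnorm=np.minimum, tconorm=np.maximum)


@dataclass
class GaussianSet:
    """One Gaussian fuzzy set: center and width in a given feature dimension."""

    center: float
    sigma: float
    dimension: int = 0
    cloud: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


def gaussian_membership(x: float, gset: GaussianSet) -> float:
    """exp(-((x - c) / sigma)^2 / 2); equals 1 at the center."""
    z = (x - gset.center) / gset.sigma
    return float(np.exp(-0.5 * z * z))


# ---------------------------------------------------------------------------
# aggregators (elementwise on scalars or arrays)
# ---------------------------------------------------------------------------

def _maybe_float(v, scalar_in: bool):
    return float(v) if scalar_in else np.asarray(v, dtype=float)


def uninorm(x, y, g: float, norms: NormPair = PRODUCT_PROBSUM):
    """Uninorm with identity element ``g``: t-norm-like below g, t-conorm-like
    above, ``min`` in the mixed region (conjunctive completion)."""
    scalar_in = np.isscalar(x) and np.isscalar(y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if g <= 0.0:
        return _maybe_float(norms.tconorm(x, y), scalar_in)
    if g >= 1.0:
        return _maybe_float(norms.tnorm(x, y), scalar_in)
    low = g * norms.tnorm(x / g, y / g)
    high = g + (1.0 - g) * norms.tconorm((x - g) / (1.0 - g), (y - g) / (1.0 - g))
    # closed sub-squares (identical on the shared corner) so that g is a true
    # identity; only the strictly mixed region falls back to min
    out = np.where((x <= g) & (y <= g), low,
                   np.where((x >= g) & (y >= g), high, np.minimum(x, y)))
    return _maybe_float(out, scalar_in)


def nullnorm(x, y, u: float, norms: NormPair = PRODUCT_PROBSUM):
    """Nullnorm with absorbing element ``u``: t-conorm-like below u, t-norm-like
    above, and exactly ``u`` in the mixed region."""
    scalar_in = np.isscalar(x) and np.isscalar(y)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if u <= 0.0:
        return _maybe_float(norms.tnorm(x, y), scalar_in)
    if u >= 1.0:
        return _maybe_float(norms.tconorm(x, y), scalar_in)
    low = u * norms.tconorm(x / u, y / u)
    high = u + (1.0 - u) * norms.tnorm((x - u) / (1.0 - u), (y - u) / (1.0 - u))
    out = np.where((x <= u) & (y <= u), low,
                   np.where((x >= u) & (y >= u), high, u))
    return _maybe_float(out, scalar_in)


def uninullnorm(x, y, beta: float, g: float, u: float,
                norms: NormPair = PRODUCT_PROBSUM):
    """Composed uninull operator: below the knot ``beta`` a uninorm with
    identity g/beta acts on the rescaled square, above it a uninorm with
    identity (u - beta)/(1 - beta); the mixed region evaluates to the knot
    ``beta`` itself (the median completion) — the only constant completion
    that keeps the composed operator monotone, since the lower sub-square is
    internally disjunctive and can exceed ``min(x, y)``.

    Requires g <= beta <= u for the rescaled identities to be well defined.
    At the parameter cube's corners the operator degenerates to the pure
    t-norm or t-conorm.
    """
    scalar_in = np.isscalar(x) and np.isscalar(y)
    if beta <= 0.0:
        return uninorm(x, y, u, norms)
    if beta >= 1.0:
        return uninorm(x, y, g, norms)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    low = beta * np.asarray(uninorm(x / beta, y / beta, g / beta, norms))
    g2 = (u - beta) / (1.0 - beta)
    high = beta + (1.0 - beta) * np.asarray(
        uninorm((x - beta) / (1.0 - beta), (y - beta) / (1.0 - beta), g2, norms))
    out = np.where((x <= beta) & (y <= beta), low,
                   np.where((x >= beta) & (y >= beta), high, beta))
    return _maybe_float(out, scalar_in)


# ---------------------------------------------------------------------------
# relevancy transformation and neurons
# ---------------------------------------------------------------------------

def relevancy_transform(w, a, kind: str, g: float = 0.5,
                        u: float = 0.5, beta: float = 0.5):
    """Blend a membership with the aggregator's neutral value by its weight.

    UNI fills with the identity g, NULL with the absorbing element u; the
    uninull neuron fills with the identity of whichever sub-square the
    membership falls in (g below the knot, u above).  AND/OR neurons handle
    weighting inside their fold and are returned unchanged here.
    """
    if kind == "UNI":
        return w * a + (1.0 - w) * g
    if kind == "NULL":
        return w * a + (1.0 - w) * u
    if kind == "UNINULL":
        fill = np.where(np.asarray(a) <= beta, g, u)
        out = w * a + (1.0 - w) * fill
        return float(out) if np.isscalar(a) or np.ndim(a) == 0 else out
    return a


@dataclass
class LogicNeuron:
    """One fuzzy rule antecedent: a Gaussian set per feature plus the
    aggregation operator and its parameters.

    ``strict_weights`` keeps the textbook AND construction T(w s a), in which
    a weight of 1 *suppresses* an input; the default complements the weight
    for AND neurons so that weight 1 uniformly means "fully relevant" across
    all five neuron kinds, matching the importance semantics of the LOFO
    weights used to build the rules.
    """

    kind: str
    gaussians: list[GaussianSet]
    g: float = 0.5
    u: float = 0.5
    beta: float = 0.5
    norms: NormPair = field(default=PRODUCT_PROBSUM)
    strict_weights: bool = False
    class_id: int = 0
    cloud_index: int = 0

    def __post_init__(self) -> None:
        if self.kind not in NEURON_KINDS:
            raise ValueError(f"unknown neuron kind {self.kind!r}")
        for p in (self.g, self.u, self.beta):
            if not 0.0 <= p <= 1.0:
                raise ValueError("neuron parameters must lie in [0, 1]")

    def memberships(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float).ravel()
        return np.array([gaussian_membership(x[gs.dimension], gs)
                         for gs in self.gaussians])

    @property
    def centers(self) -> np.ndarray:
        return np.array([gs.center for gs in self.gaussians])

    @property
    def sigmas(self) -> np.ndarray:
        return np.array([gs.sigma for gs in self.gaussians])


def neuron_activation(neuron: LogicNeuron, memberships: np.ndarray,
                      weights: np.ndarray) -> float:
    """Aggregate weighted memberships into the neuron's activation in [0, 1]."""
    a = np.asarray(memberships, dtype=float).ravel()
    w = np.asarray(weights, dtype=float).ravel()
    if a.shape != w.shape:
        raise ValueError("memberships and weights must have the same length")
    out = _fold(a[None, :], w, neuron.kind, neuron.g, neuron.u, neuron.beta,
                neuron.norms, neuron.strict_weights)
    return float(out[0])


def _fold(A: np.ndarray, w: np.ndarray, kind: str, g: float, u: float,
          beta: float, norms: NormPair, strict_weights: bool) -> np.ndarray:
    """Left-to-right fold over features (axis 1) for a block of neurons."""
    L, n = A.shape
    if kind == "AND":
        w_eff = w if strict_weights else 1.0 - w
        B = norms.tconorm(w_eff[None, :], A)
        out = B[:, 0]
        for j in range(1, n):
            out = norms.tnorm(out, B[:, j])
        return np.asarray(out, dtype=float)
    if kind == "OR":
        B = norms.tnorm(w[None, :], A)
        out = B[:, 0]
        for j in range(1, n):
            out = norms.tconorm(out, B[:, j])
        return np.asarray(out, dtype=float)
    B = relevancy_transform(w[None, :], A, kind, g, u, beta)
    out = B[:, 0]
    for j in range(1, n):
        if kind == "UNI":
            out = uninorm(out, B[:, j], g, norms)
        elif kind == "NULL":
            out = nullnorm(out, B[:, j], u, norms)
        else:
            out = uninullnorm(out, B[:, j], beta, g, u, norms)
    return np.asarray(out, dtype=float)


def layer_activations(neurons: list[LogicNeuron], x: np.ndarray,
                      weights: np.ndarray) -> np.ndarray:
    """Activation of every neuron at a sample; the model's regression vector."""
    if not neurons:
        return np.empty(0)
    x = np.asarray(x, dtype=float).ravel()
    return np.array([neuron_activation(nr, nr.memberships(x), weights)
                     for nr in neurons])


def layer_activations_fast(centers: np.ndarray, sigmas: np.ndarray, x: np.ndarray,
                           weights: np.ndarray, kind: str, g: float = 0.5,
                           u: float = 0.5, beta: float = 0.5,
                           norms: NormPair = PRODUCT_PROBSUM,
                           strict_weights: bool = False) -> np.ndarray:
    """Vectorised activation of L same-kind neurons given stacked Gaussian
    parameters (both L x n).  Equivalent to :func:`layer_activations` on a
    list of neurons sharing kind and parameters."""
    x = np.asarray(x, dtype=float).ravel()
    z = (x[None, :] - centers) / sigmas
    A = np.exp(-0.5 * z * z)
    return _fold(A, np.asarray(weights, dtype=float).ravel(), kind, g, u, beta,
                 norms, strict_weights)
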