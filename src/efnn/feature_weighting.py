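"""Leave-one-feature-out (LOFO) feature weights from a Fisher separability criterion.

The criterion is J = trace(Sw^-1 Sb) with Sw the average of the class-wise
sample covariance matrices and Sb the class-count-weighted dispersion of the
class means about the overall mean.  Each feature's weight measures the drop
in J when that feature is removed: removing an informative feature lowers J,
and the feature whose removal yields the minimal J receives weight exactly 1,
with all others compared relative to it:

    w_j = 1 - (J_j - min_i J_i) / max_i J_i

Sw and Sb are maintained from running class means, counts and rank-1 scatter
accumulators, so the weights can be recomputed after every stream sample; the
leave-one-out values come from deleting row/column j of the maintained
matrices, which is exact for this criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FeatureWeightState",
    "separability",
    "separability_from_scatter",
    "lofo_weights",
    "weights_from_J",
    "batch_scatter",
    "update_scatter",
    "recompute_weights",
]

#: Ridge factor applied to a singular within-class scatter: delta = RIDGE * trace(Sw)/n
RIDGE = 1e-8


@dataclass
class FeatureWeightState:
    """Running per-class means, counts and scatter accumulators.

    ``class_m2[c]`` is the sum of outer products of deviations from the
    running class mean, so ``class_m2[c] / (N_c - 1)`` is the class's sample
    covariance matrix.
    """

    n_features: int
    class_means: dict[int, np.ndarray] = field(default_factory=dict)
    class_counts: dict[int, int] = field(default_factory=dict)
    class_m2: dict[int, np.ndarray] = field(default_factory=dict)
    overall_mean: np.ndarray = None  # type: ignore[assignment]
    total_count: int = 0
    weights: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.overall_mean is None:
            self.overall_mean = np.zeros(self.n_features)
        if self.weights is None:
            self.weights = np.ones(self.n_features)

    def within_between(self) -> tuple[np.ndarray, np.ndarray]:
        """Current (Sw, Sb).  Classes with fewer than two samples contribute a
        zero covariance to Sw (their dispersion is not yet defined)."""
        n = self.n_features
        Sw = np.zeros((n, n))
        Sb = np.zeros((n, n))
        n_classes = len(self.class_means)
        if n_classes == 0:
            return Sw, Sb
        for c, mu in self.class_means.items():
            Nc = self.class_counts[c]
            if Nc >= 2:
                Sw += self.class_m2[c] / (Nc - 1)
            dev = mu - self.overall_mean
            Sb += (Nc / self.total_count) * np.outer(dev, dev)
        Sw /= n_classes
        return Sw, Sb


def _solve_trace(Sw: np.ndarray, Sb: np.ndarray) -> float:
    """trace(Sw^-1 Sb), ridge-regularising Sw when singular."""
    n = Sw.shape[0]
    try:
        sol = np.linalg.solve(Sw, Sb)
        if not np.all(np.isfinite(sol)):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        tr = np.trace(Sw)
        delta = RIDGE * tr / n if tr > 0 else RIDGE
        warnings.warn("singular within-class scatter; ridge-regularised")
        sol = np.linalg.solve(Sw + delta * np.eye(n), Sb)
    return float(np.trace(sol))


def batch_scatter(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batch (Sw, Sb) under the same conventions as the incremental state."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=int)
    n = X.shape[1]
    classes = np.unique(y)
    Sw = np.zeros((n, n))
    Sb = np.zeros((n, n))
    grand = X.mean(axis=0)
    for c in classes:
        Xc = X[y == c]
        Nc = Xc.shape[0]
        if Nc >= 2:
            Sw += np.cov(Xc, rowvar=False, ddof=1).reshape(n, n)
        dev = Xc.mean(axis=0) - grand
        Sb += (Nc / X.shape[0]) * np.outer(dev, dev)
    Sw /= classes.size
    return Sw, Sb


def separability(X: np.ndarray, y: np.ndarray) -> float:
    """Fisher-type class separability J = trace(Sw^-1 Sb) of a labelled batch."""
    Sw, Sb = batch_scatter(X, y)
    return _solve_trace(Sw, Sb)


def separability_from_scatter(Sw: np.ndarray, Sb: np.ndarray) -> float:
    return _solve_trace(Sw, Sb)


def weights_from_J(J: np.ndarray) -> np.ndarray:
    """Relative LOFO weights from the leave-one-feature-out criterion values."""
    J = np.asarray(J, dtype=float)
    return 1.0 - (J - J.min()) / J.max()


def lofo_weights(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """LOFO weights of a labelled batch: J_j with feature j removed, then the
    relative weighting (the argmin-J feature gets exactly 1)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] < 2:
        raise ValueError("LOFO weighting needs at least two features")
    Sw, Sb = batch_scatter(X, y)
    return _lofo_from_matrices(Sw, Sb)


def _lofo_from_matrices(Sw: np.ndarray, Sb: np.ndarray) -> np.ndarray:
    n = Sw.shape[0]
    J = np.empty(n)
    idx = np.arange(n)
    for j in range(n):
        keep = idx != j
        J[j] = _solve_trace(Sw[np.ix_(keep, keep)], Sb[np.ix_(keep, keep)])
    return weights_from_J(J)


def update_scatter(state: FeatureWeightState, x: np.ndarray, y: int) -> FeatureWeightState:
    """Absorb one labelled sample into the running means and scatter accumulators.

    Uses the incremental mean formula and the rank-1 covariance update, so
    any interleaving of the same sample set yields the same state and the
    state matches the batch computation to numerical precision.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != state.n_features:
        raise ValueError("sample dimension does not match the state")
    y = int(y)
    if y not in state.class_means:
        state.class_means[y] = np.zeros(state.n_features)
        state.class_counts[y] = 0
        state.class_m2[y] = np.zeros((state.n_features, state.n_features))
    Nc = state.class_counts[y]
    delta = x - state.class_means[y]
    state.class_means[y] = state.class_means[y] + delta / (Nc + 1)
    state.class_m2[y] = state.class_m2[y] + np.outer(delta, x - state.class_means[y])
    state.class_counts[y] = Nc + 1
    state.overall_mean = (state.total_count * state.overall_mean + x) / (state.total_count + 1)
    state.total_count += 1
    return state


def recompute_weights(state: FeatureWeightState) -> np.ndarray:
    """Recompute the LOFO weights from the maintained Sw/Sb.

    With fewer than two observed classes the criterion is undefined and all
    weights fall back to 1.
    """
    if len(state.class_means) < 2:
        warnings.warn("fewer than two classes observed; uniform weights returned")
        state.weights = np.ones(state.n_features)
        return state.weights
    Sw, Sb = state.within_between()
    state.weights = _lofo_from_matrices(Sw, Sb)
    return state.weights
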