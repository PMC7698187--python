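"""Linear readout layer: batch pseudo-inverse estimation and indicator-based
recursive weighted least squares (I-RWLS).

The readout regresses 0/1 class-indicator targets on the rule activation
vector (with a prepended bias term), one weight vector per class.  The batch
solution uses the Moore-Penrose pseudo-inverse; during streaming the weights
and the shared inverse-Hessian matrix Q are updated one sample at a time by
the recursive weighted least squares recursion with forgetting factor
``lam`` (1 = no forgetting).  With ``lam = 1`` and a large initial Q scale
``omega`` the streamed solution converges to the batch least-squares fit.

Binary decisions use the signed difference of the two class scores; an exact
zero falls back to the majority training class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ReadoutState", "rwls_step", "batch_estimate", "rwls_update",
           "predict_score", "predict_class"]


@dataclass
class ReadoutState:
    """Per-class output weights plus the shared inverse-Hessian of the RWLS."""

    v: np.ndarray          # (C, L+1) weight rows, column 0 = bias
    Q: np.ndarray          # (L+1, L+1) inverse Hessian
    lam: float = 1.0
    omega: float = 1000.0
    classes: np.ndarray = field(default_factory=lambda: np.array([0, 1]))
    majority_class: int = 0

    @property
    def n_neurons(self) -> int:
        return self.v.shape[1] - 1

    @property
    def n_classes(self) -> int:
        return self.v.shape[0]

    def grow(self, n_new: int = 1) -> None:
        """Append columns for newly evolved neurons: zero weights and a fresh
        ``omega`` diagonal entry in Q, leaving prior estimates untouched."""
        if n_new <= 0:
            return
        C, d = self.v.shape
        self.v = np.hstack([self.v, np.zeros((C, n_new))])
        Q = np.zeros((d + n_new, d + n_new))
        Q[:d, :d] = self.Q
        for j in range(n_new):
            Q[d + j, d + j] = self.omega
        self.Q = Q


def _augment(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=float).ravel()
    return np.concatenate([[1.0], z])


def batch_estimate(Z: np.ndarray, labels: np.ndarray, lam: float = 1.0,
                   omega: float = 1000.0,
                   classes: np.ndarray | None = None) -> ReadoutState:
    """Least-squares fit of all class indicator vectors via the pseudo-inverse.

    ``Z`` is the K x L activation matrix; a constant-1 bias column is
    prepended before solving.  Q is initialised to ``omega * I`` for the
    subsequent streaming phase.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    labels = np.asarray(labels, dtype=int)
    if classes is None:
        classes = np.unique(labels)
    classes = np.asarray(classes, dtype=int)
    Zaug = np.hstack([np.ones((Z.shape[0], 1)), Z])
    Y = (labels[:, None] == classes[None, :]).astype(float)
    V = (np.linalg.pinv(Zaug) @ Y).T
    counts = Y.sum(axis=0)
    majority = int(classes[int(np.argmax(counts))])
    return ReadoutState(v=V, Q=omega * np.eye(Zaug.shape[1]), lam=lam,
                        omega=omega, classes=classes, majority_class=majority)


def rwls_step(v: np.ndarray, Q: np.ndarray, z: np.ndarray, y: np.ndarray,
              lam: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """One raw RWLS recursion on given vectors (no bias handling).

    ``v`` is (C, d) or (d,), ``z`` the length-d regressor, ``y`` the target
    per class.  Returns the updated (v, Q).  The gain is
    eta = z Q / (lam + z Q z^T), then Q <- (I - eta^T z) Q / lam and
    v_k <- v_k + eta^T (y_k - z v_k).
    """
    z = np.asarray(z, dtype=float).ravel()
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite activation vector")
    single = np.ndim(v) == 1
    V = np.atleast_2d(np.asarray(v, dtype=float))
    y = np.atleast_1d(np.asarray(y, dtype=float))
    Qz = Q @ z
    eta = Qz / (lam + float(z @ Qz))
    Qn = (Q - np.outer(eta, z @ Q)) / lam
    Qn = 0.5 * (Qn + Qn.T)
    resid = y - V @ z
    Vn = V + np.outer(resid, eta)
    return (Vn[0] if single else Vn), Qn


def rwls_update(state: ReadoutState, z: np.ndarray, label: int) -> ReadoutState:
    """Absorb one labelled activation vector into the readout (bias-augmented)."""
    za = _augment(z)
    if za.size != state.v.shape[1]:
        raise ValueError("activation dimension does not match the readout")
    y = (state.classes == int(label)).astype(float)
    state.v, state.Q = rwls_step(state.v, state.Q, za, y, state.lam)
    return state


def predict_score(state: ReadoutState, z: np.ndarray) -> np.ndarray:
    """Linear class scores v_k . [1; z] for every class."""
    return state.v @ _augment(z)


def predict_class(state: ReadoutState, z: np.ndarray) -> int:
    """Crisp decision: sign of the score difference for binary problems
    (exact zero -> majority training class), argmax otherwise."""
    scores = predict_score(state, z)
    if state.n_classes == 2:
        signed = scores[1] - scores[0]
        if signed > 0:
            return int(state.classes[1])
        if signed < 0:
            return int(state.classes[0])
        return state.majority_class
    return int(state.classes[int(np.argmax(scores))])
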