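"""Linear soft-margin SVM: training, decision values, label prediction.

The classifier solves the standard primal

    min  1/2 ||w||^2 + C * sum_i xi_i
    s.t. y_i (w . x_i + b) >= 1 - xi_i,  xi_i >= 0

with a linear kernel. Training is delegated to the libsvm solver
(scikit-learn's ``SVC``); the trained model is re-expressed in primal/dual
form (w, b, per-subject dual coefficients alpha in [0, C]) so that the
KKT conditions and the representation identity w = sum_i alpha_i y_i x_i
can be verified directly. Features are not standardised: white-matter
probabilities already share the [0, 1] scale.

Sign convention for prediction: decision value > 0 is the favorable class
(+1); a value of exactly 0 maps to -1, the conservative (non-favorable)
direction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.svm import SVC

__all__ = [
    "SVMModel",
    "train_linear_svm",
    "decision_values",
    "predict_labels",
    "primal_objective",
    "kkt_violation",
]


@dataclass
class SVMModel:
    """A trained linear separator in primal and dual form."""

    w: np.ndarray
    b: float
    alpha: np.ndarray
    support_indices: np.ndarray
    C: float
    selected_columns: np.ndarray = field(default=None)

    def to_json(self) -> str:
        return json.dumps({
            "w": self.w.tolist(),
            "b": self.b,
            "alpha": self.alpha.tolist(),
            "support_indices": self.support_indices.tolist(),
            "C": self.C,
            "selected_columns": (None if self.selected_columns is None
                                 else np.asarray(self.selected_columns).tolist()),
        })

    @classmethod
    def from_json(cls, s: str) -> "SVMModel":
        d = json.loads(s)
        return cls(
            w=np.array(d["w"]),
            b=float(d["b"]),
            alpha=np.array(d["alpha"]),
            support_indices=np.array(d["support_indices"], dtype=int),
            C=float(d["C"]),
            selected_columns=(None if d["selected_columns"] is None
                              else np.array(d["selected_columns"], dtype=int)),
        )


def train_linear_svm(
    X: np.ndarray,
    y: np.ndarray,
    C: float,
    tol: float = 1e-7,
    selected_columns: np.ndarray | None = None,
) -> SVMModel:
    """Fit the soft-margin linear SVM at regularization C."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if C <= 0:
        raise ValueError(f"C must be positive, got {C}")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite feature values")
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    clf = SVC(kernel="linear", C=C, tol=tol, shrinking=True)
    clf.fit(X, y)
    # libsvm stores y_i * alpha_i for the support vectors only
    alpha = np.zeros(X.shape[0])
    alpha[clf.support_] = np.abs(clf.dual_coef_[0])
    # orient so that +1 is the positive decision side regardless of class order
    w = clf.coef_[0].copy()
    b = float(clf.intercept_[0])
    if clf.classes_[1] != 1:  # pragma: no cover - sklearn sorts classes, 1 is last
        w, b = -w, -b
    return SVMModel(
        w=w,
        b=b,
        alpha=alpha,
        support_indices=np.sort(clf.support_),
        C=float(C),
        selected_columns=(None if selected_columns is None
                          else np.asarray(selected_columns, dtype=int)),
    )


def decision_values(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Signed decision function f(x) = w . x + b per row of X."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.w.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model dimension "
            f"{model.w.shape[0]}")
    return X @ model.w + model.b


def predict_labels(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """+1 where the decision value is strictly positive, else -1."""
    f = decision_values(model, X)
    return np.where(f > 0, 1, -1)


def primal_objective(w: np.ndarray, b: float, X: np.ndarray, y: np.ndarray,
                     C: float) -> float:
    """1/2 ||w||^2 + C sum_i max(0, 1 - y_i f(x_i))."""
    margins = y * (X @ w + b)
    return 0.5 * float(w @ w) + C * float(np.maximum(0.0, 1.0 - margins).sum())


def kkt_violation(model: SVMModel, X: np.ndarray, y: np.ndarray) -> float:
    """Largest violation of the KKT optimality conditions.

    alpha = 0  =>  y f(x) >= 1 ; 0 < alpha < C  =>  y f(x) = 1 ;
    alpha = C  =>  y f(x) <= 1. Also checks sum_i alpha_i y_i = 0 and the
    box constraint. Returns the maximum residual, 0 for a perfect solution.
    """
    f = decision_values(model, X)
    m = y * f
    a, C = model.alpha, model.C
    res = [abs(float(a @ y))]
    res.append(float(np.maximum(-a, 0).max(initial=0.0)))
    res.append(float(np.maximum(a - C, 0).max(initial=0.0)))
    edge = 1e-8 * max(C, 1.0)
    at_zero = a <= edge
    at_C = a >= C - edge
    interior = ~at_zero & ~at_C
    if at_zero.any():
        res.append(float(np.maximum(1.0 - m[at_zero], 0).max(initial=0.0)))
    if at_C.any():
        res.append(float(np.maximum(m[at_C] - 1.0, 0).max(initial=0.0)))
    if interior.any():
        res.append(float(np.abs(m[interior] - 1.0).max(initial=0.0)))
    return max(res)
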