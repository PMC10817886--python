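"""Random layers, activations, one-hot targets and closed-form solvers.

This is the shared substrate of the ELM / RVFL / deep-RVFL classifiers: all
three build a design matrix B out of randomly weighted hidden layers (plus,
for the RVFL family, a direct link carrying the raw input) and solve for the
output weights α in closed form,

    η = 0 :  α = B† Y               (minimum-norm least squares, SVD pinv)
    η > 0 :  α = (BᵀB + ηI)⁻¹ BᵀY   (ridge, primal)
             α = Bᵀ (BBᵀ + ηI)⁻¹ Y  (ridge, dual — identical solution)

Hidden weights (and ELM biases) are drawn i.i.d. uniform on [−1, 1] and are
never updated after creation; training touches only α.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .errors import SolverError, ValidationError
from .rng import substream

__all__ = [
    "ACTIVATIONS",
    "RandomLayer",
    "TargetMatrix",
    "DesignMatrix",
    "SolverConfig",
    "make_random_layer",
    "activate",
    "one_hot",
    "solve_output_weights",
    "training_cost",
]


def _sigmoid(z):
    # numerically stable split form
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


ACTIVATIONS = {
    "sigmoid": _sigmoid,
    "relu": lambda z: np.maximum(z, 0.0),
    "tanh": np.tanh,
}


@dataclass(frozen=True)
class RandomLayer:
    """A fixed random hidden layer: weights, optional biases, activation.

    Regenerating with the same (d_in, h, activation, bias flag, seed)
    reproduces the entries bit-for-bit.
    """

    weights: np.ndarray  # d_in × h
    biases: np.ndarray | None
    activation: str
    seed: int

    @property
    def d_in(self) -> int:
        return self.weights.shape[0]

    @property
    def width(self) -> int:
        return self.weights.shape[1]

    def forward(self, X: np.ndarray) -> np.ndarray:
        """Activated hidden output s(XW + th) for row-sample input X."""
        Z = X @ self.weights
        if self.biases is not None:
            Z = Z + self.biases
        return activate(Z, self.activation)


@dataclass(frozen=True)
class TargetMatrix:
    """One-hot target rows with their class order."""

    values: np.ndarray
    class_order: tuple[str, ...]


@dataclass
class DesignMatrix:
    """N×m design matrix with a record of which columns came from where."""

    values: np.ndarray
    block_layout: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.block_layout:
            total = sum(w for _, w in self.block_layout)
            if total != self.values.shape[1]:
                raise ValidationError(
                    f"block widths sum to {total} but design has "
                    f"{self.values.shape[1]} columns"
                )


@dataclass(frozen=True)
class SolverConfig:
    """How to solve for the output weights.

    eta : ridge strength η ≥ 0.  η = 0 selects the pseudoinverse path.
    mode : 'pinv', 'ridge_primal', 'ridge_dual' or 'auto'.  Auto uses pinv at
        η = 0, otherwise primal when N ≥ m and dual when N < m.
    pinv_tolerance : singular-value cutoff for the pseudoinverse, or
        'default' for max(N, m)·eps·σ_max.
    """

    eta: float = 0.0
    mode: str = "auto"
    pinv_tolerance: float | str = "default"

    def __post_init__(self):
        if self.eta < 0:
            raise ValidationError("eta must be non-negative")
        if self.mode not in ("pinv", "ridge_primal", "ridge_dual", "auto"):
            raise ValidationError(f"unknown solver mode {self.mode!r}")
        if self.eta == 0 and self.mode in ("ridge_primal", "ridge_dual"):
            raise ValidationError("eta=0 requires mode 'pinv' or 'auto'")
        if self.eta > 0 and self.mode == "pinv":
            raise ValidationError("mode 'pinv' requires eta=0")
        if self.pinv_tolerance != "default" and self.pinv_tolerance < 0:
            raise ValidationError("pinv_tolerance must be >= 0")


def make_random_layer(
    d_in: int,
    h: int,
    activation: str = "sigmoid",
    with_bias: bool = False,
    seed: int = 0,
) -> RandomLayer:
    """Draw a fixed random layer with entries uniform on [−1, 1].

    The stream depends deterministically on every argument, so identical
    calls give bit-identical layers and changing e.g. the width never
    silently reuses another layer's draws.
    """
    if d_in < 1:
        raise ValidationError("d_in must be a positive integer")
    if h < 0:
        raise ValidationError("h must be non-negative")
    if activation not in ACTIVATIONS:
        raise ValidationError(
            f"unknown activation {activation!r}; expected one of {tuple(ACTIVATIONS)}"
        )
    rng = substream(seed, "random_layer", d_in, h, activation, int(bool(with_bias)))
    weights = rng.uniform(-1.0, 1.0, size=(d_in, h))
    biases = rng.uniform(-1.0, 1.0, size=h) if with_bias else None
    return RandomLayer(weights=weights, biases=biases, activation=activation, seed=seed)


def activate(Z: np.ndarray, activation: str) -> np.ndarray:
    """Elementwise activation; shape preserved; input must be finite."""
    Z = np.asarray(Z, dtype=float)
    if activation not in ACTIVATIONS:
        raise ValidationError(f"unknown activation {activation!r}")
    if not np.isfinite(Z).all():
        raise ValidationError("activation input contains non-finite values")
    return ACTIVATIONS[activation](Z)


def one_hot(labels, class_order) -> TargetMatrix:
    """Encode labels as one-hot rows in the given class order."""
    class_order = tuple(class_order)
    index = {c: j for j, c in enumerate(class_order)}
    if len(index) < 2:
        raise ValidationError("class_order must contain at least two classes")
    n, v = len(labels), len(class_order)
    Y = np.zeros((n, v))
    for i, lab in enumerate(labels):
        if lab not in index:
            raise ValidationError(f"label {lab!r} not in class_order {class_order}")
        Y[i, index[lab]] = 1.0
    return TargetMatrix(values=Y, class_order=class_order)


def _as_array(B) -> np.ndarray:
    return B.values if isinstance(B, (DesignMatrix, TargetMatrix)) else np.asarray(B, dtype=float)


def solve_output_weights(B, Y, cfg: SolverConfig = SolverConfig()) -> np.ndarray:
    """Solve min ‖Bα − Y‖² (+ η‖α‖²) for the output weights α.

    η = 0 uses a tolerance-thresholded SVD pseudoinverse (minimum-norm least
    squares).  η > 0 uses the primal or dual ridge normal equations; both
    give the same α, the cheaper one depends on whether B is tall or wide.
    """
    Bv, Yv = _as_array(B), _as_array(Y)
    if Bv.ndim != 2 or Yv.ndim != 2:
        raise ValidationError("B and Y must be 2-D")
    if Bv.shape[0] != Yv.shape[0]:
        raise ValidationError(
            f"row mismatch: B has {Bv.shape[0]} rows, Y has {Yv.shape[0]}"
        )
    n, m = Bv.shape
    mode = cfg.mode
    if mode == "auto":
        mode = "pinv" if cfg.eta == 0 else ("ridge_primal" if n >= m else "ridge_dual")

    if mode == "pinv":
        if cfg.pinv_tolerance == "default":
            rcond = max(n, m) * np.finfo(float).eps
        else:
            # np.linalg.pinv thresholds at rcond * sigma_max
            smax = np.linalg.norm(Bv, 2) if min(n, m) else 0.0
            rcond = cfg.pinv_tolerance / smax if smax > 0 else 0.0
        return np.linalg.pinv(Bv, rcond=rcond) @ Yv

    eye = np.eye(m if mode == "ridge_primal" else n)
    try:
        if mode == "ridge_primal":
            return scipy.linalg.solve(
                Bv.T @ Bv + cfg.eta * eye, Bv.T @ Yv, assume_a="pos"
            )
        return Bv.T @ scipy.linalg.solve(Bv @ Bv.T + cfg.eta * eye, Yv, assume_a="pos")
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise SolverError(
            f"ridge normal equations numerically singular at eta={cfg.eta}; "
            f"try a larger eta ({exc})"
        )


def training_cost(B, alpha, Y) -> float:
    """Sum of squared residuals of Bα − Y over all samples and output nodes."""
    Bv, Yv = _as_array(B), _as_array(Y)
    alpha = np.asarray(alpha, dtype=float)
    if Bv.shape[1] != alpha.shape[0] or Bv.shape[0] != Yv.shape[0]:
        raise ValidationError("shapes of B, alpha, Y are not conformable")
    if alpha.ndim == 2 and alpha.shape[1] != Yv.shape[1]:
        raise ValidationError("alpha column count must match Y")
    resid = Bv @ alpha - Yv
    return float(np.sum(resid * resid))
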