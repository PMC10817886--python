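"""The three randomized classifiers: ELM, RVFL network, deep RVFL.

All three share the same closed-form recipe: standardize the training
features, push them through fixed random hidden layers, assemble a design
matrix B, and solve for the output weights α in one shot.

* ELM — one random hidden layer **with** biases, no direct link: B = H.
* RVFLN — one bias-free random layer plus a direct link: B = [H X].
* dRVFL — L stacked bias-free random layers, each fed by the previous one,
  with all layer outputs and the input concatenated: B = [H¹ … H^L X].

A dRVFL with one layer is exactly an RVFLN with the same layer; the shared
seed derivation makes that an identity, not merely a distributional fact.
Models serialize to JSON and round-trip to bit-identical predictions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .errors import ResourceError, ValidationError
from .features import CLASS_ORDER, POSITIVE_CLASS, FORMAT_VERSION, FeatureMatrix
from .linalg import (
    DesignMatrix,
    RandomLayer,
    SolverConfig,
    make_random_layer,
    one_hot,
    solve_output_weights,
)
from .rng import derive_seed

__all__ = [
    "RNetModel",
    "PredictionResult",
    "fit_elm",
    "fit_rvfln",
    "fit_drvfl",
    "predict",
    "model_to_json",
    "model_from_json",
    "save_model",
    "load_model",
    "DEFAULT_WIDTH_CAP",
]

#: Safety cap on total hidden width; large solves are refused, not attempted.
DEFAULT_WIDTH_CAP = 100_000


@dataclass
class RNetModel:
    """A fitted randomized network: fixed layers + solved output weights."""

    kind: str  # 'elm' | 'rvfln' | 'drvfl'
    layers: list[RandomLayer]
    alpha: np.ndarray
    solver: SolverConfig
    class_order: tuple[str, ...]
    norm_mean: np.ndarray
    norm_scale: np.ndarray
    direct_link: bool
    seed: int

    @property
    def n_features(self) -> int:
        return len(self.norm_mean)


@dataclass
class PredictionResult:
    """Raw output-layer scores plus argmax labels.

    Ties break toward the first class in ``class_order`` (benign).
    ``positive_score`` is the malignant score column, used for ROC/AUC.
    """

    scores: np.ndarray
    labels: list[str] = field(repr=False)
    positive_score: np.ndarray = field(repr=False)


def _standardize_stats(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale = np.where(scale > 0, scale, 1.0)  # constant features pass through
    return mean, scale


def _check_train(train: FeatureMatrix):
    if len(train.classes_present()) < 2:
        raise ValidationError(
            "training data must contain both classes; got only "
            f"{train.classes_present()}"
        )


def _design(model_kind, layers, Xs, direct_link) -> DesignMatrix:
    blocks, layout = [], []
    H = Xs
    for i, layer in enumerate(layers):
        H = layer.forward(H)
        blocks.append(H)
        layout.append((f"hidden{i + 1}", layer.width))
    if direct_link:
        blocks.append(Xs)
        layout.append(("direct", Xs.shape[1]))
    values = np.hstack(blocks) if blocks else np.empty((Xs.shape[0], 0))
    return DesignMatrix(values=values, block_layout=layout)


def _fit(kind, train, layers, direct_link, cfg, seed, mean, scale) -> RNetModel:
    Xs = (train.values - mean) / scale
    B = _design(kind, layers, Xs, direct_link)
    Y = one_hot(train.labels, CLASS_ORDER)
    alpha = solve_output_weights(B, Y, cfg)
    return RNetModel(
        kind=kind,
        layers=layers,
        alpha=alpha,
        solver=cfg,
        class_order=CLASS_ORDER,
        norm_mean=mean,
        norm_scale=scale,
        direct_link=direct_link,
        seed=seed,
    )


def fit_elm(
    train: FeatureMatrix,
    h: int,
    activation: str = "sigmoid",
    cfg: SolverConfig = SolverConfig(),
    seed: int = 0,
    width_cap: int = DEFAULT_WIDTH_CAP,
) -> RNetModel:
    """Fit an extreme learning machine with ``h`` biased hidden nodes."""
    _check_train(train)
    if h < 1:
        raise ValidationError("ELM requires h >= 1")
    if h > width_cap:
        raise ResourceError(f"h={h} exceeds the width cap {width_cap}")
    mean, scale = _standardize_stats(train.values)
    layer = make_random_layer(
        train.n_features, h, activation, with_bias=True,
        seed=derive_seed(seed, "hidden", 0),
    )
    return _fit("elm", train, [layer], False, cfg, seed, mean, scale)


def fit_rvfln(
    train: FeatureMatrix,
    h: int,
    activation: str = "sigmoid",
    cfg: SolverConfig = SolverConfig(),
    seed: int = 0,
    width_cap: int = DEFAULT_WIDTH_CAP,
) -> RNetModel:
    """Fit an RVFL network: ``h`` bias-free enhancement nodes + direct link.

    ``h = 0`` degenerates to a linear least-squares classifier on the
    standardized inputs.
    """
    _check_train(train)
    if h < 0:
        raise ValidationError("RVFLN requires h >= 0")
    if h > width_cap:
        raise ResourceError(f"h={h} exceeds the width cap {width_cap}")
    mean, scale = _standardize_stats(train.values)
    layers = []
    if h > 0:
        layers.append(
            make_random_layer(
                train.n_features, h, activation, with_bias=False,
                seed=derive_seed(seed, "hidden", 0),
            )
        )
    return _fit("rvfln", train, layers, True, cfg, seed, mean, scale)


def fit_drvfl(
    train: FeatureMatrix,
    widths: list[int],
    activation: str = "sigmoid",
    cfg: SolverConfig = SolverConfig(),
    seed: int = 0,
    width_cap: int = DEFAULT_WIDTH_CAP,
) -> RNetModel:
    """Fit a deep RVFL with stacked bias-free layers of the given widths.

    Layer l feeds layer l+1; the output layer sees every layer's output and
    the standardized input.  With ``widths=[h]`` the model coincides exactly
    with :func:`fit_rvfln` at the same seed.
    """
    _check_train(train)
    widths = list(widths)
    if not widths:
        raise ValidationError("widths must be a non-empty list")
    if any(w < 1 for w in widths):
        raise ValidationError("all layer widths must be positive")
    if sum(widths) > width_cap:
        raise ResourceError(f"total width {sum(widths)} exceeds cap {width_cap}")
    mean, scale = _standardize_stats(train.values)
    layers = []
    d_in = train.n_features
    for l, w in enumerate(widths):
        layers.append(
            make_random_layer(
                d_in, w, activation, with_bias=False,
                seed=derive_seed(seed, "hidden", l),
            )
        )
        d_in = w
    return _fit("drvfl", train, layers, True, cfg, seed, mean, scale)


def predict(model: RNetModel, data: FeatureMatrix) -> PredictionResult:
    """Score samples with a fitted model: scores = Bα, labels by argmax."""
    if data.n_features != model.n_features:
        raise ValidationError(
            f"model expects {model.n_features} features, data has {data.n_features}"
        )
    Xs = (data.values - model.norm_mean) / model.norm_scale
    B = _design(model.kind, model.layers, Xs, model.direct_link)
    scores = B.values @ model.alpha
    idx = np.argmax(scores, axis=1)  # first max wins -> benign on exact ties
    labels = [model.class_order[j] for j in idx]
    pos = model.class_order.index(POSITIVE_CLASS)
    return PredictionResult(scores=scores, labels=labels, positive_score=scores[:, pos])


# --- JSON serialization ----------------------------------------------------

def model_to_json(model: RNetModel) -> str:
    doc = {
        "format_version": FORMAT_VERSION,
        "kind": model.kind,
        "seed": model.seed,
        "class_order": list(model.class_order),
        "direct_link": model.direct_link,
        "solver": {
            "eta": model.solver.eta,
            "mode": model.solver.mode,
            "pinv_tolerance": model.solver.pinv_tolerance,
        },
        "norm_mean": model.norm_mean.tolist(),
        "norm_scale": model.norm_scale.tolist(),
        "layers": [
            {
                "weights": layer.weights.tolist(),
                "biases": None if layer.biases is None else layer.biases.tolist(),
                "activation": layer.activation,
                "seed": layer.seed,
            }
            for layer in model.layers
        ],
        "alpha": model.alpha.tolist(),
    }
    return json.dumps(doc, sort_keys=True)


def model_from_json(text: str) -> RNetModel:
    doc = json.loads(text)
    layers = [
        RandomLayer(
            weights=np.asarray(l["weights"], dtype=float),
            biases=None if l["biases"] is None else np.asarray(l["biases"], dtype=float),
            activation=l["activation"],
            seed=l["seed"],
        )
        for l in doc["layers"]
    ]
    return RNetModel(
        kind=doc["kind"],
        layers=layers,
        alpha=np.asarray(doc["alpha"], dtype=float),
        solver=SolverConfig(
            eta=doc["solver"]["eta"],
            mode=doc["solver"]["mode"],
            pinv_tolerance=doc["solver"]["pinv_tolerance"],
        ),
        class_order=tuple(doc["class_order"]),
        norm_mean=np.asarray(doc["norm_mean"], dtype=float),
        norm_scale=np.asarray(doc["norm_scale"], dtype=float),
        direct_link=doc["direct_link"],
        seed=doc["seed"],
    )


def save_model(model: RNetModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(model_to_json(model))


def load_model(path) -> RNetModel:
    with open(path, "r", encoding="utf-8") as fh:
        return model_from_json(fh.read())
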