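"""Deep maxout network: forward pass, prediction and a flat-vector codec.

A maxout unit outputs the maximum over several affine "pieces" of its
input; a stack of such layers can approximate arbitrary convex activations
(absolute value and ReLU are the two-piece special cases).  The network
here is trained by a population-based optimizer, so alongside the layered
parameter containers we provide an exact, deterministic bijection between
a parameter set and a single flat vector.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import CodecError, ConfigurationError


@dataclass(frozen=True)
class Architecture:
    """Static shape of the network.

    ``input_dim`` feature-vector length; ``hidden`` unit counts of the
    hidden maxout layers; ``pieces`` affine pieces per unit (all layers);
    ``n_classes`` output units (one score per class).
    """

    input_dim: int
    n_classes: int
    hidden: tuple[int, ...] = (32, 16)
    pieces: int = 2

    def __post_init__(self):
        object.__setattr__(self, "hidden", tuple(int(h) for h in self.hidden))
        if self.input_dim < 1 or self.n_classes < 1 or self.pieces < 1:
            raise ConfigurationError("architecture dims must all be >= 1")
        if any(h < 1 for h in self.hidden):
            raise ConfigurationError("hidden sizes must all be >= 1")

    @property
    def layer_dims(self) -> list[tuple[int, int]]:
        dims = (self.input_dim,) + self.hidden + (self.n_classes,)
        return list(zip(dims[:-1], dims[1:]))

    @property
    def n_layers(self) -> int:
        return len(self.hidden) + 1

    def parameter_count(self) -> int:
        return sum(
            self.pieces * (d_in + 1) * d_out for d_in, d_out in self.layer_dims
        )


@dataclass
class MaxoutLayerParams:
    """weights: (in, out, pieces); biases: (out, pieces)."""

    weights: np.ndarray
    biases: np.ndarray

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.biases = np.asarray(self.biases, dtype=float)
        if self.weights.ndim != 3 or self.biases.ndim != 2:
            raise ConfigurationError("weights must be 3-D, biases 2-D")
        if self.weights.shape[1:] != self.biases.shape:
            raise ConfigurationError(
                f"weights {self.weights.shape} and biases {self.biases.shape} disagree"
            )


@dataclass
class DMNParams:
    """Ordered layer parameters; adjacent layer dims must chain."""

    layers: list[MaxoutLayerParams] = field(default_factory=list)

    def __post_init__(self):
        for k in range(len(self.layers) - 1):
            out_k = self.layers[k].weights.shape[1]
            in_next = self.layers[k + 1].weights.shape[0]
            if out_k != in_next:
                raise ConfigurationError(
                    f"layer {k} outputs {out_k} units but layer {k + 1} expects {in_next}"
                )

    @property
    def n_layers(self) -> int:
        return len(self.layers)


def forward(params: DMNParams, x: np.ndarray) -> np.ndarray:
    """Class scores for one feature vector or a batch.

    Each layer computes, per unit, ``max_p (x . W[:, unit, p] + b[unit, p])``;
    the final layer's outputs are returned raw (no softmax) — the training
    fitness is squared error against one-hot targets and prediction is the
    argmax, so a monotone squashing would be redundant.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    h = x[None, :] if single else x
    for k, layer in enumerate(params.layers):
        if h.shape[1] != layer.weights.shape[0]:
            raise ConfigurationError(
                f"layer {k}: input has {h.shape[1]} features, expected "
                f"{layer.weights.shape[0]}"
            )
        z = np.einsum("ni,iop->nop", h, layer.weights) + layer.biases
        h = z.max(axis=2)
    return h[0] if single else h


def predict(params: DMNParams, x: np.ndarray) -> np.ndarray | int:
    """Argmax class index of :func:`forward`; ties resolve to the lowest index."""
    g = forward(params, x)
    return int(np.argmax(g)) if g.ndim == 1 else np.argmax(g, axis=1)


def flatten_params(params: DMNParams) -> np.ndarray:
    """Serialize to one flat vector: layer-major, weights before biases,
    piece-major within each tensor."""
    chunks = []
    for layer in params.layers:
        chunks.append(layer.weights.transpose(2, 0, 1).ravel())
        chunks.append(layer.biases.transpose(1, 0).ravel())
    return np.concatenate(chunks)


def unflatten_params(theta: np.ndarray, arch: Architecture) -> DMNParams:
    """Inverse of :func:`flatten_params` for the given architecture."""
    theta = np.asarray(theta, dtype=float)
    expected = arch.parameter_count()
    if theta.shape != (expected,):
        raise CodecError(
            f"flat vector has shape {theta.shape}, architecture needs ({expected},)"
        )
    layers, pos = [], 0
    for d_in, d_out in arch.layer_dims:
        nw = arch.pieces * d_in * d_out
        w = theta[pos:pos + nw].reshape(arch.pieces, d_in, d_out).transpose(1, 2, 0)
        pos += nw
        nb = arch.pieces * d_out
        b = theta[pos:pos + nb].reshape(arch.pieces, d_out).transpose(1, 0)
        pos += nb
        layers.append(MaxoutLayerParams(weights=w.copy(), biases=b.copy()))
    return DMNParams(layers=layers)


def save_model(path: str | Path, arch: Architecture, theta: np.ndarray) -> None:
    """Write architecture + flat parameters as JSON (round-trip safe)."""
    payload = {
        "input_dim": arch.input_dim,
        "n_classes": arch.n_classes,
        "hidden": list(arch.hidden),
        "pieces": arch.pieces,
        "theta": np.asarray(theta, dtype=float).tolist(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh)


def load_model(path: str | Path) -> tuple[Architecture, np.ndarray]:
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    arch = Architecture(
        input_dim=payload["input_dim"],
        n_classes=payload["n_classes"],
        hidden=tuple(payload["hidden"]),
        pieces=payload["pieces"],
    )
    theta = np.asarray(payload["theta"], dtype=float)
    if theta.shape != (arch.parameter_count(),):
        raise CodecError("model file parameter vector does not match architecture")
    return arch, theta
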