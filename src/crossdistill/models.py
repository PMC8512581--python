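"""Declarative network specifications and builders for the benchmark nets.

Two reference architectures are used throughout the experiments:

* a two-layer digit classifier — one 4-filter 3x3 convolution with ReLU,
  flattened straight into a 10-way fully connected classifier — and
* a three-block 32x32 classifier — 3x3 convolutions with 64/128/256 filters,
  each followed by ReLU and 2x2 max pooling, then dropout(0.5) and a 10-way
  fully connected layer.

Teacher and student instances differ only in the first convolution's input
planes (1 channel for the original modality, 3 for the new one).  Specs are
plain dataclasses serializable to/from YAML; trained parameters travel in a
single-file ``.npz`` checkpoint holding spec, seed and iteration metadata.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import nn

__all__ = [
    "LayerSpec",
    "NetworkSpec",
    "mnist_net_spec",
    "cifar_net_spec",
    "build_network",
    "spec_to_yaml",
    "spec_from_yaml",
    "save_checkpoint",
    "load_checkpoint",
]

_KINDS = ("convolution", "relu", "maxpool", "dropout", "flatten", "fully_connected")


@dataclass(frozen=True)
class LayerSpec:
    kind: str
    filters: int | None = None
    kernel_size: int | None = None
    pool_size: int | None = None
    dropout_p: float | None = None
    width: int | None = None

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise ValueError(f"unknown layer kind {self.kind!r}")


@dataclass(frozen=True)
class NetworkSpec:
    layers: tuple[LayerSpec, ...]
    input_channels: int
    input_size: int
    n_classes: int
    padding: str = "same"

    def __post_init__(self):
        if self.input_channels not in (1, 3):
            raise ValueError(
                f"input_channels must be 1 (original modality) or 3 (new modality), "
                f"got {self.input_channels}"
            )
        last = self.layers[-1]
        if last.kind != "fully_connected" or last.width != self.n_classes:
            raise ValueError("final layer must be fully_connected with width n_classes")
        for ls in self.layers:
            if ls.kind == "convolution" and ls.kernel_size != 3:
                raise ValueError("every convolution must be 3x3")


def mnist_net_spec(input_channels: int = 1, input_size: int = 28,
                   n_classes: int = 10, padding: str = "same") -> NetworkSpec:
    """Two-layer digit net: conv(4 filters, 3x3) -> ReLU -> flatten -> FC."""
    return NetworkSpec(
        layers=(
            LayerSpec("convolution", filters=4, kernel_size=3),
            LayerSpec("relu"),
            LayerSpec("flatten"),
            LayerSpec("fully_connected", width=n_classes),
        ),
        input_channels=input_channels,
        input_size=input_size,
        n_classes=n_classes,
        padding=padding,
    )


def cifar_net_spec(input_channels: int = 3, input_size: int = 32,
                   n_classes: int = 10, padding: str = "same") -> NetworkSpec:
    """Three conv blocks (64/128/256 filters, ReLU, 2x2 maxpool), dropout 0.5,
    then the fully connected classifier."""
    blocks = []
    for f in (64, 128, 256):
        blocks += [
            LayerSpec("convolution", filters=f, kernel_size=3),
            LayerSpec("relu"),
            LayerSpec("maxpool", pool_size=2),
        ]
    blocks += [
        LayerSpec("dropout", dropout_p=0.5),
        LayerSpec("flatten"),
        LayerSpec("fully_connected", width=n_classes),
    ]
    return NetworkSpec(
        layers=tuple(blocks),
        input_channels=input_channels,
        input_size=input_size,
        n_classes=n_classes,
        padding=padding,
    )


def build_network(spec: NetworkSpec, seed: int = 0) -> nn.Network:
    """Instantiate a :class:`~crossdistill.nn.Network` from a spec.

    Identical (spec, seed) pairs yield bit-identical initial parameters.
    """
    layers: list[nn.Layer] = []
    channels = spec.input_channels
    size = spec.input_size
    flat = None
    for ls in spec.layers:
        if ls.kind == "convolution":
            layers.append(nn.Conv2d(channels, ls.filters, ls.kernel_size, spec.padding))
            channels = ls.filters
            if spec.padding == "valid":
                size = size - ls.kernel_size + 1
        elif ls.kind == "relu":
            layers.append(nn.ReLU())
        elif ls.kind == "maxpool":
            if size % ls.pool_size:
                raise ValueError(
                    f"spatial size {size} not divisible by pool size {ls.pool_size}"
                )
            layers.append(nn.MaxPool2d(ls.pool_size))
            size //= ls.pool_size
        elif ls.kind == "dropout":
            layers.append(nn.Dropout(ls.dropout_p))
        elif ls.kind == "flatten":
            layers.append(nn.Flatten())
            flat = channels * size * size
        elif ls.kind == "fully_connected":
            if flat is None:
                raise ValueError("fully_connected must follow a flatten layer")
            layers.append(nn.Linear(flat, ls.width))
            flat = ls.width
    net = nn.Network(layers)
    net.init_params(seed)
    return net


def spec_to_yaml(spec: NetworkSpec) -> str:
    doc = {
        "input_channels": spec.input_channels,
        "input_size": spec.input_size,
        "n_classes": spec.n_classes,
        "padding": spec.padding,
        "layers": [
            {k: v for k, v in vars(ls).items() if v is not None} for ls in spec.layers
        ],
    }
    return yaml.safe_dump(doc, sort_keys=False)


def spec_from_yaml(text: str) -> NetworkSpec:
    doc = yaml.safe_load(text)
    layers = tuple(LayerSpec(**ls) for ls in doc["layers"])
    return NetworkSpec(
        layers=layers,
        input_channels=doc["input_channels"],
        input_size=doc["input_size"],
        n_classes=doc["n_classes"],
        padding=doc.get("padding", "same"),
    )


def save_checkpoint(path: str | Path, network: nn.Network, spec: NetworkSpec,
                    seed: int, iteration: int,
                    optimizer: nn.SGD | None = None,
                    extra: dict | None = None) -> None:
    """Write parameters (+ optional momentum buffers) and metadata to .npz."""
    arrays = {f"param_{i}": p for i, p in enumerate(network.params())}
    if optimizer is not None:
        arrays.update({f"velocity_{i}": v for i, v in enumerate(optimizer.velocity)})
    meta = {
        "spec_yaml": spec_to_yaml(spec),
        "seed": int(seed),
        "iteration": int(iteration),
        "n_params": network.n_params(),
    }
    if extra:
        meta.update(extra)
    arrays["meta_json"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with io.BytesIO() as buf:
        np.savez(buf, **arrays)
        path.write_bytes(buf.getvalue())


def load_checkpoint(path: str | Path) -> tuple[nn.Network, NetworkSpec, dict]:
    """Rebuild the network from a checkpoint; returns (network, spec, meta)."""
    try:
        with np.load(Path(path)) as data:
            arrays = {k: data[k] for k in data.files}
    except Exception as exc:  # zipfile/ValueError from a truncated file
        raise OSError(f"corrupt or unreadable checkpoint {path}: {exc}") from exc
    if "meta_json" not in arrays:
        raise OSError(f"corrupt checkpoint {path}: missing metadata")
    meta = json.loads(bytes(arrays["meta_json"]).decode("utf-8"))
    spec = spec_from_yaml(meta["spec_yaml"])
    net = build_network(spec, seed=meta["seed"])
    n = len(net.params())
    state = [arrays[f"param_{i}"] for i in range(n)]
    net.set_state(state)
    meta["velocity"] = [
        arrays[f"velocity_{i}"] for i in range(n) if f"velocity_{i}" in arrays
    ] or None
    return net, spec, meta
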