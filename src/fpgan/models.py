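"""Discriminator and generator construction.

Six named deep-convolutional discriminator variants (LeNet-5, AlexNet,
ZFNet, VGGNet-11/13/16) are built from a declarative, versioned layer table
shipped with the package.  All six share one contract: a dense input
projection over the fingerprint bits (plus an optional condition one-hot),
1-D convolution/pooling stacks, and a 2-class softmax head — so any variant
can serve as the GAN discriminator.

The generator reverses the convolution process: seeded Gaussian noise is
projected and reshaped to a coarse 1-D signal and refined through four
convolutional layers with batch normalization and leaky-ReLU, ending in a
per-position sigmoid.  An optional substructure-preserving mask layer
(``y = x * unmask + mask``) pins designated fingerprint bits to exactly 1
in every sample, which is what lets a compound-series run guarantee the
shared chemical core in its output.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .fingerprints import MACCS_LENGTH, MACCS_SCHEME, encode_maccs
from .nn import Sequential

ARCHITECTURE_NAMES = ("LeNet5", "AlexNet", "ZFNet", "VGGNet11", "VGGNet13", "VGGNet16")


@dataclass(frozen=True)
class ArchitectureSpec:
    """A named discriminator variant as an ordered list of layer descriptors."""

    name: str
    layers: tuple[dict, ...]
    input_activation: str = "relu"


def _load_table() -> dict:
    with resources.files("fpgan.data").joinpath("architectures.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_architecture(name: str) -> ArchitectureSpec:
    """Load one of the six named variants from the packaged layer table."""
    table = _load_table()
    archs = table["architectures"]
    if name not in archs:
        raise KeyError(
            f"unknown architecture {name!r}; expected one of {sorted(archs)}"
        )
    entry = archs[name]
    if isinstance(entry, dict) and "base" in entry:
        base = archs[entry["base"]]
        drop = set(entry.get("drop_groups", ()))
        layers = [
            dict(d) for d in base
            if not (set(str(d.get("group", "")).split("_")) & drop)
        ]
    else:
        layers = [dict(d) for d in entry]
    for d in layers:
        d.pop("group", None)
    return ArchitectureSpec(
        name=name,
        layers=tuple(layers),
        input_activation=table["input_projection"]["activation"],
    )


@dataclass(frozen=True)
class MCSMask:
    """Paired binary mask/unmask vectors over fingerprint positions.

    ``mask`` is 1 at the feature bits of a maximum common substructure;
    ``unmask`` is its complement.  Applied as ``x * unmask + mask``.
    """

    mask: np.ndarray
    unmask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=np.uint8)
        u = np.asarray(self.unmask, dtype=np.uint8)
        if m.shape != u.shape or m.ndim != 1:
            raise ValueError("mask and unmask must be equal-length vectors")
        if not np.array_equal(u, 1 - m):
            raise ValueError("unmask must equal 1 - mask elementwise")
        m.setflags(write=False)
        u.setflags(write=False)
        object.__setattr__(self, "mask", m)
        object.__setattr__(self, "unmask", u)

    @property
    def length(self) -> int:
        return int(self.mask.size)

    @classmethod
    def from_bits(cls, mask_bits: np.ndarray) -> "MCSMask":
        m = np.asarray(mask_bits, dtype=np.uint8)
        return cls(m, (1 - m).astype(np.uint8))

    @classmethod
    def from_smarts(cls, core: str, length: int = MACCS_LENGTH) -> "MCSMask":
        """Build a mask from a core structure's MACCS feature bits."""
        fp = encode_maccs(core, length=length)
        return cls.from_bits(fp.bits)


def apply_mask(x: np.ndarray, m: MCSMask) -> np.ndarray:
    """Substructure-preserving transform ``x * unmask + mask``.

    Masked positions become exactly 1; others pass through unchanged.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] != m.length:
        raise ValueError(f"length mismatch: input {x.shape[-1]} vs mask {m.length}")
    return x * m.unmask + m.mask


def condition_join(primary: np.ndarray, label: int | np.ndarray,
                   n_classes: int) -> np.ndarray:
    """Append a one-hot class encoding to a vector or a batch of vectors."""
    primary = np.asarray(primary, dtype=float)
    if primary.ndim == 1:
        onehot = nn.one_hot(np.asarray([label]), n_classes)[0]
        return np.concatenate([primary, onehot])
    labels = np.asarray(label)
    if labels.ndim == 0:
        labels = np.full(primary.shape[0], int(labels))
    return np.concatenate([primary, nn.one_hot(labels, n_classes)], axis=1)


@dataclass
class GeneratorSpec:
    """Generator layout: noise prior, four conv blocks, output length.

    The noise vector (standard normal, ``noise_dim`` components, plus a
    one-hot condition when ``condition_dim`` is set) is densely projected to
    ``base_channels x output_length/8`` and refined through four
    convolutional layers (channels ``conv_channels``), the middle ones
    preceded by nearest-neighbour x2 upsampling; batch normalization and
    leaky-ReLU follow all but the last, which maps to one channel under a
    sigmoid so every position lies in [0, 1] before masking.
    """

    noise_dim: int = 100
    output_length: int = MACCS_LENGTH
    base_channels: int = 16
    conv_channels: tuple[int, ...] = (16, 8, 4, 1)
    kernel: int = 3
    condition_dim: int | None = None
    mask: MCSMask | None = None

    def __post_init__(self) -> None:
        if self.noise_dim < 1:
            raise ValueError("noise_dim must be >= 1")
        if len(self.conv_channels) != 4:
            raise ValueError("the generator uses exactly four convolutional layers")
        if self.conv_channels[-1] != 1:
            raise ValueError("final conv layer must emit one channel")
        if self.output_length % 8:
            raise ValueError("output_length must be divisible by 8 (three x2 upsamples)")
        if self.mask is not None and self.mask.length != self.output_length:
            raise ValueError("mask length must equal output_length")


class DiscriminatorModel:
    """A trainable 2-class fingerprint classifier with a fixed contract.

    Input: (batch, input_length [+ condition_dim]) float matrix of bits.
    Output: (batch, 2) class scores; ``predict_proba`` is row-stochastic.
    """

    def __init__(self, spec: ArchitectureSpec, input_length: int = MACCS_LENGTH,
                 condition_dim: int | None = None, seed: int = 0):
        self.spec = spec
        self.input_length = input_length
        self.condition_dim = condition_dim
        self.seed = seed
        rng = np.random.default_rng(seed)
        n_in = input_length + (condition_dim or 0)

        layers: list[nn.Layer] = [
            nn.Dense(n_in, input_length, rng),
            nn.Activation(spec.input_activation),
            nn.Reshape(input_length, 1),
        ]
        channels, length = 1, input_length
        for d in spec.layers:
            kind = d["kind"]
            if kind == "conv":
                layers.append(nn.Conv1D(channels, d["filters"], d["kernel"], rng))
                layers.append(nn.Activation(d.get("activation", "relu")))
                channels = d["filters"]
            elif kind == "pool":
                layers.append(nn.MaxPool1D(d.get("size", 2)))
                length //= d.get("size", 2)
            elif kind == "flatten":
                layers.append(nn.Flatten())
                channels, length = channels * length, 1
            elif kind == "dense":
                layers.append(nn.Dense(channels * length, d["units"], rng))
                layers.append(nn.Activation(d.get("activation", "relu")))
                channels, length = d["units"], 1
            else:
                raise ValueError(f"unknown layer kind {kind!r}")
        layers.append(nn.Dense(channels * length, 2, rng))
        self.net = Sequential(layers)

    def logits(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.net.forward(np.asarray(x, dtype=float), training=training)

    def predict_proba(self, x: np.ndarray) -> np.ndarray:
        return nn.softmax(self.logits(x))

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def checksum(self) -> str:
        return self.net.checksum()

    def save(self, path: str | Path) -> None:
        _save_model(path, self.net, {
            "model": "discriminator", "spec": self.spec.name,
            "input_length": self.input_length,
            "condition_dim": self.condition_dim, "seed": self.seed,
        })


class GeneratorModel:
    """Maps seeded noise (and optional class label) to [0,1] fingerprints."""

    def __init__(self, spec: GeneratorSpec, seed: int = 0,
                 scheme: str = MACCS_SCHEME):
        self.spec = spec
        self.seed = seed
        self.scheme = scheme
        rng = np.random.default_rng(seed)
        L0 = spec.output_length // 8
        c = spec.base_channels
        n_in = spec.noise_dim + (spec.condition_dim or 0)
        layers: list[nn.Layer] = [
            nn.Dense(n_in, c * L0, rng),
            nn.Activation("leaky_relu"),
            nn.Reshape(L0, c),
        ]
        prev = c
        for i, ch in enumerate(spec.conv_channels):
            if i in (1, 2, 3):
                layers.append(nn.Upsample1D(2))
            layers.append(nn.Conv1D(prev, ch, spec.kernel, rng))
            if i < 3:
                layers.append(nn.BatchNorm1D(ch))
                layers.append(nn.Activation("leaky_relu"))
            prev = ch
        layers.append(nn.Flatten())
        layers.append(nn.Activation("sigmoid"))
        if spec.mask is not None:
            layers.append(nn.MaskLayer(spec.mask.mask))
        self.net = Sequential(layers)

    @property
    def conditional(self) -> bool:
        return self.spec.condition_dim is not None

    def noise(self, n: int, rng: np.random.Generator) -> np.ndarray:
        return rng.standard_normal((n, self.spec.noise_dim))

    def generate(self, z: np.ndarray, label: int | np.ndarray | None = None,
                 training: bool = False) -> np.ndarray:
        """Continuous [0,1] outputs of shape (n, output_length)."""
        z = np.asarray(z, dtype=float)
        if self.conditional:
            if label is None:
                raise ValueError("conditional generator requires a class label")
            z = condition_join(z, label, self.spec.condition_dim)
        elif label is not None:
            raise ValueError("label given to an unconditional generator")
        return self.net.forward(z, training=training)

    def n_parameters(self) -> int:
        return self.net.n_parameters()

    def checksum(self) -> str:
        return self.net.checksum()

    def save(self, path: str | Path) -> None:
        _save_model(path, self.net, {
            "model": "generator", "noise_dim": self.spec.noise_dim,
            "output_length": self.spec.output_length,
            "condition_dim": self.spec.condition_dim,
            "masked": self.spec.mask is not None,
            "seed": self.seed, "scheme": self.scheme,
        })


def build_discriminator(spec: ArchitectureSpec | str,
                        input_length: int = MACCS_LENGTH,
                        condition_dim: int | None = None,
                        seed: int = 0) -> DiscriminatorModel:
    """Build one of the six named discriminator variants."""
    if isinstance(spec, str):
        spec = load_architecture(spec)
    return DiscriminatorModel(spec, input_length, condition_dim, seed)


def build_generator(spec: GeneratorSpec | None = None, seed: int = 0,
                    scheme: str = MACCS_SCHEME) -> GeneratorModel:
    return GeneratorModel(spec or GeneratorSpec(), seed=seed, scheme=scheme)


def _save_model(path: str | Path, net: Sequential, sidecar: dict) -> None:
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **net.get_weights())
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def load_weights(model: DiscriminatorModel | GeneratorModel,
                 path: str | Path) -> None:
    state = np.load(Path(path).with_suffix(".npz"))
    model.net.set_weights({k: state[k] for k in state.files})
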