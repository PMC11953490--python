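"""Encoder–bridge–decoder segmentation network with parameter plumbing.

The network is a classic U-Net: per level a double 3x3-conv block
(conv -> norm -> ReLU, twice), 2x2 max-pool downsampling, a bridge (bottleneck)
double-conv block, 2x2 transposed-conv upsampling with skip concatenation, and
a 1x1 output convolution producing pre-sigmoid logits. The bridge output after
its final activation is exposed as the latent representation R(x) used by the
contrastive regularizer.

Normalization is selectable (instance / batch / none); instance normalization
is the default since it behaves identically in training and evaluation and has
no cross-client batch statistics. Batch normalization keeps running
mean/variance buffers which are stored as ordinary (non-trainable) entries of
the parameter set, so partitioning patterns apply to them too.
"""

from __future__ import annotations

import fnmatch
import json
from collections.abc import Mapping
from dataclasses import dataclass, asdict
from typing import Iterable, Iterator

import numpy as np

from .nn import (
    Tensor,
    concat,
    conv2d,
    conv_transpose2d,
    instance_norm,
    maxpool2d,
    no_grad,
)

__all__ = [
    "NetworkConfig",
    "ParameterSet",
    "ParameterPartition",
    "ForwardResult",
    "UNet",
    "build_model",
    "forward_with_representation",
    "get_parameters",
    "set_parameters",
    "partition_parameters",
    "save_checkpoint",
    "load_checkpoint",
]

_NORM_KINDS = ("batch", "instance", "none")
_NORM_EPS = 1e-5
_BN_MOMENTUM = 0.1


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture hyperparameters.

    ``depth`` is the number of down-sampling levels; inputs must have height
    and width divisible by ``2**depth``. The bridge produces
    ``base_channels * 2**depth`` channels at ``1/2**depth`` resolution.
    """

    in_channels: int = 1
    base_channels: int = 8
    depth: int = 2
    norm_kind: str = "instance"
    out_channels: int = 1

    def __post_init__(self):
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if self.norm_kind not in _NORM_KINDS:
            raise ValueError(f"norm_kind must be one of {_NORM_KINDS}")

    @property
    def bridge_channels(self) -> int:
        return self.base_channels * 2 ** self.depth


class ParameterSet(Mapping):
    """Immutable-by-convention mapping of unique parameter names to arrays."""

    def __init__(self, entries: Mapping[str, np.ndarray] | Iterable[tuple[str, np.ndarray]]):
        self._entries: dict[str, np.ndarray] = {
            str(k): np.asarray(v) for k, v in (
                entries.items() if isinstance(entries, Mapping) else entries
            )
        }

    def __getitem__(self, name: str) -> np.ndarray:
        return self._entries[name]

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self._entries)

    def copy(self) -> "ParameterSet":
        return ParameterSet({k: v.copy() for k, v in self._entries.items()})

    def total_size(self) -> int:
        return int(sum(v.size for v in self._entries.values()))

    def allclose(self, other: "ParameterSet", **kw) -> bool:
        return set(self) == set(other) and all(
            np.allclose(self[k], other[k], **kw) for k in self
        )

    def equals(self, other: "ParameterSet") -> bool:
        return set(self) == set(other) and all(
            np.array_equal(self[k], other[k]) for k in self
        )


@dataclass(frozen=True)
class ParameterPartition:
    """Disjoint cover of parameter names into shared and personalized sets."""

    shared_names: frozenset[str]
    personalized_names: frozenset[str]

    def __post_init__(self):
        overlap = self.shared_names & self.personalized_names
        if overlap:
            raise ValueError(f"partition not disjoint: {sorted(overlap)[:3]}")


@dataclass(frozen=True)
class ForwardResult:
    """Pixel-wise logits plus the bridge latent representation R(x)."""

    logits: np.ndarray
    representation: np.ndarray


def _match(name: str, pattern: str) -> bool:
    return pattern in name or fnmatch.fnmatchcase(name, pattern)


def partition_parameters(params: ParameterSet | Iterable[str],
                         personalized_patterns: Iterable[str]) -> ParameterPartition:
    """Split parameter names by substring/glob patterns.

    A name is personalized if it contains any pattern as a substring or
    matches it as a glob; everything else is shared.
    """
    names = list(params.names if isinstance(params, ParameterSet) else params)
    patterns = list(personalized_patterns)
    personalized = frozenset(
        n for n in names if any(_match(n, p) for p in patterns)
    )
    return ParameterPartition(
        shared_names=frozenset(names) - personalized,
        personalized_names=personalized,
    )


class UNet:
    """U-Net with named parameters and a bridge-representation forward pass."""

    def __init__(self, config: NetworkConfig, seed: int = 0):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._trainable: set[str] = set()
        self._init_parameters(seed)

    # -- construction ---------------------------------------------------------

    def _add_conv(self, rng: np.random.Generator, name: str,
                  cin: int, cout: int, k: int) -> None:
        fan_in = cin * k * k
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, size=(cout, cin, k, k)).astype(np.float32)
        self._add(name + ".weight", w, trainable=True)
        self._add(name + ".bias", np.zeros(cout, np.float32), trainable=True)

    def _add_upconv(self, rng: np.random.Generator, name: str,
                    cin: int, cout: int) -> None:
        std = np.sqrt(2.0 / (cin * 4))
        w = rng.normal(0.0, std, size=(cin, cout, 2, 2)).astype(np.float32)
        self._add(name + ".weight", w, trainable=True)
        self._add(name + ".bias", np.zeros(cout, np.float32), trainable=True)

    def _add_norm(self, name: str, c: int) -> None:
        kind = self.config.norm_kind
        if kind == "none":
            return
        self._add(name + ".weight", np.ones(c, np.float32), trainable=True)
        self._add(name + ".bias", np.zeros(c, np.float32), trainable=True)
        if kind == "batch":
            self._add(name + ".running_mean", np.zeros(c, np.float32), trainable=False)
            self._add(name + ".running_var", np.ones(c, np.float32), trainable=False)

    def _add(self, name: str, value: np.ndarray, trainable: bool) -> None:
        self.params[name] = Tensor(value, requires_grad=trainable)
        if trainable:
            self._trainable.add(name)

    def _add_block(self, rng, prefix: str, cin: int, cout: int) -> None:
        self._add_conv(rng, f"{prefix}.conv1", cin, cout, 3)
        self._add_norm(f"{prefix}.norm1", cout)
        self._add_conv(rng, f"{prefix}.conv2", cout, cout, 3)
        self._add_norm(f"{prefix}.norm2", cout)

    def _init_parameters(self, seed: int) -> None:
        cfg = self.config
        rng = np.random.default_rng(seed)
        c = cfg.base_channels
        cin = cfg.in_channels
        for i in range(cfg.depth):
            self._add_block(rng, f"enc{i}", cin, c * 2 ** i)
            cin = c * 2 ** i
        self._add_block(rng, "bridge", c * 2 ** (cfg.depth - 1), cfg.bridge_channels)
        for i in reversed(range(cfg.depth)):
            self._add_upconv(rng, f"dec{i}.up", c * 2 ** (i + 1), c * 2 ** i)
            self._add_block(rng, f"dec{i}", c * 2 ** (i + 1), c * 2 ** i)
        self._add_conv(rng, "head", c, cfg.out_channels, 1)

    # -- forward --------------------------------------------------------------

    def _norm(self, x: Tensor, prefix: str, train: bool) -> Tensor:
        # x is channels-last (N, H, W, C); affine params broadcast over C.
        kind = self.config.norm_kind
        if kind == "none":
            return x
        gamma = self.params[prefix + ".weight"]
        beta = self.params[prefix + ".bias"]
        if kind == "instance":
            return instance_norm(x, gamma, beta, eps=_NORM_EPS)
        # batch norm
        rm = self.params[prefix + ".running_mean"]
        rv = self.params[prefix + ".running_var"]
        if train:
            mu = x.mean(axis=(0, 1, 2), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 1, 2), keepdims=True)
            rm.data[:] = (1 - _BN_MOMENTUM) * rm.data + _BN_MOMENTUM * mu.data.ravel()
            rv.data[:] = (1 - _BN_MOMENTUM) * rv.data + _BN_MOMENTUM * var.data.ravel()
            return xc / (var + _NORM_EPS).sqrt() * gamma + beta
        return (x - Tensor(rm.data)) / (Tensor(rv.data) + _NORM_EPS).sqrt() * gamma + beta

    def _block(self, x: Tensor, prefix: str, train: bool) -> Tensor:
        x = conv2d(x, self.params[f"{prefix}.conv1.weight"],
                   self.params[f"{prefix}.conv1.bias"], pad=1)
        x = self._norm(x, f"{prefix}.norm1", train).relu()
        x = conv2d(x, self.params[f"{prefix}.conv2.weight"],
                   self.params[f"{prefix}.conv2.bias"], pad=1)
        return self._norm(x, f"{prefix}.norm2", train).relu()

    def forward(self, x: np.ndarray | Tensor, train: bool = True,
                bridge_only: bool = False) -> tuple[Tensor | None, Tensor]:
        """Run the network; returns ``(logits, representation)`` tensors.

        With ``bridge_only=True`` the decoder is skipped and logits are None
        (used for frozen-snapshot embeddings, which only need R(x)).
        """
        cfg = self.config
        if isinstance(x, Tensor):
            x = x.data
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1] != cfg.in_channels:
            raise ValueError(
                f"expected input (batch, {cfg.in_channels}, H, W), got {x.shape}"
            )
        h, w = x.shape[2], x.shape[3]
        div = 2 ** cfg.depth
        if h % div or w % div:
            raise ValueError(
                f"input spatial size {h}x{w} not divisible by 2^depth = {div}"
            )
        # channels-last internally; public tensors are channels-first
        x = Tensor(np.ascontiguousarray(x.transpose(0, 2, 3, 1)))
        skips: list[Tensor] = []
        for i in range(cfg.depth):
            x = self._block(x, f"enc{i}", train)
            skips.append(x)
            x = maxpool2d(x)
        rep_cl = self._block(x, "bridge", train)
        rep = rep_cl.transpose(0, 3, 1, 2)
        if bridge_only:
            return None, rep
        x = rep_cl
        for i in reversed(range(cfg.depth)):
            x = conv_transpose2d(x, self.params[f"dec{i}.up.weight"],
                                 self.params[f"dec{i}.up.bias"])
            x = concat([skips[i], x], axis=3)
            x = self._block(x, f"dec{i}", train)
        logits = conv2d(x, self.params["head.weight"], self.params["head.bias"], pad=0)
        return logits.transpose(0, 3, 1, 2), rep

    # -- parameter access -----------------------------------------------------

    @property
    def parameter_names(self) -> tuple[str, ...]:
        return tuple(self.params)

    @property
    def trainable_names(self) -> tuple[str, ...]:
        return tuple(n for n in self.params if n in self._trainable)

    def trainable_params(self) -> dict[str, Tensor]:
        return {n: self.params[n] for n in self.params if n in self._trainable}

    def get_parameters(self) -> ParameterSet:
        return ParameterSet({k: t.data.copy() for k, t in self.params.items()})

    def set_parameters(self, values: Mapping[str, np.ndarray]) -> None:
        """Overwrite a subset of parameters in place (shapes must match)."""
        for name, arr in values.items():
            if name not in self.params:
                raise KeyError(f"unknown parameter name: {name!r}")
            tgt = self.params[name]
            arr = np.asarray(arr, dtype=tgt.data.dtype)
            if arr.shape != tgt.data.shape:
                raise ValueError(
                    f"shape mismatch for {name!r}: {arr.shape} vs {tgt.data.shape}"
                )
            tgt.data[...] = arr


def build_model(config: NetworkConfig, seed: int = 0) -> UNet:
    """Deterministically initialize a U-Net for the given configuration."""
    return UNet(config, seed=seed)


def forward_with_representation(model: UNet, x: np.ndarray) -> ForwardResult:
    """Single evaluation-mode pass returning logits and R(x) as arrays."""
    with no_grad():
        logits, rep = model.forward(x, train=False)
    return ForwardResult(logits=logits.data.copy(), representation=rep.data.copy())


def get_parameters(model: UNet) -> ParameterSet:
    return model.get_parameters()


def set_parameters(model: UNet, params: Mapping[str, np.ndarray]) -> None:
    model.set_parameters(params)


# -- checkpoints ----------------------------------------------------------------


def save_checkpoint(path, model: UNet, *, partition_patterns: list[str] | None = None,
                    round_index: int = 0, seeds: dict | None = None) -> None:
    """Write parameters plus a JSON metadata block to an .npz archive."""
    meta = {
        "network": asdict(model.config),
        "partition_patterns": list(partition_patterns or []),
        "round_index": int(round_index),
        "seeds": seeds or {},
    }
    arrays = {f"param/{k}": t.data for k, t in model.params.items()}
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta, sort_keys=True).encode(), dtype=np.uint8
    )
    np.savez(path, **arrays)


def load_checkpoint(path) -> tuple[UNet, dict]:
    """Restore a model (bit-exact parameters) and its metadata."""
    with np.load(path) as archive:
        meta = json.loads(bytes(archive["__meta__"]).decode())
        params = {
            k[len("param/"):]: archive[k] for k in archive.files if k.startswith("param/")
        }
    model = UNet(NetworkConfig(**meta["network"]), seed=0)
    model.set_parameters(params)
    return model, meta
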