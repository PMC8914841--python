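"""Denoiser architecture: residual encoder blocks, transposed-conv decoder.

The generator compresses a normalized trial through three residual
bottleneck blocks (a spatial convolution plus pointwise channel expansion
on the main path, with a strided 1 x 1 projection shortcut) and
reconstructs it with three transposed convolutions ending in tanh. The
critic applies four analogous residual blocks and two plain convolutions
down to one unbounded score per trial (Wasserstein critic: no sigmoid).

Kernel sizes, strides, and filter counts follow the published parameter
tables of this denoiser. The published tables list each block's layers as
X1 (spatial conv), X2 (pointwise expansion) and X3 (pointwise, carrying the
same stride as X1 and the block's output filter count) — the signature of a
projection shortcut, which is how X3 is wired here. Per-layer asymmetric
paddings are solved automatically so shortcut and main branches agree and
the generator is an exact endomorphism on (C, T); the padding trace lives
in the spec objects, not inside the layers.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np

from .nn import (BatchNorm2D, Conv2D, ConvTranspose2D, LeakyReLU, Residual,
                 Sequential, Tanh)
from .sample_entropy import SampEnParams
from .setet_norm import SetetConfig

Pad = tuple[int, int]
Kind = Literal["conv", "tconv"]
Activation = Literal["leaky_relu", "tanh", "linear"]
Role = Literal["plain", "main", "shortcut"]

#: Negative slope of the leaky rectifier used throughout both networks.
LEAKY_SLOPE = 0.2


@dataclass(frozen=True)
class LayerSpec:
    """One network layer: geometry, padding, activation, normalization.

    ``block``/``role`` describe the residual wiring: layers sharing a block
    with a ``shortcut`` member form a residual unit whose output activation
    is a leaky rectifier; ``plain`` layers stack sequentially.
    """

    name: str
    kind: Kind
    filter_size: tuple[int, int]
    stride: tuple[int, int]
    filter_count: int
    activation: Activation
    batchnorm: bool
    pad: tuple[Pad, Pad] = ((0, 0), (0, 0))
    output_padding: tuple[int, int] = (0, 0)
    block: str = ""
    role: Role = "plain"

    def __post_init__(self) -> None:
        if min(self.filter_size) < 1 or min(self.stride) < 1:
            raise ValueError(f"{self.name}: filter size and stride must be positive")
        if self.filter_count < 1:
            raise ValueError(f"{self.name}: filter count must be positive")

    def out_len(self, n: int, axis: int) -> int:
        k, s = self.filter_size[axis], self.stride[axis]
        p = self.pad[axis]
        if self.kind == "conv":
            return (n + p[0] + p[1] - k) // s + 1
        return (n - 1) * s + k - p[0] - p[1] + self.output_padding[axis]


@dataclass(frozen=True)
class NetworkSpec:
    """Ordered layers plus the input/output shape contract they satisfy."""

    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int]
    output_shape: tuple[int, int]

    def __post_init__(self) -> None:
        names = [l.name for l in self.layers]
        if len(set(names)) != len(names):
            raise ValueError("layer names must be unique")

    def grouped(self) -> list[tuple[str, list[LayerSpec]]]:
        """Consecutive layers grouped into residual blocks / plain singletons."""
        groups: list[tuple[str, list[LayerSpec]]] = []
        for l in self.layers:
            if l.role == "plain":
                groups.append(("plain", [l]))
            elif groups and groups[-1][0] == "res" and groups[-1][1][0].block == l.block:
                groups[-1][1].append(l)
            else:
                groups.append(("res", [l]))
        return groups

    def shape_trace(self) -> list[tuple[int, int]]:
        """Spatial shape after each block/layer; raises on any inconsistency."""
        shapes = [self.input_shape]
        h, w = self.input_shape
        for gkind, members in self.grouped():
            if gkind == "plain":
                (l,) = members
                h2, w2 = l.out_len(h, 0), l.out_len(w, 1)
            else:
                mains = [l for l in members if l.role == "main"]
                shorts = [l for l in members if l.role == "shortcut"]
                mh, mw = h, w
                for l in mains:
                    mh, mw = l.out_len(mh, 0), l.out_len(mw, 1)
                (sc,) = shorts
                sh_, sw_ = sc.out_len(h, 0), sc.out_len(w, 1)
                if (mh, mw) != (sh_, sw_):
                    raise ValueError(
                        f"block {members[0].block}: main path ends at "
                        f"{(mh, mw)} but shortcut at {(sh_, sw_)}")
                h2, w2 = mh, mw
            if h2 < 1 or w2 < 1:
                raise ValueError(
                    f"layer {members[0].name} collapses the map to {(h2, w2)}")
            h, w = h2, w2
            shapes.append((h, w))
        return shapes


# ---------------------------------------------------------------------------
# Published parameter tables: (name, kind, kernel, stride, filters, block, role).
# Generator B3's stride is printed [2, 3] while its block's main path strides
# [3, 2]; the two digits are read as transposed (every other shortcut in both
# tables carries exactly its block's stride).

_GEN_TABLE = [
    ("A1", "conv", (3, 10), (3, 5), 16, "A", "main"),
    ("A2", "conv", (1, 1), (1, 1), 32, "A", "main"),
    ("A3", "conv", (1, 1), (3, 5), 32, "A", "shortcut"),
    ("B1", "conv", (3, 10), (3, 2), 32, "B", "main"),
    ("B2", "conv", (1, 1), (1, 1), 64, "B", "main"),
    ("B3", "conv", (1, 1), (3, 2), 64, "B", "shortcut"),
    ("C1", "conv", (2, 3), (2, 2), 64, "C", "main"),
    ("C2", "conv", (1, 1), (1, 1), 128, "C", "main"),
    ("C3", "conv", (1, 1), (2, 2), 128, "C", "shortcut"),
    ("D1", "tconv", (2, 3), (2, 2), 128, "D", "plain"),
    ("D2", "tconv", (3, 5), (3, 2), 64, "D", "plain"),
    ("D3", "tconv", (3, 10), (3, 5), 1, "D", "plain"),
]

_DISC_TABLE = [
    ("A1", "conv", (2, 10), (2, 4), 16, "A", "main"),
    ("A2", "conv", (1, 1), (1, 1), 32, "A", "main"),
    ("A3", "conv", (1, 1), (2, 4), 32, "A", "shortcut"),
    ("B1", "conv", (2, 5), (2, 2), 32, "B", "main"),
    ("B2", "conv", (1, 1), (1, 1), 64, "B", "main"),
    ("B3", "conv", (1, 1), (2, 2), 64, "B", "shortcut"),
    ("C1", "conv", (2, 3), (2, 2), 64, "C", "main"),
    ("C2", "conv", (1, 1), (1, 1), 128, "C", "main"),
    ("C3", "conv", (1, 1), (2, 2), 128, "C", "shortcut"),
    ("D1", "conv", (2, 3), (2, 2), 128, "D", "main"),
    ("D2", "conv", (1, 1), (1, 1), 256, "D", "main"),
    ("D3", "conv", (1, 1), (2, 2), 256, "D", "shortcut"),
    ("E1", "conv", (2, 2), (2, 2), 512, "E", "plain"),
    ("F1", "conv", (1, 4), (1, 1), 1, "F", "plain"),
]


def _split(p: int) -> Pad:
    return (p // 2, p - p // 2)


def _block_pads(n_in: int, k: int, s: int) -> tuple[int, Pad]:
    """Output size and spatial-conv padding of one residual block along an axis.

    The projection shortcut (1 x 1 kernel, no padding) fixes the block
    output at ceil(n_in / s); the spatial convolution is padded to land on
    the same size.
    """
    out = -(-n_in // s)
    ptot = s * (out - 1) + k - n_in
    if ptot < 0:
        raise ValueError(f"kernel {k} smaller than stride {s} leaves a gap")
    return out, _split(ptot)


def _solve_tconv_chain(chain: list[tuple[int, int]], n_in: int,
                       target: int) -> tuple[list[int], list[Pad]]:
    """Per-layer crops so a transposed-conv chain maps ``n_in`` to ``target``.

    Crop per layer is bounded by (kernel-1) + (stride-1). Feasibility
    intervals are propagated backward from the target, then sizes are chosen
    greedily forward with minimal crop.
    """
    pmax = [(k - 1) + (s - 1) for k, s in chain]
    lo = hi = target
    bounds = [(lo, hi)]
    for (k, s), pm in zip(reversed(chain), reversed(pmax)):
        lo = max(1, math.ceil((lo - k) / s) + 1)
        hi = max(1, (hi + pm - k) // s + 1)
        bounds.append((lo, hi))
    bounds = bounds[::-1]
    if not bounds[0][0] <= n_in <= bounds[0][1]:
        raise ValueError(
            f"no crop assignment maps size {n_in} to {target} through {chain}")
    sizes, pads, n = [n_in], [], n_in
    for i, ((k, s), pm) in enumerate(zip(chain, pmax)):
        nat = (n - 1) * s + k
        lo, hi = bounds[i + 1]
        out = min(max(nat - pm, lo), min(hi, nat))
        ptot = nat - out
        if not 0 <= ptot <= pm:
            raise ValueError(
                f"transposed layer {i} (k={k}, s={s}) cannot land in "
                f"[{lo}, {hi}] from size {n}")
        pads.append(_split(ptot))
        sizes.append(out)
        n = out
    return sizes, pads


def _conv_pad_for(n_in: int, k: int, s: int, out: int) -> Pad:
    ptot = s * (out - 1) + k - n_in
    if ptot < 0:
        raise ValueError(f"size {n_in} cannot reach {out} with k={k}, s={s}")
    return _split(ptot)


def default_generator_spec(input_shape: tuple[int, int] = (19, 200)) -> NetworkSpec:
    """Generator spec: 12 published layers, paddings solved for ``input_shape``.

    The residual encoder's block outputs are fixed by the unpadded
    projection shortcuts (ceil division); the transposed-convolution decoder
    crops are solved so the output shape equals the input shape exactly.
    """
    layers: list[LayerSpec] = []
    sizes = list(input_shape)
    for name, kind, kern, stride, filters, block, role in _GEN_TABLE[:9]:
        if role == "main" and name.endswith("1"):
            pad_ax, new_sizes = [], []
            for ax in (0, 1):
                out, pad = _block_pads(sizes[ax], kern[ax], stride[ax])
                pad_ax.append(pad)
                new_sizes.append(out)
            pad = (pad_ax[0], pad_ax[1])
            block_out = new_sizes
        else:
            pad = ((0, 0), (0, 0))
        layers.append(LayerSpec(
            name=name, kind=kind, filter_size=kern, stride=stride,
            filter_count=filters, activation="leaky_relu" if name.endswith("1") else "linear",
            batchnorm=True, pad=pad, block=block, role=role))
        if role == "shortcut":
            sizes = block_out
    dec = _GEN_TABLE[9:]
    dec_pads = []
    for ax in (0, 1):
        chain = [(l[2][ax], l[3][ax]) for l in dec]
        _, pads = _solve_tconv_chain(chain, sizes[ax], input_shape[ax])
        dec_pads.append(pads)
    for i, (name, kind, kern, stride, filters, block, role) in enumerate(dec):
        last = i == len(dec) - 1
        layers.append(LayerSpec(
            name=name, kind=kind, filter_size=kern, stride=stride,
            filter_count=filters, activation="tanh" if last else "leaky_relu",
            batchnorm=not last, pad=(dec_pads[0][i], dec_pads[1][i]),
            block=block, role=role))
    spec = NetworkSpec(tuple(layers), input_shape, input_shape)
    if spec.shape_trace()[-1] != input_shape:
        raise ValueError("generator shape trace does not close on its input shape")
    return spec


def default_discriminator_spec(input_shape: tuple[int, int] = (19, 200)) -> NetworkSpec:
    """Critic spec: 14 published layers ending in one scalar score per trial.

    Residual blocks downsample by their shortcut strides; E1 is padded so
    the F1 head sees (at most) its own kernel footprint, which the padded
    head reduces to 1 x 1. The critic's first block carries no batch
    normalization.
    """
    layers: list[LayerSpec] = []
    sizes = list(input_shape)
    for name, kind, kern, stride, filters, block, role in _DISC_TABLE[:12]:
        if role == "main" and name.endswith("1"):
            pad_ax, new_sizes = [], []
            for ax in (0, 1):
                out, pad = _block_pads(sizes[ax], kern[ax], stride[ax])
                pad_ax.append(pad)
                new_sizes.append(out)
            pad = (pad_ax[0], pad_ax[1])
            block_out = new_sizes
        else:
            pad = ((0, 0), (0, 0))
        layers.append(LayerSpec(
            name=name, kind=kind, filter_size=kern, stride=stride,
            filter_count=filters, activation="leaky_relu" if name.endswith("1") else "linear",
            batchnorm=block != "A", pad=pad, block=block, role=role))
        if role == "shortcut":
            sizes = block_out
    e1 = _DISC_TABLE[12]
    f1 = _DISC_TABLE[13]
    e1_pad: list[Pad] = []
    f1_pad: list[Pad] = []
    for ax in (0, 1):
        k, s = e1[2][ax], e1[3][ax]
        pmax = (k - 1) + (s - 1)
        for target in range(f1[2][ax], 0, -1):
            ptot = s * (target - 1) + k - sizes[ax]
            if 0 <= ptot <= pmax:
                e1_pad.append(_split(ptot))
                f1_pad.append(_split(f1[2][ax] - target))
                break
            if ptot < 0 and (sizes[ax] - k) // s + 1 == target:
                e1_pad.append((0, 0))
                f1_pad.append(_split(f1[2][ax] - target))
                break
        else:
            raise ValueError(f"no feasible critic head trace for input {input_shape}")
    layers.append(LayerSpec(
        name=e1[0], kind="conv", filter_size=e1[2], stride=e1[3],
        filter_count=e1[4], activation="leaky_relu", batchnorm=True,
        pad=(e1_pad[0], e1_pad[1]), block="E", role="plain"))
    layers.append(LayerSpec(
        name=f1[0], kind="conv", filter_size=f1[2], stride=f1[3],
        filter_count=f1[4], activation="linear", batchnorm=False,
        pad=(f1_pad[0], f1_pad[1]), block="F", role="plain"))
    spec = NetworkSpec(tuple(layers), input_shape, (1, 1))
    if spec.shape_trace()[-1] != (1, 1):
        raise ValueError("discriminator shape trace does not end at a scalar")
    return spec


def _build_unit(l: LayerSpec, in_ch: int, with_act: bool) -> list[tuple[str, object]]:
    gain = math.sqrt(2.0 / (1.0 + LEAKY_SLOPE ** 2)) if l.activation != "tanh" else 1.0
    if l.kind == "conv":
        conv = Conv2D(in_ch, l.filter_count, l.filter_size, l.stride, l.pad, gain=gain)
    else:
        conv = ConvTranspose2D(in_ch, l.filter_count, l.filter_size, l.stride,
                               l.pad, l.output_padding, gain=gain)
    out: list[tuple[str, object]] = [(l.name, conv)]
    if l.batchnorm:
        out.append((f"{l.name}_bn", BatchNorm2D(l.filter_count)))
    if with_act:
        if l.activation == "leaky_relu":
            out.append((f"{l.name}_act", LeakyReLU(LEAKY_SLOPE)))
        elif l.activation == "tanh":
            out.append((f"{l.name}_act", Tanh()))
    return out


def build_network(spec: NetworkSpec, in_features: int = 1) -> Sequential:
    """Instantiate the layer stack of a :class:`NetworkSpec` (parameters unset)."""
    try:
        spec.shape_trace()
    except ValueError as err:
        raise ValueError(f"inconsistent network spec: {err}") from err
    stack: list[tuple[str, object]] = []
    n_in = in_features
    for gkind, members in spec.grouped():
        if gkind == "plain":
            (l,) = members
            stack.extend(_build_unit(l, n_in, with_act=True))
            n_in = l.filter_count
        else:
            mains = [l for l in members if l.role == "main"]
            (short,) = [l for l in members if l.role == "shortcut"]
            main_stack: list[tuple[str, object]] = []
            m_in = n_in
            for i, l in enumerate(mains):
                main_stack.extend(_build_unit(l, m_in, with_act=i < len(mains) - 1))
                m_in = l.filter_count
            short_stack = _build_unit(short, n_in, with_act=False)
            stack.append((f"block{members[0].block}", Residual(
                Sequential(main_stack), Sequential(short_stack),
                LeakyReLU(LEAKY_SLOPE))))
            n_in = short.filter_count
    return Sequential(stack)


@dataclass
class DenoiserModel:
    """Generator/critic pair with reproducible initialization.

    ``setet`` and ``sampen`` record the normalization regime the model was
    (or is to be) trained under, so a checkpoint is self-contained.
    """

    generator: Sequential
    discriminator: Sequential
    gen_spec: NetworkSpec
    disc_spec: NetworkSpec
    seed: int
    setet: SetetConfig = field(default_factory=SetetConfig)
    sampen: SampEnParams = field(default_factory=SampEnParams)

    @property
    def input_shape(self) -> tuple[int, int]:
        return self.gen_spec.input_shape


def build_model(gen_spec: NetworkSpec | None = None,
                disc_spec: NetworkSpec | None = None,
                seed: int = 0,
                setet: SetetConfig = SetetConfig(),
                sampen: SampEnParams = SampEnParams()) -> DenoiserModel:
    """Construct and seed-deterministically initialize both networks."""
    gen_spec = gen_spec or default_generator_spec()
    disc_spec = disc_spec or default_discriminator_spec()
    if gen_spec.input_shape != disc_spec.input_shape:
        raise ValueError("generator and discriminator input shapes differ")
    gen = build_network(gen_spec)
    disc = build_network(disc_spec)
    rng = np.random.default_rng(seed)
    gen.init_params(rng)
    disc.init_params(rng)
    return DenoiserModel(gen, disc, gen_spec, disc_spec, seed, setet, sampen)


def _as_batch(x: np.ndarray, shape: tuple[int, int]) -> tuple[np.ndarray, bool]:
    x = np.asarray(x, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3 or x.shape[1:] != shape:
        raise ValueError(f"expected trials of shape {shape}, got {x.shape}")
    return x[:, None], single


def generate(model: DenoiserModel, s_batch: np.ndarray, train: bool = False) -> np.ndarray:
    """Map normalized trials through the generator. Accepts (C,T) or (N,C,T)."""
    x, single = _as_batch(s_batch, model.input_shape)
    out = model.generator.forward(x, train=train)[:, 0]
    return out[0] if single else out


def discriminate(model: DenoiserModel, batch: np.ndarray, train: bool = False) -> np.ndarray:
    """Score trials with the critic: one finite real per trial, unbounded range."""
    x, single = _as_batch(batch, model.input_shape)
    out = model.discriminator.forward(x, train=train)[:, 0, 0, 0]
    return out[0] if single else out


# ---------------------------------------------------------------------------
# Checkpoint container: a single .npz holding both state dicts plus a JSON
# header with the specs, seed and normalization configuration.

def save_checkpoint(model: DenoiserModel, path: str) -> None:
    header = {
        "gen_spec": _spec_to_json(model.gen_spec),
        "disc_spec": _spec_to_json(model.disc_spec),
        "seed": model.seed,
        "setet": asdict(model.setet),
        "sampen": asdict(model.sampen),
    }
    arrays = {f"G::{k}": v for k, v in model.generator.state_dict().items()}
    arrays.update({f"D::{k}": v for k, v in model.discriminator.state_dict().items()})
    arrays["__header__"] = np.frombuffer(
        json.dumps(header).encode("utf-8"), dtype=np.uint8)
    with open(path, "wb") as fh:
        np.savez(fh, **arrays)


def load_checkpoint(path: str) -> DenoiserModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode("utf-8"))
        arrays = {k: data[k] for k in data.files if k != "__header__"}
    gen_spec = _spec_from_json(header["gen_spec"])
    disc_spec = _spec_from_json(header["disc_spec"])
    model = build_model(gen_spec, disc_spec, seed=int(header["seed"]),
                        setet=SetetConfig(**header["setet"]),
                        sampen=SampEnParams(**header["sampen"]))
    model.generator.load_state_dict(
        {k[3:]: v for k, v in arrays.items() if k.startswith("G::")})
    model.discriminator.load_state_dict(
        {k[3:]: v for k, v in arrays.items() if k.startswith("D::")})
    return model


def _spec_to_json(spec: NetworkSpec) -> dict:
    return {
        "layers": [asdict(l) for l in spec.layers],
        "input_shape": list(spec.input_shape),
        "output_shape": list(spec.output_shape),
    }


def _tup(x):
    return tuple(_tup(v) for v in x) if isinstance(x, (list, tuple)) else x


def _spec_from_json(d: dict) -> NetworkSpec:
    layers = tuple(
        LayerSpec(**{k: _tup(v) for k, v in l.items()}) for l in d["layers"]
    )
    return NetworkSpec(layers, tuple(d["input_shape"]), tuple(d["output_shape"]))
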