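"""The four-block complex-valued EEG decoder and its ablation variants.

Default architecture (C=62 channels, T=200 frequency bins):

    input (1, C, T) complex spectrum
    1. spectral block   : CConv (1, 101) same-padding, 1 -> F1=8, CBN, CReLU
    2. spatial block    : depthwise CConv (C, 1), F1 -> D*F1=16, CBN, CReLU,
                          CAvgPool (1, 4)
    3. separable block  : depthwise CConv (1, 101) same-padding, pointwise
                          1x1 -> F2=16, CBN, CReLU, CAvgPool (1, 4)
    4. classifier       : flatten (192) -> CLinear 64 -> CReLU -> CLinear K

The complex logits pass through a modulus readout and are normalized into
class probabilities (softmax by default; plain sum-normalization is a
config option).  Ablation variants delete whole blocks (including their
pooling) or replace the spatial convolution by a parameter-free channel
mean, with the classifier width recomputed from the surviving shape trace.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict
from typing import List, Optional, Tuple

import numpy as np

from . import autograd as ag
from .autograd import Tensor
from .complex_ops import (
    CAvgPool2d, CBatchNorm2d, CConv2d, CLinear, CReLU,
    ComplexTensor, modulus,
)
from .errors import ConfigurationError, DimensionError

__all__ = [
    "ModelConfig", "ModelVariant", "CVEEGNet", "build_model", "build_variant",
    "trace_shapes", "count_parameters", "count_flops", "FLOP_CONVENTION",
    "save_checkpoint", "load_checkpoint",
]

FLOP_CONVENTION = (
    "1 complex MAC = 4 real multiplies + 4 real adds (8 real ops); "
    "convolution and dense multiply-accumulates only, per input sample; "
    "biases, normalization, pooling and activations excluded"
)


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    C: electrode channels; T: samples per window (= frequency bins);
    F1: spectral filters; D: spatial depth multiplier; F2: separable
    filters; k_spec/k_sep: kernel lengths along the frequency axis;
    pool1/pool2: pooling widths; hidden: classifier width; n_classes: K.
    """

    C: int = 62
    T: int = 200
    F1: int = 8
    D: int = 2
    F2: int = 16
    k_spec: int = 101
    k_sep: int = 101
    pool1: int = 4
    pool2: int = 4
    hidden: int = 64
    n_classes: int = 3
    prob_head: str = "softmax"  # softmax | sum

    def __post_init__(self):
        for name in ("C", "T", "F1", "D", "F2", "k_spec", "k_sep",
                     "pool1", "pool2", "hidden", "n_classes"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"config field {name} must be a positive integer")
        if self.prob_head not in ("softmax", "sum"):
            raise ConfigurationError(f"unknown prob_head {self.prob_head!r}")


@dataclass
class ModelVariant:
    include_spectral: bool = True
    include_spatial: bool = True
    include_separable: bool = True
    spatial_replacement: Optional[str] = None  # None | "mean_pool"

    def __post_init__(self):
        if not (self.include_spectral or self.include_spatial or self.include_separable):
            raise ConfigurationError("variant must keep at least one block")
        if self.spatial_replacement not in (None, "mean_pool"):
            raise ConfigurationError(
                f"unknown spatial_replacement {self.spatial_replacement!r}"
            )
        if self.spatial_replacement and not self.include_spatial:
            raise ConfigurationError("mean_pool replacement requires the spatial slot")

    @classmethod
    def from_name(cls, name: str) -> "ModelVariant":
        table = {
            "full": cls(),
            "no_spectral": cls(include_spectral=False),
            "no_spatial": cls(include_spatial=False),
            "no_separable": cls(include_separable=False),
            "spatial_meanpool": cls(spatial_replacement="mean_pool"),
            "only_spectral": cls(include_spatial=False, include_separable=False),
            "only_spatial": cls(include_spectral=False, include_separable=False),
            "only_separable": cls(include_spectral=False, include_spatial=False),
        }
        if name not in table:
            raise ConfigurationError(
                f"unknown variant {name!r}; choose from {sorted(table)}"
            )
        return table[name]


FULL_VARIANT = ModelVariant()


def trace_shapes(config: ModelConfig, variant: ModelVariant = FULL_VARIANT
                 ) -> List[Tuple[str, Tuple[int, ...]]]:
    """Per-block output shapes (channels, height, width), ending in the
    flattened classifier input; independent of any built network."""
    ch, h, w = 1, config.C, config.T
    trace = [("input", (ch, h, w))]
    if variant.include_spectral:
        ch = config.F1
        trace.append(("spectral_conv", (ch, h, w)))
    if variant.include_spatial:
        if variant.spatial_replacement == "mean_pool":
            h = 1
            trace.append(("spatial_meanpool", (ch, h, w)))
        else:
            out_ch = config.D * config.F1
            if out_ch % ch:
                raise ConfigurationError(
                    f"spatial depthwise conv needs current channels ({ch}) to divide "
                    f"D*F1 ({out_ch})"
                )
            ch, h = out_ch, h - config.C + 1
            if h != 1:
                raise ConfigurationError(
                    f"spatial kernel height C={config.C} must collapse the channel axis"
                )
            trace.append(("spatial_conv", (ch, h, w)))
        w = w // config.pool1
        if w < 1:
            raise ConfigurationError("pool1 wider than the feature map")
        trace.append(("spatial_pool", (ch, h, w)))
    if variant.include_separable:
        trace.append(("separable_depthwise", (ch, h, w)))
        ch = config.F2
        trace.append(("separable_pointwise", (ch, h, w)))
        w = w // config.pool2
        if w < 1:
            raise ConfigurationError("pool2 wider than the feature map")
        trace.append(("separable_pool", (ch, h, w)))
    trace.append(("flatten", (ch * h * w,)))
    trace.append(("hidden", (config.hidden,)))
    trace.append(("logits", (config.n_classes,)))
    return trace


class _ChannelMean:
    """Parameter-free collapse of the electrode (height) axis by averaging."""

    def __call__(self, x: ComplexTensor) -> ComplexTensor:
        return ComplexTensor(
            ag.tmean(x.real, axis=2, keepdims=True),
            ag.tmean(x.imag, axis=2, keepdims=True),
        )

    def parameter_pairs(self):
        return []


class CVEEGNet:
    """Complex-valued spectral CNN for multichannel EEG classification."""

    def __init__(self, config: ModelConfig = None, variant: ModelVariant = None,
                 seed: int = 0, dtype=np.float64):
        self.config = config or ModelConfig()
        self.variant = variant or ModelVariant()
        self.seed = int(seed)
        self.dtype = np.dtype(dtype)
        rng = np.random.default_rng(self.seed)
        cfg = self.config
        self.trace = trace_shapes(cfg, self.variant)
        self.flatten_dim = dict(self.trace)["flatten"][0]

        self._layers = []   # ordered (name, layer) pairs, feature extractor only
        self._flop_items = []  # (complex MACs per sample)
        ch, h, w = 1, cfg.C, cfg.T

        def add(name, layer):
            self._layers.append((name, layer))

        if self.variant.include_spectral:
            pad = (0, (cfg.k_spec - 1) // 2)
            add("spectral.conv", CConv2d(rng, ch, cfg.F1, (1, cfg.k_spec),
                                         padding=pad, dtype=dtype))
            out_w = w + 2 * pad[1] - cfg.k_spec + 1
            self._flop_items.append(cfg.F1 * h * out_w * (1 * cfg.k_spec))
            ch, w = cfg.F1, out_w
            add("spectral.bn", CBatchNorm2d(ch, dtype=dtype))
            add("spectral.act", CReLU())
        if self.variant.include_spatial:
            if self.variant.spatial_replacement == "mean_pool":
                add("spatial.meanpool", _ChannelMean())
                h = 1
            else:
                out_ch = cfg.D * cfg.F1
                add("spatial.conv", CConv2d(rng, ch, out_ch, (cfg.C, 1),
                                            groups=ch, dtype=dtype))
                self._flop_items.append(out_ch * 1 * w * (cfg.C * 1))
                ch, h = out_ch, 1
                add("spatial.bn", CBatchNorm2d(ch, dtype=dtype))
                add("spatial.act", CReLU())
            add("spatial.pool", CAvgPool2d((1, cfg.pool1)))
            w = w // cfg.pool1
        if self.variant.include_separable:
            pad = (0, (cfg.k_sep - 1) // 2)
            add("separable.depthwise", CConv2d(rng, ch, ch, (1, cfg.k_sep),
                                               padding=pad, groups=ch, dtype=dtype))
            out_w = w + 2 * pad[1] - cfg.k_sep + 1
            self._flop_items.append(ch * h * out_w * (1 * cfg.k_sep))
            w = out_w
            add("separable.pointwise", CConv2d(rng, ch, cfg.F2, (1, 1), dtype=dtype))
            self._flop_items.append(cfg.F2 * h * w * ch)
            ch = cfg.F2
            add("separable.bn", CBatchNorm2d(ch, dtype=dtype))
            add("separable.act", CReLU())
            add("separable.pool", CAvgPool2d((1, cfg.pool2)))
            w = w // cfg.pool2

        flat = ch * h * w
        assert flat == self.flatten_dim, "shape trace and built network disagree"
        self._fc1 = CLinear(rng, flat, cfg.hidden, dtype=dtype)
        self._fc2 = CLinear(rng, cfg.hidden, cfg.n_classes, dtype=dtype)
        self._flop_items.append(flat * cfg.hidden)
        self._flop_items.append(cfg.hidden * cfg.n_classes)
        self._classifier = [("classifier.fc1", self._fc1), ("classifier.fc2", self._fc2)]
        self.training = True

    # -- mode ---------------------------------------------------------------
    def train(self):
        self.training = True
        for _, layer in self._layers:
            if isinstance(layer, CBatchNorm2d):
                layer.training = True
        return self

    def eval(self):
        self.training = False
        for _, layer in self._layers:
            if isinstance(layer, CBatchNorm2d):
                layer.training = False
        return self

    # -- forward ------------------------------------------------------------
    def _check_input(self, x: ComplexTensor):
        cfg = self.config
        if x.real.ndim != 4 or x.shape[1] != 1 or x.shape[2] != cfg.C or x.shape[3] != cfg.T:
            raise DimensionError(
                f"expected input of shape (B, 1, {cfg.C}, {cfg.T}), got {x.shape}"
            )

    def features(self, x: ComplexTensor) -> ComplexTensor:
        """Run the convolutional blocks and flatten."""
        self._check_input(x)
        for _, layer in self._layers:
            x = layer(x)
        b = x.shape[0]
        return x.reshape((b, self.flatten_dim))

    def penultimate(self, x: ComplexTensor) -> ComplexTensor:
        """Hidden-layer representation (B, hidden), after the first CLinear + CReLU."""
        h = self.features(x)
        h = self._fc1(h)
        return ComplexTensor(ag.relu(h.real), ag.relu(h.imag))

    def logits(self, x: ComplexTensor) -> ComplexTensor:
        """Complex class logits (B, K)."""
        return self._fc2(self.penultimate(x))

    def forward(self, x: ComplexTensor) -> Tensor:
        """Class probabilities (B, K): softmax (or sum-normalization) over
        the modulus of the complex logits."""
        mag = modulus(self.logits(x))
        if self.config.prob_head == "softmax":
            return ag.softmax(mag, axis=1)
        return ag.div(mag, ag.tsum(mag, axis=1, keepdims=True))

    __call__ = forward

    def predict(self, x: ComplexTensor, batch_size: int = 256) -> np.ndarray:
        """Memory-bounded inference returning probabilities as ndarray."""
        n = x.shape[0]
        out = []
        with ag.no_grad():
            for i in range(0, n, batch_size):
                xb = ComplexTensor(x.real.data[i:i + batch_size],
                                   x.imag.data[i:i + batch_size])
                out.append(self.forward(xb).data)
        return np.concatenate(out, axis=0)

    # -- parameters ----------------------------------------------------------
    def _all_layers(self):
        return self._layers + self._classifier

    def complex_parameter_pairs(self):
        pairs = []
        for _, layer in self._all_layers():
            pairs.extend(layer.parameter_pairs())
        return pairs

    def parameters(self) -> List[Tensor]:
        out = []
        for r, i in self.complex_parameter_pairs():
            out.extend((r, i))
        return out

    # -- serialization --------------------------------------------------------
    def state_dict(self):
        state = {}
        for name, layer in self._all_layers():
            if isinstance(layer, CConv2d):
                k = layer.kernel
                state[f"{name}.w_real"] = k.w_real.data.copy()
                state[f"{name}.w_imag"] = k.w_imag.data.copy()
                if k.b_real is not None:
                    state[f"{name}.b_real"] = k.b_real.data.copy()
                    state[f"{name}.b_imag"] = k.b_imag.data.copy()
            elif isinstance(layer, CLinear):
                p = layer.params
                state[f"{name}.w_real"] = p.w_real.data.copy()
                state[f"{name}.w_imag"] = p.w_imag.data.copy()
                if p.b_real is not None:
                    state[f"{name}.b_real"] = p.b_real.data.copy()
                    state[f"{name}.b_imag"] = p.b_imag.data.copy()
            elif isinstance(layer, CBatchNorm2d):
                p = layer.params
                for key in ("gamma_real", "gamma_imag", "beta_real", "beta_imag"):
                    state[f"{name}.{key}"] = getattr(p, key).data.copy()
                for key in ("running_mean_real", "running_mean_imag",
                            "running_var_real", "running_var_imag"):
                    state[f"{name}.{key}"] = getattr(p, key).copy()
        return state

    def load_state_dict(self, state):
        own = self.state_dict()
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing entries: {sorted(missing)[:5]} ...")
        for name, layer in self._all_layers():
            if isinstance(layer, (CConv2d, CLinear)):
                holder = layer.kernel if isinstance(layer, CConv2d) else layer.params
                for key in ("w_real", "w_imag", "b_real", "b_imag"):
                    t = getattr(holder, key)
                    if t is not None:
                        t.data = np.asarray(state[f"{name}.{key}"], dtype=t.data.dtype)
            elif isinstance(layer, CBatchNorm2d):
                p = layer.params
                for key in ("gamma_real", "gamma_imag", "beta_real", "beta_imag"):
                    t = getattr(p, key)
                    t.data = np.asarray(state[f"{name}.{key}"], dtype=t.data.dtype)
                for key in ("running_mean_real", "running_mean_imag",
                            "running_var_real", "running_var_imag"):
                    arr = getattr(p, key)
                    arr[:] = np.asarray(state[f"{name}.{key}"], dtype=arr.dtype)


def build_model(config: ModelConfig = None, seed: int = 0, dtype=np.float64) -> CVEEGNet:
    """Assemble the full default network."""
    return CVEEGNet(config or ModelConfig(), FULL_VARIANT, seed=seed, dtype=dtype)


def build_variant(config: ModelConfig, variant: ModelVariant, seed: int = 0,
                  dtype=np.float64) -> CVEEGNet:
    """Assemble an ablation variant; the classifier width follows the trace."""
    return CVEEGNet(config, variant, seed=seed, dtype=dtype)


def count_parameters(model: CVEEGNet) -> int:
    """Trainable complex scalars, each (real, imag) pair counted once."""
    return int(sum(r.data.size for r, _ in model.complex_parameter_pairs()))


def count_flops(model: CVEEGNet) -> int:
    """Real-operation count per input sample under FLOP_CONVENTION."""
    return int(8 * sum(model._flop_items))


# ---------------------------------------------------------------------------
# checkpoints: flat map of named real arrays + JSON config, single .npz
# ---------------------------------------------------------------------------

def save_checkpoint(model: CVEEGNet, path) -> None:
    meta = {
        "config": asdict(model.config),
        "variant": asdict(model.variant),
        "seed": model.seed,
        "dtype": model.dtype.name,
    }
    state = model.state_dict()
    state["__meta__"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path) -> CVEEGNet:
    with np.load(path) as f:
        state = {k: f[k] for k in f.files}
    meta = json.loads(bytes(state.pop("__meta__")).decode())
    model = CVEEGNet(
        ModelConfig(**meta["config"]),
        ModelVariant(**meta["variant"]),
        seed=meta["seed"],
        dtype=np.dtype(meta["dtype"]),
    )
    model.load_state_dict(state)
    return model
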