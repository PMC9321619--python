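"""Multitask Siamese network for joint PPG + respiration prediction.

Two fixed facial regions — forehead and cheek — are cropped from every video
frame and fed through the *same* convolutional branch (one set of layer
objects, so the weights are shared structurally, not copied). Each branch
reduces a frame to a scalar, so a T-frame clip yields a T-sample trace per
region; the two traces are merged by elementwise addition into the predicted
PPG signal. No dense layer follows the merge on the PPG path. In multitask
mode a small dense head reads the merged per-frame embedding and emits the
respiration trace, one sample per frame.

Each branch stage is: 3x3 convolution -> leaky ReLU -> optional 1x1
channel-reduction convolution -> leaky ReLU -> channel attention -> spatial
attention -> 2x2 max pool. The 1x1 convolutions and the attention gates keep
the parameter budget small (~0.72 M multitask, ~0.69 M single-task with the
default widths) while retaining expressiveness.

Because frames ride on the batch axis and both heads read out per frame, the
output length always equals the input frame count and the parameter count is
independent of clip length.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import nn
from .nn import leaky_relu  # re-exported: the activation used throughout

__all__ = [
    "ModelSpec",
    "VitalsPrediction",
    "SiameseVitalsNet",
    "build_model",
    "count_parameters",
    "leaky_relu",
    "MULTITASK_PARAM_BUDGET",
    "SINGLE_TASK_PARAM_BUDGET",
]

#: Published parameter budgets (trainable scalars, shared weights once).
MULTITASK_PARAM_BUDGET = 0.72e6
SINGLE_TASK_PARAM_BUDGET = 0.69e6


@dataclass(frozen=True)
class ModelSpec:
    """Architecture hyperparameters for the Siamese vitals network.

    Parameters
    ----------
    n_frames
        Clip length T the model is trained on (outputs adapt to any T).
    roi_shape
        Per-frame ROI tensor shape ``(height, width, channels)``.
    branch_widths
        Output channels of each stage's 3x3 convolution.
    pointwise_widths
        Output channels of each stage's 1x1 reduction convolution, or
        ``None`` to skip the 1x1 convolution at that stage.
    cbam_reduction_ratio
        Bottleneck ratio of the channel-attention MLP.
    spatial_kernel
        Odd kernel size of the spatial-attention convolution.
    leaky_alpha
        Negative-side slope of the leaky ReLU activation.
    dropout_rates
        Three rates assigned shallow-to-deep: after the last conv stage,
        after the embedding dense layer, and inside the respiration head.
    embed_dim
        Width of the per-frame embedding the PPG readout and respiration
        head consume.
    resp_hidden
        Hidden width of the per-frame respiration MLP head.
    multitask
        If True the network has a respiration output head; otherwise it is
        the single-task (PPG-only) Siamese variant.
    seed
        Seed for weight initialization (uniform fan-based).
    reference_budget
        Expected trainable-parameter count; a built model deviating by more
        than 10% triggers a warning.
    """

    n_frames: int = 600
    roi_shape: tuple[int, int, int] = (40, 140, 3)
    branch_widths: tuple[int, ...] = (32, 32, 32)
    pointwise_widths: tuple[int | None, ...] = (16, 16, 163)
    cbam_reduction_ratio: int = 8
    spatial_kernel: int = 7
    leaky_alpha: float = 0.01
    dropout_rates: tuple[float, float, float] = (0.25, 0.5, 0.6)
    embed_dim: int = 48
    resp_hidden: int = 588
    multitask: bool = True
    seed: int = 0
    reference_budget: float | None = None

    def __post_init__(self) -> None:
        if self.leaky_alpha <= 0:
            raise ValueError("leaky_alpha must be positive")
        if len(self.branch_widths) != len(self.pointwise_widths):
            raise ValueError("branch_widths and pointwise_widths must align")
        if any(d <= 0 for d in self.roi_shape) or self.n_frames <= 0:
            raise ValueError("roi_shape and n_frames must be positive")
        if self.cbam_reduction_ratio < 1:
            raise ValueError("cbam_reduction_ratio must be >= 1")

    @classmethod
    def default_multitask(cls) -> "ModelSpec":
        """Frozen full-size multitask spec (~0.72 M parameters)."""
        return cls(multitask=True, reference_budget=MULTITASK_PARAM_BUDGET)

    @classmethod
    def default_single_task(cls) -> "ModelSpec":
        """Frozen full-size single-task spec (~0.69 M parameters)."""
        return cls(multitask=False, reference_budget=SINGLE_TASK_PARAM_BUDGET)

    @classmethod
    def reduced(cls, multitask: bool = True, seed: int = 0) -> "ModelSpec":
        """Narrow desk-scale spec: 12x32 ROIs, 128 frames, a few thousand params."""
        return cls(
            n_frames=128,
            roi_shape=(12, 32, 3),
            branch_widths=(8, 8, 8),
            pointwise_widths=(8, 8, 16),
            embed_dim=16,
            resp_hidden=32,
            multitask=multitask,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["roi_shape"] = list(self.roi_shape)
        d["branch_widths"] = list(self.branch_widths)
        d["pointwise_widths"] = list(self.pointwise_widths)
        d["dropout_rates"] = list(self.dropout_rates)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        for k in ("roi_shape", "branch_widths", "pointwise_widths", "dropout_rates"):
            if k in d and d[k] is not None:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class VitalsPrediction:
    """Per-frame predicted traces; respiration is None in single-task mode."""

    ppg: np.ndarray
    respiration: np.ndarray | None


class SiameseVitalsNet:
    """The built network: shared branch, Add merge, optional respiration head."""

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        a = spec.leaky_alpha
        h, w, c_in = spec.roi_shape

        self.stages: list[dict] = []
        for i, (cw, pw) in enumerate(zip(spec.branch_widths, spec.pointwise_widths)):
            stage = {
                "conv": nn.Conv2D(c_in, cw, 3, rng, name=f"stage{i}.conv",
                                  need_input_grad=(i > 0)),
                "act": nn.LeakyReLU(a),
            }
            c_out = cw
            if pw is not None:
                stage["pointwise"] = nn.Conv2D(cw, pw, 1, rng, name=f"stage{i}.pw")
                stage["pw_act"] = nn.LeakyReLU(a)
                c_out = pw
            stage["ca"] = nn.ChannelAttention(
                c_out, spec.cbam_reduction_ratio, rng, alpha=a, name=f"stage{i}.ca"
            )
            stage["sa"] = nn.SpatialAttention(spec.spatial_kernel, rng, name=f"stage{i}.sa")
            stage["pool"] = nn.MaxPool2()
            self.stages.append(stage)
            c_in = c_out
            h, w = h // 2, w // 2
            if h < 1 or w < 1:
                raise ValueError("ROI too small for the number of pooling stages")

        self.flat_dim = h * w * c_in
        d1, d2, d3 = spec.dropout_rates
        self.conv_dropout = nn.Dropout(d1)
        self.embed = nn.Dense(self.flat_dim, spec.embed_dim, rng, name="embed")
        self.embed_act = nn.LeakyReLU(a)
        self.embed_dropout = nn.Dropout(d2)
        self.ppg_head = nn.Dense(spec.embed_dim, 1, rng, name="ppg_head")

        if spec.multitask:
            self.resp_hidden = nn.Dense(spec.embed_dim, spec.resp_hidden, rng,
                                        name="resp.hidden")
            self.resp_act = nn.LeakyReLU(a)
            self.resp_dropout = nn.Dropout(d3)
            self.resp_out = nn.Dense(spec.resp_hidden, 1, rng, name="resp.out")

        budget = spec.reference_budget
        if budget is not None:
            n = count_parameters(self)
            if abs(n - budget) / budget > 0.10:
                warnings.warn(
                    f"parameter count {n:,} deviates more than 10% from the "
                    f"expected budget {budget:,.0f}",
                    stacklevel=2,
                )
        self._cache = None

    # ---- parameter bookkeeping -------------------------------------------

    def branch_layers(self) -> list[nn.Layer]:
        layers: list[nn.Layer] = []
        for st in self.stages:
            layers.extend(st.values())
        layers += [self.conv_dropout, self.embed, self.embed_act,
                   self.embed_dropout, self.ppg_head]
        return layers

    def parameters(self) -> list[nn.Param]:
        """All trainable parameters; shared branch parameters appear once."""
        seen: dict[int, nn.Param] = {}
        layers = self.branch_layers()
        if self.spec.multitask:
            layers += [self.resp_hidden, self.resp_act, self.resp_dropout, self.resp_out]
        for layer in layers:
            for p in layer.params():
                seen.setdefault(id(p), p)
        return list(seen.values())

    # ---- forward / backward ----------------------------------------------

    def _branch(self, x, training, rng):
        """One branch pass: (T,h,w,c) frames -> (T,) trace and (T,E) embedding."""
        cache = []
        for st in self.stages:
            for key in ("conv", "act", "pointwise", "pw_act", "ca", "sa", "pool"):
                if key not in st:
                    continue
                x, c = st[key].forward(x, training=training, rng=rng)
                cache.append((st[key], c))
        x, c = self.conv_dropout.forward(x, training=training, rng=rng)
        cache.append((self.conv_dropout, c))
        flat_shape = x.shape
        x = x.reshape(x.shape[0], -1)
        for layer in (self.embed, self.embed_act, self.embed_dropout):
            x, c = layer.forward(x, training=training, rng=rng)
            cache.append((layer, c))
        emb = x
        trace, c = self.ppg_head.forward(emb, training=training, rng=rng)
        cache.append((self.ppg_head, c))
        return trace[:, 0], emb, (cache, flat_shape)

    def _branch_back(self, dtrace, demb, branch_cache):
        cache, flat_shape = branch_cache
        layer, c = cache[-1]  # ppg_head
        grad = layer.backward(dtrace[:, None], c)
        grad = grad + demb
        for layer, c in reversed(cache[:-1]):
            if isinstance(layer, nn.Dropout) and layer is self.conv_dropout:
                grad = layer.backward(grad.reshape(flat_shape), c)
            else:
                grad = layer.backward(grad, c)
        return grad

    def forward(self, forehead: np.ndarray, cheek: np.ndarray, *,
                training: bool = False,
                rng: np.random.Generator | None = None) -> VitalsPrediction:
        """Predict per-frame PPG (and respiration) from two ROI streams.

        Both inputs are ``(T, height, width, 3)`` tensors in [0, 1]. The same
        branch processes each, so swapping the inputs leaves the merged PPG
        unchanged.
        """
        tr_f, emb_f, cache_f = self._branch(forehead, training, rng)
        tr_c, emb_c, cache_c = self._branch(cheek, training, rng)
        ppg = tr_f + tr_c
        resp = None
        resp_cache = None
        if self.spec.multitask:
            merged = emb_f + emb_c
            x, c1 = self.resp_hidden.forward(merged, training=training, rng=rng)
            x, c2 = self.resp_act.forward(x, training=training, rng=rng)
            x, c3 = self.resp_dropout.forward(x, training=training, rng=rng)
            out, c4 = self.resp_out.forward(x, training=training, rng=rng)
            resp = out[:, 0]
            resp_cache = (c1, c2, c3, c4)
        self._cache = (cache_f, cache_c, resp_cache)
        return VitalsPrediction(ppg=ppg, respiration=resp)

    def backward(self, dppg: np.ndarray, dresp: np.ndarray | None = None) -> None:
        """Accumulate parameter gradients for the most recent forward pass."""
        if self._cache is None:
            raise RuntimeError("backward called before forward")
        cache_f, cache_c, resp_cache = self._cache
        demb = np.zeros((dppg.shape[0], self.spec.embed_dim))
        if self.spec.multitask and dresp is not None:
            c1, c2, c3, c4 = resp_cache
            g = self.resp_out.backward(dresp[:, None], c4)
            g = self.resp_dropout.backward(g, c3)
            g = self.resp_act.backward(g, c2)
            demb = self.resp_hidden.backward(g, c1)
        # merged embedding and Add both fan the gradient to each branch
        self._branch_back(dppg, demb, cache_f)
        self._branch_back(dppg, demb, cache_c)
        self._cache = None

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    # ---- persistence ------------------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {p.name: p.value.copy() for p in self.parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = {p.name: p for p in self.parameters()}
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"checkpoint is missing parameters: {sorted(missing)}")
        for name, p in params.items():
            p.value[...] = state[name]

    def save(self, path: str | Path) -> None:
        """Write weights as npz plus a sidecar YAML spec (self-describing)."""
        path = Path(path)
        np.savez(path, **self.state_dict())
        spec_path = path.with_suffix(".spec.yaml")
        spec_path.write_text(yaml.safe_dump(self.spec.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "SiameseVitalsNet":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"checkpoint not found: {path}")
        spec = ModelSpec.from_dict(
            yaml.safe_load(path.with_suffix(".spec.yaml").read_text())
        )
        net = cls(spec)
        with np.load(path) as data:
            net.load_state_dict(dict(data))
        return net


def build_model(spec: ModelSpec) -> SiameseVitalsNet:
    """Construct the network described by ``spec``."""
    return SiameseVitalsNet(spec)


def count_parameters(net: SiameseVitalsNet) -> int:
    """Trainable scalar parameters, shared branch weights counted once."""
    return sum(p.size for p in net.parameters())
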