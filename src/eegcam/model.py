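"""Seven-layer interpretable separable CNN for epoched multichannel EEG.

The architecture inverts the usual separable-convolution order on purpose:
a pointwise (1x1-over-channels) convolution first *demixes* the sensor
channels into S virtual sources, then a grouped temporal convolution learns
features from each demixed signal independently (depthwise when
``groups == S``, the default).  ReLU, batch normalization, global average
pooling over time, a dense read-out and log-softmax complete the model.

Everything is plain numpy: forward, training-mode batch statistics, and the
caches the backward pass (in :mod:`eegcam.training`) needs.  The depthwise
structure is what makes the relevance reconstruction in
:mod:`eegcam.interpret` well-defined: each feature map belongs to exactly
one demixed channel.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.random import default_rng
from scipy.signal import fftconvolve


@dataclass(frozen=True)
class ModelConfig:
    n_channels: int = 60
    n_samples: int = 320
    spatial_filters: int = 16        # S: number of demixed channels
    temporal_kernel_len: int = 64    # L
    depth_multiplier: int = 2        # D: feature maps per demixed channel
    n_classes: int = 2
    groups: Optional[int] = None     # None -> spatial_filters (true depthwise)
    pointwise_bias: bool = True
    depthwise_bias: bool = False
    batchnorm_eps: float = 1e-5
    batchnorm_momentum: float = 0.1
    init_scheme: str = "uniform_fanin"
    init_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.spatial_filters, self.depth_multiplier, self.n_classes) < 1:
            raise ValueError("spatial_filters, depth_multiplier, n_classes >= 1")
        if self.n_samples <= self.temporal_kernel_len:
            raise ValueError(
                f"n_samples ({self.n_samples}) must exceed temporal kernel "
                f"length ({self.temporal_kernel_len})")
        g = self.effective_groups
        if self.spatial_filters % g or self.n_maps % g:
            raise ValueError("groups must divide both S and S*D")

    @property
    def effective_groups(self) -> int:
        return self.spatial_filters if self.groups is None else self.groups

    @property
    def n_maps(self) -> int:
        """Feature maps after the temporal convolution (S*D)."""
        return self.spatial_filters * self.depth_multiplier

    @property
    def conv_len(self) -> int:
        """Temporal length after valid convolution."""
        return self.n_samples - self.temporal_kernel_len + 1

    @property
    def is_depthwise(self) -> bool:
        return self.effective_groups == self.spatial_filters


@dataclass
class ModelParams:
    """All learnable parameters plus batch-norm running statistics."""

    config: ModelConfig
    pointwise_w: np.ndarray              # (S, n_channels)
    pointwise_b: Optional[np.ndarray]    # (S,) or None
    depthwise_k: np.ndarray              # (n_maps, S//groups, L)
    depthwise_b: Optional[np.ndarray]    # (n_maps,) or None
    bn_gamma: np.ndarray                 # (n_maps,)
    bn_beta: np.ndarray
    bn_running_mean: np.ndarray
    bn_running_var: np.ndarray
    dense_w: np.ndarray                  # (n_classes, n_maps)
    dense_b: np.ndarray                  # (n_classes,)

    def __post_init__(self) -> None:
        c = self.config
        cg = c.spatial_filters // c.effective_groups
        expect = {
            "pointwise_w": (c.spatial_filters, c.n_channels),
            "depthwise_k": (c.n_maps, cg, c.temporal_kernel_len),
            "bn_gamma": (c.n_maps,), "bn_beta": (c.n_maps,),
            "bn_running_mean": (c.n_maps,), "bn_running_var": (c.n_maps,),
            "dense_w": (c.n_classes, c.n_maps), "dense_b": (c.n_classes,),
        }
        for name, shape in expect.items():
            arr = getattr(self, name)
            if arr.shape != shape:
                raise ValueError(f"{name} has shape {arr.shape}, expected {shape}")
        if np.any(self.bn_running_var < 0):
            raise ValueError("bn_running_var must be nonnegative")

    def trainable(self) -> Dict[str, np.ndarray]:
        out = {"pointwise_w": self.pointwise_w, "depthwise_k": self.depthwise_k,
               "bn_gamma": self.bn_gamma, "bn_beta": self.bn_beta,
               "dense_w": self.dense_w, "dense_b": self.dense_b}
        if self.pointwise_b is not None:
            out["pointwise_b"] = self.pointwise_b
        if self.depthwise_b is not None:
            out["depthwise_b"] = self.depthwise_b
        return out

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.config,
            self.pointwise_w.copy(),
            None if self.pointwise_b is None else self.pointwise_b.copy(),
            self.depthwise_k.copy(),
            None if self.depthwise_b is None else self.depthwise_b.copy(),
            self.bn_gamma.copy(), self.bn_beta.copy(),
            self.bn_running_mean.copy(), self.bn_running_var.copy(),
            self.dense_w.copy(), self.dense_b.copy(),
        )

    def is_finite(self) -> bool:
        return all(np.all(np.isfinite(a)) for a in self.trainable().values())


@dataclass
class Activations:
    """Intermediate signals of one forward pass (needed for relevance)."""

    demixed: np.ndarray    # (n, S, T)
    conv_out: np.ndarray   # (n, n_maps, T')
    relu_out: np.ndarray   # (n, n_maps, T')
    bn_out: np.ndarray     # (n, n_maps, T')
    pooled: np.ndarray     # (n, n_maps)
    log_probs: np.ndarray  # (n, n_classes)


def build_model(config: ModelConfig) -> ModelParams:
    """Allocate and initialize parameters (uniform fan-in, seed-controlled)."""
    if config.init_scheme != "uniform_fanin":
        raise ValueError(f"unknown init scheme {config.init_scheme!r}")
    rng = default_rng(config.init_seed)
    cg = config.spatial_filters // config.effective_groups

    def u(shape, fan_in):
        b = 1.0 / np.sqrt(fan_in)
        return rng.uniform(-b, b, size=shape)

    return ModelParams(
        config=config,
        pointwise_w=u((config.spatial_filters, config.n_channels), config.n_channels),
        pointwise_b=np.zeros(config.spatial_filters) if config.pointwise_bias else None,
        depthwise_k=u((config.n_maps, cg, config.temporal_kernel_len),
                      cg * config.temporal_kernel_len),
        depthwise_b=np.zeros(config.n_maps) if config.depthwise_bias else None,
        bn_gamma=np.ones(config.n_maps),
        bn_beta=np.zeros(config.n_maps),
        bn_running_mean=np.zeros(config.n_maps),
        bn_running_var=np.ones(config.n_maps),
        dense_w=u((config.n_classes, config.n_maps), config.n_maps),
        dense_b=np.zeros(config.n_classes),
    )


def layer_shapes(config: ModelConfig, batch="N") -> List[tuple]:
    """Output-shape trace of the seven layers for a batch of size ``batch``."""
    n = batch
    s, m, t, tp = (config.spatial_filters, config.n_maps,
                   config.n_samples, config.conv_len)
    k = config.n_classes
    return [
        (n, s, 1, t),    # pointwise conv (spatial demixing)
        (n, m, 1, tp),   # grouped/depthwise temporal conv
        (n, m, 1, tp),   # ReLU
        (n, m, 1, tp),   # batch norm
        (n, m),          # global average pool over time
        (n, k),          # dense read-out
        (n, k),          # softmax
    ]


def _grouped_conv(demixed: np.ndarray, kernels: np.ndarray, groups: int) -> np.ndarray:
    """Valid grouped temporal convolution (correlation), stride 1.

    demixed: (n, S, T); kernels: (M, S//groups, L) -> (n, M, T-L+1).
    FFT-based (kernel flipped so the operation is cross-correlation, the
    deep-learning convention).
    """
    n, s, t = demixed.shape
    m, cg, L = kernels.shape
    mg = m // groups
    out = np.empty((n, m, t - L + 1))
    kf = kernels[:, :, ::-1]
    for g in range(groups):
        dg = demixed[:, None, g * cg:(g + 1) * cg, :]        # (n, 1, cg, T)
        kg = kf[None, g * mg:(g + 1) * mg, :, :]             # (1, mg, cg, L)
        conv = fftconvolve(dg, kg, mode="valid", axes=3)     # (n, mg, cg, T')
        out[:, g * mg:(g + 1) * mg] = conv.sum(axis=2)
    return out


def _grouped_conv_backward(demixed: np.ndarray, kernels: np.ndarray,
                           d_out: np.ndarray, groups: int
                           ) -> Tuple[np.ndarray, np.ndarray]:
    """Gradients of the grouped valid convolution.

    Returns (d_kernels, d_demixed).
    """
    n, s, t = demixed.shape
    m, cg, L = kernels.shape
    mg = m // groups
    dk = np.empty_like(kernels)
    dx = np.zeros_like(demixed)
    for g in range(groups):
        dg = d_out[:, g * mg:(g + 1) * mg]               # (n, mg, T')
        xg = demixed[:, g * cg:(g + 1) * cg, :]          # (n, cg, T)
        # dK[m,c,l] = sum_{n,tau} d_out[n,m,tau] x[n,c,tau+l]: valid corr
        corr = fftconvolve(xg[:, None, :, :], dg[:, :, None, ::-1],
                           mode="valid", axes=3)         # (n, mg, cg, L)
        dk[g * mg:(g + 1) * mg] = corr.sum(axis=0)
        # d_demixed: full convolution of d_out with the (unflipped) kernel
        kg = kernels[g * mg:(g + 1) * mg]                # (mg, cg, L)
        conv = fftconvolve(dg[:, :, None, :], kg[None, :, :, :],
                           mode="full", axes=3)          # (n, mg, cg, T)
        dx[:, g * cg:(g + 1) * cg] = conv.sum(axis=1)
    return dk, dx


def forward(params: ModelParams, batch: np.ndarray, train_mode: bool = False,
            return_cache: bool = False):
    """Run the network on a (n, n_channels, n_samples) batch.

    Returns ``(log_probs, Activations)``; with ``return_cache=True`` a third
    element carries what backprop needs.  In ``train_mode`` batch-norm uses
    batch statistics and updates the running estimates in place; otherwise
    the running statistics are used and the call has no side effects.
    """
    c = params.config
    x = np.asarray(batch, dtype=float)
    if x.ndim == 2:
        x = x[None]
    if x.shape[1:] != (c.n_channels, c.n_samples):
        raise ValueError(
            f"batch shape {x.shape[1:]} does not match model "
            f"({c.n_channels}, {c.n_samples})")
    n = x.shape[0]

    demixed = np.matmul(params.pointwise_w, x)  # (n, S, T) via batched BLAS
    if params.pointwise_b is not None:
        demixed += params.pointwise_b[None, :, None]

    conv = _grouped_conv(demixed, params.depthwise_k, c.effective_groups)
    if params.depthwise_b is not None:
        conv += params.depthwise_b[None, :, None]

    relu = np.maximum(conv, 0.0)

    eps = c.batchnorm_eps
    if train_mode:
        mean = relu.mean(axis=(0, 2))
        var = relu.var(axis=(0, 2))
        mcount = n * relu.shape[2]
        mom = c.batchnorm_momentum
        params.bn_running_mean *= (1 - mom)
        params.bn_running_mean += mom * mean
        # running variance uses the unbiased estimator (torch convention)
        unbiased = var * mcount / max(mcount - 1, 1)
        params.bn_running_var *= (1 - mom)
        params.bn_running_var += mom * unbiased
    else:
        mean = params.bn_running_mean
        var = params.bn_running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (relu - mean[None, :, None]) * inv_std[None, :, None]
    bn = params.bn_gamma[None, :, None] * xhat + params.bn_beta[None, :, None]

    pooled = bn.mean(axis=2)
    logits = pooled @ params.dense_w.T + params.dense_b
    log_probs = logits - _logsumexp(logits)

    acts = Activations(demixed, conv, relu, bn, pooled, log_probs)
    if not return_cache:
        return log_probs, acts
    cache = {"x": x, "xhat": xhat, "inv_std": inv_std, "train_mode": train_mode}
    return log_probs, acts, cache


def _logsumexp(z: np.ndarray) -> np.ndarray:
    zmax = z.max(axis=1, keepdims=True)
    return zmax + np.log(np.exp(z - zmax).sum(axis=1, keepdims=True))


def backward(params: ModelParams, acts: Activations, cache: Dict,
             labels: np.ndarray) -> Dict[str, np.ndarray]:
    """Gradients of the mean NLL loss w.r.t. all trainable parameters."""
    c = params.config
    x = cache["x"]
    n = x.shape[0]
    probs = np.exp(acts.log_probs)
    d_logits = probs.copy()
    d_logits[np.arange(n), labels] -= 1.0
    d_logits /= n

    grads: Dict[str, np.ndarray] = {}
    grads["dense_w"] = d_logits.T @ acts.pooled
    grads["dense_b"] = d_logits.sum(axis=0)
    d_pooled = d_logits @ params.dense_w                   # (n, m)

    tp = acts.bn_out.shape[2]
    d_bn = d_pooled[:, :, None] / tp * np.ones((1, 1, tp))

    xhat, inv_std = cache["xhat"], cache["inv_std"]
    grads["bn_gamma"] = (d_bn * xhat).sum(axis=(0, 2))
    grads["bn_beta"] = d_bn.sum(axis=(0, 2))
    gamma = params.bn_gamma[None, :, None]
    if cache["train_mode"]:
        mcount = n * tp
        d_xhat = d_bn * gamma
        d_relu = (inv_std[None, :, None] / mcount) * (
            mcount * d_xhat
            - d_xhat.sum(axis=(0, 2), keepdims=True)
            - xhat * (d_xhat * xhat).sum(axis=(0, 2), keepdims=True))
    else:
        d_relu = d_bn * gamma * inv_std[None, :, None]

    d_conv = d_relu * (acts.conv_out > 0)
    if params.depthwise_b is not None:
        grads["depthwise_b"] = d_conv.sum(axis=(0, 2))
    dk, d_demixed = _grouped_conv_backward(
        acts.demixed, params.depthwise_k, d_conv, c.effective_groups)
    grads["depthwise_k"] = dk

    grads["pointwise_w"] = np.matmul(
        d_demixed, x.transpose(0, 2, 1)).sum(axis=0)
    if params.pointwise_b is not None:
        grads["pointwise_b"] = d_demixed.sum(axis=(0, 2))
    return grads


def predict_log_probs(params: ModelParams, batch: np.ndarray,
                      batch_size: int = 256) -> np.ndarray:
    """Evaluation-mode log class probabilities, batched for memory."""
    batch = np.asarray(batch, dtype=float)
    chunks = [forward(params, batch[i:i + batch_size])[0]
              for i in range(0, len(batch), batch_size)]
    return np.concatenate(chunks, axis=0)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(params: ModelParams, path) -> None:
    """Single-file archive: parameter arrays + the JSON-encoded config."""
    arrays = {k: v for k, v in params.trainable().items()}
    arrays["bn_running_mean"] = params.bn_running_mean
    arrays["bn_running_var"] = params.bn_running_var
    cfg = np.frombuffer(json.dumps(asdict(params.config)).encode(), dtype=np.uint8)
    np.savez(path, __config__=cfg, **arrays)


def load_checkpoint(path) -> ModelParams:
    with np.load(path) as z:
        cfg_dict = json.loads(bytes(z["__config__"].tobytes()).decode())
        config = ModelConfig(**cfg_dict)
        get = lambda k: z[k] if k in z.files else None
        return ModelParams(
            config=config,
            pointwise_w=z["pointwise_w"],
            pointwise_b=get("pointwise_b"),
            depthwise_k=z["depthwise_k"],
            depthwise_b=get("depthwise_b"),
            bn_gamma=z["bn_gamma"], bn_beta=z["bn_beta"],
            bn_running_mean=z["bn_running_mean"],
            bn_running_var=z["bn_running_var"],
            dense_w=z["dense_w"], dense_b=z["dense_b"],
        )
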