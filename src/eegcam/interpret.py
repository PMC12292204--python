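"""CAM-style relevance maps, band power, and scalp topographies.

The relevance reconstruction uses only quantities the architecture exposes:

1. temporal relevance per feature map = dense read-out weight of the target
   class x its (rectified, post-batch-norm) activation;
2. per-demixed-channel relevance = sum over that channel's D feature maps,
   linearly upsampled from the valid-convolution length back to n_samples;
3. channel x time relevance = redistribution of each demixed channel's
   relevance over input channels proportional to |pointwise weight|;
4. the map is rectified (negative evidence clipped) and normalized to sum 1.

Requires the depthwise configuration (one demixed channel per feature-map
group); with grouped mixing the map->channel attachment is ill-defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence

import numpy as np
from scipy.signal import periodogram

from .bands import BandDef, get_band
from .model import ModelParams, forward
from .montage import Montage
from .synth import Epoch, EpochSpec


@dataclass
class RelevanceMap:
    """Nonnegative channels x time importance mass summing to 1."""

    weights: np.ndarray
    predicted_class: int
    epoch: Epoch

    def __post_init__(self) -> None:
        if self.weights.shape != self.epoch.data.shape:
            raise ValueError("relevance dims must match the epoch")
        if np.any(self.weights < -1e-12):
            raise ValueError("relevance must be nonnegative")
        if abs(self.weights.sum() - 1.0) > 1e-6:
            raise ValueError("relevance must sum to 1")


@dataclass
class BandPowerTopography:
    band: BandDef
    values: np.ndarray  # per-channel power, uV^2
    montage: Montage

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("band powers must be nonnegative")


def compute_relevance(params: ModelParams, epoch: Epoch, target_class: int,
                      use_post_bn: bool = True) -> RelevanceMap:
    """Channel x time relevance of ``epoch`` toward ``target_class``.

    ``use_post_bn=False`` switches the activation source to the pre-batch-
    norm rectified feature maps.  If the map degenerates (no positive
    evidence, e.g. zero dense weights for the class), the documented
    fallback is the uniform map.
    """
    c = params.config
    if not c.is_depthwise:
        raise ValueError("relevance mapping requires the depthwise configuration")
    if not params.is_finite():
        raise ValueError("model parameters contain non-finite values")
    if not (0 <= target_class < c.n_classes):
        raise ValueError("target_class out of range")

    log_p, acts = forward(params, epoch.data)
    act = (acts.bn_out if use_post_bn else acts.relu_out)[0]  # (n_maps, T')
    fm_rel = params.dense_w[target_class][:, None] * act

    d = c.depth_multiplier
    chan_rel = fm_rel.reshape(c.spatial_filters, d, -1).sum(axis=1)  # (S, T')

    tp = chan_rel.shape[1]
    grid = np.linspace(0.0, tp - 1.0, c.n_samples)
    up = np.empty((c.spatial_filters, c.n_samples))
    for s in range(c.spatial_filters):
        up[s] = np.interp(grid, np.arange(tp), chan_rel[s])

    w_abs = np.abs(params.pointwise_w)                      # (S, C)
    row_sum = w_abs.sum(axis=1, keepdims=True)
    zero_rows = row_sum[:, 0] == 0
    row_sum[zero_rows] = 1.0
    w_norm = w_abs / row_sum
    w_norm[zero_rows] = 1.0 / c.n_channels

    rel = w_norm.T @ up                                     # (C, n_samples)
    rel = np.clip(rel, 0.0, None)
    total = rel.sum()
    if total <= 0 or not np.isfinite(total):
        rel = np.full_like(rel, 1.0 / rel.size)
    else:
        rel = rel / total
    return RelevanceMap(rel, int(log_p[0].argmax()), epoch)


def band_power(data: np.ndarray | Epoch, band: BandDef | str,
               spec: EpochSpec) -> np.ndarray:
    """Per-channel power (uV^2) in ``band`` via a single-taper periodogram.

    Boxcar window with constant detrending, so the per-band powers partition
    the signal variance (Parseval).  Band interval is [f_lo, f_hi).
    """
    if isinstance(band, str):
        band = get_band(band)
    if isinstance(data, Epoch):
        data = data.data
    if band.f_hi > spec.fs / 2 + 1e-9:
        raise ValueError(f"band {band.name!r} exceeds Nyquist ({spec.fs / 2} Hz)")
    freqs, psd = periodogram(data, fs=spec.fs, window="boxcar",
                             detrend="constant", axis=-1, scaling="density")
    df = freqs[1] - freqs[0]
    mask = (freqs >= band.f_lo) & (freqs < band.f_hi)
    return psd[..., mask].sum(axis=-1) * df


def band_power_topography(epoch: Epoch, band: BandDef | str, spec: EpochSpec,
                          montage: Montage) -> BandPowerTopography:
    if isinstance(band, str):
        band = get_band(band)
    return BandPowerTopography(band, band_power(epoch, band, spec), montage)


def idw_interpolate(values: np.ndarray, montage: Montage,
                    query_points: np.ndarray, power: float = 2.0,
                    eps: float = 1e-9) -> np.ndarray:
    """Inverse-distance-weighted interpolation; exact at electrode positions."""
    values = np.asarray(values, dtype=float)
    if values.shape != (len(montage),):
        raise ValueError("values length must equal montage size")
    q = np.atleast_2d(np.asarray(query_points, dtype=float))
    d = np.linalg.norm(q[:, None, :] - montage.positions[None, :, :], axis=2)
    out = np.empty(len(q))
    exact = d < eps
    has_exact = exact.any(axis=1)
    out[has_exact] = values[exact.argmax(axis=1)[has_exact]]
    rest = ~has_exact
    if rest.any():
        w = 1.0 / d[rest] ** power
        out[rest] = (w * values[None, :]).sum(axis=1) / w.sum(axis=1)
    return out


def topographic_grid(values: np.ndarray, montage: Montage,
                     resolution: int = 64, power: float = 2.0) -> np.ma.MaskedArray:
    """IDW interpolation of a per-channel quantity onto the unit disc.

    Returns a masked (resolution x resolution) grid, masked outside the disc;
    grid rows run from y=+1 (nose) down to y=-1.
    """
    if len(montage) < 3:
        raise ValueError("topographic interpolation needs >= 3 channels")
    xs = np.linspace(-1.0, 1.0, resolution)
    ys = np.linspace(1.0, -1.0, resolution)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = idw_interpolate(values, montage, pts, power=power)
    grid = vals.reshape(resolution, resolution)
    mask = gx ** 2 + gy ** 2 > 1.0
    return np.ma.masked_array(grid, mask=mask)


def localization_score(rmap: RelevanceMap, target_channels: Sequence[str],
                       montage: Montage) -> float:
    """Total relevance mass on the named channels (summed over time)."""
    if len(target_channels) == 0:
        raise ValueError("target channel set must be non-empty")
    idx = [montage.index(name) for name in target_channels]
    return float(rmap.weights[idx, :].sum())


def region_relevance_density(rmap_mean: np.ndarray, montage: Montage) -> Dict[str, float]:
    """Per-region relevance mass divided by region size (channel density).

    Used to name the dominant region of a (mean) relevance map without
    biasing toward large regions.
    """
    out = {}
    for region, idx in montage.region_indices().items():
        if idx.size:
            out[region] = float(rmap_mean[idx, :].sum() / idx.size)
    return out
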