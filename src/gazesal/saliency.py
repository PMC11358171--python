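"""Six-channel spatiotemporal saliency on gaze-centered patches.

Per frame, the patch is decomposed into luminance, red-green, yellow-blue
(cone-opponent space), orientation (Gabor bank), texture (LoG bank), and
optical-flow-magnitude channel maps. Each channel map is expanded into a
4-level Gaussian pyramid, passed through an iterated center-surround
activation (5 passes of LoG convolution, half-wave rectification, and
Gaussian blur), and normalized by a per-channel factor derived from the
summed response of its salient regions. Factors and final maps are
blended with the previous two frames' values through a 0.5-decay temporal
buffer; the six blended normalization factors are exported per frame as
the channel features used downstream. The final saliency map is the
channel-summed, level-averaged, temporally blended map squashed through a
logistic to [0, 1]; the saliency index is its mean over a gaze-centered
region (the full patch by default).

Cone responses come from a Hunt-Pointer-Estevez-style matrix applied to
linearized RGB: luminance = L + M, red-green = L - M, yellow-blue =
(L + M) - S.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from gazesal.flow import flow_magnitude
from gazesal.kernels import (
    convolve2d,
    convolve_stack,
    gabor_kernel,
    gaussian_blur,
    gaussian_kernel2d,
    log_kernel,
)
from gazesal.patches import PatchSequence

CHANNELS = ("luminance", "red_green", "yellow_blue", "orientation", "texture", "flow_mag")
N_CHANNELS = len(CHANNELS)

# Hunt-Pointer-Estevez cone fundamentals (D65-normalized), rows L, M, S,
# applied to linear RGB.
RGB_TO_LMS = np.array(
    [
        [0.31399022, 0.63951294, 0.04649755],
        [0.15537241, 0.75789446, 0.08670142],
        [0.01775239, 0.10944209, 0.87256922],
    ]
)


@dataclass(frozen=True)
class SaliencyConfig:
    """All filter and fusion parameters of the saliency model."""

    pyramid_levels: int = 4
    pyramid_blur_sigma: float = 1.0
    gabor_orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    gabor_wavelength_fracs: tuple[float, ...] = (1 / 6, 1 / 12)  # of patch side
    log_scale_fracs: tuple[float, ...] = (1 / 16, 1 / 8, 1 / 4)  # of patch side
    flow_sigma: float = 2.0
    activation_passes: int = 5
    activation_log_sigma: float = 1.2
    activation_blur_sigma: float = 1.0
    salient_quantile: float = 0.9
    decay: float = 0.5
    logistic_gain: float = 60.0
    logistic_midpoint: float = 0.02
    linearize_rgb: bool = True


DEFAULT_CONFIG = SaliencyConfig()


def config_to_yaml(config: SaliencyConfig, path) -> None:
    """Write all filter/fusion parameters to a YAML file."""
    import dataclasses

    import yaml

    data = {
        k: list(v) if isinstance(v, tuple) else v
        for k, v in dataclasses.asdict(config).items()
    }
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def config_from_yaml(path) -> SaliencyConfig:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh)
    for key in ("gabor_orientations", "gabor_wavelength_fracs", "log_scale_fracs"):
        if key in data:
            data[key] = tuple(data[key])
    return SaliencyConfig(**data)


@dataclass
class ChannelMaps:
    """Raw per-channel response maps for one patch."""

    luminance: np.ndarray
    red_green: np.ndarray
    yellow_blue: np.ndarray
    orientation: np.ndarray
    texture: np.ndarray
    flow_mag: np.ndarray

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in CHANNELS}


@dataclass
class TemporalBuffer:
    """Holds the previous two frames' per-frame factors and saliency maps.

    Histories store each frame's *own* (unblended) values, most recent
    first, capped at two entries. Blending weights for (current, t-1,
    t-2) are ``(1, decay, decay**2)`` normalized to sum to one over the
    entries present, so a transient event's contribution halves on each
    subsequent frame and vanishes once it leaves the buffer.
    """

    decay: float = 0.5
    factors_history: list[np.ndarray] = field(default_factory=list)
    map_history: list[np.ndarray] = field(default_factory=list)

    def blend_factors(self, raw: np.ndarray) -> np.ndarray:
        return self._blend(raw, self.factors_history)

    def blend_map(self, current: np.ndarray) -> np.ndarray:
        return self._blend(current, self.map_history)

    def _blend(self, current: np.ndarray, history: list[np.ndarray]) -> np.ndarray:
        total = np.array(current, dtype=float)
        weight = 1.0
        for k, past in enumerate(history):
            w = self.decay ** (k + 1)
            total = total + w * past
            weight += w
        return total / weight

    def push(self, factors: np.ndarray, final_map: np.ndarray) -> None:
        self.factors_history.insert(0, np.array(factors, dtype=float))
        self.map_history.insert(0, np.array(final_map, dtype=float))
        del self.factors_history[2:]
        del self.map_history[2:]


@dataclass
class SaliencyFrameFeatures:
    """Per-frame exported quantities."""

    norm_factors: np.ndarray  # (6,) blended normalization factors
    final_map: np.ndarray  # (w, w) in [0, 1]
    saliency_index: float
    zero_channels: tuple[str, ...] = ()  # channels whose factor was ~0


def _srgb_to_linear(rgb: np.ndarray) -> np.ndarray:
    low = rgb <= 0.04045
    return np.where(low, rgb / 12.92, ((rgb + 0.055) / 1.055) ** 2.4)


def rgb_to_cone_channels(patch_rgb: np.ndarray, linearize: bool = True):
    """(luminance, red_green, yellow_blue, grayscale) cone-opponent maps."""
    rgb = np.asarray(patch_rgb, dtype=float)
    if linearize:
        rgb = _srgb_to_linear(np.clip(rgb, 0.0, 1.0))
    lms = rgb @ RGB_TO_LMS.T
    lum = lms[..., 0] + lms[..., 1]
    rg = lms[..., 0] - lms[..., 1]
    yb = lum - lms[..., 2]
    white_lum = RGB_TO_LMS[0].sum() + RGB_TO_LMS[1].sum()
    gray = lum / white_lum
    return lum, rg, yb, gray


def decompose_channels(
    patch_rgb: np.ndarray,
    prev_patch_rgb: np.ndarray | None = None,
    config: SaliencyConfig = DEFAULT_CONFIG,
) -> ChannelMaps:
    """Extract the six raw channel maps from one RGB patch.

    ``prev_patch_rgb`` feeds the optical-flow channel; if absent (first
    frame) the flow map is zero.
    """
    patch_rgb = np.asarray(patch_rgb, dtype=float)
    if patch_rgb.ndim != 3 or patch_rgb.shape[2] != 3:
        raise ValueError(f"patch must be (h, w, 3), got {patch_rgb.shape}")
    if prev_patch_rgb is not None and prev_patch_rgb.shape != patch_rgb.shape:
        raise ValueError("previous patch shape differs from current patch")
    side = min(patch_rgb.shape[:2])
    lum, rg, yb, gray = rgb_to_cone_channels(patch_rgb, config.linearize_rgb)

    orientation = np.zeros_like(gray)
    for frac in config.gabor_wavelength_fracs:
        wavelength = max(frac * side, 2.0)
        for theta_deg in config.gabor_orientations:
            resp = convolve2d(gray, gabor_kernel(wavelength, np.deg2rad(theta_deg)))
            orientation = np.maximum(orientation, np.abs(resp))

    texture = np.zeros_like(gray)
    for frac in config.log_scale_fracs:
        sigma = max(frac * side, 0.5)
        texture = np.maximum(texture, np.abs(convolve2d(gray, log_kernel(sigma))))

    if prev_patch_rgb is None:
        flow = np.zeros_like(gray)
    else:
        _, _, _, prev_gray = rgb_to_cone_channels(prev_patch_rgb, config.linearize_rgb)
        flow = flow_magnitude(prev_gray, gray, sigma=config.flow_sigma)

    return ChannelMaps(
        luminance=lum,
        red_green=rg,
        yellow_blue=yb,
        orientation=orientation,
        texture=texture,
        flow_mag=flow,
    )


def build_pyramid(
    base_map: np.ndarray, levels: int = 4, blur_sigma: float = 1.0
) -> list[np.ndarray]:
    """Gaussian pyramid at relative scales 1, 1/2, 1/4, ... (ceil halving).

    Gaussian blur is applied before each decimation.
    """
    base_map = np.asarray(base_map, dtype=float)
    if min(base_map.shape) < 2 ** (levels - 1):
        raise ValueError(
            f"map of shape {base_map.shape} too small for a {levels}-level pyramid"
        )
    pyramid = [base_map]
    for _ in range(levels - 1):
        blurred = gaussian_blur(pyramid[-1], blur_sigma)
        pyramid.append(blurred[::2, ::2])
    return pyramid


def _bilinear_resize_stack(stack: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear resize of a (n, h, w) stack with edge clamping.

    Sample points follow the pixel-center convention
    ``src = (dst + 0.5) * (in / out) - 0.5``.
    """
    n, h, w = stack.shape
    H, W = out_shape
    r = np.clip((np.arange(H) + 0.5) * h / H - 0.5, 0, h - 1)
    c = np.clip((np.arange(W) + 0.5) * w / W - 0.5, 0, w - 1)
    r0 = np.floor(r).astype(int)
    c0 = np.floor(c).astype(int)
    r1 = np.minimum(r0 + 1, h - 1)
    c1 = np.minimum(c0 + 1, w - 1)
    fr = (r - r0)[None, :, None]
    fc = (c - c0)[None, None, :]
    top = stack[:, r0][:, :, c0] * (1 - fc) + stack[:, r0][:, :, c1] * fc
    bot = stack[:, r1][:, :, c0] * (1 - fc) + stack[:, r1][:, :, c1] * fc
    return top * (1 - fr) + bot * fr


def upsample_to(level: np.ndarray, out_shape: tuple[int, int]) -> np.ndarray:
    """Bilinear upsampling of a single 2-D map."""
    return _bilinear_resize_stack(level[None], out_shape)[0]


def center_surround_activate(
    stack: list[np.ndarray], config: SaliencyConfig = DEFAULT_CONFIG
) -> list[np.ndarray]:
    """Iterated center-surround: ``passes`` x (LoG conv -> rectify -> blur)."""
    log_k = log_kernel(config.activation_log_sigma)
    out = []
    for level in stack:
        m = np.asarray(level, dtype=float)
        for _ in range(config.activation_passes):
            m = convolve2d(m, log_k)
            m = np.maximum(m, 0.0)
            m = gaussian_blur(m, config.activation_blur_sigma)
        out.append(m)
    return out


def _raw_factor(stack: list[np.ndarray], quantile: float) -> float:
    """Summed response of salient regions (values at or above the map quantile)."""
    total = 0.0
    for level in stack:
        thresh = np.quantile(level, quantile)
        total += float(level[level >= thresh].sum())
    return total


ZERO_FACTOR_EPS = 1e-12


def normalize_stacks(
    stacks: dict[str, list[np.ndarray]],
    buffer: TemporalBuffer,
    config: SaliencyConfig = DEFAULT_CONFIG,
) -> tuple[dict[str, list[np.ndarray]], np.ndarray, np.ndarray, tuple[str, ...]]:
    """Scale each channel's stack by its temporally blended normalization factor.

    Returns the scaled stacks, the 6-vector of blended factors (exported
    as this frame's channel features), the 6-vector of raw per-frame
    factors (what enters the temporal buffer), and the names of channels
    whose factor was ~0 (scaled by 1 instead, i.e. left untouched).
    """
    levels = _levels_from_dict(stacks)
    scaled_levels, blended, raw, zero_channels = _normalize_levels(levels, buffer, config)
    return _dict_from_levels(scaled_levels), blended, raw, zero_channels


def _levels_from_dict(stacks: dict[str, list[np.ndarray]]) -> list[np.ndarray]:
    """dict-of-channel-lists -> level-major list of (6, h, w) arrays."""
    n_levels = len(stacks[CHANNELS[0]])
    return [np.stack([stacks[name][lv] for name in CHANNELS]) for lv in range(n_levels)]


def _dict_from_levels(levels: list[np.ndarray]) -> dict[str, list[np.ndarray]]:
    return {name: [lv[ci] for lv in levels] for ci, name in enumerate(CHANNELS)}


def _normalize_levels(
    levels: list[np.ndarray], buffer: TemporalBuffer, config: SaliencyConfig
) -> tuple[list[np.ndarray], np.ndarray, np.ndarray, tuple[str, ...]]:
    raw = np.zeros(N_CHANNELS)
    for arr in levels:
        thresh = np.quantile(arr, config.salient_quantile, axis=(1, 2))
        raw += np.where(arr >= thresh[:, None, None], arr, 0.0).sum(axis=(1, 2))
    blended = buffer.blend_factors(raw)
    zero_channels = tuple(name for name, f in zip(CHANNELS, blended) if f <= ZERO_FACTOR_EPS)
    scale = np.where(blended <= ZERO_FACTOR_EPS, 1.0, blended)
    scaled = [arr / scale[:, None, None] for arr in levels]
    return scaled, blended, raw, zero_channels


def _logistic(x: np.ndarray, gain: float, midpoint: float) -> np.ndarray:
    return expit(gain * (x - midpoint))


def fuse_saliency(
    stacks: dict[str, list[np.ndarray]],
    buffer: TemporalBuffer,
    config: SaliencyConfig = DEFAULT_CONFIG,
) -> tuple[np.ndarray, np.ndarray]:
    """Collapse normalized stacks into the final [0, 1] saliency map.

    Per channel the pyramid levels are upsampled to the base scale,
    summed, and divided by the stack size; channel maps are summed,
    blended with the buffer's decayed past per-frame maps, and squashed
    through the logistic. Returns ``(final_map, current_map)``; the
    current (pre-blend, pre-logistic) map is what enters the temporal
    buffer.
    """
    return _fuse_levels(_levels_from_dict(stacks), buffer, config)


def _fuse_levels(
    levels: list[np.ndarray], buffer: TemporalBuffer, config: SaliencyConfig
) -> tuple[np.ndarray, np.ndarray]:
    base_shape = levels[0].shape[1:]
    combined = np.zeros(base_shape)
    for arr in levels:
        if arr.shape[1:] != base_shape:
            arr = _bilinear_resize_stack(arr, base_shape)
        combined += arr.sum(axis=0)
    combined /= len(levels)
    blended = buffer.blend_map(combined)
    final = _logistic(blended, config.logistic_gain, config.logistic_midpoint)
    return final, combined


def saliency_index(final_map: np.ndarray, region: np.ndarray | tuple | None = None) -> float:
    """Mean saliency over ``region`` (a boolean mask or index tuple; default all)."""
    final_map = np.asarray(final_map, dtype=float)
    if region is None:
        values = final_map
    elif isinstance(region, np.ndarray) and region.dtype == bool:
        values = final_map[region]
    else:
        values = final_map[region]
    if np.size(values) == 0:
        raise ValueError("saliency index region is empty")
    return float(np.mean(values))


def _batched_stacks(
    channels: ChannelMaps, config: SaliencyConfig
) -> dict[str, list[np.ndarray]]:
    """Pyramid + activation as dict-of-channel-lists (testing convenience)."""
    return _dict_from_levels(_activated_levels(channels, config))


def _activated_levels(channels: ChannelMaps, config: SaliencyConfig) -> list[np.ndarray]:
    """Pyramid + activation with the six channels convolved as one stack.

    Numerically identical to composing `build_pyramid` and
    `center_surround_activate` per channel (the convolutions run on a
    (6, h, w) array with the same kernels and boundary handling).
    """
    base = np.stack([channels.as_dict()[name] for name in CHANNELS])
    if min(base.shape[1:]) < 2 ** (config.pyramid_levels - 1):
        raise ValueError(
            f"map of shape {base.shape[1:]} too small for a "
            f"{config.pyramid_levels}-level pyramid"
        )
    blur_k = gaussian_kernel2d(config.pyramid_blur_sigma)
    levels = [base]
    for _ in range(config.pyramid_levels - 1):
        blurred = convolve_stack(levels[-1], blur_k)
        levels.append(blurred[:, ::2, ::2])
    log_k = log_kernel(config.activation_log_sigma)
    act_blur_k = gaussian_kernel2d(config.activation_blur_sigma)
    activated = []
    for level in levels:
        m = level
        for _ in range(config.activation_passes):
            m = convolve_stack(m, log_k)
            m = np.maximum(m, 0.0)
            m = convolve_stack(m, act_blur_k)
        activated.append(m)
    return activated


def process_frame(
    patch_rgb: np.ndarray,
    prev_patch_rgb: np.ndarray | None,
    buffer: TemporalBuffer,
    config: SaliencyConfig = DEFAULT_CONFIG,
) -> SaliencyFrameFeatures:
    """One full saliency pass for a frame; updates the buffer in place."""
    channels = decompose_channels(patch_rgb, prev_patch_rgb, config)
    levels = _activated_levels(channels, config)
    levels, factors, raw_factors, zero_channels = _normalize_levels(levels, buffer, config)
    final_map, current_map = _fuse_levels(levels, buffer, config)
    buffer.push(raw_factors, current_map)
    return SaliencyFrameFeatures(
        norm_factors=factors,
        final_map=final_map,
        saliency_index=saliency_index(final_map),
        zero_channels=zero_channels,
    )


def run_saliency_sequence(
    seq: PatchSequence, config: SaliencyConfig = DEFAULT_CONFIG
) -> list[SaliencyFrameFeatures]:
    """Stateful pass over a patch sequence with a fresh temporal buffer.

    Invalid frames are processed as the zero patches they carry, matching
    the missing-gaze convention upstream.
    """
    if len(seq) == 0:
        raise ValueError("patch sequence is empty")
    buffer = TemporalBuffer(decay=config.decay)
    features = []
    prev: np.ndarray | None = None
    for t in range(len(seq)):
        patch = seq.patches[t]
        features.append(process_frame(patch, prev, buffer, config))
        prev = patch
    return features


def features_to_vector(features: list[SaliencyFrameFeatures]) -> np.ndarray:
    """Frame-major concatenation of the six exported factors (length 6*T)."""
    return np.concatenate([f.norm_factors for f in features])


def features_to_matrix(features: list[SaliencyFrameFeatures]) -> np.ndarray:
    """(T, 6) array of exported factors."""
    return np.stack([f.norm_factors for f in features])
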