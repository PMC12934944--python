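"""Motion-energy features: a quadrature spatiotemporal Gabor filter bank.

A low-level visual control model.  Each filter is a complex spatial Gabor
(a quadrature sine/cosine pair in its real and imaginary parts) combined
with a complex windowed temporal exponential; the filter's energy at a
frame is the squared modulus of the full spatiotemporal response, pooled
over pixels.  Signed temporal frequencies give direction selectivity:
a grating drifting in a filter's preferred direction excites it, the
time-reversed grating excites its opposite-sign partner.  Temporal kernels
with nonzero frequency are forced to zero mean, so static input yields
exactly zero motion energy.

Per-frame features across the whole stimulus set are reduced with PCA and
averaged over frames, yielding one motion-energy vector per video.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from sklearn.decomposition import PCA

from .features import RepresentationSet

__all__ = [
    "FrameStack",
    "MotionEnergyConfig",
    "FilterSpec",
    "build_filter_bank",
    "motion_energy",
    "pca_reduce_and_pool",
]


@dataclass(frozen=True)
class FrameStack:
    """An ordered stack of grayscale frames with a frame rate in Hz."""

    frames: np.ndarray  # (T, H, W); color (T, H, W, C) is averaged to gray
    frame_rate: float = 10.0

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.ndim == 4:  # color input: mean over channels
            frames = frames.mean(axis=3)
        if frames.ndim != 3:
            raise ValueError("frames must be (T, H, W) or (T, H, W, C)")
        if frames.shape[0] < 2:
            raise ValueError("a frame stack needs at least 2 frames")
        if self.frame_rate <= 0:
            raise ValueError("frame rate must be positive")
        object.__setattr__(self, "frames", frames)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass(frozen=True)
class MotionEnergyConfig:
    """Gabor-bank geometry and PCA retention settings.

    Spatial frequencies are in cycles per image width, temporal frequencies
    in Hz (each nonzero frequency is instantiated with both signs, i.e. both
    drift directions), orientations in degrees.  Retention is either a fixed
    component count or the smallest count reaching a variance target.
    """

    spatial_frequencies: tuple[float, ...] = (2.0, 4.0, 8.0)
    temporal_frequencies: tuple[float, ...] = (1.0, 2.0)
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    spatial_size: int = 15  # spatial kernel width, pixels
    temporal_window: int = 9  # temporal kernel length, frames
    include_static: bool = True  # zero-temporal-frequency channels
    n_components: int | None = 128
    variance_target: float | None = None
    log_transform: bool = False  # log(1 + energy) before PCA

    def __post_init__(self) -> None:
        if not self.spatial_frequencies or not self.orientations:
            raise ValueError("filter bank needs >= 1 filter")
        if any(f <= 0 for f in self.spatial_frequencies):
            raise ValueError("spatial frequencies must be positive")
        if any(f <= 0 for f in self.temporal_frequencies):
            raise ValueError(
                "temporal frequencies must be positive (signs are generated)"
            )
        if self.spatial_size < 3 or self.temporal_window < 2:
            raise ValueError("filter windows too small")
        if self.n_components is None and self.variance_target is None:
            raise ValueError("set n_components or variance_target")
        if self.n_components is not None and self.n_components < 1:
            raise ValueError("component count must be >= 1")
        if self.variance_target is not None and not (
            0.0 < self.variance_target <= 1.0
        ):
            raise ValueError("variance target must lie in (0, 1]")


@dataclass(frozen=True)
class FilterSpec:
    """One bank member: orientation (deg), cycles/image, signed Hz."""

    orientation: float
    spatial_frequency: float
    temporal_frequency: float  # signed; 0 = static channel


def _spatial_kernel(size: int, orientation_deg: float, cycles_per_image: float,
                    image_width: int) -> np.ndarray:
    half = (size - 1) / 2.0
    coords = np.arange(size) - half
    xx, yy = np.meshgrid(coords, coords, indexing="xy")
    theta = np.deg2rad(orientation_deg)
    u = xx * np.cos(theta) + yy * np.sin(theta)
    sigma = size / 6.0
    envelope = np.exp(-(xx**2 + yy**2) / (2.0 * sigma**2))
    f_px = cycles_per_image / image_width
    kernel = envelope * np.exp(2j * np.pi * f_px * u)
    kernel -= kernel.mean()  # DC-free: no response to uniform luminance
    return kernel / np.abs(kernel).sum()


def _temporal_kernel(window: int, hz: float, frame_rate: float) -> np.ndarray:
    t = np.arange(window) - (window - 1) / 2.0
    envelope = np.hanning(window + 2)[1:-1]
    kernel = envelope * np.exp(-2j * np.pi * (hz / frame_rate) * t)
    if hz != 0:
        kernel -= kernel.mean()  # exact null response to static input
    else:
        kernel = (envelope / envelope.sum()).astype(complex)
    return kernel


def build_filter_bank(cfg: MotionEnergyConfig) -> list[FilterSpec]:
    """Enumerate the bank in a fixed, documented order."""
    bank: list[FilterSpec] = []
    for sf in cfg.spatial_frequencies:
        for ori in cfg.orientations:
            for tf in cfg.temporal_frequencies:
                bank.append(FilterSpec(ori, sf, tf))
                bank.append(FilterSpec(ori, sf, -tf))
            if cfg.include_static:
                bank.append(FilterSpec(ori, sf, 0.0))
    return bank


def motion_energy(stack: FrameStack, cfg: MotionEnergyConfig) -> np.ndarray:
    """Per-frame motion energy for every filter in the bank.

    Returns a (n_frames - temporal_window + 1, n_filters) matrix: only
    frame positions with full temporal support are kept, so zero-mean
    temporal kernels respond exactly zero to static input.  Column order
    follows :func:`build_filter_bank`.
    """
    frames = stack.frames
    if stack.n_frames < cfg.temporal_window:
        raise ValueError(
            f"{stack.n_frames} frames shorter than the temporal window "
            f"({cfg.temporal_window})"
        )
    bank = build_filter_bank(cfg)
    width = frames.shape[2]
    spatial_cache: dict[tuple[float, float], np.ndarray] = {}
    n_out = stack.n_frames - cfg.temporal_window + 1
    out = np.empty((n_out, len(bank)))
    for col, spec in enumerate(bank):
        key = (spec.orientation, spec.spatial_frequency)
        if key not in spatial_cache:
            kern = _spatial_kernel(
                cfg.spatial_size, spec.orientation, spec.spatial_frequency, width
            )
            spatial_cache[key] = signal.fftconvolve(
                frames.astype(complex), kern[None, :, :], mode="same", axes=(1, 2)
            )
        spatial_resp = spatial_cache[key]
        t_kern = _temporal_kernel(
            cfg.temporal_window, spec.temporal_frequency, stack.frame_rate
        )
        resp = signal.fftconvolve(
            spatial_resp, t_kern[:, None, None], mode="valid", axes=0
        )
        out[:, col] = (np.abs(resp) ** 2).mean(axis=(1, 2))
    return out


def _retained_components(ratios: np.ndarray, cfg: MotionEnergyConfig) -> int:
    if cfg.n_components is not None:
        if cfg.n_components > len(ratios):
            raise ValueError(
                f"requested {cfg.n_components} components but only "
                f"{len(ratios)} are available"
            )
        return cfg.n_components
    cum = np.cumsum(ratios)
    # smallest k whose cumulative explained variance reaches the target
    reach = np.flatnonzero(cum >= cfg.variance_target - 1e-12)
    if reach.size == 0:
        raise ValueError(
            f"variance target {cfg.variance_target} unreachable "
            f"(max {cum[-1]:.6f})"
        )
    return int(reach[0]) + 1


def pca_reduce_and_pool(per_video: dict[str, np.ndarray],
                        cfg: MotionEnergyConfig) -> RepresentationSet:
    """PCA-reduce framewise features and average over frames per video.

    Components are fitted on the frames of *all* videos pooled together so
    that the reduced representations share one basis; each video's frame
    projections are then averaged into a single vector.
    """
    labels = tuple(per_video)
    mats = [np.asarray(per_video[l], dtype=float) for l in labels]
    widths = {m.shape[1] for m in mats}
    if len(widths) != 1:
        raise ValueError("per-video feature matrices have differing widths")
    stacked = np.vstack(mats)
    if cfg.log_transform:
        stacked = np.log1p(stacked)
        mats = [np.log1p(m) for m in mats]
    pca = PCA(n_components=min(stacked.shape), svd_solver="full")
    pca.fit(stacked)
    k = _retained_components(pca.explained_variance_ratio_, cfg)
    vectors = np.stack(
        [pca.transform(m)[:, :k].mean(axis=0) for m in mats]
    )
    return RepresentationSet(labels, vectors)
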