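"""Input front ends: compress rendered frame streams into the 100-dimensional
per-timestep vectors the RNNs consume.

Two encoder kinds are provided:

``pixel_pca``
    Incremental PCA fitted directly on flattened 100x100 frames, streamed in
    batches of trials.

``gabor_pca``
    An MT-like motion-energy front end — 3-D (space x space x time) Gabor
    quadrature pairs covering 8 directions x 2 spatiotemporal frequency
    pairs = 16 energy channels on a spatially down-sampled stream — followed
    by the same incremental PCA. The exact filter parameters of cortical-area
    MT models vary across the literature; this bank is a conventional
    energy-model approximation, not a calibrated fit to physiology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve
from sklearn.decomposition import IncrementalPCA

__all__ = [
    "FrameEncoder",
    "GaborBank",
    "gabor_mt_features",
    "fit_encoder",
]

N_INPUT = 100  # RNN input dimensionality after PCA


@dataclass
class GaborBank:
    """16-channel spatiotemporal Gabor energy bank.

    8 motion directions x 2 (spatial frequency, speed) pairs; each channel is
    a quadrature pair whose squared responses are summed, giving
    phase-invariant motion energy tuned to drift in the preferred direction.
    """

    n_directions: int = 8
    spatial_freqs: tuple[float, float] = (0.10, 0.20)   # cycles / pixel
    speeds: tuple[float, float] = (1.5, 0.75)           # pixels / frame
    size_xy: int = 9
    size_t: int = 5
    sigma_xy: float = 2.5
    sigma_t: float = 1.5
    kernels: list[tuple[np.ndarray, np.ndarray]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kernels:
            return
        half_xy = self.size_xy // 2
        half_t = self.size_t // 2
        ax = np.arange(-half_xy, half_xy + 1)
        at = np.arange(-half_t, half_t + 1)
        # kernel axes ordered (t, row, col); row increases downward in image
        # convention, so direction theta=0 means rightward drift
        tt, rr, cc = np.meshgrid(at, ax, ax, indexing="ij")
        env = np.exp(
            -(rr**2 + cc**2) / (2 * self.sigma_xy**2) - tt**2 / (2 * self.sigma_t**2)
        )
        for d in range(self.n_directions):
            theta = 2 * np.pi * d / self.n_directions
            ux, uy = np.cos(theta), -np.sin(theta)  # image rows grow downward
            for sf, sp in zip(self.spatial_freqs, self.speeds):
                # a grating drifting at velocity v in direction u has
                # temporal frequency ft = sf * v; energy filters matched to
                # that drift use phase sf*(u.x) - ft*t
                phase = 2 * np.pi * (sf * (ux * cc + uy * rr) - sf * sp * tt)
                even = env * np.cos(phase)
                odd = env * np.sin(phase)
                # remove the temporal DC at every spatial location so static
                # (non-moving) patterns produce (near-)zero motion energy
                even -= even.mean(axis=0, keepdims=True)
                odd -= odd.mean(axis=0, keepdims=True)
                self.kernels.append((even, odd))

    @property
    def n_channels(self) -> int:
        return len(self.kernels)


def _downsample(frames: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean spatial downsampling of a (T, H, W) stream."""
    t, h, w = frames.shape
    h2, w2 = h // factor, w // factor
    return (
        frames[:, : h2 * factor, : w2 * factor]
        .reshape(t, h2, factor, w2, factor)
        .mean(axis=(2, 4))
    )


def gabor_mt_features(
    frames: np.ndarray, bank: GaborBank | None = None, downsample: int = 2
) -> np.ndarray:
    """Motion-energy features, flattened per timestep.

    Returns (T, n_channels * H' * W') with H' = W' = n_pixels // downsample.
    Temporal convolution uses zero padding ("same"), so a trial must be at
    least one frame long; static or blank streams yield (near-)zero energy.
    """
    bank = bank or GaborBank()
    ds = _downsample(frames.astype(float), downsample)
    t, h, w = ds.shape
    out = np.empty((t, bank.n_channels, h, w))
    for k, (even, odd) in enumerate(bank.kernels):
        r_e = fftconvolve(ds, even, mode="same")
        r_o = fftconvolve(ds, odd, mode="same")
        out[:, k] = r_e**2 + r_o**2
    return out.reshape(t, -1)


@dataclass
class FrameEncoder:
    """PCA projection from frame (or Gabor-energy) space to N_INPUT dims."""

    kind: str = "pixel_pca"  # or "gabor_pca"
    n_components: int = N_INPUT
    batch_trials: int = 32
    subset_trials: int = 512
    downsample: int = 2
    bank: GaborBank | None = None
    _ipca: IncrementalPCA | None = None

    @property
    def fitted(self) -> bool:
        return self._ipca is not None and hasattr(self._ipca, "components_")

    @property
    def components(self) -> np.ndarray:
        self._require_fitted()
        return self._ipca.components_

    @property
    def mean(self) -> np.ndarray:
        self._require_fitted()
        return self._ipca.mean_

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        self._require_fitted()
        return self._ipca.explained_variance_ratio_

    def _require_fitted(self) -> None:
        if not self.fitted:
            raise RuntimeError("encoder is not fitted")

    def _features(self, frames: np.ndarray) -> np.ndarray:
        if self.kind == "pixel_pca":
            return frames.reshape(frames.shape[0], -1).astype(float)
        if self.kind == "gabor_pca":
            return gabor_mt_features(frames, self.bank, self.downsample)
        raise ValueError(f"unknown encoder kind {self.kind!r}")

    def fit(self, trials: list[np.ndarray], seed: int = 0) -> "FrameEncoder":
        """Fit incremental PCA on a stream of rendered trials.

        Trials are shuffled (seeded), truncated to ``subset_trials``, and fed
        to :class:`~sklearn.decomposition.IncrementalPCA` in batches of
        ``batch_trials`` whole trials (visible and occluded frames alike).
        """
        rng = np.random.default_rng(seed)
        order = rng.permutation(len(trials))[: self.subset_trials]
        n_frames = sum(trials[i].shape[0] for i in order)
        if n_frames < self.n_components:
            raise ValueError(
                f"{n_frames} frames < {self.n_components} components requested"
            )
        ipca = IncrementalPCA(n_components=self.n_components)
        buf: list[np.ndarray] = []
        n_batches = 0
        for j, i in enumerate(order):
            buf.append(self._features(trials[i]))
            if len(buf) == self.batch_trials or j == len(order) - 1:
                batch = np.concatenate(buf, axis=0)
                # a trailing batch smaller than n_components cannot be
                # partial-fitted; fold it into nothing rather than fail
                if batch.shape[0] >= self.n_components:
                    ipca.partial_fit(batch)
                    n_batches += 1
                buf = []
        if n_batches == 0:
            raise ValueError("not enough frames per batch to fit PCA")
        self._ipca = ipca
        return self

    def transform(self, frames: np.ndarray) -> np.ndarray:
        """Encode one trial: (T, H, W) frames -> (T, n_components)."""
        self._require_fitted()
        feats = self._features(frames)
        if feats.shape[1] != self.mean.shape[0]:
            raise ValueError(
                f"feature dim {feats.shape[1]} != fitted dim {self.mean.shape[0]}"
            )
        return (feats - self.mean) @ self.components.T


def fit_encoder(
    kind: str,
    trials: list[np.ndarray],
    n_components: int = N_INPUT,
    batch_trials: int = 32,
    subset_trials: int = 512,
    downsample: int = 2,
    seed: int = 0,
) -> FrameEncoder:
    """Convenience constructor + fit."""
    enc = FrameEncoder(
        kind=kind,
        n_components=n_components,
        batch_trials=batch_trials,
        subset_trials=subset_trials,
        downsample=downsample,
    )
    return enc.fit(trials, seed=seed)
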