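"""Spike-train similarity measures.

Binary spike trains are smoothed with a symmetric Gaussian kernel into
*activity signals*, and distances are integrated squared differences of
those signals — a van Rossum-style metric with a Gaussian window so that
temporal tolerance extends both before and after each spike:

* the pairwise distance ``D_P`` compares rasters neuron by neuron and sums
  the per-neuron integrals;
* the aggregate distance ``D_A`` first sums activity over neurons and
  compares the two network-level signals.

Inter-spike-interval (ISI) distributions are compared as l2 distances
between fixed-bin histograms of the pooled per-neuron intervals.  All
integrals are unit-weight sums over timesteps, so distances are reported
in natural timestep units.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.signal import fftconvolve

from .models import WeightMatrix

__all__ = [
    "KernelSpec",
    "activity_signal",
    "network_activity_signal",
    "pairwise_distance",
    "aggregate_distance",
    "isi_observations",
    "isi_l2",
    "spike_count_stats",
    "weight_error",
]

#: Default kernel width in timesteps: 5*sqrt(2) steps, ~21 ms at a 3 ms step.
DEFAULT_SIGMA = 5.0 * math.sqrt(2.0)


@dataclasses.dataclass(frozen=True)
class KernelSpec:
    """Truncated symmetric Gaussian smoothing kernel.

    ``sigma`` is the Gaussian width in timesteps; the kernel is evaluated on
    integer offsets in ``[-radius, radius]`` (default ``ceil(5 sigma)``) and
    is *not* normalized: a lone spike contributes a unit-height Gaussian
    bump to the activity signal.
    """

    sigma: float = DEFAULT_SIGMA
    radius: int | None = None

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.radius is not None and self.radius < 4 * self.sigma:
            raise ValueError("kernel support radius must be at least 4 sigma")

    @property
    def effective_radius(self) -> int:
        return self.radius if self.radius is not None else math.ceil(5.0 * self.sigma)

    def taps(self) -> np.ndarray:
        """Kernel values on integer offsets ``-radius..radius`` (odd length)."""
        t = np.arange(-self.effective_radius, self.effective_radius + 1, dtype=float)
        return np.exp(-0.5 * (t / self.sigma) ** 2)


def _smooth_columns(x: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Convolve each column of ``x`` with the kernel, zero-padded, same length."""
    taps = kernel.taps()
    if x.ndim == 1:
        return fftconvolve(x, taps, mode="same")
    return fftconvolve(x, taps[:, None], mode="same", axes=0)


def activity_signal(train: np.ndarray, kernel: KernelSpec | None = None) -> np.ndarray:
    """Gaussian-smoothed activity signal of one binary spike train.

    Returns a length-``T`` nonnegative vector; a single spike at ``t0``
    yields ``exp(-(t - t0)^2 / (2 sigma^2))`` within the kernel support.
    """
    kernel = kernel or KernelSpec()
    train = np.asarray(train, dtype=float)
    if train.ndim != 1:
        raise ValueError("activity_signal expects a single 1-D spike train")
    return _smooth_columns(train, kernel)


def network_activity_signal(spikes: np.ndarray, kernel: KernelSpec | None = None) -> np.ndarray:
    """Network-summed activity signal ``A(S, t)`` of a ``(T, N)`` raster."""
    kernel = kernel or KernelSpec()
    spikes = np.asarray(spikes, dtype=float)
    if spikes.ndim != 2:
        raise ValueError("expected a (T, N) raster")
    return _smooth_columns(spikes.sum(axis=1), kernel)


def _check_same_shape(s: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(s, dtype=float)
    r = np.asarray(r, dtype=float)
    if s.ndim != 2 or r.ndim != 2:
        raise ValueError("rasters must be 2-D (T, N) arrays")
    if s.shape != r.shape:
        raise ValueError(f"raster shapes differ: {s.shape} vs {r.shape}")
    return s, r


def pairwise_distance(s: np.ndarray, r: np.ndarray, kernel: KernelSpec | None = None) -> float:
    """Neuron-by-neuron integrated squared activity difference ``D_P(S, R)``.

    Smoothing is linear, so the per-neuron signal difference equals the
    smoothed raster difference; one convolution of ``S - R`` suffices.
    """
    kernel = kernel or KernelSpec()
    s, r = _check_same_shape(s, r)
    diff = _smooth_columns(s - r, kernel)
    return float(np.sum(diff * diff))


def aggregate_distance(s: np.ndarray, r: np.ndarray, kernel: KernelSpec | None = None) -> float:
    """Integrated squared difference of network-summed signals ``D_A(S, R)``.

    Invariant under any relabeling of neurons within either raster.
    """
    kernel = kernel or KernelSpec()
    s, r = _check_same_shape(s, r)
    diff = _smooth_columns(s.sum(axis=1) - r.sum(axis=1), kernel)
    return float(np.sum(diff * diff))


def isi_observations(spikes: np.ndarray) -> np.ndarray:
    """Pooled inter-spike intervals of a raster, in timesteps.

    Intervals are differences of consecutive spike times within each neuron;
    neurons with fewer than two spikes contribute nothing.  Per-neuron
    observations are concatenated into one network-wide sample.
    """
    spikes = np.asarray(spikes)
    if spikes.ndim != 2:
        raise ValueError("expected a (T, N) raster")
    out = [np.diff(np.flatnonzero(spikes[:, i])) for i in range(spikes.shape[1])]
    return np.concatenate(out) if out else np.empty(0, dtype=int)


def isi_l2(
    s: np.ndarray, r: np.ndarray, bin_width: int = 3
) -> float:
    """l2 distance between fixed-bin ISI histograms of two rasters.

    Both interval samples are binned on shared edges of width ``bin_width``
    timesteps spanning the pooled range; the distance is the Euclidean norm
    of the count-vector difference (zero when either both rasters produce
    identical interval multisets or neither produces any interval).
    """
    if bin_width < 1:
        raise ValueError("bin_width must be a positive number of timesteps")
    isi_s = isi_observations(s)
    isi_r = isi_observations(r)
    if isi_s.size == 0 and isi_r.size == 0:
        return 0.0
    pooled = np.concatenate([isi_s, isi_r])
    lo = int(pooled.min())
    hi = int(pooled.max())
    edges = np.arange(lo, hi + bin_width + 1, bin_width, dtype=float)
    h_s, _ = np.histogram(isi_s, bins=edges)
    h_r, _ = np.histogram(isi_r, bins=edges)
    return float(np.linalg.norm(h_s - h_r))


def spike_count_stats(spikes: np.ndarray) -> tuple[float, float]:
    """Mean and population variance of per-neuron spike counts."""
    spikes = np.asarray(spikes)
    if spikes.ndim != 2:
        raise ValueError("expected a (T, N) raster")
    counts = spikes.sum(axis=0).astype(float)
    return float(counts.mean()), float(counts.var())


def weight_error(w_a: WeightMatrix | np.ndarray, w_b: WeightMatrix | np.ndarray) -> float:
    """Component-wise sum of squared weight differences (squared Frobenius norm)."""
    a = w_a.w if isinstance(w_a, WeightMatrix) else np.asarray(w_a, dtype=float)
    b = w_b.w if isinstance(w_b, WeightMatrix) else np.asarray(w_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"weight shapes differ: {a.shape} vs {b.shape}")
    d = a - b
    return float(np.sum(d * d))
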