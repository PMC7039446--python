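"""Integrate-and-fire network models and their initial conditions.

Two model classes are simulated:

* a deterministic leaky integrate-and-fire (LIF) network, integrated with
  forward Euler, whose synaptic weights carry units of volts and whose
  external drive is a current in amperes; and
* a probabilistic integrate-and-fire (PIF) network, a discrete-time branching
  process in which every quantity is dimensionless and each neuron fires with
  probability equal to its summed weighted input plus external drive.

Rasters are plain ``(T, N)`` uint8 arrays (``S[t, i] = 1`` iff neuron ``i``
spiked at step ``t``); voltage traces are ``(T, N)`` float arrays in mV.
Weight matrices follow the convention ``W[i, j]`` = strength of the synapse
from presynaptic neuron ``j`` onto postsynaptic neuron ``i``.

Sign structure: each neuron is globally excitatory or inhibitory — every
outgoing weight of an inhibitory neuron is <= 0 and every outgoing weight of
an excitatory neuron is >= 0. Self-connections are fixed at zero.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

__all__ = [
    "LIFParams",
    "WeightMatrix",
    "simulate_lif",
    "simulate_pif",
    "build_pif_network",
    "normalize_spectral_radius",
    "init_weights",
    "draw_sign_mask",
    "generate_lif_inputs",
    "generate_pif_inputs",
    "WEIGHT_CONFIGS",
]

#: Named initial-weight configurations: (reference magnitude law, naive
#: magnitude law).  Magnitudes are in volts.
WEIGHT_CONFIGS = ("uniform", "gaussian", "sparse", "naive-half-max")

# Table-of-record values for the weight magnitude distributions (volts).
_UNIFORM_HIGH = 5e-3
_GAUSS_MU = 0.4e-3
_GAUSS_SIGMA = 0.4e-3
_HALF_MAX_HIGH = 2.5e-3
_SPARSE_ZERO_FRACTION = 0.5


def _as_rng(rng: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


@dataclasses.dataclass(frozen=True)
class LIFParams:
    """Single-neuron and integration parameters for the LIF network.

    Defaults are typical values for biological neurons: membrane time
    constant 30 ms, membrane resistance 100 MOhm, threshold 30 mV, Euler
    step 3 ms, and 20% of neurons inhibitory.
    """

    tau_m: float = 30.0  # membrane time constant, ms
    r_m: float = 100.0  # membrane resistance, MOhm
    v_th: float = 30.0  # spike threshold, mV
    dt: float = 3.0  # Euler step, ms
    n: int = 400  # neuron count
    inhib_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.r_m <= 0 or self.v_th <= 0 or self.dt <= 0:
            raise ValueError("tau_m, r_m, v_th and dt must all be positive")
        if self.n < 1:
            raise ValueError("need at least one neuron")
        if not 0.0 <= self.inhib_fraction < 1.0:
            raise ValueError("inhib_fraction must lie in [0, 1)")


@dataclasses.dataclass
class WeightMatrix:
    """Signed synaptic weight matrix with per-neuron sign labels.

    ``w[i, j]`` (volts) is the synapse from ``j`` to ``i``; ``inhibitory[j]``
    labels presynaptic neuron ``j``.  The diagonal is identically zero
    (no autapses).
    """

    w: np.ndarray
    inhibitory: np.ndarray

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        self.inhibitory = np.asarray(self.inhibitory, dtype=bool)
        self.validate()

    @property
    def n(self) -> int:
        return self.w.shape[0]

    def copy(self) -> "WeightMatrix":
        return WeightMatrix(self.w.copy(), self.inhibitory.copy())

    def validate(self) -> None:
        if self.w.ndim != 2 or self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")
        if self.inhibitory.shape != (self.w.shape[0],):
            raise ValueError("sign mask length must equal neuron count")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")
        if np.any(np.diagonal(self.w) != 0.0):
            raise ValueError("self-connections must be zero")
        if np.any(self.w[:, self.inhibitory] > 0.0):
            raise ValueError("inhibitory neurons must have non-positive outgoing weights")
        if np.any(self.w[:, ~self.inhibitory] < 0.0):
            raise ValueError("excitatory neurons must have non-negative outgoing weights")


def _check_currents(currents: np.ndarray, n: int) -> np.ndarray:
    currents = np.asarray(currents, dtype=float)
    if currents.ndim != 2 or currents.shape[1] != n:
        raise ValueError(
            f"input currents must be (T, {n}); got shape {currents.shape}"
        )
    if currents.shape[0] < 1:
        raise ValueError("need at least one time step of input")
    if not np.all(np.isfinite(currents)):
        raise ValueError("input currents must be finite")
    return currents


def simulate_lif(
    weights: WeightMatrix,
    currents: np.ndarray,
    params: LIFParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate the LIF network with forward Euler.

    Subthreshold dynamics per step: ``V <- V + (dt/tau)(-V + R_m I + sum_j
    W_ij s_j)``, where the synaptic sum uses the spikes of the *previous*
    step (one-step synaptic delay, which makes the update order-independent).
    A neuron whose updated potential reaches ``v_th`` emits a spike and is
    reset to 0 mV before being recorded; membrane potentials start at 0 mV.
    There is no refractory period.

    Parameters
    ----------
    weights:
        Synaptic weights in volts.
    currents:
        ``(T, N)`` external input currents in amperes.
    params:
        Neuron parameters; defaults to :class:`LIFParams`.

    Returns
    -------
    (spikes, voltages):
        ``(T, N)`` uint8 raster and ``(T, N)`` float voltage traces in mV
        (recorded after reset, hence always below threshold).
    """
    params = params or LIFParams(n=weights.n)
    weights.validate()
    if weights.n != params.n:
        raise ValueError("weight matrix size does not match params.n")
    currents = _check_currents(currents, weights.n)

    t_steps, n = currents.shape
    alpha = params.dt / params.tau_m
    # R_m [MOhm] * I [A] -> volts * 1e6; convert to mV.
    drive_mv = params.r_m * currents * 1e9
    w_mv = weights.w * 1e3

    spikes = np.zeros((t_steps, n), dtype=np.uint8)
    voltages = np.empty((t_steps, n), dtype=float)
    v = np.zeros(n)
    s_prev = np.zeros(n)
    for t in range(t_steps):
        v = v + alpha * (-v + drive_mv[t] + w_mv @ s_prev)
        fired = v >= params.v_th
        v[fired] = 0.0
        spikes[t] = fired
        voltages[t] = v
        s_prev = fired.astype(float)
    return spikes, voltages


def simulate_pif(
    weights: WeightMatrix | np.ndarray,
    inputs: np.ndarray,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate the probabilistic integrate-and-fire network.

    Each neuron fires at step ``t`` iff ``sum_j W_ij s_j(t-1) + I_i(t-1) >=
    xi``, with ``xi ~ Uniform[0, 1)`` drawn independently per neuron and
    step; equivalently it fires with probability ``min(1, W s + I)`` for
    nonnegative arguments.  The state at step 0 is all-quiescent.  Weights
    must be nonnegative (the PIF is purely excitatory).
    """
    w = weights.w if isinstance(weights, WeightMatrix) else np.asarray(weights, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("PIF weights must be nonnegative")
    inputs = _check_currents(inputs, w.shape[0])
    gen = _as_rng(rng)

    t_steps, n = inputs.shape
    spikes = np.zeros((t_steps, n), dtype=np.uint8)
    s_prev = np.zeros(n)
    for t in range(1, t_steps):
        p = w @ s_prev + inputs[t - 1]
        xi = gen.random(n)
        fired = p - xi >= 0.0
        spikes[t] = fired
        s_prev = fired.astype(float)
    return spikes


def normalize_spectral_radius(w: np.ndarray) -> np.ndarray:
    """Divide a matrix by its largest-magnitude eigenvalue.

    The returned matrix has spectral radius exactly 1 — the critical
    branching point for the PIF dynamics.  Raises on a nilpotent/zero
    matrix, whose spectral radius cannot be scaled.
    """
    w = np.asarray(w, dtype=float)
    lam = float(np.max(np.abs(np.linalg.eigvals(w))))
    if lam <= 0.0:
        raise ValueError("matrix has zero spectral radius; cannot normalize")
    return w / lam


def build_pif_network(
    n: int = 400,
    p: float = 0.1,
    w_range: tuple[float, float] = (0.0, 0.02),
    rng: int | np.random.Generator | None = None,
    max_resample: int = 100,
) -> WeightMatrix:
    """Random sparse excitatory PIF weight matrix, tuned to criticality.

    Each off-diagonal synapse exists with probability ``p`` and draws its
    strength from ``Uniform(w_range)``; the matrix is then rescaled by
    :func:`normalize_spectral_radius` so its spectral radius is exactly 1.
    An all-zero draw (possible at tiny ``n p``) is resampled.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("connection probability must lie in (0, 1]")
    lo, hi = w_range
    if lo < 0 or hi < lo:
        raise ValueError("w_range must be a nonnegative interval")
    gen = _as_rng(rng)
    for _ in range(max_resample):
        mask = gen.random((n, n)) < p
        np.fill_diagonal(mask, False)
        w = np.where(mask, gen.uniform(lo, hi, (n, n)), 0.0)
        try:
            return WeightMatrix(normalize_spectral_radius(w), np.zeros(n, dtype=bool))
        except ValueError:
            continue
    raise RuntimeError("could not draw a weight matrix with nonzero spectral radius")


def _draw_magnitudes(
    config: str, role: str, n: int, gen: np.random.Generator
) -> np.ndarray:
    if config in ("uniform", "sparse"):
        return gen.uniform(0.0, _UNIFORM_HIGH, (n, n))
    if config == "gaussian":
        # Redraw negative samples so magnitudes follow a proper truncated
        # Gaussian rather than piling mass at zero.
        mags = gen.normal(_GAUSS_MU, _GAUSS_SIGMA, (n, n))
        while True:
            bad = mags < 0
            k = int(bad.sum())
            if k == 0:
                return mags
            mags[bad] = gen.normal(_GAUSS_MU, _GAUSS_SIGMA, k)
    if config == "naive-half-max":
        high = _HALF_MAX_HIGH if role == "naive" else _UNIFORM_HIGH
        return gen.uniform(0.0, high, (n, n))
    raise ValueError(f"unknown weight configuration {config!r}")


def draw_sign_mask(
    n: int, inhib_fraction: float, rng: int | np.random.Generator | None = None
) -> np.ndarray:
    """Randomly assign ``round(inhib_fraction * n)`` neurons as inhibitory."""
    gen = _as_rng(rng)
    k = int(round(inhib_fraction * n))
    mask = np.zeros(n, dtype=bool)
    mask[gen.choice(n, size=k, replace=False)] = True
    return mask


def init_weights(
    config: str,
    role: str,
    n: int = 400,
    inhib_fraction: float = 0.2,
    rng: int | np.random.Generator | None = None,
    inhibitory: np.ndarray | Sequence[bool] | None = None,
) -> WeightMatrix:
    """Draw an initial weight matrix from one of the named configurations.

    ``config`` selects the magnitude law (volts): ``uniform`` U[0, 5 mV] for
    both roles; ``gaussian`` |N(0.4 mV, 0.4 mV)| (negative draws redrawn);
    ``sparse`` U[0, 5 mV] with exactly ``floor(0.5 N^2)`` off-diagonal
    entries of the *naive* matrix zeroed; ``naive-half-max`` U[0, 5 mV]
    reference vs U[0, 2.5 mV] naive.  ``role`` is ``"reference"`` or
    ``"naive"``.  Signs are applied per presynaptic neuron; pass
    ``inhibitory`` to share one sign assignment across the networks of a
    trial (drawn here otherwise).
    """
    if role not in ("reference", "naive"):
        raise ValueError("role must be 'reference' or 'naive'")
    gen = _as_rng(rng)
    if inhibitory is None:
        inhibitory = draw_sign_mask(n, inhib_fraction, gen)
    inhibitory = np.asarray(inhibitory, dtype=bool)

    mags = _draw_magnitudes(config, role, n, gen)
    if config == "sparse" and role == "naive":
        k = math.floor(_SPARSE_ZERO_FRACTION * n * n)
        off_diag = np.flatnonzero(~np.eye(n, dtype=bool).ravel())
        if k > off_diag.size:
            raise ValueError("network too small to zero half of all synapses")
        drop = gen.choice(off_diag, size=k, replace=False)
        mags.ravel()[drop] = 0.0

    w = np.where(inhibitory[None, :], -mags, mags)
    np.fill_diagonal(w, 0.0)
    return WeightMatrix(w, inhibitory)


def generate_lif_inputs(
    t_steps: int,
    n: int,
    mu: float = 2.5e-10,
    sigma: float = 1e-10,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """I.i.d. Gaussian external currents (amperes), ``(T, N)``.

    The default N(2.5e-10 A, 1e-10 A) is tuned so a zero-weight network
    fires at 0 < f <= 1 Hz while synaptic currents dominate once weights
    are nonzero.
    """
    if t_steps < 1 or n < 1:
        raise ValueError("t_steps and n must be >= 1")
    return _as_rng(rng).normal(mu, sigma, (t_steps, n))


def generate_pif_inputs(
    t_steps: int,
    n: int,
    scale: float = 1e-3,
    rng: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Scaled Poisson(1) external drive for the PIF (dimensionless)."""
    if t_steps < 1 or n < 1:
        raise ValueError("t_steps and n must be >= 1")
    if scale < 0:
        raise ValueError("scale must be nonnegative")
    return scale * _as_rng(rng).poisson(1.0, (t_steps, n)).astype(float)
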