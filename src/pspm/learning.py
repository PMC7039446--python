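"""Pre-Synaptic Pool Modification (PSPM) training loop.

PSPM tunes the weights of a recurrent LIF network so its output raster
reproduces a set of reference spike trains.  Each epoch:

1. simulate the network to get observed trains O;
2. optimally pair each neuron's observed spikes with its reference spikes
   (:mod:`pspm.matching`);
3. for every unpaired reference spike (a *missing* spike), stochastically
   strengthen the incoming synapses from every presynaptic neuron that
   spiked within ``z`` steps before the desired time; for every unpaired
   observed spike (an *extra* spike), weaken them — purely local updates
   driven by the recent causal history of the spike;
4. apply a network-wide homeostatic update: every synapse receives an
   additive draw from ``Uniform[0, (x - y) * homeo_scale]`` where ``x`` and
   ``y`` are the total reference and observed spike counts (the interval is
   negative, hence depressing, when the network overshoots);
5. mirror every local update into a *control* network at an independently
   chosen random synapse, and give the control the same homeostatic
   treatment — the control isolates what update *placement* contributes
   beyond update count and magnitude.

Weights never change sign: an excitatory weight pushed below zero (or an
inhibitory weight above zero) is clipped to exactly 0.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .matching import match_spike_trains
from .metrics import KernelSpec, aggregate_distance, pairwise_distance
from .models import LIFParams, WeightMatrix, simulate_lif

__all__ = [
    "LearningConfig",
    "EpochRecord",
    "TrialResult",
    "local_updates",
    "homeostatic_update",
    "control_mirror",
    "run_pspm",
]


@dataclasses.dataclass(frozen=True)
class LearningConfig:
    """Hyper-parameters of the PSPM rule.

    ``a_cap`` — unpaired-spike penalty of the matcher (timesteps).
    ``z`` — causal window looking back from an unpaired spike (timesteps).
    ``delta_max`` — upper bound of the local update magnitude draw (volts).
    ``homeo_scale`` — homeostatic volts per unit spike-count mismatch.
    ``epochs`` — number of simulate/match/update rounds.

    The default update magnitudes are calibrated to the synaptic weight
    scale: with weights of a few millivolts and a ~0.1 step-to-membrane
    coupling, cumulative pool updates recurring over ~10^2 epochs must
    reach the millivolt voltage-margin scale to induce or eliminate a
    spike, which puts the per-draw cap near 1e-4 V and the homeostatic
    unit (which is additionally multiplied by a spike-count mismatch of
    order 10^2-10^3) near 1e-8 V.  The two defaults keep a fixed ratio of
    1e4 between local and homeostatic scales.
    """

    a_cap: float = 15.0
    z: int = 10
    delta_max: float = 1e-4
    homeo_scale: float = 1e-8
    epochs: int = 150
    rng_seed: int | None = None
    strict_pairing: bool = False

    def __post_init__(self) -> None:
        if self.a_cap <= 0 or self.z <= 0 or self.delta_max <= 0 or self.homeo_scale <= 0:
            raise ValueError("a_cap, z, delta_max and homeo_scale must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be nonnegative")


@dataclasses.dataclass(frozen=True)
class EpochRecord:
    """Per-epoch training diagnostics."""

    epoch: int
    missing: int  # unpaired reference spikes (to induce)
    extra: int  # unpaired observed spikes (to eliminate)
    x: int  # total reference spike count
    y: int  # total observed spike count
    n_local_updates: int
    sum_abs_delta: float
    d_p: float
    d_a: float


@dataclasses.dataclass
class TrialResult:
    """Outcome of one PSPM trial: optimized and control networks plus history."""

    w_optimized: WeightMatrix
    w_control: WeightMatrix
    raster_optimized: np.ndarray
    raster_control: np.ndarray
    history: list[EpochRecord]


def _clip_signs(w: WeightMatrix, rows, cols) -> None:
    """Clip sign-crossing entries at ``w.w[rows, cols]`` to exactly 0."""
    vals = w.w[rows, cols]
    inh = w.inhibitory[cols]
    w.w[rows, cols] = np.where(inh, np.minimum(vals, 0.0), np.maximum(vals, 0.0))


def _presynaptic_pool(
    obs: np.ndarray, neuron: int, t: int, z: int
) -> np.ndarray:
    """Neurons (other than ``neuron``) with a spike in the window ``[t-z, t]``."""
    lo = max(0, t - z)
    pool = np.flatnonzero(obs[lo : t + 1].any(axis=0))
    return pool[pool != neuron]


def _apply_local(
    w: WeightMatrix,
    obs: np.ndarray,
    neuron: int,
    t: int,
    sign: int,
    cfg: LearningConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    pool = _presynaptic_pool(obs, neuron, t, cfg.z)
    if pool.size == 0:
        return pool, np.empty(0)
    deltas = sign * rng.uniform(0.0, cfg.delta_max, pool.size)
    w.w[neuron, pool] += deltas
    _clip_signs(w, neuron, pool)
    return pool, deltas


def local_updates(
    w: WeightMatrix,
    obs_trains: np.ndarray,
    neuron: int,
    unpaired_time: int,
    direction: str,
    cfg: LearningConfig,
    rng: int | np.random.Generator | None = None,
) -> tuple[WeightMatrix, list[tuple[int, int, float]]]:
    """Stochastic update of ``neuron``'s presynaptic pool for one unpaired spike.

    ``direction`` is ``"induce"`` for a missing reference spike (weights of
    neurons that fired in ``[t - z, t]`` are increased by independent draws
    from ``Uniform[0, delta_max]``) or ``"eliminate"`` for an extra observed
    spike (same magnitudes, subtracted).  Returns the updated copy of ``w``
    and the list of applied ``(post, pre, signed_delta)`` entries, recorded
    before sign clipping so a control network can mirror them exactly.
    """
    if direction not in ("induce", "eliminate"):
        raise ValueError("direction must be 'induce' or 'eliminate'")
    obs_trains = np.asarray(obs_trains)
    if not 0 <= unpaired_time < obs_trains.shape[0]:
        raise ValueError("unpaired_time outside the raster")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = w.copy()
    pool, deltas = _apply_local(w, obs_trains, neuron, unpaired_time,
                                +1 if direction == "induce" else -1, cfg, gen)
    return w, [(neuron, int(j), float(d)) for j, d in zip(pool, deltas)]


def _apply_homeostatic(
    w: WeightMatrix, x: int, y: int, cfg: LearningConfig, rng: np.random.Generator
) -> np.ndarray:
    n = w.n
    bound = (x - y) * cfg.homeo_scale
    if bound == 0.0:
        return np.zeros((n, n))
    # the draw interval is [0, bound]; bound < 0 means depression
    draws = rng.uniform(min(bound, 0.0), max(bound, 0.0), (n, n))
    np.fill_diagonal(draws, 0.0)
    w.w += draws
    np.minimum(w.w, 0.0, where=w.inhibitory[None, :], out=w.w)
    np.maximum(w.w, 0.0, where=~w.inhibitory[None, :], out=w.w)
    return draws


def homeostatic_update(
    w: WeightMatrix,
    x: int,
    y: int,
    cfg: LearningConfig,
    rng: int | np.random.Generator | None = None,
) -> tuple[WeightMatrix, np.ndarray]:
    """Network-wide additive scaling toward the reference activity level.

    Every off-diagonal synapse receives an independent draw from
    ``Uniform[0, (x - y) * homeo_scale]`` volts — potentiating when the
    network spikes too little (``y < x``), depressing when it spikes too
    much, and a no-op when counts agree.  Sign-crossing weights are clipped
    to 0.  Returns the updated copy and the matrix of applied draws.
    """
    if x < 0 or y < 0:
        raise ValueError("spike counts must be nonnegative")
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w = w.copy()
    draws = _apply_homeostatic(w, x, y, cfg, gen)
    return w, draws


def _clip_all_signs(w: WeightMatrix) -> None:
    np.minimum(w.w, 0.0, where=w.inhibitory[None, :], out=w.w)
    np.maximum(w.w, 0.0, where=~w.inhibitory[None, :], out=w.w)
    np.fill_diagonal(w.w, 0.0)


def _apply_mirror(
    w_ctrl: WeightMatrix,
    deltas: np.ndarray,
    rng: np.random.Generator,
) -> None:
    """Scatter ``deltas`` onto uniformly random off-diagonal synapses.

    Each delta draws an independent target among the ``n (n - 1)``
    off-diagonal positions; repeated hits on one synapse accumulate.  All
    deltas of a batch are summed onto their targets before one sign-clipping
    pass, so the result is independent of delta order.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.size == 0:
        return
    n = w_ctrl.n
    ii = rng.integers(n, size=deltas.size)
    jj = rng.integers(n - 1, size=deltas.size)
    jj[jj >= ii] += 1
    np.add.at(w_ctrl.w, (ii, jj), deltas)
    _clip_all_signs(w_ctrl)


def control_mirror(
    w_ctrl: WeightMatrix,
    applied: list[tuple[int, int, float]] | np.ndarray,
    rng: int | np.random.Generator | None = None,
) -> WeightMatrix:
    """Apply each recorded local delta at a uniformly random off-diagonal synapse.

    The control network thereby receives exactly the same number and
    magnitudes of weight changes as the optimized network, but at random
    locations.  ``applied`` may be the ``(post, pre, delta)`` list from
    :func:`local_updates` or a bare array of signed deltas; only the
    magnitudes are used.  Sign clipping applies at the target synapses after
    the whole batch lands.
    """
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    w_ctrl = w_ctrl.copy()
    arr = np.asarray(applied, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, 2]
    _apply_mirror(w_ctrl, arr, gen)
    return w_ctrl


def run_pspm(
    reference: np.ndarray,
    w_naive: WeightMatrix,
    currents: np.ndarray,
    params: LIFParams | None = None,
    cfg: LearningConfig | None = None,
    kernel: KernelSpec | None = None,
) -> TrialResult:
    """Train a LIF network to reproduce ``reference`` spike trains.

    The naive network is copied into an optimized and a control network.
    Each epoch simulates the optimized network on the fixed input currents,
    matches every neuron's spikes against the reference, applies local pool
    updates for all unpaired spikes (missing before extra, neurons in index
    order, all pairings computed from the epoch's raster before any weight
    change), then one homeostatic pass; the control receives the mirrored
    local deltas at random synapses plus its own homeostatic draws from the
    same ``(x - y)`` interval.  Fully reproducible given ``cfg.rng_seed``.

    Returns the trained networks, their final rasters, and per-epoch
    diagnostics including distance-measure snapshots.
    """
    cfg = cfg or LearningConfig()
    params = params or LIFParams(n=w_naive.n)
    kernel = kernel or KernelSpec()
    reference = np.asarray(reference)
    if reference.ndim != 2 or reference.shape[1] != w_naive.n:
        raise ValueError("reference raster must be (T, N) with N matching the network")
    if reference.shape != np.asarray(currents).shape:
        raise ValueError("reference raster and input currents must share a shape")

    w_opt = w_naive.copy()
    w_ctrl = w_naive.copy()
    n = w_naive.n
    seeds = np.random.SeedSequence(cfg.rng_seed).spawn(4)
    rng_local, rng_homeo, rng_site, rng_ctrl_homeo = (np.random.default_rng(s) for s in seeds)

    ref_times = [np.flatnonzero(reference[:, i]) for i in range(n)]
    x = int(reference.sum())
    history: list[EpochRecord] = []

    for epoch in range(cfg.epochs):
        obs, _ = simulate_lif(w_opt, currents, params)
        y = int(obs.sum())

        # Pairings are all computed from this epoch's raster before any
        # weight is touched, so matching is independent of update order.
        missing: list[list[int]] = [[] for _ in range(n)]
        extra: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            obs_i = np.flatnonzero(obs[:, i])
            pairing = match_spike_trains(ref_times[i], obs_i, cfg.a_cap, cfg.strict_pairing)
            missing[i] = [int(ref_times[i][k]) for k in pairing.unpaired_ref]
            extra[i] = [int(obs_i[l]) for l in pairing.unpaired_obs]
        n_missing = sum(len(m) for m in missing)
        n_extra = sum(len(e) for e in extra)

        # Neurons in index order; per neuron, missing-spike inductions
        # before extra-spike eliminations.
        delta_batches: list[np.ndarray] = []
        for i in range(n):
            for t in missing[i]:
                delta_batches.append(_apply_local(w_opt, obs, i, t, +1, cfg, rng_local)[1])
            for t in extra[i]:
                delta_batches.append(_apply_local(w_opt, obs, i, t, -1, cfg, rng_local)[1])
        deltas = np.concatenate(delta_batches) if delta_batches else np.empty(0)

        _apply_homeostatic(w_opt, x, y, cfg, rng_homeo)
        _apply_mirror(w_ctrl, deltas, rng_site)
        _apply_homeostatic(w_ctrl, x, y, cfg, rng_ctrl_homeo)

        history.append(
            EpochRecord(
                epoch=epoch,
                missing=n_missing,
                extra=n_extra,
                x=x,
                y=y,
                n_local_updates=int(deltas.size),
                sum_abs_delta=float(np.abs(deltas).sum()),
                d_p=pairwise_distance(obs, reference, kernel),
                d_a=aggregate_distance(obs, reference, kernel),
            )
        )

    final_opt, _ = simulate_lif(w_opt, currents, params)
    final_ctrl, _ = simulate_lif(w_ctrl, currents, params)
    return TrialResult(w_opt, w_ctrl, final_opt, final_ctrl, history)
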