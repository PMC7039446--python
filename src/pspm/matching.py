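"""Optimal spike pairing between two single-neuron spike trains.

A reference train and an observed train are aligned by a string-matching
dynamic program over a cost matrix.  Pairing spikes ``k`` (reference) and
``l`` (observed) costs their absolute temporal offset; leaving a spike
unpaired costs a flat cap ``a_cap``.  The resulting matching is monotone
(non-crossing) and minimizes the total cost

    sum over pairs |t_ref - t_obs|  +  a_cap * (#unpaired).

Indices in :class:`SpikePairing` are 0-based positions into the input trains.
"""

from __future__ import annotations

import dataclasses
import json

import numpy as np

__all__ = [
    "CostMatrix",
    "SpikePairing",
    "temporal_distance",
    "build_cost_matrix",
    "backtrack_pairs",
    "match_spike_trains",
]

#: Default unpaired-spike penalty, in timesteps (~45 ms at a 3 ms step).
DEFAULT_A_CAP = 15.0

_EPS = 1e-9


def temporal_distance(t_ref: float, t_obs: float) -> float:
    """Absolute temporal offset between two spike times (timesteps)."""
    return abs(float(t_ref) - float(t_obs))


@dataclasses.dataclass(frozen=True)
class CostMatrix:
    """The ``(n+1) x (m+1)`` pairing cost table and its unpaired penalty.

    ``lam[k, l]`` is the minimum cost of optimally pairing the first ``k``
    reference spikes with the first ``l`` observed spikes; the base cases
    ``lam[k, 0] = k * a_cap`` and ``lam[0, l] = l * a_cap`` leave every
    spike unpaired.
    """

    lam: np.ndarray
    a_cap: float

    @property
    def total_cost(self) -> float:
        return float(self.lam[-1, -1])


@dataclasses.dataclass(frozen=True)
class SpikePairing:
    """Optimal monotone pairing: matched index pairs plus unpaired spikes."""

    pairs: tuple[tuple[int, int], ...]
    unpaired_ref: tuple[int, ...]
    unpaired_obs: tuple[int, ...]
    total_cost: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "pairs": [list(p) for p in self.pairs],
                "unpaired_ref": list(self.unpaired_ref),
                "unpaired_obs": list(self.unpaired_obs),
                "total_cost": self.total_cost,
            }
        )


def _as_times(train) -> np.ndarray:
    t = np.asarray(train, dtype=float).ravel()
    if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
        raise ValueError("spike times must be nonnegative and strictly increasing")
    return t


def build_cost_matrix(ref, obs, a_cap: float = DEFAULT_A_CAP) -> CostMatrix:
    """Fill the pairing cost table by dynamic programming.

    The recursion considers, at ``(k, l)``: pairing ``k`` with ``l`` at cost
    ``d_kl``; leaving ``k`` unpaired at cost ``a_cap``; leaving ``l``
    unpaired at cost ``a_cap``; or leaving both unpaired at ``2 a_cap``
    (dominated by the two single skips, but kept as an explicit branch).
    Rows are vectorized: the left-to-right dependence ``lam[k, l-1] + a_cap``
    is folded in with a running minimum of ``candidate[l] - l * a_cap``.
    """
    if a_cap <= 0:
        raise ValueError("a_cap must be positive")
    ref = _as_times(ref)
    obs = _as_times(obs)
    n, m = ref.size, obs.size

    lam = np.empty((n + 1, m + 1))
    lam[0, :] = a_cap * np.arange(m + 1)
    lam[:, 0] = a_cap * np.arange(n + 1)
    if n and m:
        d = np.abs(ref[:, None] - obs[None, :])
        l_arange = np.arange(1, m + 1)
        for k in range(1, n + 1):
            cand = np.minimum(lam[k - 1, :-1] + d[k - 1], lam[k - 1, 1:] + a_cap)
            cand = np.minimum(cand, lam[k - 1, :-1] + 2.0 * a_cap)
            # lam[k, l] = min(cand[l], lam[k, l-1] + a_cap): prefix minimum
            # of the a_cap-detrended candidates.
            u = np.empty(m + 1)
            u[0] = lam[k, 0]
            u[1:] = cand - a_cap * l_arange
            lam[k, 1:] = np.minimum.accumulate(u)[1:] + a_cap * l_arange
    return CostMatrix(lam, float(a_cap))


def backtrack_pairs(cost: CostMatrix, ref, obs, strict: bool = False) -> SpikePairing:
    """Recover an optimal pairing from a filled cost table.

    Ties among recursion branches are broken with the fixed precedence
    (pair, skip-reference, skip-observed, skip-both), making the returned
    pairing bit-reproducible; any order would be cost-optimal.

    With ``strict=True``, matched pairs farther apart than ``a_cap`` (which
    the recursion admits whenever the offset is below ``2 a_cap``) are
    demoted to unpaired spikes after backtracking, and the reported total
    cost is adjusted accordingly.
    """
    ref = _as_times(ref)
    obs = _as_times(obs)
    lam, a = cost.lam, cost.a_cap
    if lam.shape != (ref.size + 1, obs.size + 1):
        raise ValueError("cost matrix does not match the given spike trains")

    pairs: list[tuple[int, int]] = []
    un_ref: list[int] = []
    un_obs: list[int] = []
    k, l = ref.size, obs.size
    while k > 0 or l > 0:
        here = lam[k, l]
        if k > 0 and l > 0 and abs(here - (lam[k - 1, l - 1] + abs(ref[k - 1] - obs[l - 1]))) <= _EPS:
            pairs.append((k - 1, l - 1))
            k, l = k - 1, l - 1
        elif k > 0 and abs(here - (lam[k - 1, l] + a)) <= _EPS:
            un_ref.append(k - 1)
            k -= 1
        elif l > 0 and abs(here - (lam[k, l - 1] + a)) <= _EPS:
            un_obs.append(l - 1)
            l -= 1
        elif k > 0 and l > 0 and abs(here - (lam[k - 1, l - 1] + 2.0 * a)) <= _EPS:
            un_ref.append(k - 1)
            un_obs.append(l - 1)
            k, l = k - 1, l - 1
        else:  # pragma: no cover - unreachable on a well-formed table
            raise RuntimeError("cost matrix inconsistent with recursion")
    pairs.reverse()
    un_ref.reverse()
    un_obs.reverse()
    total = cost.total_cost

    if strict:
        kept = []
        for pk, pl in pairs:
            d = abs(ref[pk] - obs[pl])
            if d > a + _EPS:
                un_ref.append(pk)
                un_obs.append(pl)
                total += 2.0 * a - d
            else:
                kept.append((pk, pl))
        pairs = kept
        un_ref.sort()
        un_obs.sort()

    return SpikePairing(tuple(pairs), tuple(un_ref), tuple(un_obs), float(total))


def match_spike_trains(
    ref, obs, a_cap: float = DEFAULT_A_CAP, strict: bool = False
) -> SpikePairing:
    """Build the cost matrix and backtrack in one call."""
    cost = build_cost_matrix(ref, obs, a_cap)
    return backtrack_pairs(cost, ref, obs, strict=strict)
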