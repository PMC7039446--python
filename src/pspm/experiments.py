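"""Top-level experiment runner for the two studies.

* **LIF learning study** — repeated trials: draw a reference and a naive
  network from one of the named initial-weight configurations, simulate the
  reference to obtain goal spike trains, train the naive network with PSPM,
  and score naive / optimized / control rasters against the reference with
  every similarity measure plus the weight-matrix error.

* **PIF criticality study** — build a critical PIF network (spectral radius
  1), simulate a long reference raster, split it into segments, train one
  all-excitatory LIF per segment, concatenate the optimized and control
  outputs, and run the avalanche criticality report on all four rasters.

Seeding: every random draw descends from the master seed through
``SeedSequence([master_seed, trial_index, stream])``, so adding trials never
perturbs existing ones.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
import yaml

from .avalanches import CriticalityReport, criticality_report
from .learning import LearningConfig, TrialResult, run_pspm
from .metrics import (
    KernelSpec,
    aggregate_distance,
    isi_l2,
    pairwise_distance,
    spike_count_stats,
    weight_error,
)
from .models import (
    LIFParams,
    WeightMatrix,
    draw_sign_mask,
    build_pif_network,
    generate_lif_inputs,
    generate_pif_inputs,
    init_weights,
    simulate_lif,
    simulate_pif,
)

__all__ = [
    "ExperimentConfig",
    "TrialSummary",
    "PIFStudyResult",
    "run_lif_learning_study",
    "run_pif_criticality_study",
]

_NETWORKS = ("naive", "optimized", "control")


@dataclasses.dataclass
class ExperimentConfig:
    """Configuration of a study; defaults follow the reference conditions."""

    study: str = "lif_learning"  # or "pif_criticality"
    config_name: str = "naive-half-max"
    n: int = 400
    t_steps: int = 10_000
    epochs: int = 150
    trials: int = 30
    master_seed: int = 0
    inhib_fraction: float = 0.2
    # learning block
    a_cap: float = 15.0
    z: int = 10
    delta_max: float = 1e-4
    homeo_scale: float = 1e-8
    # metrics block
    kernel_sigma: float = dataclasses.field(default_factory=lambda: KernelSpec().sigma)
    isi_bin_width: int = 3
    # avalanche / PIF block
    percentile: float = 20.0
    pif_t_steps: int = 50_000
    segments: int = 5
    pif_p: float = 0.1
    pif_w_high: float = 0.02
    pif_input_scale: float = 1e-3
    lif_naive_high: float = 1e-3

    def learning_config(self, seed: int) -> LearningConfig:
        return LearningConfig(
            a_cap=self.a_cap,
            z=self.z,
            delta_max=self.delta_max,
            homeo_scale=self.homeo_scale,
            epochs=self.epochs,
            rng_seed=seed,
        )

    def kernel(self) -> KernelSpec:
        return KernelSpec(sigma=self.kernel_sigma)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclasses.dataclass
class TrialSummary:
    """All similarity measures for one trial, per network, against the reference."""

    trial: int
    metrics: dict[str, dict[str, float]]  # metrics[network][measure]


@dataclasses.dataclass
class PIFStudyResult:
    """Criticality reports for the PIF reference and the three LIF rasters."""

    reports: dict[str, CriticalityReport | None]
    rasters: dict[str, np.ndarray]
    failures: dict[str, str]


def _trial_seed(master: int, trial: int, stream: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([master, trial, stream])


def _score(
    raster: np.ndarray,
    reference: np.ndarray,
    w: WeightMatrix,
    w_ref: WeightMatrix,
    kernel: KernelSpec,
    isi_bin_width: int,
) -> dict[str, float]:
    mean, var = spike_count_stats(raster)
    return {
        "d_p": pairwise_distance(raster, reference, kernel),
        "d_a": aggregate_distance(raster, reference, kernel),
        "isi_l2": isi_l2(raster, reference, isi_bin_width),
        "spike_mean": mean,
        "spike_var": var,
        "weight_error": weight_error(w, w_ref),
    }


def run_lif_learning_trial(cfg: ExperimentConfig, trial: int) -> tuple[TrialSummary, TrialResult]:
    """One learning trial: reference + naive draw, PSPM training, scoring."""
    mask = draw_sign_mask(
        cfg.n, cfg.inhib_fraction, np.random.default_rng(_trial_seed(cfg.master_seed, trial, 0))
    )
    w_ref = init_weights(
        cfg.config_name, "reference", cfg.n, cfg.inhib_fraction,
        np.random.default_rng(_trial_seed(cfg.master_seed, trial, 1)), inhibitory=mask,
    )
    w_naive = init_weights(
        cfg.config_name, "naive", cfg.n, cfg.inhib_fraction,
        np.random.default_rng(_trial_seed(cfg.master_seed, trial, 2)), inhibitory=mask,
    )
    currents = generate_lif_inputs(
        cfg.t_steps, cfg.n, rng=np.random.default_rng(_trial_seed(cfg.master_seed, trial, 3))
    )
    params = LIFParams(n=cfg.n, inhib_fraction=cfg.inhib_fraction)
    reference, _ = simulate_lif(w_ref, currents, params)
    naive_raster, _ = simulate_lif(w_naive, currents, params)

    lcfg = cfg.learning_config(
        int(_trial_seed(cfg.master_seed, trial, 4).generate_state(1)[0])
    )
    result = run_pspm(reference, w_naive, currents, params, lcfg, cfg.kernel())

    kernel = cfg.kernel()
    metrics = {
        "naive": _score(naive_raster, reference, w_naive, w_ref, kernel, cfg.isi_bin_width),
        "optimized": _score(
            result.raster_optimized, reference, result.w_optimized, w_ref, kernel, cfg.isi_bin_width
        ),
        "control": _score(
            result.raster_control, reference, result.w_control, w_ref, kernel, cfg.isi_bin_width
        ),
    }
    return TrialSummary(trial, metrics), result


def aggregate_table(summaries: list[TrialSummary]) -> pd.DataFrame:
    """Mean and SD of every measure across trials, one row per network."""
    rows = []
    for s in summaries:
        for network in _NETWORKS:
            rows.append({"trial": s.trial, "network": network, **s.metrics[network]})
    df = pd.DataFrame(rows)
    agg = df.drop(columns="trial").groupby("network", sort=False).agg(["mean", "std"])
    agg.columns = [f"{m}_{stat}" for m, stat in agg.columns]
    agg["trials"] = len(summaries)
    return agg


def run_lif_learning_study(cfg: ExperimentConfig) -> tuple[list[TrialSummary], pd.DataFrame]:
    """Run all trials of the learning study and aggregate the results."""
    summaries = [run_lif_learning_trial(cfg, t)[0] for t in range(cfg.trials)]
    return summaries, aggregate_table(summaries)


def run_pif_criticality_study(cfg: ExperimentConfig) -> PIFStudyResult:
    """Criticality transfer: train LIF networks on critical PIF spike trains.

    The PIF reference raster (``pif_t_steps`` steps) is split into
    ``segments`` equal stretches; each stretch is the reference for one
    PSPM run on a fresh all-excitatory naive LIF (weights U[0,
    ``lif_naive_high``] V) driven by Gaussian currents.  Naive, optimized
    and control outputs are concatenated across segments before avalanche
    analysis.  Networks whose rasters cannot support a power-law fit (the
    expected situation for the naive networks) are reported as failures
    rather than reports.
    """
    if cfg.pif_t_steps % cfg.segments:
        raise ValueError("pif_t_steps must divide evenly into segments")
    w_pif = build_pif_network(
        cfg.n, cfg.pif_p, (0.0, cfg.pif_w_high),
        np.random.default_rng(_trial_seed(cfg.master_seed, 0, 10)),
    )
    pif_inputs = generate_pif_inputs(
        cfg.pif_t_steps, cfg.n, cfg.pif_input_scale,
        np.random.default_rng(_trial_seed(cfg.master_seed, 0, 11)),
    )
    reference = simulate_pif(
        w_pif, pif_inputs, np.random.default_rng(_trial_seed(cfg.master_seed, 0, 12))
    )

    seg_len = cfg.pif_t_steps // cfg.segments
    params = LIFParams(n=cfg.n, inhib_fraction=0.0)
    mask = np.zeros(cfg.n, dtype=bool)  # exclusively excitatory
    pieces: dict[str, list[np.ndarray]] = {k: [] for k in _NETWORKS}
    for seg in range(cfg.segments):
        ref_seg = reference[seg * seg_len : (seg + 1) * seg_len]
        rng_w = np.random.default_rng(_trial_seed(cfg.master_seed, seg, 13))
        w_naive = WeightMatrix(
            _excitatory_uniform(cfg.n, cfg.lif_naive_high, rng_w), mask.copy()
        )
        currents = generate_lif_inputs(
            seg_len, cfg.n, rng=np.random.default_rng(_trial_seed(cfg.master_seed, seg, 14))
        )
        naive_raster, _ = simulate_lif(w_naive, currents, params)
        lcfg = cfg.learning_config(
            int(_trial_seed(cfg.master_seed, seg, 15).generate_state(1)[0])
        )
        result = run_pspm(ref_seg, w_naive, currents, params, lcfg, cfg.kernel())
        pieces["naive"].append(naive_raster)
        pieces["optimized"].append(result.raster_optimized)
        pieces["control"].append(result.raster_control)

    rasters = {"reference": reference}
    rasters.update({k: np.concatenate(v, axis=0) for k, v in pieces.items()})
    reports: dict[str, CriticalityReport | None] = {}
    failures: dict[str, str] = {}
    for name, raster in rasters.items():
        try:
            reports[name] = criticality_report(raster, cfg.percentile)
        except ValueError as exc:
            reports[name] = None
            failures[name] = str(exc)
    return PIFStudyResult(reports, rasters, failures)


def _excitatory_uniform(n: int, high: float, rng: np.random.Generator) -> np.ndarray:
    w = rng.uniform(0.0, high, (n, n))
    np.fill_diagonal(w, 0.0)
    return w
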