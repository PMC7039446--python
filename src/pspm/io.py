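"""File formats: spike-event rasters (TSV) and weight matrices (npy + JSON).

Raster format — tab-separated spike events, one per line, with a header
comment carrying the raster shape so empty rasters round-trip:

    # pspm-raster	T=10000	N=400
    timestep	neuron_id
    12	3
    ...

Timesteps and neuron ids are 0-based.  Weight matrices are stored as a
dense ``.npy`` array (volts) beside a ``.json`` sidecar with the sign mask
and provenance metadata; a plain-text TSV export is also provided.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np

from .models import WeightMatrix

__all__ = [
    "write_raster",
    "read_raster",
    "write_weights",
    "read_weights",
    "export_weights_tsv",
]

_HEADER_RE = re.compile(r"#\s*pspm-raster\tT=(\d+)\tN=(\d+)\s*$")


def write_raster(path: str | Path, spikes: np.ndarray) -> None:
    """Write a ``(T, N)`` binary raster as a spike-event TSV."""
    spikes = np.asarray(spikes)
    if spikes.ndim != 2:
        raise ValueError("expected a (T, N) raster")
    t_steps, n = spikes.shape
    ts, ns = np.nonzero(spikes)
    with open(path, "w") as fh:
        fh.write(f"# pspm-raster\tT={t_steps}\tN={n}\n")
        fh.write("timestep\tneuron_id\n")
        for t, i in zip(ts, ns):
            fh.write(f"{t}\t{i}\n")


def read_raster(path: str | Path) -> np.ndarray:
    """Read a spike-event TSV back into a dense ``(T, N)`` uint8 raster."""
    path = Path(path)
    with open(path) as fh:
        lines = fh.readlines()
    if not lines:
        raise ValueError(f"{path}: empty raster file")
    m = _HEADER_RE.match(lines[0])
    if not m:
        raise ValueError(f"{path}:1: missing or malformed raster header")
    t_steps, n = int(m.group(1)), int(m.group(2))
    spikes = np.zeros((t_steps, n), dtype=np.uint8)
    for lineno, line in enumerate(lines[1:], start=2):
        line = line.strip()
        if not line or line.startswith("timestep"):
            continue
        parts = line.split("\t")
        try:
            t, i = int(parts[0]), int(parts[1])
        except (IndexError, ValueError) as exc:
            raise ValueError(f"{path}:{lineno}: malformed spike event {line!r}") from exc
        if not (0 <= t < t_steps and 0 <= i < n):
            raise ValueError(f"{path}:{lineno}: spike event ({t}, {i}) outside raster")
        spikes[t, i] = 1
    return spikes


def write_weights(
    path: str | Path,
    weights: WeightMatrix,
    seed: int | None = None,
    config_name: str | None = None,
) -> None:
    """Write weights as ``<path>.npy`` plus a ``<path>.json`` metadata sidecar."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npy", ".json") else path
    np.save(base.with_suffix(".npy"), weights.w)
    meta = {
        "n": weights.n,
        "units": "V",
        "inhibitory": weights.inhibitory.astype(int).tolist(),
        "seed": seed,
        "config_name": config_name,
    }
    base.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def read_weights(path: str | Path) -> WeightMatrix:
    """Read a weight matrix written by :func:`write_weights`."""
    path = Path(path)
    base = path.with_suffix("") if path.suffix in (".npy", ".json") else path
    w = np.load(base.with_suffix(".npy"))
    meta = json.loads(base.with_suffix(".json").read_text())
    return WeightMatrix(w, np.asarray(meta["inhibitory"], dtype=bool))


def export_weights_tsv(path: str | Path, weights: WeightMatrix) -> None:
    """Plain-text export: one header line of sign labels, then the matrix."""
    with open(path, "w") as fh:
        labels = "\t".join("inh" if b else "exc" for b in weights.inhibitory)
        fh.write(f"# signs\t{labels}\n")
        np.savetxt(fh, weights.w, delimiter="\t", fmt="%.12e")
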