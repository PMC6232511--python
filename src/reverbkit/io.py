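"""Plain-text readers/writers for traces and rasters, and fixture generation.

Formats are deliberately trivial, diffable, language-agnostic text:

* trace file — ``#``-prefixed header lines of the form ``# key = value``
  (must include ``dt_ms``), then one integer count per line in bin order;
* raster file — header lines with ``n_neurons``, ``n_bins``, ``dt_ms``,
  then one ``neuron_id<TAB>bin_index`` line per spike event.

Round trips are lossless: write-then-read reproduces counts/events and
dt exactly, and header metadata is preserved.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from . import regime
from .process import (ActivityTrace, ProcessParams, SpikeRaster,
                      simulate_branching, simulate_raster)

__all__ = [
    "read_trace", "write_trace", "read_raster", "write_raster",
    "make_fixtures",
]

FORMAT_VERSION = "1"


def _format_value(v):
    if isinstance(v, (list, tuple, dict)):
        return json.dumps(v)
    return str(v)


def write_trace(trace: ActivityTrace, path) -> Path:
    """Write an ActivityTrace as delimited text with '#' headers."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        fh.write(f"# dt_ms = {trace.dt!r}\n")
        for key, val in trace.meta.items():
            if key == "dt_ms":
                continue
            fh.write(f"# {key} = {_format_value(val)}\n")
        np.savetxt(fh, trace.counts, fmt="%d")
    return path


def read_trace(path) -> ActivityTrace:
    """Read a trace file; errors name the offending line."""
    path = Path(path)
    meta = {}
    counts = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            try:
                c = int(line)
            except ValueError:
                raise ValueError(
                    f"{path}: malformed count {line!r} at line {lineno}") from None
            if c < 0:
                raise ValueError(f"{path}: negative count at line {lineno}")
            counts.append(c)
    if not counts:
        raise ValueError(f"{path}: no bins")
    if "dt_ms" not in meta:
        raise ValueError(f"{path}: missing '# dt_ms = ...' header")
    dt = float(meta.pop("dt_ms"))
    return ActivityTrace(np.asarray(counts, dtype=np.int64), dt, meta=meta)


def write_raster(raster: SpikeRaster, path) -> Path:
    """Write a SpikeRaster as tab-separated neuron_id/bin_index events."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# format_version = {FORMAT_VERSION}\n")
        fh.write(f"# n_neurons = {raster.n_neurons}\n")
        fh.write(f"# n_bins = {raster.n_bins}\n")
        fh.write(f"# dt_ms = {raster.dt!r}\n")
        for key, val in raster.meta.items():
            if key in ("n_neurons", "n_bins", "dt_ms"):
                continue
            fh.write(f"# {key} = {_format_value(val)}\n")
        for nid, b in zip(raster.neuron_ids, raster.bin_indices):
            fh.write(f"{nid}\t{b}\n")
    return path


def read_raster(path) -> SpikeRaster:
    path = Path(path)
    meta = {}
    nids, bins_ = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            try:
                nid, b = int(parts[0]), int(parts[1])
            except (ValueError, IndexError):
                raise ValueError(
                    f"{path}: malformed event {line!r} at line {lineno}") from None
            nids.append(nid)
            bins_.append(b)
    for key in ("n_neurons", "n_bins", "dt_ms"):
        if key not in meta:
            raise ValueError(f"{path}: missing '# {key} = ...' header")
    return SpikeRaster(
        n_neurons=int(meta.pop("n_neurons")),
        neuron_ids=np.asarray(nids, dtype=np.int64),
        bin_indices=np.asarray(bins_, dtype=np.int64),
        n_bins=int(meta.pop("n_bins")),
        dt=float(meta.pop("dt_ms")),
        meta=meta,
    )


# canonical fixture regimes: irregular, reverberating (in-vivo median),
# near-critical; h chosen so all traces share the same stationary rate.
FIXTURE_M = (0.0, 0.9, 0.98, 0.999)
FIXTURE_RATE = 20.0        # target stationary rate, spikes/bin
FIXTURE_BINS = 10_000
FIXTURE_DT = 4.0


def make_fixtures(out_dir, seed: int = 0) -> dict:
    """Generate canonical small fixtures plus a ground-truth manifest.

    Writes equal-rate traces at m in {0, 0.9, 0.98, 0.999}, a 50-neuron
    raster per regime, one 100-trial ensemble with an efficacy step
    0.7 -> 0.95 mid-trial, and ``manifest.json`` mapping each file to its
    generating parameters.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(seed)
    manifest = {"seed": seed, "files": {}}
    for i, m in enumerate(FIXTURE_M):
        h = FIXTURE_RATE * (1.0 - m)       # equal stationary rate across regimes
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        params = ProcessParams(m=m, h=h, n_bins=FIXTURE_BINS, dt=FIXTURE_DT, seed=sub)
        name = f"trace_m{m:g}.txt"
        write_trace(simulate_branching(params), out / name)
        manifest["files"][name] = {"kind": "trace", "m": m, "h": h,
                                   "dt": FIXTURE_DT, "n_bins": FIXTURE_BINS,
                                   "seed": sub,
                                   "regime": regime.classify_regime(m)}
        rparams = ProcessParams(m=m, h=h, n_bins=2000, dt=FIXTURE_DT,
                                n_neurons=50, seed=sub)
        rname = f"raster_m{m:g}.txt"
        write_raster(simulate_raster(rparams), out / rname)
        manifest["files"][rname] = {"kind": "raster", "m": m, "h": h,
                                    "dt": FIXTURE_DT, "n_bins": 2000,
                                    "n_neurons": 50, "seed": sub}
    # trial ensemble with an efficacy step mid-trial
    trial_dir = out / "trials_step"
    trial_dir.mkdir(exist_ok=True)
    schedule = [(0, 0.7), (500, 0.95)]
    n_trials, n_bins = 100, 1000
    for j in range(n_trials):
        sub = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
        params = ProcessParams(m=0.7, h=3.0, n_bins=n_bins, dt=FIXTURE_DT,
                               seed=sub, m_schedule=schedule)
        write_trace(simulate_branching(params), trial_dir / f"trial_{j:03d}.txt")
    manifest["files"]["trials_step/"] = {
        "kind": "trial_ensemble", "n_trials": n_trials, "n_bins": n_bins,
        "h": 3.0, "dt": FIXTURE_DT, "m_schedule": schedule,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
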