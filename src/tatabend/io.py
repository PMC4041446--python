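"""Readers/writers for the package's plain formats and the staged pipeline.

Formats: photon-HDF5-layout files (h5py) and a 3-column TSV dialect for
photon streams; long-format CSV for traces, idealized paths and dwell
tables; CSV for burst tables; JSON for fit results and run manifests; YAML
for run configuration.  All headers state units: photon clocks are integer
microseconds, durations seconds, intensities counts per frame.
"""
from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bursts import (
    Burst,
    BurstSearchParams,
    CorrectionFactors,
    FilterThresholds,
    analyze_stream,
    fit_populations,
)
from .containers import PhotonStream, Trace
from .hmm import decode, extract_dwells, fit_hmm
from .kinetics import derive_rates, fit_dwells, transition_frequencies
from .simulate import SimulationConfig, simulate_photon_stream, simulate_traces

TIMESTAMP_UNIT_S = 1e-6


# --------------------------------------------------------------------------
# photon streams
# --------------------------------------------------------------------------

def write_photon_hdf5(stream: PhotonStream, path):
    """Write a photon-HDF5-layout file (timestamps, detectors, ALEX spec)."""
    with h5py.File(path, "w") as f:
        pd_grp = f.create_group("photon_data")
        pd_grp.create_dataset("timestamps", data=stream.timestamps_us, dtype="i8")
        pd_grp.create_dataset("detectors", data=stream.channel, dtype="u1")
        spec = pd_grp.create_group("timestamps_specs")
        spec.create_dataset("timestamps_unit", data=TIMESTAMP_UNIT_S)
        ms = pd_grp.create_group("measurement_specs")
        ms.create_dataset("measurement_type", data=np.bytes_("smFRET-usALEX"))
        ms.create_dataset("alex_period", data=int(stream.alternation_period_us))
        f.create_dataset("acquisition_duration", data=float(stream.duration_s))
        if stream.background_rates:
            f.attrs["background_rates"] = json.dumps(stream.background_rates)


def read_photon_hdf5(path) -> PhotonStream:
    with h5py.File(path, "r") as f:
        ts = f["photon_data/timestamps"][()]
        det = f["photon_data/detectors"][()]
        unit = float(f["photon_data/timestamps_specs/timestamps_unit"][()])
        period = int(f["photon_data/measurement_specs/alex_period"][()])
        duration = float(f["acquisition_duration"][()])
        bg = json.loads(f.attrs["background_rates"]) if "background_rates" in f.attrs else None
    ts_us = np.round(ts * (unit / TIMESTAMP_UNIT_S)).astype(np.int64)
    stream = PhotonStream(timestamps_us=ts_us, channel=det.astype(np.int8),
                          alternation_period_us=period, duration_s=duration,
                          background_rates=bg)
    from .bursts import classify_photons
    return classify_photons(stream)


def write_photon_tsv(stream: PhotonStream, path):
    """3-column TSV dialect: timestamp_us, channel, excitation_slot."""
    with open(path, "w") as f:
        f.write("# tatabend photon stream; timestamps in integer microseconds\n")
        f.write(f"# alternation_period_us={stream.alternation_period_us}\n")
        f.write(f"# duration_s={stream.duration_s}\n")
        if stream.background_rates:
            f.write(f"# background_rates={json.dumps(stream.background_rates)}\n")
        f.write("timestamp_us\tchannel\texcitation_slot\n")
        slot = stream.excitation_slot
        if slot is None:
            slot = np.full(len(stream), -1, dtype=np.int8)
        for t, c, s in zip(stream.timestamps_us, stream.channel, slot):
            f.write(f"{t}\t{c}\t{s}\n")


def read_photon_tsv(path) -> PhotonStream:
    """Read the TSV dialect, reporting malformed rows with line numbers."""
    period, duration, bg = 100, None, None
    ts, ch, slot = [], [], []
    with open(path) as f:
        for lineno, line in enumerate(f, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("# ")
                if body.startswith("alternation_period_us="):
                    period = int(body.split("=", 1)[1])
                elif body.startswith("duration_s="):
                    duration = float(body.split("=", 1)[1])
                elif body.startswith("background_rates="):
                    bg = json.loads(body.split("=", 1)[1])
                continue
            if line.startswith("timestamp_us"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}: line {lineno}: expected 3 columns")
            try:
                t, c, s = int(parts[0]), int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            if c not in (0, 1):
                raise ValueError(f"{path}: line {lineno}: unknown channel code {c}")
            if ts and t <= ts[-1]:
                raise ValueError(
                    f"{path}: line {lineno}: timestamp {t} not strictly increasing")
            ts.append(t)
            ch.append(c)
            slot.append(s)
    if not ts:
        warnings.warn(f"{path}: empty photon stream")
    if duration is None:
        duration = (ts[-1] * TIMESTAMP_UNIT_S) if ts else 0.0
    slot_arr = np.asarray(slot, dtype=np.int8)
    return PhotonStream(
        timestamps_us=np.asarray(ts, dtype=np.int64),
        channel=np.asarray(ch, dtype=np.int8),
        excitation_slot=None if (slot_arr.size and slot_arr[0] < 0) else slot_arr,
        alternation_period_us=period,
        duration_s=duration, background_rates=bg)


def read_photon_stream(path, dialect: str | None = None) -> PhotonStream:
    """Dispatch on dialect ('photon-hdf5' | 'tsv', guessed from the suffix)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "photon-hdf5" if path.suffix in (".h5", ".hdf5") else "tsv"
    if dialect == "photon-hdf5":
        return read_photon_hdf5(path)
    if dialect == "tsv":
        return read_photon_tsv(path)
    raise ValueError(f"unknown dialect {dialect!r}")


# --------------------------------------------------------------------------
# traces, paths, dwells, bursts
# --------------------------------------------------------------------------

def write_traces_csv(traces: list[Trace], path):
    """Long format: trace_id, frame, time_s, I_D, I_A (counts/frame)."""
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "trace_id": tr.trace_id,
            "frame": np.arange(tr.n_frames),
            "time_s": tr.time_s,
            "I_D": tr.donor,
            "I_A": tr.acceptor,
        }))
    # %.17g keeps float64 round-trippable so the round trip is bit-identical
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.17g")


def read_traces(path, frame_period_s: float | None = None) -> list[Trace]:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trace_id", "frame", "time_s", "I_D", "I_A"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    traces = []
    for tid, g in df.groupby("trace_id", sort=False):
        g = g.sort_values("frame")
        if frame_period_s is None:
            dts = np.diff(g["time_s"].to_numpy())
            if dts.size and (np.ptp(dts) > 1e-9 * max(1.0, dts[0])):
                raise ValueError(f"{path}: trace {tid}: inconsistent frame period")
            dt = float(dts[0]) if dts.size else np.nan
        else:
            dt = frame_period_s
        traces.append(Trace(trace_id=str(tid), frame_period_s=dt,
                            donor=g["I_D"].to_numpy(), acceptor=g["I_A"].to_numpy()))
    return traces


def write_state_paths_csv(paths, path):
    rows = [pd.DataFrame({"trace_id": p.trace_id,
                          "frame": np.arange(len(p)), "state": p.states})
            for p in paths]
    pd.concat(rows, ignore_index=True).to_csv(path, index=False)


def write_ground_truth_csv(paths, trace_ids, path):
    """Ground-truth CTMC segments: trace_id, state, t_start_s, t_end_s."""
    rows = []
    for tid, segs in zip(trace_ids, paths):
        for state, t0, t1 in segs:
            rows.append({"trace_id": tid, "state": state,
                         "t_start_s": t0, "t_end_s": t1})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_dwells_csv(dwells: pd.DataFrame, path):
    dwells.to_csv(path, index=False)


def read_dwells(path) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"trace_id", "state", "duration_s", "censored"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_bursts_csv(bursts: list[Burst], path):
    rows = [{
        "start_us": b.start_us, "stop_us": b.stop_us,
        "n_photons": b.n_photons,
        "F_DD": b.F_DD, "F_AD": b.F_AD, "F_AA": b.F_AA,
        "E": b.E, "S": b.S,
        "alex_2cde": b.alex_2cde, "fret_2cde": b.fret_2cde,
        "kept": "filtered" not in b.flags,
    } for b in bursts]
    pd.DataFrame(rows).to_csv(path, index=False)


# --------------------------------------------------------------------------
# run configuration and pipeline
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Validated configuration for an end-to-end run."""

    mode: str = "tirf"                       # "tirf" or "confocal"
    out_dir: str = "tatabend_out"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    n_traces: int = 50
    trace_duration_s: float = 30.0
    n_bursts: int = 2000
    burst_params: BurstSearchParams = field(default_factory=BurstSearchParams)
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    corrections: CorrectionFactors = field(default_factory=CorrectionFactors)
    hmm_states: int = 2
    hmm_restarts: int = 10
    hmm_tol: float = 1e-6
    topology: str = "two-state"
    n_components: int = 2

    def __post_init__(self):
        if self.mode not in ("tirf", "confocal"):
            raise ValueError("mode must be 'tirf' or 'confocal'")
        if self.hmm_states not in (1, 2, 3):
            raise ValueError(f"invalid hmm_states K={self.hmm_states}")
        if self.n_traces < 1 or self.trace_duration_s <= 0 or self.n_bursts < 0:
            raise ValueError("invalid problem sizes")
        self.simulation.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        for key, typ in (("simulation", SimulationConfig),
                         ("burst_params", BurstSearchParams),
                         ("thresholds", FilterThresholds),
                         ("corrections", CorrectionFactors)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute simulate -> (bursts | idealize) -> kinetics as configured.

    Writes every artifact plus a manifest (config hash, seed, version) to
    the output directory; rerunning with the same config and seed
    reproduces stochastic stages bit-identically.  Returns the results
    bundle as a dict.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {"mode": config.mode}
    stage = "simulate"
    try:
        if config.mode == "confocal":
            stream = simulate_photon_stream(config.simulation, config.n_bursts,
                                            rng_seed=config.seed)
            write_photon_tsv(stream, out / "photons.tsv")
            stage = "bursts"
            bursts = analyze_stream(stream, config.burst_params,
                                    corrections=config.corrections,
                                    thresholds=config.thresholds)
            write_bursts_csv(bursts, out / "bursts.csv")
            stage = "populations"
            e_values = [b.E for b in bursts if np.isfinite(b.E)]
            fit = fit_populations(e_values, config.n_components)
            results["population_fit"] = {
                "components": [{"mean": m, "sd": s, "weight": w}
                               for m, s, w in fit.components],
                "bent_fraction": fit.bent_fraction,
                "n_bursts": len(e_values),
            }
        else:
            traces, truth = simulate_traces(config.simulation, config.n_traces,
                                            config.trace_duration_s,
                                            rng_seed=config.seed)
            write_traces_csv(traces, out / "traces.csv")
            write_ground_truth_csv(truth, [t.trace_id for t in traces],
                                   out / "ground_truth.csv")
            stage = "idealize"
            model = fit_hmm(traces, config.hmm_states,
                            n_restarts=config.hmm_restarts, tol=config.hmm_tol,
                            seed=config.seed)
            paths = decode(model, traces)
            write_state_paths_csv(paths, out / "paths.csv")
            dwells = extract_dwells(paths)
            write_dwells_csv(dwells, out / "dwells.csv")
            stage = "kinetics"
            fits = fit_dwells(dwells)
            stats = transition_frequencies(paths, n_states=config.hmm_states)
            rates = derive_rates(fits, stats, config.topology)
            results["hmm"] = {"means": model.means.tolist(),
                              "sds": model.sds.tolist(),
                              "log_likelihood": model.log_likelihood}
            results["dwell_fits"] = {s: {"tau_s": f.tau_s, "se_s": f.se_s,
                                         "n": f.n_dwells}
                                     for s, f in fits.items()}
            results["rates_per_s"] = {f"k_{i+1}{j+1}": k
                                      for (i, j), k in rates.rates.items()}
    except Exception as exc:
        record = {"stage": stage, "error": type(exc).__name__, "message": str(exc)}
        with open(out / "error.json", "w") as f:
            json.dump(record, f, indent=2)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {"config_hash": config.digest(), "seed": config.seed,
                "version": __version__, "config": config.to_dict()}
    with open(out / "manifest.json", "w") as f:
        json.dump(manifest, f, indent=2, default=str)
    with open(out / "results.json", "w") as f:
        json.dump(results, f, indent=2, default=float)
    return results
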