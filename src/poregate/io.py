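"""Readers, writers, configuration and the pipeline driver.

Formats: generator traces and derived series are TSV with '#'-prefixed
header lines; structured reports and manifests are JSON; trajectories may
also arrive as multi-model PDB (read through MDAnalysis, with coordinates
converted Angstrom -> nm at the boundary).  All randomness flows from
config seeds, so equal configs give byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import gating, hydration, kinetics, synthetic
from .constants import DEFAULT_TEMPERATURE_K, WET_THRESHOLD_NM

logger = logging.getLogger("poregate")

TRACE_COLUMNS = ("time_ns", "state", "n_wat", "z_gap_nm", "d_mean_nm")
SERIES_COLUMNS = ("time_ns", "n_wat", "z_gap_nm", "z_gap_center_nm", "wet")


# ---------------------------------------------------------------- TSV traces

def write_trace(path, trace) -> None:
    """Write one generator trajectory trace as headered TSV."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# poregate trajectory trace: {trace.source}\n")
        fh.write("# " + "\t".join(TRACE_COLUMNS) + "\n")
        for i in range(len(trace.time)):
            zg = trace.z_gap[i]
            fh.write(f"{trace.time[i]:.6g}\t{trace.state[i]}\t"
                     f"{trace.n_wat[i]:d}\t"
                     f"{'nan' if np.isnan(zg) else format(zg, '.6g')}\t"
                     f"{trace.d_mean[i]:.6g}\n")


def read_trace(path) -> synthetic.TrajectoryTrace:
    """Read a trace TSV back into a :class:`TrajectoryTrace` (no positions)."""
    path = Path(path)
    times, states, nwat, zgap, dmean = [], [], [], [], []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(TRACE_COLUMNS):
            raise ValueError(f"{path}:{lineno}: expected "
                             f"{len(TRACE_COLUMNS)} columns, got {len(parts)}")
        times.append(float(parts[0]))
        states.append(parts[1])
        nwat.append(int(parts[2]))
        zgap.append(float(parts[3]))
        dmean.append(float(parts[4]))
    state = np.array(states)
    z_gap = np.array(zgap)
    wet = np.where(np.isnan(z_gap), state != "dry",
                   z_gap <= WET_THRESHOLD_NM)
    return synthetic.TrajectoryTrace(
        time=np.array(times), state=state, n_wat=np.array(nwat, dtype=int),
        z_gap=z_gap, d_mean=np.array(dmean), wet=wet.astype(bool),
        water_z=None, source=path.stem)


def write_ensemble(directory, ensemble, extra_meta=None) -> None:
    """Write per-trajectory trace TSVs plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for trace in ensemble:
        write_trace(directory / f"{trace.source}.tsv", trace)
    model = ensemble.model
    manifest = {
        "states": list(model.states),
        "rate_matrix_per_s": np.asarray(model.rate_matrix).tolist(),
        "nwat_dists": model.nwat_dists,
        "coupling": {"intercept_nm": model.coupling_intercept,
                     "slope_nm_per_water": model.coupling_slope,
                     "noise_nm": model.coupling_noise},
        "region_nm": list(model.region),
        "seed": ensemble.seed,
        "n_traj": len(ensemble),
        "dt_ns": ensemble.dt,
        "duration_ns": ensemble.duration,
    }
    manifest.update(extra_meta or {})
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_ensemble(directory) -> list:
    """Read every trace TSV in a directory (sorted by name)."""
    directory = Path(directory)
    traces = [read_trace(p) for p in sorted(directory.glob("*.tsv"))]
    if not traces:
        raise ValueError(f"no trace TSVs found in {directory}")
    return traces


def write_series(path, series) -> None:
    """Write a HydrationSeries as headered TSV."""
    with Path(path).open("w") as fh:
        fh.write(f"# poregate hydration series: {series.source}\n")
        fh.write(f"# wet threshold (nm): {series.threshold}\n")
        fh.write("# " + "\t".join(SERIES_COLUMNS) + "\n")
        for i in range(len(series)):
            fh.write(f"{series.time[i]:.6g}\t{series.n_wat[i]:d}\t"
                     f"{series.z_gap[i]:.6g}\t{series.z_gap_center[i]:.6g}\t"
                     f"{int(series.wet[i])}\n")


def read_series(path) -> hydration.HydrationSeries:
    path = Path(path)
    rows = []
    threshold = WET_THRESHOLD_NM
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if line.startswith("# wet threshold"):
            threshold = float(line.rsplit(":", 1)[1])
            continue
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != len(SERIES_COLUMNS):
            raise ValueError(f"{path}:{lineno}: malformed series row")
        rows.append(parts)
    arr = np.array(rows, dtype=float)
    return hydration.HydrationSeries(
        time=arr[:, 0], n_wat=arr[:, 1].astype(int), z_gap=arr[:, 2],
        z_gap_center=arr[:, 3], wet=arr[:, 4].astype(bool),
        threshold=threshold, source=path.stem)


# ------------------------------------------------------------ umbrella I/O

def write_windows(directory, windows, temperature: float) -> None:
    """One TSV per window (time_ns, z_nm) plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, w in enumerate(windows):
        name = f"window{i:04d}.tsv"
        with (directory / name).open("w") as fh:
            fh.write("# time_ns\tz_nm\n")
            for j, z in enumerate(w.samples):
                fh.write(f"{j * w.sample_dt:.9g}\t{z:.6g}\n")
        meta.append({"file": name, "center_nm": w.center,
                     "spring_k_kcal_mol_nm2": w.spring_k,
                     "sample_dt_ns": w.sample_dt})
    (directory / "manifest.json").write_text(json.dumps(
        {"temperature_K": temperature, "windows": meta}, indent=2))


def read_windows(directory):
    """Read umbrella windows written by :func:`write_windows`.

    Returns ``(windows, temperature)``.
    """
    from .pmf import UmbrellaWindow

    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    windows = []
    for entry in manifest["windows"]:
        data = np.loadtxt(directory / entry["file"], comments="#", ndmin=2)
        windows.append(UmbrellaWindow(
            center=entry["center_nm"],
            spring_k=entry["spring_k_kcal_mol_nm2"],
            samples=data[:, 1],
            sample_dt=entry["sample_dt_ns"]))
    return windows, manifest["temperature_K"]


# ----------------------------------------------------------------- PDB I/O

def read_trajectory(path, water_selection: str = "name OW OH2 O and resname "
                    "SOL HOH TIP3 WAT", protein_selection: str = "protein"):
    """Frames of water-oxygen and protein coordinates from a multi-model PDB.

    Returns ``(frames, protein)``: ``frames`` is a list of
    ``(time_ns, water_xyz_nm)`` pairs (frame index as time when the file has
    no time stamps) and ``protein`` a dict with ``coords`` per frame,
    ``names`` and ``elements``.  PDB coordinates (Angstrom) are converted
    to nm.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(path))
    water = u.select_atoms(water_selection)
    protein = u.select_atoms(protein_selection)
    frames, prot_coords = [], []
    for i, ts in enumerate(u.trajectory):
        t = float(i) if not np.isfinite(ts.time) else float(ts.time)
        frames.append((t, water.positions.astype(float) / 10.0))
        prot_coords.append(protein.positions.astype(float) / 10.0)
    elements = []
    for atom in protein:
        try:
            elements.append(atom.element)
        except Exception:
            elements.append(atom.name[0])
    return frames, {"coords": prot_coords,
                    "names": [a.name for a in protein],
                    "elements": elements}


def write_fixture_pdb(path, fixture) -> None:
    """Write a ring-atom pore fixture as a single-model PDB (nm -> Angstrom)."""
    with Path(path).open("w") as fh:
        for i, (x, y, z) in enumerate(fixture.coords, start=1):
            fh.write(f"ATOM  {i:5d}  C   POR A{1:4d}    "
                     f"{10 * x:8.3f}{10 * y:8.3f}{10 * z:8.3f}"
                     f"  1.00  0.00           C\n")
        fh.write("END\n")


# ------------------------------------------------------------ configuration

class ConfigError(ValueError):
    pass


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Validated pipeline configuration.

    ``stages`` holds one parameter block per requested stage (simulate,
    hydration, kinetics, gating); ``seed`` feeds every random stage;
    ``temperature`` (K) is required whenever a free energy is requested.
    """

    seed: int = 0
    temperature: float = DEFAULT_TEMPERATURE_K
    wet_threshold: float = WET_THRESHOLD_NM
    region: dict = field(default_factory=lambda: {
        "name": "MM", "z_lo": -0.95, "z_hi": 0.95, "cylinder_radius": 0.8})
    stages: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return {"seed": self.seed, "temperature": self.temperature,
                "wet_threshold": self.wet_threshold, "region": self.region,
                "stages": self.stages}

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def validate(self) -> None:
        if "kinetics" in self.stages and self.stages["kinetics"].get(
                "free_energy", True) and not self.temperature:
            raise ConfigError("kinetics free energies requested but "
                              "'temperature' is missing")
        if "simulate" in self.stages:
            sim = self.stages["simulate"]
            for key in ("n_traj", "duration", "dt"):
                if key not in sim:
                    raise ConfigError(f"simulate stage missing {key!r}")
            if sim["n_traj"] < 1:
                raise ConfigError("simulate.n_traj must be at least 1")
        if not self.stages:
            raise ConfigError("no stages configured")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def region_spec(self) -> hydration.RegionSpec:
        return hydration.RegionSpec(**self.region)


def pipeline_run(config: RunConfig, outdir) -> dict:
    """Run the configured stages in order and write the result bundle.

    Order: simulate -> hydration -> kinetics -> gating.  Every output file
    carries the config hash; a stage failure raises :class:`PipelineError`
    naming the stage, with earlier outputs preserved on disk.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = {"config_hash": config.config_hash, "stages": {}}
    region = config.region_spec()
    ensemble = None
    series = None

    def _run(stage, fn):
        t0 = _time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage name
            (outdir / "result.json").write_text(json.dumps(bundle, indent=2))
            raise PipelineError(stage, exc) from exc
        elapsed = _time.perf_counter() - t0
        logger.info("stage %s finished in %.2f s", stage, elapsed)
        bundle["stages"][stage] = {"seconds": round(elapsed, 3), **result}

    if "simulate" in config.stages:
        def _simulate():
            nonlocal ensemble
            p = dict(config.stages["simulate"])
            # YAML 1.1 reads "5.0e7" (no sign) as a string; coerce numerics
            model = synthetic.default_wetting_model(
                wetting_rate=float(p.pop("wetting_rate",
                                         synthetic.DEFAULT_WETTING_RATE)),
                wet_occupancy=float(p.pop("wet_occupancy", 0.01)),
                three_state=bool(p.pop("three_state", False)))
            ensemble = synthetic.simulate_wetting_ensemble(
                model, n_traj=int(p["n_traj"]), duration=float(p["duration"]),
                dt=float(p["dt"]), seed=config.seed,
                include_positions=bool(p.get("include_positions", False)))
            write_ensemble(outdir / "traces", ensemble,
                           extra_meta={"config_hash": config.config_hash})
            return {"n_traj": len(ensemble)}
        _run("simulate", _simulate)

    if "hydration" in config.stages:
        def _hydration():
            nonlocal series
            src = config.stages["hydration"].get("traces")
            traces = read_ensemble(src) if src else list(ensemble or ())
            if not traces:
                raise ConfigError("hydration stage has no input ensemble")
            series = []
            for tr in traces:
                if tr.water_z is not None:
                    series.append(hydration.hydration_series(
                        tr, region, config.wet_threshold))
                else:
                    series.append(hydration.HydrationSeries(
                        time=tr.time, n_wat=tr.n_wat, z_gap=tr.z_gap,
                        z_gap_center=np.full(len(tr.time), np.nan),
                        wet=tr.wet, threshold=config.wet_threshold,
                        source=tr.source))
            sdir = outdir / "series"
            sdir.mkdir(exist_ok=True)
            for s in series:
                write_series(sdir / f"{s.source}.tsv", s)
            fracs = [s.wet_fraction for s in series]
            return {"n_series": len(series),
                    "mean_wet_fraction": float(np.mean(fracs))}
        _run("hydration", _hydration)

    if "kinetics" in config.stages:
        def _kinetics():
            if series is None:
                raise ConfigError("kinetics stage requires a hydration stage")
            p = config.stages["kinetics"]
            censoring = p.get("censoring", "kaplan_meier")
            out = {}
            rates = {}
            for state, label in (("dry", "wetting"), ("wet", "dewetting")):
                try:
                    est = kinetics.ensemble_rates(series, state, censoring)
                except ValueError as exc:
                    out[f"{label}_rate_per_s"] = None
                    out[f"{label}_diagnostic"] = str(exc)
                    continue
                rates[state] = est
                out[f"{label}_rate_per_s"] = est.rate
                out[f"{label}_rate_sd_per_s"] = (
                    est.uncertainty if np.isfinite(est.uncertainty) else None)
                out[f"{label}_mean_lifetime_ns"] = est.fit.mean_lifetime
            if p.get("free_energy", True) and len(rates) == 2:
                out["dry_minus_wet_free_energy_kcal_mol"] = \
                    kinetics.state_free_energy(
                        rates["wet"].fit.integral, rates["dry"].fit.integral,
                        config.temperature)
                out["temperature_K"] = config.temperature
            (outdir / "kinetics.json").write_text(json.dumps(
                {"config_hash": config.config_hash, **out}, indent=2))
            return out
        _run("kinetics", _kinetics)

    if "gating" in config.stages:
        def _gating():
            p = config.stages["gating"]
            model = gating.model_from_coefficients(
                a=p.get("a"), b=p.get("b"), c=p.get("c"), m=p.get("m"),
                provenance=p.get("provenance", "N_wat(t0)"))
            out = {}
            if model.barrier_fit is not None:
                out["open_state_n_wat"] = gating.open_state_hydration(model)
                for n in p.get("predict_at", ()):
                    out[f"barrier_at_{n}_kcal_mol"] = \
                        gating.predict_barrier(model, n)
            if model.diameter_fit is not None and model.barrier_fit is not None:
                out["open_state_diameter_nm"] = gating.diameter_for_hydration(
                    model, out["open_state_n_wat"])
            (outdir / "gating.json").write_text(json.dumps(
                {"config_hash": config.config_hash, **out}, indent=2))
            return out
        _run("gating", _gating)

    (outdir / "result.json").write_text(json.dumps(bundle, indent=2))
    return bundle
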