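"""File formats, run configuration, pipeline orchestration, water counting.

Formats are deliberately plain text:

* COLVAR-style window files — ``#! FIELDS time z1 [z2]`` header, then
  whitespace-delimited rows, one per stored sample;
* window metadata — blank-line-separated key/value records
  (``file``, ``center_z1`` [, ``center_z2``], ``kappa``);
* gridded PMF — ``z1 [z2] F count`` rows, row-major, with a commented header
  recording bins, temperature, and the min-zero normalization;
* minima / path / profile tables as CSV; rate reports as JSON.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path as FsPath

import numpy as np
import pandas as pd
import yaml

from . import mfep as mfep_mod
from . import rates as rates_mod
from . import surface_tools
from . import wham as wham_mod
from .constants import DEFAULT_TEMPERATURE, kt
from .errors import ChainOverflowError, ConfigurationError, FormatError
from .landscapes import GaussianTerm, SyntheticSurface, UmbrellaWindow, \
    make_surface
from .mfep import NebSettings, Path
from .wham import PMFGrid

logger = logging.getLogger(__name__)

__all__ = ["AxialSnapshot", "RunConfig", "read_windows", "write_windows",
           "read_pmf", "write_pmf", "write_offsets", "read_minima",
           "write_minima", "write_path_csv", "read_path_csv",
           "write_profile_csv", "read_profile_csv", "write_rates_json",
           "surface_from_spec", "surface_to_spec", "run_pipeline",
           "waters_between_ions"]


# -- COLVAR windows ----------------------------------------------------------

def _cv_names(ndim):
    return [f"z{i + 1}" for i in range(ndim)]


def write_windows(directory, windows, metadata_file="windows.meta",
                  prefix="window"):
    """Write one COLVAR file per window plus the metadata index."""
    directory = FsPath(directory)
    directory.mkdir(parents=True, exist_ok=True)
    records = []
    for i, w in enumerate(windows):
        name = f"{prefix}_{i:04d}.colvar"
        names = _cv_names(w.ndim)
        with open(directory / name, "w") as fh:
            fh.write("#! FIELDS time " + " ".join(names) + "\n")
            for t, row in enumerate(w.samples):
                fh.write(f"{float(t):.1f} "
                         + " ".join(repr(float(v)) for v in row) + "\n")
        rec = [f"file: {name}"]
        rec += [f"center_{n}: {repr(float(c))}"
                for n, c in zip(names, w.centers)]
        rec.append(f"kappa: {repr(float(w.force_constant[0]))}")
        if w.seed is not None:
            rec.append(f"seed: {w.seed}")
        records.append("\n".join(rec))
    meta = directory / metadata_file
    meta.write_text("\n\n".join(records) + "\n")
    return meta


def _parse_meta(meta_path):
    records, current = [], {}
    for ln, line in enumerate(meta_path.read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            if current:
                records.append(current)
                current = {}
            continue
        if ":" not in line:
            raise FormatError(f"{meta_path}:{ln}: expected 'key: value'")
        key, _, val = line.partition(":")
        current[key.strip()] = val.strip()
    if current:
        records.append(current)
    return records


def read_windows(directory, metadata_file="windows.meta", cv_columns=None):
    """Read umbrella windows listed in a metadata file.

    ``cv_columns`` optionally maps CV order to 0-based numeric-column indices
    of the COLVAR files (default: columns 1..ndim, after the time column).
    """
    directory = FsPath(directory)
    meta_path = directory / metadata_file
    if not meta_path.exists():
        raise FileNotFoundError(f"metadata file {meta_path} not found")
    windows = []
    for rec in _parse_meta(meta_path):
        if "file" not in rec:
            raise FormatError(f"{meta_path}: record without 'file' key")
        centers = [float(v) for k, v in sorted(rec.items())
                   if k.startswith("center_")]
        if not centers:
            raise FormatError(f"{meta_path}: record {rec['file']} lists no "
                              "center_* keys")
        kappa = float(rec.get("kappa", 0.0))
        fpath = directory / rec["file"]
        if not fpath.exists():
            raise FileNotFoundError(f"window file {fpath} not found")
        cols = cv_columns if cv_columns is not None \
            else list(range(1, 1 + len(centers)))
        rows = []
        ncol = None
        for ln, line in enumerate(fpath.read_text().splitlines(), 1):
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            parts = s.split()
            if ncol is None:
                ncol = len(parts)
            elif len(parts) != ncol:
                raise FormatError(
                    f"{fpath}:{ln}: expected {ncol} columns, got {len(parts)}")
            if max(cols) >= len(parts):
                raise FormatError(
                    f"{fpath}:{ln}: CV column {max(cols)} out of range")
            try:
                rows.append([float(parts[c]) for c in cols])
            except ValueError as err:
                raise FormatError(f"{fpath}:{ln}: {err}") from err
        if not rows:
            raise FormatError(f"{fpath}: no samples")
        seed = int(rec["seed"]) if "seed" in rec else None
        windows.append(UmbrellaWindow(np.array(centers), kappa,
                                      np.array(rows), seed=seed))
        logger.info("read %d samples from %s", len(rows), fpath.name)
    return windows


# -- gridded PMF -------------------------------------------------------------

def write_pmf(path, pmf: PMFGrid):
    """Write a PMF grid as 'z1 [z2] F count' rows with a descriptive header."""
    path = FsPath(path)
    names = _cv_names(pmf.ndim)
    centers = pmf.centers
    with open(path, "w") as fh:
        fh.write(f"# pmfpath PMF grid, bins per CV: "
                 f"{' '.join(str(len(c)) for c in centers)}\n")
        fh.write(f"# temperature_K: {pmf.temperature}\n")
        fh.write("# normalization: sampled minimum = 0 kJ/mol; "
                 "unsampled bins are nan\n")
        fh.write("# columns: " + " ".join(names) + " F_kJ_mol count\n")
        mesh = np.meshgrid(*centers, indexing="ij")
        flat = [m.ravel() for m in mesh]
        for i in range(len(flat[0])):
            coords = " ".join(repr(float(c[i])) for c in flat)
            fh.write(f"{coords} {repr(float(pmf.free_energy.ravel()[i]))} "
                     f"{int(pmf.counts.ravel()[i])}\n")
    return path


def read_pmf(path) -> PMFGrid:
    path = FsPath(path)
    temperature = DEFAULT_TEMPERATURE
    data = []
    for line in path.read_text().splitlines():
        s = line.strip()
        if s.startswith("# temperature_K:"):
            temperature = float(s.split(":")[1])
        if not s or s.startswith("#"):
            continue
        data.append([float(v) for v in s.split()])
    arr = np.array(data)
    ndim = arr.shape[1] - 2
    axes = [np.unique(arr[:, d]) for d in range(ndim)]
    shape = tuple(len(a) for a in axes)
    free = arr[:, ndim].reshape(shape)
    counts = arr[:, ndim + 1].reshape(shape)
    edges = []
    for a in axes:
        step = a[1] - a[0] if len(a) > 1 else 1.0
        edges.append(np.concatenate([a - step / 2, [a[-1] + step / 2]]))
    return PMFGrid(edges=edges, free_energy=free, counts=counts,
                   temperature=temperature)


def write_offsets(path, result):
    with open(path, "w") as fh:
        fh.write("# window free-energy offsets f_k (kJ/mol), f_0 = 0\n")
        fh.write(f"# iterations: {result.n_iterations} "
                 f"final_change_kJ_mol: {result.final_change!r} "
                 f"reliable: {result.reliable_offsets}\n")
        for i, f in enumerate(result.window_offsets):
            fh.write(f"{i} {repr(float(f))}\n")


# -- tables ------------------------------------------------------------------

def write_minima(path, minima):
    df = pd.DataFrame({
        "index": [m.index for m in minima],
        **{f"z{d + 1}": [float(m.location[d]) for m in minima]
           for d in range(len(minima[0].location))},
        "F_kJ_mol": [m.energy for m in minima],
        "label": [m.label or "" for m in minima],
    })
    df.to_csv(path, index=False)
    return path


def read_minima(path):
    df = pd.read_csv(path, keep_default_na=False)
    zcols = [c for c in df.columns if c.startswith("z")]
    return [surface_tools.Minimum(
        location=np.array([row[c] for c in zcols]),
        energy=float(row["F_kJ_mol"]), index=int(row["index"]),
        label=str(row["label"]) or None) for _, row in df.iterrows()]


def write_path_csv(path, p: Path):
    lam = p.arc_length
    df = pd.DataFrame({
        "node": np.arange(len(p.nodes)),
        **{f"z{d + 1}": p.nodes[:, d] for d in range(p.nodes.shape[1])},
        "lambda_nm": lam,
        "F_kJ_mol": p.energies,
    })
    df.to_csv(path, index=False)
    return path


def read_path_csv(path, endpoints=(None, None), converged=True) -> Path:
    df = pd.read_csv(path)
    zcols = [c for c in df.columns if c.startswith("z")]
    return Path(nodes=df[zcols].to_numpy(),
                energies=df["F_kJ_mol"].to_numpy(),
                endpoints=tuple(endpoints), converged=converged,
                max_force_residual=np.nan)


def write_profile_csv(path, profile):
    marker = np.array([""] * len(profile.lam), dtype=object)
    for kind, i in profile.markers:
        marker[i] = kind
    pd.DataFrame({"lambda_nm": profile.lam,
                  "F_kJ_mol": profile.free_energy,
                  "marker": marker}).to_csv(path, index=False)
    return path


def read_profile_csv(path):
    df = pd.read_csv(path, keep_default_na=False)
    markers = [(str(row["marker"]), i) for i, row in df.iterrows()
               if row["marker"]]
    return mfep_mod.Profile1D(lam=df["lambda_nm"].to_numpy(),
                              free_energy=df["F_kJ_mol"].to_numpy(),
                              markers=markers)


def write_rates_json(path, report: dict):
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return path


def chain_report(chain, rate=None) -> dict:
    """JSON-serializable summary of a rate chain."""
    def ext(e):
        return {"kind": e.kind, "lambda_nm": e.lam,
                "F_kJ_mol": e.free_energy, "omega": e.curvature_omega,
                "fit_window_nm": e.fit_window,
                "fit_residual_kJ_mol": e.fit_residual}

    rep = {
        "kT_kJ_mol": chain.kT,
        "valleys": [ext(e) for e in chain.valleys],
        "peaks": [ext(e) for e in chain.peaks],
        "barriers_forward_kJ_mol": list(map(float, chain.barriers_forward))
        if chain.barriers_forward is not None else None,
        "barriers_backward_kJ_mol": list(map(float, chain.barriers_backward))
        if chain.barriers_backward is not None else None,
        "log_forward_rates": list(map(float, chain.log_forward)),
        "log_backward_rates": list(map(float, chain.log_backward)),
    }
    if rate is not None:
        rep["total_rate"] = {"log_value": rate.log_value,
                             "value": rate.value,
                             "is_upper_bound": rate.is_bound}
    return rep


# -- surface specifications --------------------------------------------------

def surface_from_spec(spec: dict) -> SyntheticSurface:
    """Build a surface from a parsed specification dictionary.

    Layout: ``{terms: [{amplitude, center, widths}...], domain: [[lo,hi]...],
    baseline: 0.0}``.
    """
    unknown = set(spec) - {"terms", "domain", "baseline"}
    if unknown:
        raise ConfigurationError(f"unknown surface keys: {sorted(unknown)}")
    try:
        terms = [GaussianTerm(float(t["amplitude"]),
                              tuple(map(float, t["center"])),
                              tuple(map(float, t["widths"])))
                 for t in spec["terms"]]
        domain = [tuple(map(float, d)) for d in spec["domain"]]
    except (KeyError, TypeError) as err:
        raise ConfigurationError(f"malformed surface spec: {err}") from err
    return make_surface(terms, domain, baseline=float(spec.get("baseline", 0.0)))


def surface_to_spec(surface: SyntheticSurface) -> dict:
    return {"terms": [{"amplitude": t.amplitude, "center": list(t.center),
                       "widths": list(t.widths)} for t in surface.terms],
            "domain": [list(d) for d in surface.domain],
            "baseline": surface.baseline}


# -- run configuration and pipeline ------------------------------------------

@dataclass
class RunConfig:
    """Resolved settings for one end-to-end pipeline run."""

    windows_dir: str
    metadata_file: str = "windows.meta"
    output_dir: str = "pmfpath_out"
    seed: int = 0
    # WHAM
    n_bins: int = 100
    wham_tolerance: float = 1e-6
    wham_max_iterations: int = 100_000
    temperature: float = DEFAULT_TEMPERATURE
    # minima / interpolation
    min_separation: float = 0.1
    max_energy: float | None = None
    min_persistence: float = 2.0  # kJ/mol; suppress histogram-noise minima
    smoothing: object = "auto"  # spline smoothing: 0, float, or "auto"
    # NEB
    n_images: int = 32
    spring_constant: float = 500.0
    neb_max_iterations: int = 5000
    force_tolerance: float = 0.5
    # projection / rates
    min_prominence: float = 0.5
    fit_window: float | None = None
    curvature_convention: str = "peak"
    start_state: int | None = None
    end_state: int | None = None
    max_paths: int = 10

    _SECTIONS = {
        "input": {"windows_dir", "metadata_file"},
        "output": {"output_dir", "seed"},
        "wham": {"n_bins", "wham_tolerance", "wham_max_iterations",
                 "temperature"},
        "minima": {"min_separation", "max_energy", "min_persistence",
                   "smoothing"},
        "neb": {"n_images", "spring_constant", "neb_max_iterations",
                "force_tolerance"},
        "rates": {"min_prominence", "fit_window", "curvature_convention",
                  "start_state", "end_state", "max_paths"},
    }

    def __post_init__(self):
        if self.n_bins < 2:
            raise ConfigurationError("n_bins must be at least 2")
        if self.wham_tolerance <= 0 or self.force_tolerance <= 0:
            raise ConfigurationError("tolerances must be positive")
        if self.temperature <= 0:
            raise ConfigurationError("temperature must be positive")
        if self.min_separation < 0 or self.min_prominence < 0:
            raise ConfigurationError("separation/prominence must be >= 0")
        if self.n_images < 3:
            raise ConfigurationError("n_images must be at least 3")
        if not (self.smoothing == "auto"
                or (isinstance(self.smoothing, (int, float))
                    and self.smoothing >= 0)):
            raise ConfigurationError("smoothing must be 'auto' or a "
                                     "non-negative number")
        if self.curvature_convention not in ("peak", "valley"):
            raise ConfigurationError("curvature_convention must be "
                                     "'peak' or 'valley'")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        fields = {f.name for f in dataclasses.fields(cls)
                  if not f.name.startswith("_")}
        flat = {}
        for key, val in raw.items():
            if key in cls._SECTIONS:
                if not isinstance(val, dict):
                    raise ConfigurationError(f"section {key!r} must be a map")
                for sub, sval in val.items():
                    if sub not in cls._SECTIONS[key]:
                        raise ConfigurationError(
                            f"unknown key {key}.{sub!r} in configuration")
                    flat[sub] = sval
            elif key in fields:
                flat[key] = val
            else:
                raise ConfigurationError(f"unknown key {key!r} in configuration")
        if "windows_dir" not in flat:
            raise ConfigurationError("configuration must set windows_dir")
        return cls(**flat)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(FsPath(path).read_text()) or {}
        return cls.from_dict(raw)

    def to_yaml(self, path):
        FsPath(path).write_text(yaml.safe_dump(dataclasses.asdict(self),
                                               sort_keys=True))


def _pick_endpoints(graph, minima, config):
    if config.start_state is not None and config.end_state is not None:
        return config.start_state, config.end_state
    # default: the most distant connected pair of minima in CV space
    import networkx as nx
    best, pair = -1.0, None
    for i, mi in enumerate(minima):
        for mj in minima[i + 1:]:
            if not nx.has_path(graph, mi.index, mj.index):
                continue
            d = float(np.linalg.norm(mi.location - mj.location))
            if d > best:
                best, pair = d, (mi.index, mj.index)
    if pair is None:
        raise ConfigurationError("no connected pair of minima to bridge")
    return pair


def run_pipeline(config: RunConfig) -> dict:
    """Windows → WHAM → minima → MFEP → 1D profile → rate chain → reports.

    Writes the PMF grid, offsets, minima table, ranked paths, profile and
    rate JSON into ``config.output_dir`` together with the resolved config,
    and returns the in-memory report bundle.  When the rate chain overflows
    the ODE solver, the rate-limiting upper bound is reported and flagged.
    """
    out = FsPath(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    report = {"warnings": []}

    def stage(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        try:
            result = fn(*args, **kwargs)
        except Exception as err:
            logger.error("stage %s failed: %s", name, err)
            raise
        logger.info("stage %-10s done in %.2fs", name, time.perf_counter() - t0)
        return result

    windows = stage("read", read_windows, config.windows_dir,
                    config.metadata_file)
    wres = stage("wham", wham_mod.wham, windows, n_bins=config.n_bins,
                 tolerance=config.wham_tolerance,
                 max_iterations=config.wham_max_iterations,
                 temperature=config.temperature)
    if not wres.reliable_offsets:
        report["warnings"].append("non-overlapping window clusters")
    write_pmf(out / "pmf.txt", wres.pmf)
    write_offsets(out / "offsets.txt", wres)

    interp = surface_tools.interpolate(wres.pmf, smoothing=config.smoothing)
    minima = stage("minima", surface_tools.find_minima, interp,
                   min_separation=config.min_separation,
                   max_energy=config.max_energy,
                   min_persistence=config.min_persistence)
    if len(minima) < 2:
        raise ConfigurationError("fewer than two minima found on the PMF")
    write_minima(out / "minima.csv", minima)

    settings = NebSettings(n_images=config.n_images,
                           spring_constant=config.spring_constant,
                           max_iterations=config.neb_max_iterations,
                           force_tolerance=config.force_tolerance)
    graph = stage("snippets", mfep_mod.build_path_graph, interp, minima,
                  neb_settings=settings)
    start, end = _pick_endpoints(graph, minima, config)
    paths = stage("paths", mfep_mod.enumerate_paths, graph, start, end,
                  max_paths=config.max_paths)
    for rank, p in enumerate(paths):
        write_path_csv(out / f"path_{rank:02d}.csv", p)
    profile = stage("project", mfep_mod.project_1d, paths[0],
                    min_prominence=config.min_prominence)
    write_profile_csv(out / "profile.csv", profile)

    chain = stage("chain", rates_mod.build_chain, profile,
                  kT=kt(config.temperature), fit_window=config.fit_window,
                  convention=config.curvature_convention)
    try:
        occ = stage("solve", rates_mod.solve_chain, chain)
        rate = rates_mod.total_rate(occ)
    except ChainOverflowError as err:
        report["warnings"].append(f"rate chain overflow: {err}")
        rate = rates_mod.rate_limiting_bound(chain)
        occ = None
    rep = chain_report(chain, rate)
    rep["endpoints"] = [start, end]
    rep["warnings"] = report["warnings"]
    write_rates_json(out / "rates.json", rep)

    report.update({"wham": wres, "minima": minima, "paths": paths,
                   "profile": profile, "chain": chain, "rate": rate,
                   "occupancy": occ, "output_dir": str(out)})
    return report


# -- water-between-ions observable -------------------------------------------

@dataclass
class AxialSnapshot:
    """Axial (z) coordinates of filter ions and waters for one frame."""

    ions: np.ndarray  # nm, sorted ascending
    waters: np.ndarray  # nm
    frame: int = 0

    def __post_init__(self):
        self.ions = np.asarray(self.ions, dtype=float)
        self.waters = np.asarray(self.waters, dtype=float)
        if len(self.ions) == 0:
            raise ValueError("snapshot needs at least one ion")
        if not np.all(np.isfinite(self.ions)) \
                or not np.all(np.isfinite(self.waters)):
            raise ValueError("coordinates must be finite")


def waters_between_ions(snapshot, lower_bound, upper_bound):
    """Water counts strictly between each adjacent ion pair inside a region.

    Only ion pairs whose members both lie in [lower_bound, upper_bound] are
    counted; ions must be sorted ascending.
    """
    if isinstance(snapshot, AxialSnapshot):
        ions, waters = snapshot.ions, snapshot.waters
    else:
        ions, waters = (np.asarray(a, dtype=float) for a in snapshot)
    if np.any(np.diff(ions) < 0):
        raise ValueError("ion coordinates must be sorted ascending")
    waters = np.sort(waters)
    counts = []
    for zlo, zhi in zip(ions[:-1], ions[1:]):
        if zlo < lower_bound or zhi > upper_bound:
            continue
        n = int(np.searchsorted(waters, zhi, side="left")
                - np.searchsorted(waters, zlo, side="right"))
        counts.append(max(0, n))  # coincident ions bracket nothing
    return counts
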