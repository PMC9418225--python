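"""Readers, writers and run configuration.

Formats:

* Label rasters: NIfTI (integer volume, zooms interpreted in the unit
  given by ``units``) or a small self-describing whitespace text format.
* Vessel trees: the versioned JSON schema of :mod:`.vessels`.
* Field exports: legacy ASCII VTK structured-points (cell data) for 3D
  rasters, CSV for nodal/element tables, JSON for balance reports and
  the run manifest.  Every export names its units.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .domain import Material, VoxelGrid
from .errors import ConfigurationError
from .flow import FlowParams, FlowSolution
from .heat import MODE_HB, ThermalParams, ThermalSolution
from .pipeline import Problem, solve_problem
from .vessels import load_tree_json

__all__ = [
    "read_raster_text", "write_raster_text", "read_raster_nifti",
    "write_vtk_structured_points", "RunConfig", "load_problem", "run_pipeline",
]

_RASTER_MAGIC = "# vasotherm-raster-v1"
_LABEL_LEGEND = " ".join(f"{m.name}={int(m)}" for m in Material)


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

def write_raster_text(grid: VoxelGrid, path) -> None:
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write(_RASTER_MAGIC + "\n")
        fh.write(f"shape {nx} {ny} {nz}\n")
        fh.write(f"spacing_m {grid.spacing[0]:.12g} {grid.spacing[1]:.12g} "
                 f"{grid.spacing[2]:.12g}\n")
        fh.write(f"labels {_LABEL_LEGEND}\n")
        flat = grid.labels.reshape(nx * ny, nz)
        for row in flat:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")


def read_raster_text(path) -> VoxelGrid:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != _RASTER_MAGIC:
        raise ConfigurationError(f"{path}: not a vasotherm raster (bad magic)")
    header = {}
    i = 1
    while i < len(lines) and not lines[i].lstrip("-").strip()[:1].isdigit():
        key, *rest = lines[i].split()
        header[key] = rest
        i += 1
    try:
        shape = tuple(int(v) for v in header["shape"])
        spacing = tuple(float(v) for v in header["spacing_m"])
    except KeyError as exc:
        raise ConfigurationError(f"{path}: raster header missing {exc}") from exc
    data = np.loadtxt(lines[i:], dtype=np.int8).reshape(shape)
    return VoxelGrid(shape, spacing, data)


def read_raster_nifti(path, units: str = "mm", background_label: int = 0) -> VoxelGrid:
    """Load an integer label volume from NIfTI.

    ``units`` gives the unit of the header zooms (mm by default);
    ``background_label`` is remapped to EXTERIOR.
    """
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.dataobj).astype(np.int16)
    if data.ndim != 3:
        raise ConfigurationError(f"{path}: expected a 3D label volume")
    scale = {"m": 1.0, "mm": 1e-3, "um": 1e-6}.get(units)
    if scale is None:
        raise ConfigurationError(f"unknown unit {units!r}")
    spacing = tuple(float(z) * scale for z in img.header.get_zooms()[:3])
    labels = np.where(data == background_label, int(Material.EXTERIOR), data)
    valid = {int(m) for m in Material}
    found = set(np.unique(labels).tolist())
    if not found <= valid:
        raise ConfigurationError(
            f"{path}: unknown label values {sorted(found - valid)}; expected "
            f"{_LABEL_LEGEND}"
        )
    return VoxelGrid(data.shape, spacing, labels.astype(np.int8))


# ---------------------------------------------------------------------------
# VTK legacy structured points (cell data; voxel fields)
# ---------------------------------------------------------------------------

def write_vtk_structured_points(path, grid: VoxelGrid, fields: dict[str, np.ndarray],
                                comment: str = "vasotherm fields (SI units, deg C)"):
    nx, ny, nz = grid.shape
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write(comment[:255] + "\n")
        fh.write("ASCII\nDATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}\n")
        fh.write(f"SPACING {grid.spacing[0]:.9g} {grid.spacing[1]:.9g} "
                 f"{grid.spacing[2]:.9g}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"CELL_DATA {nx * ny * nz}\n")
        for name, arr in fields.items():
            a = np.asarray(arr, dtype=float)
            if a.shape != grid.shape:
                raise ConfigurationError(
                    f"field {name!r} shape {a.shape} != grid shape {grid.shape}"
                )
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            flat = a.ravel(order="F")  # VTK expects x varying fastest
            flat = np.where(np.isfinite(flat), flat, -9999.0)
            for chunk in range(0, flat.size, 9):
                fh.write(" ".join(f"{v:.9g}" for v in flat[chunk:chunk + 9]) + "\n")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Complete run description; round-trips losslessly through YAML."""

    raster: str
    artery: str
    vein: str
    output_dir: str = "out"
    epsilon: float = 10e-3
    flow: FlowParams = field(default_factory=FlowParams)
    thermal: ThermalParams = field(default_factory=ThermalParams)
    mode: str = "custom"       # pbm | wjm | custom
    tol: float = 1e-8
    max_iter: int = 2000
    preconditioner: str = "ilu"
    method: str = "auto"
    dense_threshold: int = 4000
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.mode in MODE_HB:
            self.thermal = dataclasses.replace(self.thermal, h_b=MODE_HB[self.mode])
        elif self.mode != "custom":
            raise ConfigurationError(f"unknown mode {self.mode!r}")

    # ---- (de)serialization ---------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        problems = []
        for key, typ in (("flow", FlowParams), ("thermal", ThermalParams)):
            sub = d.get(key, {})
            known = {f.name for f in dataclasses.fields(typ)}
            extra = set(sub) - known
            if extra:
                problems.append(f"{key}: unknown keys {sorted(extra)}")
            else:
                d[key] = typ(**sub)
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(d) - known
        if extra:
            problems.append(f"top level: unknown keys {sorted(extra)}")
        if problems:
            raise ConfigurationError("bad config: " + "; ".join(problems))
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a mapping")
        cfg = cls.from_dict(data)
        return cfg

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def load_problem(config: RunConfig, base_dir=".") -> Problem:
    """Load and validate a full problem from a run configuration.

    All validation failures are collected and reported together.
    """
    base = Path(base_dir)
    errors = []
    grid = artery = vein = None
    raster_path = base / config.raster
    try:
        if raster_path.suffix in (".nii", ".gz"):
            grid = read_raster_nifti(raster_path)
        else:
            grid = read_raster_text(raster_path)
    except (OSError, ConfigurationError, ValueError) as exc:
        errors.append(f"raster {config.raster}: {exc}")
    for attr, kind in (("artery", "artery"), ("vein", "vein")):
        try:
            tree = load_tree_json(base / getattr(config, attr))
            if tree.kind != kind:
                raise ConfigurationError(f"tree kind is {tree.kind!r}, expected {kind!r}")
            if attr == "artery":
                artery = tree
            else:
                vein = tree
        except (OSError, ConfigurationError, json.JSONDecodeError) as exc:
            errors.append(f"{attr} tree {getattr(config, attr)}: {exc}")
    if errors:
        raise ConfigurationError("problem failed to load:\n  " + "\n  ".join(errors))
    return Problem(grid, artery, vein, config.epsilon, config.flow, config.thermal)


def run_pipeline(config: RunConfig, base_dir=".") -> dict:
    """Run flow + heat and write all artifacts to the output directory.

    Writes VTK volumes (pressures, source/sink rates, perfusion flux,
    temperature), CSV tables (node pressures in Pa, element flows in
    m^3/s, element temperatures in deg C, voxel temperatures), JSON
    balance reports, and a machine-readable manifest.  Returns the
    manifest dict.
    """
    problem = load_problem(config, base_dir)
    out = Path(base_dir) / config.output_dir
    out.mkdir(parents=True, exist_ok=True)
    result = solve_problem(
        problem, tol=config.tol, method=config.method,
        preconditioner=config.preconditioner, maxiter=config.max_iter,
        dense_threshold=config.dense_threshold,
    )
    write_flow_outputs(result.flow, out)
    write_thermal_outputs(result.heat, out)
    with open(out / "mass_balance.json", "w") as fh:
        json.dump(_jsonable(result.mass_balance), fh, indent=1)
    with open(out / "energy_balance.json", "w") as fh:
        json.dump(_jsonable(result.energy_balance), fh, indent=1)
    manifest = {
        "package_version": _pkg_version,
        "config_hash": config.content_hash(),
        "config": config.to_dict(),
        "flow_solver": _jsonable(_trim_info(result.flow.solver_info)),
        "heat_solver": _jsonable(_trim_info(result.heat.solver_info)),
        "energy_residual_W": result.heat.energy_residual,
        "mass_mismatch_relative": result.mass_balance["global_mismatch_relative"],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def write_flow_outputs(flow: FlowSolution, out: Path) -> None:
    grid = flow.grid
    write_vtk_structured_points(
        out / "flow.vtk", grid,
        {"P_a_Pa": flow.P_a, "P_v_Pa": flow.P_v, "Q_a_m3s": flow.Q_a,
         "Q_v_m3s": flow.Q_v, "u_perf": flow.u_perf},
        comment="compartment pressures (Pa), source/sink rates (m3/s)",
    )
    pd.DataFrame(
        [{"kind": k, "node": n, "pressure_Pa": p}
         for (k, n), p in sorted(flow.node_pressures.items())]
    ).to_csv(out / "node_pressures.csv", index=False)
    pd.DataFrame(
        [{"kind": k, "element": e, "flow_m3s": q}
         for (k, e), q in sorted(flow.element_flows.items())]
    ).to_csv(out / "element_flows.csv", index=False)


def write_thermal_outputs(heat: ThermalSolution, out: Path) -> None:
    grid = heat.system.grid
    write_vtk_structured_points(
        out / "temperature.vtk", grid,
        {"T_degC": heat.element_raster()},
        comment="temperature (deg C); element temperatures broadcast to member voxels",
    )
    pd.DataFrame(
        [{"kind": k, "element": e, "T_degC": t}
         for (k, e), t in sorted(heat.T_elem.items())]
    ).to_csv(out / "element_temperatures.csv", index=False)
    tl = heat.system.tissue_linear
    pd.DataFrame(
        {"voxel_linear_index": tl, "T_degC": heat.x[: tl.size]}
    ).to_csv(out / "voxel_temperatures.csv", index=False)


def _trim_info(info: dict) -> dict:
    return {k: v for k, v in info.items() if k != "residual_history"} | {
        "final_residual_history_tail": info.get("residual_history", [])[-3:]
    }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
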