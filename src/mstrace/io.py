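"""Persistent container format, run configuration and fixture presets.

Runs are stored in a single hierarchical HDF5 file: the grid and its
physical attributes, the dense matrices (complex values split into paired
real/imag float64 datasets for maximal portability), the plate stack, the
object map, and — after reconstruction — the accumulated phase maps, the
rectified image and the per-cycle metric traces.  Reading then writing a
container reproduces every dataset bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .optics import FieldGrid, ReflectionMatrix, ValidationError, make_grid
from .synthesis import MediumModel, ObjectMap, PhasePlate

SCHEMA_VERSION = 1


# --------------------------------------------------------------------------
# low-level helpers
# --------------------------------------------------------------------------

def _write_complex(group: h5py.Group, name: str, values: np.ndarray) -> None:
    sub = group.create_group(name)
    sub.create_dataset("real", data=np.ascontiguousarray(values.real),
                       dtype="f8")
    sub.create_dataset("imag", data=np.ascontiguousarray(values.imag),
                       dtype="f8")


def _read_complex(group: h5py.Group, name: str) -> np.ndarray:
    sub = group[name]
    return sub["real"][()] + 1j * sub["imag"][()]


def _write_grid(f: h5py.File, grid: FieldGrid) -> None:
    g = f.require_group("grid")
    g.attrs["n"] = grid.n
    g.attrs["pitch_um"] = grid.pitch
    g.attrs["wavelength_um"] = grid.wavelength
    g.attrs["na"] = grid.na


def _read_grid(f: h5py.File) -> FieldGrid:
    g = f["grid"]
    return make_grid(int(g.attrs["n"]), float(g.attrs["pitch_um"]),
                     float(g.attrs["wavelength_um"]), float(g.attrs["na"]))


# --------------------------------------------------------------------------
# container
# --------------------------------------------------------------------------

class Container:
    """Read/write facade over the run container file."""

    def __init__(self, path: str | Path):
        self.path = Path(path)

    # -- writing ------------------------------------------------------------
    def write_simulation(self, grid: FieldGrid, medium: MediumModel,
                         obj: ObjectMap, r: ReflectionMatrix,
                         meta: dict | None = None) -> None:
        with h5py.File(self.path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            _write_grid(f, grid)
            plates = f.create_group("plates")
            for k, plate in enumerate(medium.plates):
                d = plates.create_dataset(f"{k}", data=plate.wrapped(),
                                          dtype="f8")
                d.attrs["depth_um"] = plate.depth
                d.attrs["pitch_um"] = plate.pitch
            _write_complex(f, "object", obj.amplitude_reflectance)
            m = f.create_group("matrices")
            _write_complex(m, "R", r.values)
            m["R"].attrs["input_plane_um"] = r.input_plane
            m["R"].attrs["output_plane_um"] = r.output_plane
            m["R"].attrs["basis"] = r.basis
            m["R"].attrs["time_gated"] = r.time_gated
            f.create_group("meta").attrs["json"] = json.dumps(meta or {})

    def append_mst(self, result, extra_meta: dict | None = None) -> None:
        """Store an MSTResults (or raw MSTResult) under /mst."""
        with h5py.File(self.path, "a") as f:
            if "mst" in f:
                del f["mst"]
            g = f.create_group("mst")
            phases = (result.layer_phases if hasattr(result, "layer_phases")
                      else result.accumulated_phases)
            for k, phi in enumerate(phases):
                wrapped = np.angle(np.exp(1j * phi))
                d = g.create_dataset(f"phase_c_{k}", data=wrapped, dtype="f8")
                d.attrs["units"] = "rad"
                g.create_dataset(f"phase_c_unwrapped_{k}", data=phi,
                                 dtype="f8")
            g.create_dataset("image", data=result.mst_image, dtype="f8")
            _write_complex(g, "object_estimate",
                           np.asarray(result.object_estimate))
            g.create_dataset("xi1_trace", data=np.asarray(result.xi1_trace))
            g.create_dataset("xi2_trace", data=np.asarray(result.xi2_trace))
            g.attrs["converged"] = bool(result.converged)
            g.attrs["cycles_run"] = int(result.cycles_run)
            if extra_meta:
                g.attrs["json"] = json.dumps(extra_meta)

    # -- reading ------------------------------------------------------------
    def read_grid(self) -> FieldGrid:
        with h5py.File(self.path, "r") as f:
            return _read_grid(f)

    def read_reflection(self) -> ReflectionMatrix:
        with h5py.File(self.path, "r") as f:
            if "matrices" not in f or "R" not in f["matrices"]:
                raise ValidationError(
                    f"container {self.path} is missing /matrices/R")
            grid = _read_grid(f)
            node = f["matrices"]["R"]
            return ReflectionMatrix(
                values=_read_complex(f["matrices"], "R"), grid=grid,
                basis=str(node.attrs["basis"]),
                input_plane=float(node.attrs["input_plane_um"]),
                output_plane=float(node.attrs["output_plane_um"]),
                time_gated=bool(node.attrs["time_gated"]))

    def read_medium(self) -> MediumModel:
        with h5py.File(self.path, "r") as f:
            grid = _read_grid(f)
            plates = []
            for k in sorted(f["plates"], key=int):
                node = f["plates"][k]
                plates.append(PhasePlate(
                    phase_map=node[()], depth=float(node.attrs["depth_um"]),
                    pitch=float(node.attrs["pitch_um"])))
            return MediumModel(grid=grid, plates=plates)

    def read_object(self) -> ObjectMap:
        with h5py.File(self.path, "r") as f:
            grid = _read_grid(f)
            return ObjectMap(grid, _read_complex(f, "object"))

    def read_mst(self) -> dict:
        with h5py.File(self.path, "r") as f:
            if "mst" not in f:
                raise ValidationError(
                    f"container {self.path} has no /mst group "
                    "(run the reconstruction first)")
            g = f["mst"]
            phases = []
            k = 0
            while f"phase_c_unwrapped_{k}" in g:
                phases.append(g[f"phase_c_unwrapped_{k}"][()])
                k += 1
            return {
                "phases": phases,
                "image": g["image"][()],
                "object_estimate": _read_complex(g, "object_estimate"),
                "xi1_trace": list(g["xi1_trace"][()]),
                "xi2_trace": list(g["xi2_trace"][()]),
                "converged": bool(g.attrs["converged"]),
                "cycles_run": int(g.attrs["cycles_run"]),
            }

    def read_meta(self) -> dict:
        with h5py.File(self.path, "r") as f:
            return json.loads(f["meta"].attrs.get("json", "{}"))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

_SIM_KEYS = {"grid_n", "pitch_um", "wavelength_um", "na", "layer_depths_um",
             "correlation_length_um", "target_optical_depth", "phase_std_rad",
             "object_kind", "object_params", "overlays", "seed",
             "background_relative_power", "background_correlation_length_um"}
_MST_KEYS = {"layer_depths_um", "max_cycles", "phase_increment_tolerance_rad",
             "power_iteration_max_steps", "power_iteration_tolerance",
             "fov_masking", "layer_order", "compute_traces"}


@dataclass
class RunConfig:
    """Validated simulate/reconstruct configuration.

    Unknown keys are rejected; every physical quantity carries its unit in
    the key name.
    """

    simulation: dict = dc_field(default_factory=dict)
    mst: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = set(self.simulation) - _SIM_KEYS
        if bad:
            raise ValidationError(
                f"unknown simulation keys: {sorted(bad)}")
        bad = set(self.mst) - _MST_KEYS
        if bad:
            raise ValidationError(f"unknown mst keys: {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {"simulation", "mst"}
        if unknown:
            raise ValidationError(f"unknown config sections: {sorted(unknown)}")
        return cls(simulation=data.get("simulation", {}),
                   mst=data.get("mst", {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"simulation": self.simulation, "mst": self.mst},
                           fh, sort_keys=True)


# --------------------------------------------------------------------------
# fixture presets
# --------------------------------------------------------------------------

def fixture_generator(scale: str, seed: int) -> tuple[RunConfig, dict]:
    """Deterministic study presets plus an expectation manifest.

    ``tiny`` (16^2, one plate) exercises the full pipeline in seconds;
    ``small`` (32^2, two plates) is the integration scale; ``reference``
    (64^2, the four-plate stack at depths 35/50/70/100 um calibrated to a
    one-way thickness of 3.3 mean free paths) is the headline numerical
    phantom.  The manifest lists which checks are meaningful at each scale.
    """
    presets = {
        "tiny": dict(grid_n=16, layers=[8.0], od=0.8, cycles=8, ell=2.5),
        "small": dict(grid_n=32, layers=[12.0, 20.0], od=1.2, cycles=10,
                      ell=2.5),
        # correlation length follows the resolvability-regime scaling of
        # the reference phantom (1.3 um at a 45 um ROI)
        "reference": dict(grid_n=64, layers=[35.0, 50.0, 70.0, 100.0], od=3.3,
                      cycles=12, ell=1.3 * 45.0 / (64 * 0.45)),
    }
    if scale not in presets:
        raise ValidationError(f"unknown fixture scale {scale!r}")
    p = presets[scale]
    cfg = RunConfig(
        simulation={
            "grid_n": p["grid_n"], "pitch_um": 0.45, "wavelength_um": 0.9,
            "na": 1.0, "layer_depths_um": p["layers"],
            "correlation_length_um": p["ell"],
            "target_optical_depth": p["od"],
            "object_kind": "siemens_star",
            "object_params": {"n_spokes": 8}, "seed": int(seed),
        },
        mst={"max_cycles": p["cycles"]},
    )
    manifest = {
        "scale": scale,
        "checks": {
            "exact_inversion": True,
            "single_plate_recovery": scale in ("tiny", "small"),
            "headline_targets": scale == "reference",
        },
    }
    return cfg, manifest
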