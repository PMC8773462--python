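"""Scenario configuration, presets, and end-to-end runs.

A :class:`ScenarioConfig` bundles exactly one geometry source (generated
sphere shell, generated cell-like body, or a mesh file), the signaling
parameters, the numerical controls, and probe locations.  Configurations
round-trip through YAML with explicit unit suffixes on every physical key
(``D_um2_per_s``, ``beta_uM_um_per_s``, ...) so that units cannot silently
drift.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mesh_io
from .analytic import compartmental_timecourse, membrane_flux_equivalent
from .dynamics import SignalingParameters, SimulationConfig, TimeCourse, simulate
from .generate import generate_cell_like_mesh, generate_sphere_shell_mesh
from .mesh import TetMesh, probe_nodes

__all__ = [
    "ScenarioConfig",
    "ScenarioError",
    "PRESETS",
    "preset",
    "build_geometry",
    "run_scenario",
    "convergence_study",
]

log = logging.getLogger("campfem")

# reference cell dimensions (concentric-sphere model), μm
SPHERE_R_O = 9.34
SPHERE_R_I = 5.26


class ScenarioError(ValueError):
    """Invalid or inconsistent scenario configuration."""


@dataclass
class ScenarioConfig:
    """Fully specified simulation scenario.

    ``geometry`` holds exactly one of:
    ``{"kind": "sphere", "R_o_um", "R_i_um", "edge_um", "seed"}``,
    ``{"kind": "cell_like", "edge_um", "seed"}`` or
    ``{"kind": "file", "path"}``.
    """

    name: str
    geometry: dict
    params: SignalingParameters
    sim: SimulationConfig
    probe_points_um: list = field(default_factory=list)
    output_dir: str | None = None

    def validate(self) -> None:
        kind = self.geometry.get("kind")
        if kind not in {"sphere", "cell_like", "file"}:
            raise ScenarioError(f"unknown geometry kind {self.geometry.get('kind')!r}")
        if kind == "file" and "path" not in self.geometry:
            raise ScenarioError("file geometry requires a 'path'")
        self.sim.validate_phase_times(self.params)

    # -- YAML round trip ----------------------------------------------

    def to_dict(self) -> dict:
        p, s = self.params, self.sim
        return {
            "name": self.name,
            "geometry": dict(self.geometry),
            "signaling": {
                "D_um2_per_s": p.D,
                "E_AC_uM_per_s": p.E_AC,
                "V_max_uM_per_s": p.V_max,
                "K_M_uM": p.K_M,
                "C_o_uM": p.C_o,
                "t_s_s": p.t_s,
                "t_d_s": p.t_d,
                "beta_uM_um_per_s": dict(p.face_fluxes),
                "dirichlet_uM": dict(p.dirichlet),
            },
            "simulation": {
                "dt_s": s.dt,
                "t_end_s": s.t_end,
                "gamma": s.gamma,
                "inner_tol": s.inner_tol,
                "max_inner": s.max_inner,
                "snapshot_stride": s.snapshot_stride,
            },
            "probe_points_um": [list(map(float, pt)) for pt in self.probe_points_um],
            "output_dir": self.output_dir,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        try:
            sig = data["signaling"]
            sim = data["simulation"]
            params = SignalingParameters(
                D=float(sig["D_um2_per_s"]),
                E_AC=float(sig.get("E_AC_uM_per_s", 0.0)),
                V_max=float(sig.get("V_max_uM_per_s", 0.0)),
                K_M=float(sig.get("K_M_uM", 2.0)),
                C_o=float(sig.get("C_o_uM", 0.05)),
                t_s=float(sig.get("t_s_s", 0.0)),
                t_d=float(sig.get("t_d_s", 0.0)),
                face_fluxes={k: float(v) for k, v in
                             (sig.get("beta_uM_um_per_s") or {}).items()},
                dirichlet={k: float(v) for k, v in
                           (sig.get("dirichlet_uM") or {}).items()},
            )
            config = SimulationConfig(
                dt=float(sim["dt_s"]),
                t_end=float(sim["t_end_s"]),
                gamma=float(sim.get("gamma", 2.0 / 3.0)),
                inner_tol=float(sim.get("inner_tol", 1e-8)),
                max_inner=int(sim.get("max_inner", 50)),
                snapshot_stride=int(sim.get("snapshot_stride", 0)),
            )
            out = cls(
                name=str(data.get("name", "scenario")),
                geometry=dict(data["geometry"]),
                params=params,
                sim=config,
                probe_points_um=[tuple(p) for p in data.get("probe_points_um", [])],
                output_dir=data.get("output_dir"),
            )
        except KeyError as exc:
            raise ScenarioError(f"missing configuration key: {exc}") from exc
        out.validate()
        return out

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def build_geometry(geometry: dict) -> TetMesh:
    """Materialize the geometry section of a scenario."""
    kind = geometry.get("kind")
    if kind == "sphere":
        return generate_sphere_shell_mesh(
            R_o=float(geometry.get("R_o_um", SPHERE_R_O)),
            R_i=float(geometry.get("R_i_um", SPHERE_R_I)),
            target_edge_length=float(geometry.get("edge_um", 2.4)),
            seed=int(geometry.get("seed", 0)),
        )
    if kind == "cell_like":
        return generate_cell_like_mesh(
            seed=int(geometry.get("seed", 0)),
            target_edge_length=float(geometry.get("edge_um", 1.8)),
        )
    if kind == "file":
        return mesh_io.read_mesh(geometry["path"], geometry.get("format"))
    raise ScenarioError(f"unknown geometry kind {kind!r}")


# -- presets ---------------------------------------------------------------

_REFERENCE_RATES = dict(E_AC=0.1412, V_max=0.295, K_M=2.0, C_o=0.05)


def _sphere_geom(edge=2.4, seed=1):
    return {"kind": "sphere", "R_o_um": SPHERE_R_O, "R_i_um": SPHERE_R_I,
            "edge_um": edge, "seed": seed}


def _sphere_probes():
    # subplasmalemmal, mid-cytosolic and perinuclear radii along +x
    return [(SPHERE_R_O, 0.0, 0.0), (7.8, 0.0, 0.0), (SPHERE_R_I, 0.0, 0.0)]


def _preset_compartmental_pde_only() -> ScenarioConfig:
    """Uniform cytosolic degradation only (well-mixed): decay from C_o."""
    return ScenarioConfig(
        name="compartmental_pde_only",
        geometry=_sphere_geom(),
        params=SignalingParameters(D=300.0, E_AC=0.0, V_max=0.295, K_M=2.0,
                                   C_o=0.05),
        sim=SimulationConfig(dt=1.0, t_end=600.0),
        probe_points_um=_sphere_probes(),
    )


def _preset_compartmental_ac_only() -> ScenarioConfig:
    """Uniform cytosolic synthesis only: exactly linear growth."""
    return ScenarioConfig(
        name="compartmental_ac_only",
        geometry=_sphere_geom(),
        params=SignalingParameters(D=300.0, E_AC=0.1412, V_max=0.0, K_M=2.0,
                                   C_o=0.05),
        sim=SimulationConfig(dt=1.0, t_end=600.0),
        probe_points_um=_sphere_probes(),
    )


def _preset_compartmental_ac_pde() -> ScenarioConfig:
    """Uniform synthesis + degradation: saturating rise to the steady state."""
    return ScenarioConfig(
        name="compartmental_ac_pde",
        geometry=_sphere_geom(),
        params=SignalingParameters(D=300.0, **_REFERENCE_RATES),
        sim=SimulationConfig(dt=1.0, t_end=600.0),
        probe_points_um=_sphere_probes(),
    )


def _preset_dirichlet_shell() -> ScenarioConfig:
    """Prescribed concentrations on both surfaces; relaxes to A + B/r."""
    return ScenarioConfig(
        name="dirichlet_shell",
        geometry=_sphere_geom(),
        params=SignalingParameters(
            D=30.0, E_AC=0.0, V_max=0.0, C_o=0.05,
            dirichlet={"plasma_membrane": 4.0, "perinuclear": 1.0},
        ),
        sim=SimulationConfig(dt=1.0, t_end=60.0),
        probe_points_um=[(7.468, 0.0, 0.0), (7.112, 0.0, 0.0)],
    )


def _preset_membrane_ac_cytosol_pde(D: float = 3.0) -> ScenarioConfig:
    """Membrane-confined synthesis (flux β) with cytosolic degradation.

    β is the flux equivalent to the uniform volumetric synthesis rate on
    the concentric-sphere cell (total-activity equivalence).
    """
    beta = membrane_flux_equivalent(0.1412, SPHERE_R_O, SPHERE_R_I)
    return ScenarioConfig(
        name="membrane_ac_cytosol_pde",
        geometry=_sphere_geom(),
        params=SignalingParameters(
            D=D, E_AC=0.0, V_max=0.295, K_M=2.0, C_o=0.05,
            face_fluxes={"plasma_membrane": round(beta, 4)},
        ),
        sim=SimulationConfig(dt=2.0, t_end=600.0),
        probe_points_um=_sphere_probes(),
    )


def _preset_membrane_ac_cytosol_pde_slow() -> ScenarioConfig:
    return _preset_membrane_ac_cytosol_pde(D=0.3)


def _preset_delayed_start() -> ScenarioConfig:
    """Membrane synthesis from t_s = 10 s, degradation from t_d = 20 s."""
    return ScenarioConfig(
        name="delayed_start",
        geometry=_sphere_geom(),
        params=SignalingParameters(
            D=10.0, E_AC=0.0, V_max=0.295, K_M=2.0, C_o=0.05,
            t_s=10.0, t_d=20.0,
            face_fluxes={"plasma_membrane": 2.0},
        ),
        sim=SimulationConfig(dt=1.0, t_end=300.0),
        probe_points_um=_sphere_probes(),
    )


def _preset_cell_like_membrane_ac() -> ScenarioConfig:
    """Membrane synthesis + cytosolic degradation on the cell-like geometry."""
    return ScenarioConfig(
        name="cell_like_membrane_ac",
        geometry={"kind": "cell_like", "edge_um": 1.8, "seed": 1},
        params=SignalingParameters(
            D=10.0, E_AC=0.0, V_max=0.295, K_M=2.0, C_o=0.05,
            face_fluxes={"plasma_membrane": 2.0},
        ),
        sim=SimulationConfig(dt=2.0, t_end=300.0),
        # subplasmalemmal, cytosolic and perinuclear probes
        probe_points_um=[(14.0, 0.0, 0.0), (9.0, 4.0, 0.0), (3.0, 1.0, 2.2)],
    )


PRESETS = {
    "compartmental_pde_only": _preset_compartmental_pde_only,
    "compartmental_ac_only": _preset_compartmental_ac_only,
    "compartmental_ac_pde": _preset_compartmental_ac_pde,
    "dirichlet_shell": _preset_dirichlet_shell,
    "membrane_ac_cytosol_pde": _preset_membrane_ac_cytosol_pde,
    "membrane_ac_cytosol_pde_slow": _preset_membrane_ac_cytosol_pde_slow,
    "delayed_start": _preset_delayed_start,
    "cell_like_membrane_ac": _preset_cell_like_membrane_ac,
}


def preset(name: str) -> ScenarioConfig:
    """A fresh copy of a named preset configuration."""
    try:
        return PRESETS[name]()
    except KeyError:
        raise ScenarioError(
            f"unknown preset {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


# -- running ----------------------------------------------------------------


def run_scenario(
    config: ScenarioConfig,
    write_outputs: bool = True,
    mesh: TetMesh | None = None,
) -> tuple[TimeCourse, dict]:
    """Build the geometry, simulate, and (optionally) write outputs.

    Returns the :class:`TimeCourse` and a machine-readable run summary.
    Outputs (when enabled and ``output_dir`` is set): ``probes.csv``,
    ``summary.json``, ``snapshots/*.vtu``, ``run.log``.
    """
    config.validate()
    t0 = time.perf_counter()
    if mesh is None:
        mesh = build_geometry(config.geometry)
    idx, dist = (np.empty(0, dtype=int), np.empty(0))
    if config.probe_points_um:
        idx, dist = probe_nodes(mesh, config.probe_points_um)
    sim = SimulationConfig(**{**config.sim.__dict__, "probe_node_ids": list(map(int, idx))})
    course = simulate(mesh, config.params, sim)

    summary = {
        "scenario": config.name,
        "n_nodes": mesh.n_nodes,
        "n_elements": mesh.n_elements,
        "probe_nodes": [int(i) for i in idx],
        "probe_snap_distance_um": [float(d) for d in dist],
        "final_time_s": float(course.times[-1]),
        "final_probe_uM": {
            int(node): float(series[-1]) for node, series in course.probes.items()
        },
        "max_inner_iterations": int(course.inner_iterations.max()),
        "mean_inner_iterations": float(
            course.inner_iterations[1:].mean() if len(course.inner_iterations) > 1 else 0
        ),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }

    if write_outputs and config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        course.write_probes_csv(out / "probes.csv")
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        if course.snapshots:
            snap_dir = out / "snapshots"
            snap_dir.mkdir(exist_ok=True)
            for k, (t, state) in enumerate(course.snapshots):
                mesh_io.write_vtu(
                    mesh, snap_dir / f"snapshot_{k:04d}.vtu",
                    {"cAMP_uM": state},
                )
        handler = logging.FileHandler(out / "run.log")
        handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
        log.addHandler(handler)
        try:
            log.info("scenario %s finished: %s", config.name, json.dumps(summary))
        finally:
            log.removeHandler(handler)
            handler.close()
    return course, summary


def _curve_discrepancy(a: np.ndarray, b: np.ndarray) -> float:
    """Sup-norm difference normalized by the reference curve's maximum."""
    scale = max(float(np.abs(b).max()), 1e-30)
    return float(np.abs(a - b).max()) / scale


def convergence_study(
    config: ScenarioConfig,
    dt_values: list[float] | None = None,
    edge_lengths: list[float] | None = None,
) -> pd.DataFrame:
    """Probe-curve discrepancies across time-step or mesh refinement levels.

    For compartmental scenarios (no flux, no Dirichlet) the reference is the
    well-mixed analytic solution; otherwise the finest discretization serves
    as reference.  Exactly one of ``dt_values`` / ``edge_lengths`` must list
    at least two levels.
    """
    config.validate()
    if (dt_values is None) == (edge_lengths is None):
        raise ScenarioError("specify exactly one of dt_values or edge_lengths")
    levels = dt_values if dt_values is not None else edge_lengths
    if len(levels) < 2:
        raise ScenarioError("need at least two refinement levels")

    p = config.params
    compartmental = not p.face_fluxes and not p.dirichlet

    runs = []
    for level in levels:
        cfg_dict = config.to_dict()
        if dt_values is not None:
            cfg_dict["simulation"]["dt_s"] = float(level)
        else:
            cfg_dict["geometry"]["edge_um"] = float(level)
        cfg = ScenarioConfig.from_dict(cfg_dict)
        cfg.output_dir = None
        course, _ = run_scenario(cfg, write_outputs=False)
        runs.append((level, course))

    rows = []
    if compartmental:
        for level, course in runs:
            ref = compartmental_timecourse(course.times, p.E_AC, p.V_max, p.K_M, p.C_o)
            for node, series in course.probes.items():
                rows.append({
                    "level": level, "probe_node": node,
                    "discrepancy": _curve_discrepancy(series, ref),
                    "reference": "analytic",
                })
    else:
        # finest level is the last after sorting (smallest dt / edge)
        finest_level = min(levels)
        finest = dict(runs)[finest_level]
        ref_final = {k: v[-1] for k, v in finest.probes.items()}
        for level, course in runs:
            if level == finest_level:
                continue
            for k, (node, series) in enumerate(course.probes.items()):
                ref_node = list(finest.probes)[k]  # probes snap per-mesh
                rows.append({
                    "level": level, "probe_node": node,
                    "discrepancy": abs(series[-1] - ref_final[ref_node])
                    / max(abs(ref_final[ref_node]), 1e-30),
                    "reference": f"finest (level {finest_level})",
                })
    return pd.DataFrame(rows)
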