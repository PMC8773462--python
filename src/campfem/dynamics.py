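"""Time integration of the cAMP reaction–diffusion system.

The semi-discrete balance [K1]{ċ} + [K2]{c} = loads runs through three
phases: pure diffusion before synthesis starts (t < t_s), synthesis without
degradation (t_s ≤ t < t_d), and synthesis with Michaelis–Menten degradation
(t ≥ t_d).  Each step solves the γ-weighted implicit system

    [K1/Δt + γ(K2+K3)] c_{i+1} = [K1/Δt − (1−γ)(K2+K3)] c_i
                                 + (1−γ) R_i + γ R_{i+1}

with γ = 2/3 by default (unconditionally stable for γ ≥ 1/2).  During the
degradation phase the saturating rate M(C) = V_max C/(K_M + C) is
quasi-linearized about the current iterate C1 as a·C − (b − E_AC), giving a
state-dependent reaction matrix [K3] and source {R2b}; the step is re-solved
with updated (a, b) until the nodal solution stops changing.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .fem import AssembledSystem, apply_dirichlet, assemble_global
from .mesh import TetMesh

__all__ = [
    "Phase",
    "SignalingParameters",
    "SimulationConfig",
    "TimeCourse",
    "michaelis_menten_rate",
    "quasi_linearize",
    "phase_of",
    "advance_time_step",
    "simulate",
]


class ConvergenceError(RuntimeError):
    """Quasi-linearization inner iteration failed to converge."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


def michaelis_menten_rate(C, V_max: float, K_M: float):
    """Saturating degradation rate M(C) = V_max*C/(K_M + C), in μM/s."""
    C = np.asarray(C, dtype=float)
    if (C < 0).any():
        warnings.warn("Michaelis-Menten rate evaluated at negative concentration",
                      stacklevel=2)
    out = V_max * C / (K_M + C)
    return float(out) if out.ndim == 0 else out


def quasi_linearize(C1, V_max: float, K_M: float, E_AC):
    """Linearize M(C) about C1: M ≈ a·C + (E_AC − b), returning (a, b).

    a = V_max K_M / (K_M + C1)²  (1/s) is the local slope;
    b = E_AC − V_max C1² / (K_M + C1)²  (μM/s) is the net constant source
    entering the linearized balance dC/dt = −a C + b.
    """
    C1 = np.asarray(C1, dtype=float)
    denom = (K_M + C1) ** 2
    a = V_max * K_M / denom
    b = np.asarray(E_AC, dtype=float) - V_max * C1**2 / denom
    if a.ndim == 0:
        return float(a), float(b)
    return a, b


class Phase(enum.Enum):
    DIFFUSION_ONLY = "diffusion_only"
    SYNTHESIS = "synthesis"
    SYNTHESIS_AND_DEGRADATION = "synthesis_and_degradation"


def phase_of(t: float, t_s: float, t_d: float) -> Phase:
    """Which activity phase a time point belongs to (intervals closed on the left)."""
    if t < 0:
        raise ValueError("time must be non-negative")
    if t < t_s:
        return Phase.DIFFUSION_ONLY
    if t < t_d:
        return Phase.SYNTHESIS
    return Phase.SYNTHESIS_AND_DEGRADATION


@dataclass
class SignalingParameters:
    """Physical parameters of the cAMP synthesis–diffusion–degradation model.

    Units: D μm²/s; E_AC, V_max μM/s; K_M, C_o μM; t_s, t_d s; face fluxes β
    μM·μm/s per boundary-set label (positive = influx); Dirichlet values μM
    per boundary-set label (prescribed on all nodes of that surface).
    """

    D: float
    E_AC: float = 0.0
    V_max: float = 0.0
    K_M: float = 2.0
    C_o: float = 0.05
    t_s: float = 0.0
    t_d: float = 0.0
    face_fluxes: dict[str, float] = field(default_factory=dict)
    dirichlet: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.K_M <= 0:
            raise ValueError("K_M must be positive")
        if self.V_max < 0:
            raise ValueError("V_max must be non-negative")
        if self.D < 0:
            raise ValueError("D must be non-negative")
        if self.t_s > self.t_d:
            raise ValueError("degradation may not start before synthesis (t_s <= t_d)")


@dataclass
class SimulationConfig:
    """Numerical controls for the time march."""

    dt: float
    t_end: float
    gamma: float = 2.0 / 3.0
    inner_tol: float = 1e-8
    max_inner: int = 50
    probe_node_ids: list[int] = field(default_factory=list)
    snapshot_stride: int = 0  # 0 = no full-field snapshots

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not (0.5 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [1/2, 1] (explicit schemes refused)")
        if self.inner_tol <= 0:
            raise ValueError("inner tolerance must be positive")

    def validate_phase_times(self, params: SignalingParameters) -> None:
        """Activity switch-on times must fall on the time grid."""
        for name, t in (("t_s", params.t_s), ("t_d", params.t_d)):
            k = t / self.dt
            if abs(k - round(k)) > 1e-9:
                raise ValueError(
                    f"{name}={t} s is not an integer multiple of dt={self.dt} s"
                )


@dataclass
class TimeCourse:
    """Recorded simulation output: probe traces every step, optional snapshots."""

    times: np.ndarray
    probes: dict[int, np.ndarray]
    inner_iterations: np.ndarray
    snapshots: list[tuple[float, np.ndarray]] = field(default_factory=list)
    final_state: np.ndarray | None = None

    def probe_dataframe(self) -> pd.DataFrame:
        data = {"time_s": self.times}
        for node, series in self.probes.items():
            data[f"node_{node}_uM"] = series
        return pd.DataFrame(data)

    def write_probes_csv(self, path) -> None:
        self.probe_dataframe().to_csv(path, index=False)


def _phase_load(system: AssembledSystem, phase: Phase) -> np.ndarray:
    """Load vector at a time point whose phase has no state dependence."""
    if phase is Phase.DIFFUSION_ONLY:
        return np.zeros(system.n_nodes)
    return system.R1 + system.R2  # synthesis phases share R1 + R2s


def _dirichlet_arrays(mesh: TetMesh, params: SignalingParameters):
    nodes, values = [], []
    for label, value in params.dirichlet.items():
        idx = mesh.face_set_nodes(label)
        nodes.append(idx)
        values.append(np.full(idx.size, float(value)))
    if not nodes:
        return np.empty(0, dtype=np.int64), np.empty(0)
    nodes = np.concatenate(nodes)
    values = np.concatenate(values)
    uniq, first = np.unique(nodes, return_index=True)
    for u in uniq[np.bincount(np.searchsorted(uniq, nodes)) > 1]:
        vals = values[nodes == u]
        if not np.allclose(vals, vals[0]):
            raise ValueError(f"conflicting Dirichlet values prescribed on node {u}")
    return uniq, values[first]


def build_system(mesh: TetMesh, params: SignalingParameters) -> AssembledSystem:
    """Assemble the global operators for one mesh/parameter combination."""
    rate_map = {"cytosol": params.E_AC} if params.E_AC else {}
    return assemble_global(mesh, params.D, params.face_fluxes, rate_map)


def _solve_reduced(A: sp.spmatrix, rhs, dir_nodes, dir_values):
    if dir_nodes.size:
        A_red, rhs_red, red = apply_dirichlet(A, rhs, dir_nodes, dir_values)
        if A_red.shape[0] == 0:
            return red.expand(np.empty(0))
        return red.expand(splu(A_red.tocsc()).solve(rhs_red))
    return splu(A.tocsc()).solve(rhs)


def advance_time_step(
    c_i: np.ndarray,
    system: AssembledSystem,
    params: SignalingParameters,
    config: SimulationConfig,
    t_i: float,
    dirichlet: tuple[np.ndarray, np.ndarray] | None = None,
) -> tuple[np.ndarray, int]:
    """One γ-weighted implicit step from t_i to t_i + Δt.

    Returns the new nodal vector and the number of quasi-linearization inner
    iterations (1 when the target phase has no degradation).
    """
    dt, gamma = config.dt, config.gamma
    t_next = t_i + dt
    phase_i = phase_of(t_i, params.t_s, params.t_d)
    phase_next = phase_of(t_next, params.t_s, params.t_d)
    if dirichlet is None:
        dirichlet = _dirichlet_arrays(system.mesh, params)
    dir_nodes, dir_values = dirichlet

    K1, K2 = system.K1, system.K2
    M_dt = K1.multiply(1.0 / dt)

    if phase_next is not Phase.SYNTHESIS_AND_DEGRADATION:
        R_old = _phase_load(system, phase_i)
        R_new = _phase_load(system, phase_next)
        A = (M_dt + gamma * K2).tocsr()
        rhs = (M_dt - (1.0 - gamma) * K2) @ c_i + (1.0 - gamma) * R_old + gamma * R_new
        return _solve_reduced(A, rhs, dir_nodes, dir_values), 1

    # degradation phase: rebuild [K3], {R2b} from the current iterate C1
    if phase_i is Phase.SYNTHESIS_AND_DEGRADATION:
        R_extra_old = None  # both endpoints use the linearized load
    else:
        R_extra_old = _phase_load(system, phase_i)
    c1 = c_i.copy()
    last_change = np.inf
    for iteration in range(1, config.max_inner + 1):
        c1_elem = system.element_means(c1)
        denom = (params.K_M + c1_elem) ** 2
        a_e = params.V_max * params.K_M / denom
        b_e = system.element_rates - params.V_max * c1_elem**2 / denom
        K3 = system.reaction_matrix(a_e)
        R2b = system.R1 + system.linearized_source(b_e)
        K23 = K2 + K3
        A = (M_dt + gamma * K23).tocsr()
        R_old = R2b if R_extra_old is None else R_extra_old
        rhs = (
            (M_dt - (1.0 - gamma) * K23) @ c_i
            + (1.0 - gamma) * R_old
            + gamma * R2b
        )
        c_new = _solve_reduced(A, rhs, dir_nodes, dir_values)
        scale = max(float(np.abs(c_new).max()), 1e-30)
        last_change = float(np.abs(c_new - c1).max()) / scale
        c1 = c_new
        if last_change <= config.inner_tol:
            return c1, iteration
        if params.V_max == 0.0:
            return c1, iteration  # no state dependence: converged in one pass
    raise ConvergenceError(
        f"quasi-linearization did not converge in {config.max_inner} iterations "
        f"(last relative change {last_change:.3e})",
        last_change,
    )


def simulate(
    mesh: TetMesh,
    params: SignalingParameters,
    config: SimulationConfig,
    system: AssembledSystem | None = None,
) -> TimeCourse:
    """March the model from t = 0 to t_end, recording probes every step.

    The initial field is uniform at C_o with Dirichlet surfaces pinned to
    their prescribed values.  Full-field snapshots are stored every
    ``snapshot_stride`` steps when the stride is positive.
    """
    config.validate_phase_times(params)
    if system is None:
        system = build_system(mesh, params)
    dirichlet = _dirichlet_arrays(mesh, params)

    n_steps = int(round(config.t_end / config.dt))
    if abs(n_steps * config.dt - config.t_end) > 1e-9 * max(config.t_end, 1.0):
        raise ValueError("t_end must be an integer multiple of dt")

    c = np.full(mesh.n_nodes, params.C_o)
    if dirichlet[0].size:
        c[dirichlet[0]] = dirichlet[1]

    probes = list(config.probe_node_ids)
    times = np.empty(n_steps + 1)
    probe_data = {p: np.empty(n_steps + 1) for p in probes}
    iters = np.zeros(n_steps + 1, dtype=int)
    snaps: list[tuple[float, np.ndarray]] = []

    def record(k: int, t: float, state: np.ndarray) -> None:
        times[k] = t
        for p in probes:
            probe_data[p][k] = state[p]
        if config.snapshot_stride and (k % config.snapshot_stride == 0 or k == n_steps):
            snaps.append((t, state.copy()))

    record(0, 0.0, c)
    min_seen = float(c.min()) if c.size else 0.0
    for k in range(1, n_steps + 1):
        t_i = (k - 1) * config.dt
        c, n_inner = advance_time_step(c, system, params, config, t_i, dirichlet)
        if not np.isfinite(c).all():
            raise FloatingPointError(
                f"non-finite concentration at step {k} (t = {k * config.dt} s)"
            )
        min_seen = min(min_seen, float(c.min()))
        iters[k] = n_inner
        record(k, k * config.dt, c)

    if min_seen < -1e-6:
        warnings.warn(
            f"transient negative concentrations (min {min_seen:.3e} μM); "
            "values are not clamped",
            stacklevel=2,
        )
    return TimeCourse(
        times=times,
        probes=probe_data,
        inner_iterations=iters,
        snapshots=snaps,
        final_state=c.copy(),
    )
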