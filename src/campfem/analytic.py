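"""Closed-form and high-accuracy reference solutions.

These serve as independent oracles for the FEM solver:

* the compartmental (well-mixed) balance dC/dt = E_AC - V_max C/(K_M + C),
  solved both from its implicit separated-variables relation and by adaptive
  stiff integration;
* the steady diffusion profile A + B/r in a spherical shell with prescribed
  concentrations on both surfaces;
* the membrane flux equivalent to a uniform volumetric synthesis rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "CompartmentalSolution",
    "compartmental_timecourse",
    "compartmental_steady_state",
    "shell_steady_state",
    "membrane_flux_equivalent",
    "rate_ratio",
]


def compartmental_steady_state(E_AC: float, V_max: float, K_M: float) -> float | None:
    """Steady concentration solving E_AC = V_max*C/(K_M + C), or None.

    A finite steady state exists only when 0 <= E_AC < V_max (synthesis
    below the saturating hydrolysis capacity); E_AC = 0 gives 0.
    """
    if K_M <= 0:
        raise ValueError("K_M must be positive")
    if E_AC == 0.0:
        return 0.0 if V_max > 0 else None
    if 0.0 < E_AC < V_max:
        return E_AC * K_M / (V_max - E_AC)
    return None  # no finite steady state


def _implicit_time(C: float, E_AC: float, V_max: float, K_M: float, C_o: float) -> float:
    """Time at which the compartmental solution reaches C (separation of variables).

    With p = E_AC*K_M and q = E_AC - V_max the balance reads
    dC/dt = (p + q C)/(K_M + C), so

        t = (C - C_o)/q + (K_M - p/q)/q * ln((p + q C)/(p + q C_o))   (q != 0)
        t = (K_M (C - C_o) + (C^2 - C_o^2)/2) / p                      (q == 0)
    """
    p = E_AC * K_M
    q = E_AC - V_max
    if q == 0.0:
        if p == 0.0:
            return 0.0 if C == C_o else np.inf
        return (K_M * (C - C_o) + 0.5 * (C * C - C_o * C_o)) / p
    num, den = p + q * C, p + q * C_o
    if num * den <= 0.0 or den == 0.0:  # crossed the q·C + p = 0 asymptote
        return np.inf
    return (C - C_o) / q + (K_M - p / q) / q * np.log(num / den)


@dataclass
class CompartmentalSolution:
    """Well-mixed cAMP balance with Michaelis–Menten degradation.

    Independent of geometry, location and diffusion coefficient: with zero
    boundary flux and uniform rates the spatial problem collapses onto this
    single ordinary differential equation.
    """

    E_AC: float  # μM/s
    V_max: float  # μM/s
    K_M: float  # μM
    C_o: float  # μM

    def __post_init__(self) -> None:
        if self.K_M <= 0:
            raise ValueError("K_M must be positive")
        if self.V_max < 0 or self.E_AC < 0 or self.C_o < 0:
            raise ValueError("rates and initial concentration must be non-negative")

    @property
    def steady_state(self) -> float | None:
        return compartmental_steady_state(self.E_AC, self.V_max, self.K_M)

    def rate(self, C: float) -> float:
        return self.E_AC - self.V_max * C / (self.K_M + C)

    # -- closed form ---------------------------------------------------

    def _value_implicit(self, t: float) -> float:
        if t == 0.0:
            return self.C_o
        if self.V_max == 0.0:  # pure synthesis: exactly linear
            return self.C_o + self.E_AC * t
        r0 = self.rate(self.C_o)
        if r0 == 0.0:
            return self.C_o
        ss = self.steady_state
        if r0 > 0:
            if ss is not None:
                lo, hi = self.C_o, ss
                # approach is asymptotic; clip the bracket just below ss
                hi = ss - 1e-15 * max(ss, 1.0)
                if _implicit_time(hi, self.E_AC, self.V_max, self.K_M, self.C_o) <= t:
                    return ss
            else:
                hi = self.C_o + (self.E_AC + self.V_max) * t + 1.0
                lo = self.C_o
        else:
            # decay toward the steady state (0 when E_AC = 0)
            lo = 1e-300 if not ss else ss + 1e-15 * max(ss, 1.0)
            hi = self.C_o
            if _implicit_time(lo, self.E_AC, self.V_max, self.K_M, self.C_o) <= t:
                return ss if ss is not None else 0.0
        f = lambda c: _implicit_time(c, self.E_AC, self.V_max, self.K_M, self.C_o) - t
        if f(lo) * f(hi) > 0:  # monotone in C; expand toward the open end
            return self.C_o if abs(f(lo)) < abs(f(hi)) else hi
        return brentq(f, lo, hi, xtol=1e-12, rtol=8.9e-16)

    def evaluate(self, t_grid, method: str = "implicit") -> np.ndarray:
        """Concentration C(t) in μM on ``t_grid`` (s).

        ``method`` is "implicit" (closed-form relation, root-solved per time
        point) or "ode" (adaptive Radau integration, rtol 1e-12).
        """
        t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
        if (t_grid < 0).any():
            raise ValueError("times must be non-negative")
        if method == "implicit":
            return np.array([self._value_implicit(t) for t in t_grid])
        if method == "ode":
            if t_grid[-1] == 0.0:
                return np.full_like(t_grid, self.C_o)
            sol = solve_ivp(
                lambda t, c: [self.rate(c[0])],
                (0.0, float(t_grid[-1])),
                [self.C_o],
                t_eval=t_grid,
                method="Radau",
                rtol=1e-12,
                atol=1e-14,
            )
            if not sol.success:
                raise RuntimeError(f"ODE oracle failed: {sol.message}")
            return sol.y[0]
        raise ValueError(f"unknown method {method!r}")


def compartmental_timecourse(
    t_grid, E_AC: float, V_max: float, K_M: float, C_o: float,
    method: str = "implicit",
) -> np.ndarray:
    """Evaluate the well-mixed solution C(t); see :class:`CompartmentalSolution`."""
    return CompartmentalSolution(E_AC, V_max, K_M, C_o).evaluate(t_grid, method)


def shell_steady_state(
    r, R_o: float, R_i: float, C_at_Ro: float, C_at_Ri: float
) -> np.ndarray:
    """Steady diffusion profile A + B/r between two concentric spheres.

    Both surfaces hold prescribed concentrations; the Laplace solution in
    the shell is A + B/r with A, B fixed by the boundary values.
    """
    if not (0 < R_i < R_o):
        raise ValueError("require 0 < R_i < R_o")
    r = np.asarray(r, dtype=float)
    tol = 1e-9 * R_o
    if (r < R_i - tol).any() or (r > R_o + tol).any():
        raise ValueError(f"radius outside the shell [{R_i}, {R_o}]")
    B = (C_at_Ri - C_at_Ro) / (1.0 / R_i - 1.0 / R_o)
    A = C_at_Ro - B / R_o
    return A + B / r


def membrane_flux_equivalent(E_AC: float, R_o: float, R_i: float) -> float:
    """Membrane flux β (μM·μm/s) matching a uniform volumetric synthesis rate.

    Equates total production E_AC * V_cytosol with β * S_membrane on the
    concentric-sphere cell: β = E_AC (R_o³ − R_i³) / (3 R_o²).
    """
    if R_o <= 0 or R_i < 0 or R_i >= R_o:
        raise ValueError("require 0 <= R_i < R_o")
    return E_AC * (R_o**3 - R_i**3) / (3.0 * R_o**2)


def rate_ratio(V_max: float, K_M: float) -> float:
    """First-order degradation rate V_max/K_M (1/s), the low-concentration limit.

    Well-mixed responses with C ≪ K_M depend on V_max and K_M only through
    this ratio.
    """
    if K_M <= 0:
        raise ValueError("K_M must be positive")
    return V_max / K_M
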