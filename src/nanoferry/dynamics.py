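"""Inner-cell particle dynamics and feedback-linearizing position control.

After crossing the membrane, the drug-loaded carrier moves through the
cytoplasm under Stokes drag and the magnetophoretic force of an external,
axially linear magnetic field b_z = alpha*z + c(t).  Along the field axis
the motion reduces to the scalar linear ODE

    z'' + C z' = kappa * alpha^2 * z + kappa * alpha * c(t),

with the drag rate C = 18 mu / (rho_p d_p^2) = 1/tau_p (tau_p the particle
velocity response time) and the magnetophoretic coefficient
kappa = V chi_bead / (m_p mu_0).  Intracellular flow is taken as zero and
gravity/buoyancy is negligible at carrier scale (both can be switched on).

Position control picks the field offset c(t) by feedback linearization:

    c(t) = (C z' - kappa alpha^2 z + z_d'' - m1 e' - m2 e) / (kappa alpha),

which cancels the plant terms exactly and leaves the tracking error
e = z - z_d obeying the chosen linear dynamics e'' + m1 e' + m2 e = 0,
asymptotically stable for any m1, m2 > 0.  The commanded field follows as
b_z = alpha z + c(t).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .geometry import CarrierProperties
from .synthetic import Target

MU0 = 4.0 * math.pi * 1e-7  # vacuum permeability [N/A^2]

#: drag-rate x step-size threshold beyond which the explicit integrator is
#: abandoned for a stiff method
STIFFNESS_SWITCH = 10.0


@dataclass(frozen=True)
class Environment:
    """Intracellular fluid environment."""

    mu_visc: float = 1e-3      # dynamic viscosity [Pa s]
    rho_fluid: float = 1000.0  # fluid density [kg/m^3]
    u_fluid: float = 0.0       # axial fluid velocity [m/s]; zero inside the cell
    g: float = 9.81            # gravitational acceleration [m/s^2]
    mu0: float = MU0           # vacuum permeability, fixed

    def __post_init__(self) -> None:
        if not self.mu_visc > 0:
            raise ValueError(f"viscosity must be positive, got {self.mu_visc}")
        if abs(self.mu0 - MU0) > 1e-22:
            raise ValueError("mu0 is a physical constant; it cannot be overridden")


@dataclass(frozen=True)
class FieldProfile:
    """Axially linear field b_z(z, t) = alpha*z + c(t) plus device limits."""

    alpha: float                              # field gradient [T/m]
    c_of_t: Callable[[float], float]          # time-dependent offset [T]
    bz_max: float = 2.4                       # device field limit [T]
    grad_max: float = 0.180                   # device gradient limit [T/m]

    def __post_init__(self) -> None:
        if not math.isfinite(self.alpha):
            raise ValueError("alpha must be finite")
        if not (self.bz_max > 0 and self.grad_max > 0):
            raise ValueError("device limits must be positive")

    def bz(self, z: float, t: float) -> float:
        return self.alpha * z + self.c_of_t(t)


@dataclass(frozen=True)
class ControllerGains:
    """Error-dynamics gains: e'' + m1 e' + m2 e = 0."""

    m1: float  # [1/s]
    m2: float  # [1/s^2]

    def __post_init__(self) -> None:
        if not (self.m1 > 0 and self.m2 > 0):
            raise ValueError(f"gains must be positive, got m1={self.m1}, m2={self.m2}")

    @classmethod
    def critically_damped(cls, omega: float) -> "ControllerGains":
        """Gains m1 = 2w, m2 = w^2 placing both error poles at -w."""
        return cls(m1=2.0 * omega, m2=omega * omega)


@dataclass(frozen=True)
class DerivedCoefficients:
    """Drag and magnetophoresis coefficients of the motion equation."""

    tau_p: float   # velocity response time [s]
    C_drag: float  # drag rate 1/tau_p [1/s]
    kappa: float   # magnetophoretic coefficient V chi/(m_p mu0) [m s^-2 T^-2 m]

    def __post_init__(self) -> None:
        if not (self.tau_p > 0 and self.C_drag > 0 and self.kappa > 0):
            raise ValueError("derived coefficients must be positive")
        if abs(self.C_drag * self.tau_p - 1.0) > 1e-9:
            raise ValueError("C_drag must equal 1/tau_p")


@dataclass
class Trajectory:
    """Simulated particle path with the field and force along it."""

    t: np.ndarray
    z: np.ndarray
    zdot: np.ndarray
    bz: np.ndarray
    force: np.ndarray                  # magnetic force [N]
    e: np.ndarray | None = None        # tracking error [m] (closed loop)
    metrics: dict = field(default_factory=dict)


# -- pointwise force laws ---------------------------------------------------

def response_time(carrier: CarrierProperties, env: Environment) -> DerivedCoefficients:
    """tau_p = rho_p d_p^2 / (18 mu), its reciprocal drag rate, and kappa."""
    tau_p = carrier.rho_p * carrier.d_p**2 / (18.0 * env.mu_visc)
    kappa = carrier.V * carrier.chi_bead / (carrier.m_p * env.mu0)
    return DerivedCoefficients(tau_p=tau_p, C_drag=1.0 / tau_p, kappa=kappa)


def drag_force(carrier: CarrierProperties, env: Environment, v_p: float) -> float:
    """Stokes drag (1/tau_p) m_p (v_p - u_fluid) [N]; opposes relative motion
    in the assembled equation of motion."""
    if not math.isfinite(v_p):
        raise ValueError("particle velocity must be finite")
    coeffs = response_time(carrier, env)
    return coeffs.C_drag * carrier.m_p * (v_p - env.u_fluid)


def gravitational_force(carrier: CarrierProperties, env: Environment) -> float:
    """Buoyancy-corrected weight m_p g (rho_p - rho_fluid)/rho_p [N].

    Excluded from the motion equation by default — negligible against the
    magnetic and drag forces at carrier scale.
    """
    return carrier.m_p * env.g * (carrier.rho_p - env.rho_fluid) / carrier.rho_p


def magnetic_force_z(
    carrier: CarrierProperties, env: Environment, bz: float, dbz_dz: float
) -> float:
    """Axial magnetophoretic force (V chi_bead / mu0) * b_z * db_z/dz [N]."""
    if not (math.isfinite(bz) and math.isfinite(dbz_dz)):
        raise ValueError("field values must be finite")
    return carrier.V * carrier.chi_bead / env.mu0 * bz * dbz_dz


# -- simulation -------------------------------------------------------------

def _integrate(rhs, t_grid, y0, C_drag, dt, rtol, atol):
    """solve_ivp wrapper with stiffness-aware method choice and blow-up check."""
    method = "LSODA" if C_drag * dt > STIFFNESS_SWITCH else "RK45"
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y0,
        method=method,
        t_eval=t_grid,
        rtol=rtol,
        atol=atol,
        dense_output=False,
    )
    if not sol.success:
        raise RuntimeError(
            f"integration failed ({sol.message}); try a smaller dt or the stiff path"
        )
    y = sol.y
    scale = max(abs(y0[0]), 1.0)
    if not np.all(np.isfinite(y)) or np.max(np.abs(y[0])) > 1e12 * scale + 1e6:
        raise RuntimeError("trajectory blew up; reduce dt or check field parameters")
    return y


def simulate_open_loop(
    state0: tuple[float, float],
    carrier: CarrierProperties,
    env: Environment,
    fieldprofile: FieldProfile,
    t_final: float,
    dt: float,
    *,
    include_gravity: bool = False,
    rtol: float = 1e-8,
    atol: tuple[float, float] | None = None,
) -> Trajectory:
    """Integrate z'' + C z' = kappa alpha (alpha z + c(t)) from ``state0``.

    Records position, velocity, the local field b_z and the magnetic force at
    each output step (spacing ``dt``).
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    coeffs = response_time(carrier, env)
    C, kappa = coeffs.C_drag, coeffs.kappa
    alpha, c_of_t = fieldprofile.alpha, fieldprofile.c_of_t
    a_grav = -env.g * (carrier.rho_p - env.rho_fluid) / carrier.rho_p if include_gravity else 0.0

    def rhs(t, y):
        z, zdot = y
        acc = -C * (zdot - env.u_fluid) + kappa * alpha * (alpha * z + c_of_t(t)) + a_grav
        return (zdot, acc)

    t_grid = np.arange(0.0, t_final + 0.5 * dt, dt)
    if atol is None:
        zscale = max(abs(state0[0]), 1e-12)
        atol = (1e-2 * rtol * zscale, 1e-2 * rtol * zscale / t_final)
    y = _integrate(rhs, t_grid, list(state0), C, dt, rtol, atol)
    z, zdot = y
    bz = alpha * z + np.array([c_of_t(ti) for ti in t_grid])
    force = carrier.V * carrier.chi_bead / env.mu0 * bz * alpha
    return Trajectory(t=t_grid, z=z, zdot=zdot, bz=bz, force=force)


def controller_offset(
    state: tuple[float, float],
    target_vals: tuple[float, float, float],
    gains: ControllerGains,
    coeffs: DerivedCoefficients,
    alpha: float,
) -> float:
    """Feedback-linearizing field offset c [T] for one state/target sample.

    ``target_vals`` is (z_d, z_d', z_d'') at the current time.  Raises when
    kappa*alpha = 0: with no field gradient the magnetic force cannot
    actuate the axial motion.
    """
    z, zdot = state
    zd, zd_dot, zd_ddot = target_vals
    ka = coeffs.kappa * alpha
    if ka == 0.0:
        raise ZeroDivisionError("kappa*alpha = 0: axial actuation is singular")
    e = z - zd
    e_dot = zdot - zd_dot
    return (coeffs.C_drag * zdot - coeffs.kappa * alpha**2 * z
            + zd_ddot - gains.m1 * e_dot - gains.m2 * e) / ka


def simulate_closed_loop(
    state0: tuple[float, float],
    target: Target,
    gains: ControllerGains,
    carrier: CarrierProperties,
    env: Environment,
    alpha: float,
    t_final: float,
    dt: float,
    *,
    settle_band: float = 0.02,
    rtol: float = 1e-10,
    atol: tuple[float, float] | None = None,
) -> Trajectory:
    """Closed-loop tracking of ``target`` with the linearizing controller.

    The offset c(t) is evaluated along the simulated state (full-state
    feedback), so the integrated plant obeys e'' + m1 e' + m2 e = 0 exactly
    up to integration error.  Metrics: ``settling_time`` — first time after
    which |e| stays within ``settle_band`` x |e(0)| — and ``peak_bz``.
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    coeffs = response_time(carrier, env)

    def c_at(t, y):
        return controller_offset(
            tuple(y), (target.zd(t), target.zd_dot(t), target.zd_ddot(t)), gains, coeffs, alpha
        )

    def rhs(t, y):
        z, zdot = y
        c = c_at(t, y)
        acc = -coeffs.C_drag * (zdot - env.u_fluid) \
            + coeffs.kappa * alpha * (alpha * z + c)
        return (zdot, acc)

    t_grid = np.arange(0.0, t_final + 0.5 * dt, dt)
    if atol is None:
        zscale = max(abs(state0[0]), target.amplitude, 1e-15)
        vscale = zscale * max(1.0 / t_final, math.sqrt(gains.m2))
        atol = (1e-2 * rtol * zscale, 1e-2 * rtol * vscale)
    # the linearizing feedback cancels the stiff drag term, so the explicit
    # path is fine regardless of C_drag
    y = _integrate(rhs, t_grid, list(state0), 0.0, dt, rtol, atol)
    z, zdot = y
    c_vals = np.array([c_at(ti, (zi, vi)) for ti, zi, vi in zip(t_grid, z, zdot)])
    bz = alpha * z + c_vals
    force = carrier.V * carrier.chi_bead / env.mu0 * bz * alpha
    e = z - np.array([target.zd(ti) for ti in t_grid])

    metrics = {
        "settling_time": settling_time(t_grid, e, band=settle_band),
        "peak_bz": float(np.max(np.abs(bz))),
        "final_error": float(e[-1]),
    }
    return Trajectory(t=t_grid, z=z, zdot=zdot, bz=bz, force=force, e=e, metrics=metrics)


def settling_time(t: np.ndarray, e: np.ndarray, band: float = 0.02) -> float:
    """First time after which |e| stays within ``band`` x |e(0)|.

    0 when the error never leaves the band; NaN when it never settles
    inside the simulated horizon.
    """
    e0 = abs(e[0])
    if e0 == 0.0:
        return 0.0
    outside = np.abs(e) > band * e0
    if not outside.any():
        return 0.0
    last = int(np.max(np.nonzero(outside)))
    if last + 1 >= len(t):
        return float("nan")
    return float(t[last + 1])


def gain_sweep(
    m_values: np.ndarray,
    carrier: CarrierProperties,
    env: Environment,
    alpha: float,
    target: Target,
    t_final: float,
    dt: float,
    *,
    settle_band: float = 0.02,
) -> pd.DataFrame:
    """Closed-loop metrics across a grid of gain magnitudes.

    Each grid value m maps to critically damped gains (m1, m2) = (2m, m^2);
    faster error dynamics (larger m) shorten the settling time at the cost
    of a higher peak field.
    """
    rows = []
    for m in np.asarray(m_values, dtype=float):
        gains = ControllerGains.critically_damped(m)
        traj = simulate_closed_loop(
            (0.0, 0.0), target, gains, carrier, env, alpha, t_final, dt,
            settle_band=settle_band,
        )
        rows.append(
            {
                "m": m,
                "m1": gains.m1,
                "m2": gains.m2,
                "settling_time": traj.metrics["settling_time"],
                "peak_bz": traj.metrics["peak_bz"],
            }
        )
    return pd.DataFrame(rows)
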