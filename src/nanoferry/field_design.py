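"""Feasible magnetic field/gradient regions for target crossing times.

Crossing the bilayer at constant speed v_s = x_membrane / t_cross demands a
steady resistance-balancing force H(1) * v_s (the transfer function's DC
gain times the speed, with v_s expressed in the model's Å/ps input unit).
Equating this to the magnetophoretic force (V chi_bead / mu0) * b_z db_z/dz
gives the required field-gradient product

    b_z * db_z/dz = mu0 * H(1) * v_s / (V * chi_bead)     [T^2/m],

and a bound or band on v_s maps onto bounds [L_b, L_u] on the product.  The
feasible actuation set is the part of the device box
0 <= b_z <= 2.4 T, 0 <= db_z/dz <= 0.180 T/m between the two hyperbolas
b_z * g = L_b and b_z * g = L_u.  Shorter crossing deadlines push L_b up
and shrink the region; beyond L_b = 0.432 T^2/m (the box corner product)
the region is empty.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dynamics import Environment
from .geometry import CarrierProperties
from .membrane_tf import TransferFunctionModel, dc_gain, is_stable
from .units import m_per_s_to_angstrom_per_ps

#: device box: maximum field [T] and field gradient [T/m]
BZ_MAX_DEFAULT = 2.4
GRAD_MAX_DEFAULT = 0.180

#: default bilayer thickness [m] (typical POPC membrane)
X_MEMBRANE_DEFAULT = 4.0e-9

#: default symmetric tolerance band on the crossing velocity
VELOCITY_BAND_DEFAULT = 0.10


@dataclass(frozen=True)
class CrossingSpec:
    """A membrane-crossing requirement: time, thickness, implied speed."""

    t_cross: float                      # [s]
    x_membrane: float = X_MEMBRANE_DEFAULT  # [m]
    v_s: float = None                   # [m/s]; derived when omitted

    def __post_init__(self) -> None:
        if not (self.t_cross > 0 and self.x_membrane > 0):
            raise ValueError("crossing time and membrane thickness must be positive")
        v = self.x_membrane / self.t_cross
        if self.v_s is None:
            object.__setattr__(self, "v_s", v)
        elif abs(self.v_s - v) > 1e-12 * v:
            raise ValueError(f"v_s={self.v_s} inconsistent with x/t={v}")


@dataclass
class FieldRegion:
    """Feasible (b_z, db_z/dz) set between two product hyperbolas in a box."""

    L_b: float                     # lower product bound [T^2/m]
    L_u: float                     # upper product bound [T^2/m]
    bz_max: float = BZ_MAX_DEFAULT
    grad_max: float = GRAD_MAX_DEFAULT
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.L_b < 0 or self.L_b > self.L_u:
            raise ValueError(f"need 0 <= L_b <= L_u, got [{self.L_b}, {self.L_u}]")
        if not (self.bz_max > 0 and self.grad_max > 0):
            raise ValueError("box limits must be positive")

    @property
    def is_empty(self) -> bool:
        """No box point reaches the lower product bound."""
        return self.L_b > self.bz_max * self.grad_max

    def contains(self, bz: float, grad: float) -> bool:
        return (
            0.0 <= bz <= self.bz_max
            and 0.0 <= grad <= self.grad_max
            and self.L_b <= bz * grad <= self.L_u
        )

    def boundary_curves(self, n: int = 200) -> dict[str, np.ndarray]:
        """Sampled hyperbolas bz*g = L_b and bz*g = L_u inside the box.

        Each curve is an (m, 2) array of (bz, grad) points; an empty array
        when the bound has no trace in the box.
        """
        curves: dict[str, np.ndarray] = {}
        for name, L in (("lower", self.L_b), ("upper", self.L_u)):
            if L <= 0 or L > self.bz_max * self.grad_max:
                curves[name] = np.empty((0, 2))
                continue
            bz_lo = L / self.grad_max  # smallest bz keeping g = L/bz inside the box
            bz = np.linspace(bz_lo, self.bz_max, n)
            curves[name] = np.column_stack([bz, L / bz])
        return curves

    def area(self, resolution: int = 500) -> float:
        """Region area [T * T/m] by grid quadrature over the box."""
        bz = np.linspace(0.0, self.bz_max, resolution)
        g = np.linspace(0.0, self.grad_max, resolution)
        B, G = np.meshgrid(bz, g, indexing="ij")
        inside = (B * G >= self.L_b) & (B * G <= self.L_u)
        cell = (self.bz_max / (resolution - 1)) * (self.grad_max / (resolution - 1))
        return float(np.count_nonzero(inside) * cell)


def crossing_velocity(t_cross: float, x_membrane: float = X_MEMBRANE_DEFAULT) -> float:
    """Constant crossing speed [m/s] for a bilayer of given thickness."""
    if not (t_cross > 0 and x_membrane > 0):
        raise ValueError("crossing time and membrane thickness must be positive")
    return x_membrane / t_cross


def required_product(
    v_s: float,
    model: TransferFunctionModel,
    carrier: CarrierProperties,
    env: Environment,
) -> float:
    """Steady-state field-gradient product [T^2/m] sustaining speed ``v_s`` [m/s]."""
    if not is_stable(model):
        raise ValueError("model is unstable: no steady-state force exists")
    v_aps = m_per_s_to_angstrom_per_ps(v_s)
    force = dc_gain(model) * v_aps  # [N]
    return env.mu0 * force / (carrier.V * carrier.chi_bead)


def feasible_region(
    L_b: float,
    L_u: float,
    bz_max: float = BZ_MAX_DEFAULT,
    grad_max: float = GRAD_MAX_DEFAULT,
) -> FieldRegion:
    """Feasible actuation region between the two product hyperbolas."""
    return FieldRegion(L_b=L_b, L_u=L_u, bz_max=bz_max, grad_max=grad_max)


#: crossing times routinely examined in region design [s]: 30 s, 1/2/5/10 min
DEFAULT_CROSSING_TIMES = (30.0, 60.0, 120.0, 300.0, 600.0)


def design_for_times(
    times: tuple[float, ...],
    model: TransferFunctionModel,
    carrier: CarrierProperties,
    env: Environment,
    *,
    x_membrane: float = X_MEMBRANE_DEFAULT,
    band: float | None = None,
    bz_max: float = BZ_MAX_DEFAULT,
    grad_max: float = GRAD_MAX_DEFAULT,
) -> list[FieldRegion]:
    """One feasible region per target crossing time.

    Each time is read as a deadline ("cross within t"): the minimum
    acceptable speed x_membrane / t fixes the lower product bound L_b, and
    the upper bound is whatever the device can deliver (the box corner
    product), so regions for successively shorter deadlines are nested and
    the t -> infinity limit recovers the full box.

    Passing ``band`` switches to time-window targeting: the velocity band
    [(1-band) v_s, (1+band) v_s] maps linearly onto [L_b, L_u], selecting
    the thin hyperbola strip that crosses in approximately t seconds.
    Region metadata records the time, nominal speed and nominal product.
    """
    capacity = bz_max * grad_max
    regions = []
    for t in times:
        if not t > 0:
            raise ValueError("crossing times must be positive")
        v_s = crossing_velocity(t, x_membrane)
        nominal = required_product(v_s, model, carrier, env)
        if band is None:
            L_b, L_u = nominal, max(capacity, nominal)
        else:
            L_b, L_u = (1.0 - band) * nominal, (1.0 + band) * nominal
        region = FieldRegion(
            L_b=L_b,
            L_u=L_u,
            bz_max=bz_max,
            grad_max=grad_max,
            meta={
                "t_cross_s": t,
                "x_membrane_m": x_membrane,
                "v_s_m_per_s": v_s,
                "nominal_product_T2_per_m": nominal,
                "band": band,
            },
        )
        regions.append(region)
    return regions
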