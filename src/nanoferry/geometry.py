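"""Carrier geometry: CNT diameter from chirality and sphere-equivalent radius.

A single-wall carbon nanotube is indexed by the chiral pair (m, n) that
describes how the graphene sheet is rolled; together with the graphene
lattice constant a0 this fixes the tube diameter

    d = (a0 / pi) * sqrt(n^2 + m^2 + m n).

For magnetophoresis the elongated tube is replaced by its volume-equivalent
sphere: a cylinder of length L and radius r has the same volume as a sphere
of radius

    r_ave = ((3/4) * L * r^2) ** (1/3),

and the sphere-drag (Stokes) and magnetic-volume formulas are applied to
that equivalent sphere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

#: graphene lattice constant [nm]
A0_LATTICE_NM = 0.246
#: default magnetic susceptibility of the bead-loaded carrier (dimensionless)
CHI_BEAD_DEFAULT = 0.17


@dataclass(frozen=True)
class ChiralIndices:
    """Chiral index pair (m, n) plus the graphene lattice constant in nm."""

    m: int
    n: int
    a0_lattice: float = A0_LATTICE_NM

    def __post_init__(self) -> None:
        if self.m < 0 or self.n < 0:
            raise ValueError(f"chiral indices must be non-negative, got ({self.m}, {self.n})")
        if self.m + self.n == 0:
            raise ValueError("chiral indices (0, 0) do not define a tube")
        if not self.a0_lattice > 0:
            raise ValueError(f"lattice constant must be positive, got {self.a0_lattice}")


@dataclass(frozen=True)
class CarrierProperties:
    """Geometric, inertial and magnetic properties of a functionalized carrier.

    All fields are SI.  ``d_p`` is the effective particle diameter used in the
    Stokes drag law; by default it is the equivalent-sphere diameter
    ``2 * r_ave`` but it may be overridden at construction.
    """

    L_cnt: float          # tube length [m]
    r_cnt: float          # tube radius [m]
    r_ave: float          # volume-equivalent sphere radius [m]
    V: float              # carrier volume [m^3]
    rho_p: float          # density [kg/m^3]
    d_p: float            # effective particle diameter [m]
    m_p: float            # mass [kg]
    chi_bead: float = CHI_BEAD_DEFAULT  # magnetic susceptibility, dimensionless

    def __post_init__(self) -> None:
        for name in ("L_cnt", "r_cnt", "r_ave", "V", "rho_p", "d_p", "m_p"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive, got {getattr(self, name)}")
        v_sphere = (4.0 / 3.0) * math.pi * self.r_ave ** 3
        if abs(self.V - v_sphere) > 1e-12 * v_sphere:
            raise ValueError(
                f"volume {self.V} inconsistent with equivalent radius {self.r_ave} "
                f"(expected {v_sphere})"
            )


def cnt_diameter(idx: ChiralIndices) -> float:
    """Tube diameter [nm] from the chiral indices.

    >>> round(cnt_diameter(ChiralIndices(150, 150)), 3)
    20.344
    """
    m, n = idx.m, idx.n
    return idx.a0_lattice / math.pi * math.sqrt(n * n + m * m + m * n)


def equivalent_radius(L_cnt: float, r_cnt: float) -> float:
    """Radius [m] of the sphere with the same volume as the cylinder (L, r).

    Solves (4/3) pi r_ave^3 = pi r_cnt^2 L_cnt.
    """
    if not (L_cnt > 0 and r_cnt > 0):
        raise ValueError(f"cylinder dimensions must be positive, got L={L_cnt}, r={r_cnt}")
    return (0.75 * L_cnt * r_cnt * r_cnt) ** (1.0 / 3.0)


def build_carrier(
    L_cnt: float,
    r_cnt: float,
    rho_p: float,
    chi_bead: float = CHI_BEAD_DEFAULT,
    d_p: float | None = None,
) -> CarrierProperties:
    """Assemble a :class:`CarrierProperties` from primitive dimensions.

    ``d_p`` defaults to the equivalent-sphere diameter ``2 * r_ave``, the
    diameter at which sphere-drag formulas see the tube.
    """
    if not rho_p > 0:
        raise ValueError(f"density must be positive, got {rho_p}")
    r_ave = equivalent_radius(L_cnt, r_cnt)
    V = (4.0 / 3.0) * math.pi * r_ave ** 3
    return CarrierProperties(
        L_cnt=L_cnt,
        r_cnt=r_cnt,
        r_ave=r_ave,
        V=V,
        rho_p=rho_p,
        d_p=2.0 * r_ave if d_p is None else d_p,
        m_p=rho_p * V,
        chi_bead=chi_bead,
    )
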