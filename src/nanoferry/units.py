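"""Unit conversions used at the package boundary.

Internally everything is SI.  The membrane transfer function is the one
exception: its input velocity is expressed in Å/ps (the scale at which
steered-pulling records are taken) and its output force in newtons, so the
gain ``k`` carries units of N per (Å/ps).  The converters here make every
crossing between the two unit systems explicit.
"""

from __future__ import annotations

#: metres per ångström
M_PER_ANGSTROM = 1e-10
#: metres per nanometre
M_PER_NM = 1e-9
#: seconds per picosecond
S_PER_PS = 1e-12
#: (m/s) per (Å/ps): 1 Å/ps = 1e-10 m / 1e-12 s = 100 m/s
M_PER_S_PER_ANGSTROM_PER_PS = M_PER_ANGSTROM / S_PER_PS


def angstrom_per_ps_to_m_per_s(v: float) -> float:
    """Convert a velocity from Å/ps to m/s."""
    return v * M_PER_S_PER_ANGSTROM_PER_PS


def m_per_s_to_angstrom_per_ps(v: float) -> float:
    """Convert a velocity from m/s to Å/ps."""
    return v / M_PER_S_PER_ANGSTROM_PER_PS


def nm_to_m(x: float) -> float:
    return x * M_PER_NM


def m_to_nm(x: float) -> float:
    return x / M_PER_NM


def angstrom_to_m(x: float) -> float:
    return x * M_PER_ANGSTROM


def m_to_angstrom(x: float) -> float:
    return x / M_PER_ANGSTROM
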