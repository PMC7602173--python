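"""Discrete transfer-function model of membrane-crossing resistance.

The resistance force a functionalized CNT feels while being pulled through a
lipid bilayer is modelled as a discrete-time LTI map from pulling velocity
(in Å/ps) to interaction force (in N):

    F(z) = H(z) V(z),

where H has the fixed factored pole-zero structure

    H(z) = k z^-1 (1 + a0 z^-1)(1 - a1 z^-1 + a2 z^-2)(1 + a3 z^-1 + a4 z^-2)
           -----------------------------------------------------------------
           (1 + b0 z^-1)(1 - b1 z^-1)(1 - b2 z^-1 + b3 z^-2)(1 + b4 z^-1 + b5 z^-2)

The mixed signs inside the factors are part of the convention: coefficient
values are stored exactly as tabulated for that convention, and
:func:`expand` maps them onto plain ascending-power polynomials in z^-1
(the b/a arrays scipy.signal.lfilter consumes).

The explicit z^-1 in the numerator encodes a one-sample delay: the impulse
response satisfies h[0] = 0 and h[1] = k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
from scipy import signal

#: Identified coefficient set for the functionalized-CNT / POPC-bilayer
#: crossing model (gain k in N per (Å/ps), remaining coefficients
#: dimensionless).
REFERENCE_COEFFICIENTS: Mapping[str, float] = {
    "k": 1.7244e-9,
    "a0": 1.186,
    "a1": 2.16,
    "a2": 1.169,
    "a3": 0.4392,
    "a4": 1.06,
    "b0": 0.9237,
    "b1": 0.5969,
    "b2": 1.997,
    "b3": 0.9972,
    "b4": 0.4635,
    "b5": 0.9926,
}

#: default sampling period [s] (1 ps, the natural steered-pulling timestep)
TS_DEFAULT = 1e-12


@dataclass(frozen=True)
class TransferFunctionModel:
    """Factored discrete transfer function from velocity [Å/ps] to force [N].

    ``a_coeffs`` = (a0..a4) are the numerator-section coefficients,
    ``b_coeffs`` = (b0..b5) the denominator-section coefficients, stored in
    the sign convention of the factored form (see module docstring).
    """

    k: float
    a_coeffs: tuple[float, float, float, float, float]
    b_coeffs: tuple[float, float, float, float, float, float]
    Ts: float = TS_DEFAULT

    def __post_init__(self) -> None:
        if not self.Ts > 0:
            raise ValueError(f"sampling period must be positive, got {self.Ts}")
        if len(self.a_coeffs) != 5 or len(self.b_coeffs) != 6:
            raise ValueError("expected 5 numerator and 6 denominator section coefficients")
        object.__setattr__(self, "a_coeffs", tuple(float(c) for c in self.a_coeffs))
        object.__setattr__(self, "b_coeffs", tuple(float(c) for c in self.b_coeffs))

    # -- factor views -------------------------------------------------------

    def numerator_factors(self) -> list[np.ndarray]:
        """Numerator factors as ascending polynomials in z^-1 (gain excluded).

        The leading [0, 1] factor is the explicit one-sample delay z^-1.
        """
        a0, a1, a2, a3, a4 = self.a_coeffs
        return [
            np.array([0.0, 1.0]),          # z^-1
            np.array([1.0, a0]),           # 1 + a0 z^-1
            np.array([1.0, -a1, a2]),      # 1 - a1 z^-1 + a2 z^-2
            np.array([1.0, a3, a4]),       # 1 + a3 z^-1 + a4 z^-2
        ]

    def denominator_factors(self) -> list[np.ndarray]:
        """Denominator factors as ascending polynomials in z^-1."""
        b0, b1, b2, b3, b4, b5 = self.b_coeffs
        return [
            np.array([1.0, b0]),           # 1 + b0 z^-1
            np.array([1.0, -b1]),          # 1 - b1 z^-1
            np.array([1.0, -b2, b3]),      # 1 - b2 z^-1 + b3 z^-2
            np.array([1.0, b4, b5]),       # 1 + b4 z^-1 + b5 z^-2
        ]


@dataclass
class TraceRecord:
    """Paired velocity/force time series on a uniform grid.

    t in seconds, u in Å/ps, y in N.  ``meta`` carries free-form provenance
    (generator seed, ground-truth coefficients, nominal velocity, ...).
    """

    t: np.ndarray
    u: np.ndarray
    y: np.ndarray
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.t) == len(self.u) == len(self.y)):
            raise ValueError("t, u, y must have equal lengths")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if not np.allclose(dt, dt[0], rtol=1e-9, atol=0.0):
                raise ValueError("time grid must be uniform")

    @property
    def Ts(self) -> float:
        """Sampling period [s]."""
        if len(self.t) < 2:
            raise ValueError("need at least two samples to define Ts")
        return float(self.t[1] - self.t[0])


def reference_model(Ts: float = TS_DEFAULT) -> TransferFunctionModel:
    """The identified membrane-resistance model with its published coefficients.

    ``Ts`` is free: the tabulated coefficients define the discrete dynamics
    per sample, and all steady-state design quantities are Ts-independent.
    """
    c = REFERENCE_COEFFICIENTS
    return TransferFunctionModel(
        k=c["k"],
        a_coeffs=(c["a0"], c["a1"], c["a2"], c["a3"], c["a4"]),
        b_coeffs=(c["b0"], c["b1"], c["b2"], c["b3"], c["b4"], c["b5"]),
        Ts=Ts,
    )


def expand(model: TransferFunctionModel) -> tuple[np.ndarray, np.ndarray]:
    """Expand the factored form into (num, den) ascending polynomials in z^-1.

    num has degree 6 with zero constant term (the explicit delay); den is
    monic of degree 6.  These are directly the (b, a) arrays of
    ``scipy.signal.lfilter``.
    """
    num = np.array([model.k])
    for f in model.numerator_factors():
        num = np.convolve(num, f)
    den = np.array([1.0])
    for f in model.denominator_factors():
        den = np.convolve(den, f)
    return num, den


def simulate_force(model: TransferFunctionModel, u: Sequence[float]) -> np.ndarray:
    """Force response [N] to a velocity input series [Å/ps], zero initial state."""
    u = np.asarray(u, dtype=float)
    if not np.all(np.isfinite(u)):
        raise ValueError("input velocity series contains non-finite values")
    num, den = expand(model)
    return signal.lfilter(num, den, u)


def dc_gain(model: TransferFunctionModel) -> float:
    """Steady-state gain H(1) [N per (Å/ps)].

    Raises ``ZeroDivisionError`` when z = 1 is a pole (no steady state).
    """
    num, den = expand(model)
    d1 = float(np.sum(den))
    n1 = float(np.sum(num))
    if d1 == 0.0:
        raise ZeroDivisionError("z = 1 is a pole of the model; DC gain undefined")
    return n1 / d1


def poles_zeros(model: TransferFunctionModel) -> tuple[np.ndarray, np.ndarray]:
    """(poles, zeros) in the z-plane, from the expanded polynomials."""
    num, den = expand(model)
    poles = np.roots(den)
    # strip the delay: zeros are roots of the degree-5 polynomial after z^-1
    num_core = np.trim_zeros(num, "f")
    zeros = np.roots(num_core) if len(num_core) > 1 else np.array([])
    return poles, zeros


def is_stable(model: TransferFunctionModel) -> bool:
    """True iff every pole lies strictly inside the unit circle."""
    poles, _ = poles_zeros(model)
    return bool(np.all(np.abs(poles) < 1.0))


def frequency_response(
    model: TransferFunctionModel, omega_grid: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    """|H(e^{j w})| and unwrapped phase on a grid of w in [0, pi] rad/sample."""
    omega = np.asarray(omega_grid, dtype=float)
    if np.any(omega < 0) or np.any(omega > np.pi):
        raise ValueError("frequencies must lie in [0, pi] rad/sample")
    num, den = expand(model)
    zinv = np.exp(-1j * omega)
    h = np.polynomial.polynomial.polyval(zinv, num) / np.polynomial.polynomial.polyval(zinv, den)
    return np.abs(h), np.unwrap(np.angle(h))


# -- serialization ----------------------------------------------------------

def model_to_dict(model: TransferFunctionModel) -> dict[str, Any]:
    return {"k": model.k, "a": list(model.a_coeffs), "b": list(model.b_coeffs), "Ts": model.Ts}


def model_from_dict(d: Mapping[str, Any]) -> TransferFunctionModel:
    return TransferFunctionModel(
        k=float(d["k"]), a_coeffs=tuple(d["a"]), b_coeffs=tuple(d["b"]), Ts=float(d["Ts"])
    )


def save_model(model: TransferFunctionModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2) + "\n")


def load_model(path: str | Path) -> TransferFunctionModel:
    return model_from_dict(json.loads(Path(path).read_text()))
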