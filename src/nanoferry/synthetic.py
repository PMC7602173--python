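"""Synthetic steered-crossing records and tracking targets.

The generator emulates the data-collection protocol behind the membrane
model: a carrier is pulled through the bilayer at a set of constant
velocities (1.0 to 2.0 Å/ps in 0.1 Å/ps steps) while the interaction force
is recorded.  Here the "membrane" is a known ground-truth transfer function,
so every record carries its own truth and parameter-recovery experiments are
exact.  Measurement noise is additive Gaussian on the force channel only,
scaled to a stated fraction of the record's peak force; inputs are exact.

Records begin with a rest preamble (zero input) so the zero-initial-state
assumption of the filter holds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .membrane_tf import TS_DEFAULT, TraceRecord, TransferFunctionModel, simulate_force

#: pulling velocities of the crossing protocol [Å/ps]
DEFAULT_VELOCITIES: tuple[float, ...] = tuple(round(1.0 + 0.1 * i, 1) for i in range(11))


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions under which synthetic crossing records are produced."""

    velocities: tuple[float, ...] = DEFAULT_VELOCITIES
    n_samples: int = 2000
    noise_sigma: float = 0.0       # additive force noise, fraction of peak |force|
    seed: int = 0
    Ts: float = TS_DEFAULT
    n_rest: int = 50               # rest preamble length [samples]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.velocities):
            raise ValueError("velocities must be positive")
        if not 0.0 <= self.noise_sigma < 1.0:
            raise ValueError(f"noise_sigma must be in [0, 1), got {self.noise_sigma}")
        if self.n_samples < 10:
            raise ValueError("n_samples must be at least 10")
        if not 0 <= self.n_rest < self.n_samples:
            raise ValueError("rest preamble must fit inside the record")


def generate_crossing_records(
    spec: GeneratorSpec, truth: TransferFunctionModel
) -> list[TraceRecord]:
    """One constant-velocity record per protocol velocity.

    Each record is the truth model's force response to a rest-then-constant
    velocity input, plus seeded Gaussian noise at ``noise_sigma`` x peak
    |force|.  The same spec (same seed) reproduces records bit for bit.
    """
    rng = np.random.default_rng(spec.seed)
    t = np.arange(spec.n_samples) * spec.Ts
    records = []
    for v in spec.velocities:
        u = np.full(spec.n_samples, float(v))
        u[: spec.n_rest] = 0.0
        y_clean = simulate_force(truth, u)
        y = y_clean
        if spec.noise_sigma > 0:
            scale = spec.noise_sigma * np.max(np.abs(y_clean))
            y = y_clean + rng.normal(0.0, scale, size=y_clean.shape)
        records.append(
            TraceRecord(
                t=t,
                u=u,
                y=y,
                meta={
                    "kind": "constant_velocity_crossing",
                    "velocity_A_per_ps": v,
                    "noise_sigma": spec.noise_sigma,
                    "seed": spec.seed,
                    "truth": {"k": truth.k, "a": list(truth.a_coeffs), "b": list(truth.b_coeffs)},
                },
            )
        )
    return records


#: default impulse spacing [samples].  Identification inputs are designed
#: dense: at 40-sample spacing the membrane model's ringing responses
#: overlap enough that the response crest factor (peak/RMS) stays below 5,
#: the usual input-design consideration when measurement noise is scaled to
#: the record's peak.
IMPULSE_SPACING_DEFAULT = 40


def generate_impulse_train(
    spec: GeneratorSpec, spacing: int | None = None
) -> TraceRecord:
    """Impulse-train velocity input suited to identification.

    Impulse amplitudes cycle through ``spec.velocities`` in order, one
    impulse every ``spacing`` samples.  The force channel is zero — this is
    an input record; pass it through a model to obtain an identification
    pair.
    """
    if spacing is None:
        spacing = IMPULSE_SPACING_DEFAULT
    if spacing < 1:
        raise ValueError("impulse spacing must be >= 1")
    t = np.arange(spec.n_samples) * spec.Ts
    u = np.zeros(spec.n_samples)
    idx = np.arange(spec.n_rest, spec.n_samples, spacing)
    for j, i in enumerate(idx):
        u[i] = spec.velocities[j % len(spec.velocities)]
    return TraceRecord(
        t=t,
        u=u,
        y=np.zeros(spec.n_samples),
        meta={"kind": "impulse_train", "spacing": spacing, "seed": spec.seed},
    )


def make_identification_record(
    spec: GeneratorSpec, truth: TransferFunctionModel, spacing: int | None = None
) -> TraceRecord:
    """Impulse-train input filtered through the truth model, with seeded noise."""
    base = generate_impulse_train(spec, spacing=spacing)
    y_clean = simulate_force(truth, base.u)
    y = y_clean
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        scale = spec.noise_sigma * np.max(np.abs(y_clean))
        y = y_clean + rng.normal(0.0, scale, size=y_clean.shape)
    meta = dict(base.meta)
    meta.update(
        kind="impulse_train_response",
        noise_sigma=spec.noise_sigma,
        truth={"k": truth.k, "a": list(truth.a_coeffs), "b": list(truth.b_coeffs)},
    )
    return TraceRecord(t=base.t, u=base.u, y=y, meta=meta)


# -- tracking targets -------------------------------------------------------

@dataclass(frozen=True)
class Target:
    """Desired position profile z_d(t) with analytic first and second derivatives."""

    kind: str
    amplitude: float          # [m]
    t_final: float            # [s]
    zd: Callable[[float], float] = field(repr=False, compare=False, default=None)
    zd_dot: Callable[[float], float] = field(repr=False, compare=False, default=None)
    zd_ddot: Callable[[float], float] = field(repr=False, compare=False, default=None)


def make_target(profile_kind: str, amplitude: float, t_final: float) -> Target:
    """Built-in target profiles for inner-cell translocation.

    ``step``: z_d = amplitude for t >= 0 (derivatives zero);
    ``ramp``: linear rise to amplitude over t_final, then hold;
    ``smoothstep``: quintic ease with zero velocity/acceleration at both ends.
    Amplitudes of interest span 1 Å to 1000 Å (1e-10 to 1e-7 m).
    """
    if not (amplitude > 0 and t_final > 0):
        raise ValueError("amplitude and t_final must be positive")
    A, T = float(amplitude), float(t_final)

    if profile_kind == "step":
        return Target("step", A, T, zd=lambda t: A, zd_dot=lambda t: 0.0, zd_ddot=lambda t: 0.0)

    if profile_kind == "ramp":
        rate = A / T

        def zd(t: float) -> float:
            return A if t >= T else rate * t

        def zd_dot(t: float) -> float:
            return 0.0 if t >= T else rate

        return Target("ramp", A, T, zd=zd, zd_dot=zd_dot, zd_ddot=lambda t: 0.0)

    if profile_kind == "smoothstep":
        # quintic 10 s^3 - 15 s^4 + 6 s^5: C^2, endpoint derivatives vanish
        def zd(t: float) -> float:
            if t <= 0:
                return 0.0
            if t >= T:
                return A
            s = t / T
            return A * (10 * s**3 - 15 * s**4 + 6 * s**5)

        def zd_dot(t: float) -> float:
            if t <= 0 or t >= T:
                return 0.0
            s = t / T
            return A / T * (30 * s**2 - 60 * s**3 + 30 * s**4)

        def zd_ddot(t: float) -> float:
            if t <= 0 or t >= T:
                return 0.0
            s = t / T
            return A / T**2 * (60 * s - 180 * s**2 + 120 * s**3)

        return Target("smoothstep", A, T, zd=zd, zd_dot=zd_dot, zd_ddot=zd_ddot)

    raise ValueError(f"unknown target profile kind: {profile_kind!r}")
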