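"""Ontogenetic growth model and temperature fold-change laws.

The model treats development as a quarter-power growth process

    dm/dt = a(T) * m^z * [1 - (m/M)^(1-z)],        z = 3/4 by default,

whose rate coefficient ``a`` carries an Arrhenius (Boltzmann-factor)
temperature dependence with activation energy ``E``.  Measuring temperature
``T`` in degrees Celsius relative to the water freezing point ``Ta = 273 K``
gives the rate multiplier

    a(T) / a(0 °C) = exp[ E/(K*Ta^2) * T/(1 + T/Ta) ]
                   ≈ exp[ E/(K*Ta^2) * T ]            (linearized; T << Ta).

Two closed-form fold-change laws follow when eclosion mass is temperature
independent and the brain grows with its own, lower activation energy
``E' = E − ΔE``:

    developmental time:  t/t0 = exp[-alpha * (T - T0)],  alpha = E /(K*Ta^2)
    connectivity:        n/n0 = exp[-beta  * (T - T0)],  beta  = 4*ΔE/(K*Ta^2)

with reference temperature ``T0`` (25 °C throughout).  Temperatures cross the
public API in °C; kelvin only appears inside :func:`rate_factor`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .errors import InvalidArgumentError, NumericalError

__all__ = [
    "BOLTZMANN_EV_PER_K",
    "WATER_FREEZING_K",
    "ThermalConstants",
    "GrowthParams",
    "ScalingParams",
    "ActivationEnergies",
    "GrowthTrajectory",
    "rate_factor",
    "solve_growth",
    "time_to_mass",
    "devtime_fold_change",
    "connectivity_fold_change",
    "activation_energies",
    "relative_brain_stage",
]

#: Boltzmann constant in electron-volt per kelvin.
BOLTZMANN_EV_PER_K = 8.617e-5
#: Reference temperature for the Celsius substitution: water freezing point, kelvin.
WATER_FREEZING_K = 273.0

Mode = Literal["exact", "linearized"]


def _check_finite_real(name: str, value) -> np.ndarray:
    arr = np.asarray(value)
    if np.iscomplexobj(arr):
        raise InvalidArgumentError(f"{name} must be real, got complex values")
    arr = arr.astype(float, copy=False)
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError(f"{name} must be finite, got {value!r}")
    return arr


@dataclass(frozen=True)
class ThermalConstants:
    """Physical constants of the Arrhenius rate law.

    Attributes
    ----------
    boltzmann_k
        Boltzmann constant, eV/K.
    t_a
        Reference temperature of the Celsius substitution, kelvin.  The water
        freezing point (273 K) unless deliberately overridden.
    """

    boltzmann_k: float = BOLTZMANN_EV_PER_K
    t_a: float = WATER_FREEZING_K

    def __post_init__(self) -> None:
        if not (self.boltzmann_k > 0 and np.isfinite(self.boltzmann_k)):
            raise InvalidArgumentError("boltzmann_k must be strictly positive and finite")
        if not (self.t_a > 0 and np.isfinite(self.t_a)):
            raise InvalidArgumentError("t_a must be strictly positive and finite")

    @property
    def kt2(self) -> float:
        """K * Ta^2 — the denominator converting activation energy (eV) to a per-°C factor."""
        return self.boltzmann_k * self.t_a**2


DEFAULT_CONSTANTS = ThermalConstants()


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the quarter-power growth equation.

    ``base_rate`` is the rate coefficient a(Ta, E) at the Celsius origin
    (0 °C), in mass^(1-exponent) per unit time.  If the metabolic provenance
    triple (``metabolic_norm`` B0, ``cell_mass`` m_c, ``cell_energy`` E_c) is
    supplied, ``base_rate`` must equal B0*m_c/E_c.
    """

    base_rate: float
    activation_energy: float
    asymptotic_mass: float
    initial_mass: float = 0.0
    exponent: float = 0.75
    cell_mass: float | None = None
    cell_energy: float | None = None
    metabolic_norm: float | None = None

    def __post_init__(self) -> None:
        if not (self.base_rate > 0):
            raise InvalidArgumentError("base_rate must be > 0")
        if not (self.activation_energy > 0):
            raise InvalidArgumentError("activation_energy must be > 0")
        if not (self.asymptotic_mass > 0):
            raise InvalidArgumentError("asymptotic_mass must be > 0")
        if not (0.0 <= self.initial_mass < self.asymptotic_mass):
            raise InvalidArgumentError("initial_mass must satisfy 0 <= m0 < asymptotic_mass")
        if not (0.0 < self.exponent < 1.0):
            raise InvalidArgumentError("exponent must lie strictly between 0 and 1")
        prov = (self.metabolic_norm, self.cell_mass, self.cell_energy)
        if all(v is not None for v in prov):
            implied = self.metabolic_norm * self.cell_mass / self.cell_energy
            if not np.isclose(self.base_rate, implied, rtol=1e-9):
                raise InvalidArgumentError(
                    f"base_rate {self.base_rate} inconsistent with B0*m_c/E_c = {implied}"
                )


@dataclass(frozen=True)
class ScalingParams:
    """Fitted macroscopic scaling factors of the exponential fold-change laws.

    alpha and beta are in per-°C; gamma = alpha − beta/4 governs step-cycle
    predictions and, when omitted, is derived.  ``ref_temp`` is T0 in °C.
    """

    alpha: float
    beta: float
    ref_temp: float = 25.0
    gamma: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        _check_finite_real("alpha", self.alpha)
        _check_finite_real("beta", self.beta)
        if not (10.0 <= self.ref_temp <= 35.0):
            raise InvalidArgumentError("ref_temp must lie within [10, 35] °C")
        derived = self.alpha - self.beta / 4.0
        if self.gamma is None:
            object.__setattr__(self, "gamma", derived)
        elif abs(self.gamma - derived) > 1e-12:
            raise InvalidArgumentError(
                f"gamma={self.gamma} violates gamma = alpha - beta/4 = {derived}"
            )

    def delta_e(self, constants: ThermalConstants = DEFAULT_CONSTANTS) -> float:
        """Activation-energy gap ΔE = beta*K*Ta^2/4, eV."""
        return self.beta * constants.kt2 / 4.0


#: The study's fitted factors: alpha = 0.128 per °C, beta = 0.133 per °C, T0 = 25 °C.
FITTED_SCALING = ScalingParams(alpha=0.128, beta=0.133, ref_temp=25.0)


def rate_factor(
    temp_c,
    activation_energy: float,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "linearized",
):
    """Temperature multiplier of the growth rate, relative to the rate at 0 °C.

    ``exact`` evaluates exp[E/(K*Ta^2) * T/(1+T/Ta)] (the full Boltzmann factor
    after the Celsius substitution); ``linearized`` drops the 1/(1+T/Ta)
    correction, which is at most ~10% for T ≤ 32 °C.  The fitted alpha and
    beta refer to the linearized form, hence the default.
    """
    t = _check_finite_real("temp_c", temp_c)
    e = _check_finite_real("activation_energy", activation_energy)
    if not np.all(e > 0):
        raise InvalidArgumentError("activation_energy must be > 0")
    slope = e / constants.kt2
    if mode == "linearized":
        exponent = slope * t
    elif mode == "exact":
        exponent = slope * t / (1.0 + t / constants.t_a)
    else:
        raise InvalidArgumentError(f"mode must be 'exact' or 'linearized', got {mode!r}")
    out = np.exp(exponent)
    return float(out) if np.isscalar(temp_c) or out.ndim == 0 else out


@dataclass(frozen=True)
class GrowthTrajectory:
    """Mass trajectory on a uniform time grid."""

    times: np.ndarray
    masses: np.ndarray
    temp_c: float
    params: GrowthParams


def _growth_rate_constant(
    params: GrowthParams,
    temp_c: float,
    constants: ThermalConstants,
    mode: Mode,
) -> float:
    """Linear relaxation rate of u = (m/M)^(1-z): du/dt = k (1 - u)."""
    a = params.base_rate * rate_factor(temp_c, params.activation_energy, constants, mode)
    return (1.0 - params.exponent) * a * params.asymptotic_mass ** (params.exponent - 1.0)


def solve_growth(
    params: GrowthParams,
    temp_c: float,
    t_end: float,
    n_steps: int = 200,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "linearized",
    rtol: float = 1e-8,
) -> GrowthTrajectory:
    """Integrate the growth equation at a fixed temperature.

    The ODE is integrated in the substituted coordinate u = (m/M)^(1-z), in
    which dm/dt = a m^z [1-(m/M)^(1-z)] becomes the linear relaxation
    du/dt = k (1-u).  The substitution removes the non-Lipschitz fixed point
    at m = 0 (growth from zero mass — the model's initial condition after
    metamorphic pruning — is unreachable for any integrator working in the
    raw mass coordinate) while leaving the solve genuinely numerical.
    """
    if not (t_end > 0):
        raise InvalidArgumentError("t_end must be > 0")
    if n_steps < 2:
        raise InvalidArgumentError("n_steps must be >= 2")
    k = _growth_rate_constant(params, temp_c, constants, mode)
    one_minus_z = 1.0 - params.exponent
    u0 = (params.initial_mass / params.asymptotic_mass) ** one_minus_z
    times = np.linspace(0.0, t_end, n_steps)
    sol = solve_ivp(
        lambda _t, u: k * (1.0 - u),
        (0.0, t_end),
        [u0],
        t_eval=times,
        rtol=rtol,
        atol=1e-14,
        max_step=t_end / 20.0,  # keep dense-output error small at early times
        method="RK45",
    )
    if not sol.success:
        raise NumericalError(
            f"growth ODE failed at T={temp_c} °C: {sol.message}; "
            f"nfev={sol.nfev}, last t={sol.t[-1] if sol.t.size else 'none'}"
        )
    # clip roundoff excursions and project onto the monotone envelope the
    # dynamics guarantee (du/dt >= 0 for u <= 1)
    u = np.maximum.accumulate(np.clip(sol.y[0], 0.0, 1.0))
    masses = params.asymptotic_mass * u ** (1.0 / one_minus_z)
    return GrowthTrajectory(times=times, masses=masses, temp_c=float(temp_c), params=params)


def time_to_mass(
    params: GrowthParams,
    temp_c: float,
    target_mass: float | None = None,
    constants: ThermalConstants = DEFAULT_CONSTANTS,
    mode: Mode = "linearized",
    rtol: float = 1e-10,
) -> float:
    """Time for the growth ODE to reach a target mass (developmental time).

    Defaults to the small-mass regime target 1e-3 * M, so the implied
    developmental times follow the exponential fold-change law.  Solved with
    an integrator event, not the closed form.
    """
    if target_mass is None:
        target_mass = 1e-3 * params.asymptotic_mass
    if not (params.initial_mass < target_mass < params.asymptotic_mass):
        raise InvalidArgumentError("target_mass must lie in (initial_mass, asymptotic_mass)")
    k = _growth_rate_constant(params, temp_c, constants, mode)
    one_minus_z = 1.0 - params.exponent
    u0 = (params.initial_mass / params.asymptotic_mass) ** one_minus_z
    u_target = (target_mass / params.asymptotic_mass) ** one_minus_z
    # generous horizon: relaxation time to the target, times safety margin
    horizon = -np.log((1.0 - u_target) / (1.0 - u0)) / k * 4.0 + 1.0 / k

    def event(_t, u):
        return u[0] - u_target

    event.terminal = True
    event.direction = 1
    sol = solve_ivp(
        lambda _t, u: k * (1.0 - u),
        (0.0, horizon),
        [u0],
        events=event,
        rtol=rtol,
        atol=1e-14,
        method="RK45",
        dense_output=True,
    )
    if not sol.success or not sol.t_events[0].size:
        raise NumericalError(
            f"target mass not reached within horizon {horizon} at T={temp_c} °C "
            f"({sol.message}; nfev={sol.nfev})"
        )
    return float(sol.t_events[0][0])


def devtime_fold_change(temp_c, scaling: ScalingParams):
    """Developmental-time ratio t/t0 = exp[-alpha (T - T0)]."""
    t = _check_finite_real("temp_c", temp_c)
    out = np.exp(-scaling.alpha * (t - scaling.ref_temp))
    return float(out) if out.ndim == 0 else out


def connectivity_fold_change(temp_c, scaling: ScalingParams):
    """Synaptic-partner ratio n/n0 = exp[-beta (T - T0)].

    Identically 1 at every temperature when beta = 0 (no activation-energy
    gap between body and brain growth).
    """
    t = _check_finite_real("temp_c", temp_c)
    out = np.exp(-scaling.beta * (t - scaling.ref_temp))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ActivationEnergies:
    """Activation energies implied by the fitted scaling factors, eV."""

    e: float
    delta_e: float
    e_prime: float


def activation_energies(
    scaling: ScalingParams, constants: ThermalConstants = DEFAULT_CONSTANTS
) -> ActivationEnergies:
    """Convert (alpha, beta) to activation energies.

    E = alpha*K*Ta^2 is the activation energy of the reaction limiting whole-
    body development; ΔE = beta*K*Ta^2/4 the gap to the brain's reaction; the
    brain's activation energy is E' = E − ΔE.  Warns (rather than failing)
    when beta ≥ 4*alpha, which would imply a negative E'.
    """
    if not (scaling.alpha > 0 and scaling.beta >= 0):
        raise InvalidArgumentError("alpha must be > 0 and beta >= 0")
    e = scaling.alpha * constants.kt2
    delta_e = scaling.beta * constants.kt2 / 4.0
    e_prime = e - delta_e
    if e_prime <= 0:
        warnings.warn(
            f"beta >= 4*alpha implies a non-positive brain activation energy (E'={e_prime:.4g} eV)",
            RuntimeWarning,
            stacklevel=2,
        )
    return ActivationEnergies(e=e, delta_e=delta_e, e_prime=e_prime)


def relative_brain_stage(temp_c, scaling: ScalingParams):
    """Fold advancement of brain state at a matched fraction of ontogenesis.

    The brain develops with the faster-relative rate E' but for a body-set
    duration, so at any fixed fraction of ontogenesis (in the small-mass
    regime) its state is advanced by exp[-beta (T - T0)] relative to the
    reference temperature — colder development yields a more advanced brain.
    The fraction drops out: the advancement is the connectivity fold change.
    """
    return connectivity_fold_change(temp_c, scaling)
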