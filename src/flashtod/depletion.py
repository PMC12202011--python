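"""Zero-dimensional two-stage kinetic model of radiolytic oxygen depletion.

A continuous irradiation at constant dose rate generates generic radiolytic
species (first stage) which either capture dissolved oxygen (second stage)
or decay through oxygen-independent channels.  The well-mixed system is

    d[R]/dt  = g * ddot - k_capture * [R] * [O2] - k_decay * [R]
    d[O2]/dt = -k_capture * [R] * [O2]
               + recovery_rate * ([O2]_ambient - [O2]) - metabolic_rate

with ``[R](0) = 0`` and ``[O2](0)`` set from the initial oxygen tension via
the solubility coefficient.  Oxygen is hard-clamped at zero: radicals are
still produced in the anoxic regime but then only decay.

A quasi-steady-state (QSS) reduction eliminates the radical pool:

    d[O2]/dt = -g * ddot * [O2] / ([O2] + K_R) + recovery - metabolism,
    K_R = k_decay / k_capture

valid when the radical relaxation time ``1/(k_decay + k_capture*[O2])`` is
short compared to the exposure duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import DomainError, IntegrationError

#: Default total pressure used for %O2 <-> mmHg conversion.
TOTAL_PRESSURE_MMHG = 760.0

#: Dissolved-oxygen solubility of water at 37 degC, mol m^-3 mmHg^-1.
DEFAULT_SOLUBILITY = 1.295e-3


@dataclass(frozen=True)
class KineticParams:
    """Rate constants and closure parameters of the depletion model.

    Parameters
    ----------
    g_consumption:
        Radiolytic species yield per unit dose, mol m^-3 Gy^-1.
    k_capture:
        Second-order rate constant for radical + O2, m^3 mol^-1 s^-1.
    k_decay:
        First-order radical loss to non-oxygen channels, s^-1.
    recovery_rate:
        First-order relaxation of oxygen toward ambient, s^-1.
    metabolic_rate:
        Zero-order metabolic oxygen consumption, mol m^-3 s^-1.
    solubility:
        Dissolved-O2 concentration per unit partial pressure,
        mol m^-3 mmHg^-1.
    """

    g_consumption: float = 3e-4
    k_capture: float = 1e7
    k_decay: float = 3000.0
    recovery_rate: float = 2.0
    metabolic_rate: float = 0.0
    solubility: float = DEFAULT_SOLUBILITY

    def __post_init__(self) -> None:
        for name in (
            "g_consumption",
            "k_capture",
            "k_decay",
            "recovery_rate",
            "metabolic_rate",
            "solubility",
        ):
            value = getattr(self, name)
            if not np.isfinite(value) or value < 0:
                raise DomainError(f"{name} must be finite and >= 0, got {value!r}")
        if self.solubility <= 0:
            raise DomainError("solubility must be > 0")
        if self.k_capture <= 0:
            raise DomainError("k_capture must be > 0")

    @property
    def half_capture_concentration(self) -> float:
        """K_R = k_decay / k_capture, mol m^-3 (half-capture oxygen level)."""
        return self.k_decay / self.k_capture


@dataclass(frozen=True)
class Exposure:
    """One continuous irradiation: total dose (Gy) at a constant rate (Gy/s)."""

    dose: float
    dose_rate: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.dose) or self.dose < 0:
            raise DomainError(f"dose must be finite and >= 0, got {self.dose!r}")
        if not np.isfinite(self.dose_rate) or self.dose_rate <= 0:
            raise DomainError(
                f"dose_rate must be finite and > 0, got {self.dose_rate!r}"
            )

    @property
    def duration(self) -> float:
        """Delivery time in seconds (zero dose implies zero duration)."""
        return self.dose / self.dose_rate


@dataclass(frozen=True)
class OxygenEnvironment:
    """Initial and ambient oxygen tension of the irradiated system, mmHg."""

    initial_pO2: float
    ambient_pO2: float | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.initial_pO2) or self.initial_pO2 < 0:
            raise DomainError(
                f"initial_pO2 must be finite and >= 0, got {self.initial_pO2!r}"
            )
        if self.ambient_pO2 is None:
            object.__setattr__(self, "ambient_pO2", self.initial_pO2)
        elif not np.isfinite(self.ambient_pO2) or self.ambient_pO2 < 0:
            raise DomainError(
                f"ambient_pO2 must be finite and >= 0, got {self.ambient_pO2!r}"
            )


@dataclass(frozen=True)
class DepletionTrace:
    """Time course of oxygen tension and radical concentration."""

    times: np.ndarray
    pO2: np.ndarray
    radical_conc: np.ndarray
    end_pO2: float
    method: str = "full"
    params: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "pO2", np.asarray(self.pO2, dtype=float))
        object.__setattr__(
            self, "radical_conc", np.asarray(self.radical_conc, dtype=float)
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.times,
                "pO2_mmHg": self.pO2,
                "radical_mol_m3": self.radical_conc,
            }
        )

    def write_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def percent_to_mmhg(
    percent_O2: float, total_pressure_mmhg: float = TOTAL_PRESSURE_MMHG
) -> float:
    """Convert a gas-phase oxygen fraction (% O2) to partial pressure (mmHg)."""
    if not np.isfinite(percent_O2) or percent_O2 < 0:
        raise DomainError(f"percent_O2 must be finite and >= 0, got {percent_O2!r}")
    if total_pressure_mmhg <= 0:
        raise DomainError("total_pressure_mmhg must be > 0")
    return percent_O2 / 100.0 * total_pressure_mmhg


def mmhg_to_percent(
    pO2: float, total_pressure_mmhg: float = TOTAL_PRESSURE_MMHG
) -> float:
    """Inverse of :func:`percent_to_mmhg`."""
    if not np.isfinite(pO2) or pO2 < 0:
        raise DomainError(f"pO2 must be finite and >= 0, got {pO2!r}")
    return pO2 / total_pressure_mmhg * 100.0


def pressure_to_concentration(pO2: float, params: KineticParams) -> float:
    """Dissolved-O2 concentration (mol m^-3) at a partial pressure (mmHg)."""
    if not np.isfinite(pO2) or pO2 < 0:
        raise DomainError(f"pO2 must be finite and >= 0, got {pO2!r}")
    return pO2 * params.solubility


def concentration_to_pressure(conc: float, params: KineticParams) -> float:
    """Inverse of :func:`pressure_to_concentration`."""
    if not np.isfinite(conc) or conc < 0:
        raise DomainError(f"conc must be finite and >= 0, got {conc!r}")
    return conc / params.solubility


def _time_grid(duration: float, n_points: int) -> np.ndarray:
    # FLASH transients: log spacing resolves the sub-millisecond onset.
    if duration < 0.1:
        grid = np.concatenate(
            [[0.0], np.geomspace(duration * 1e-6, duration, n_points - 1)]
        )
    else:
        grid = np.linspace(0.0, duration, n_points)
    grid[-1] = duration
    return grid


def simulate_depletion(
    env: OxygenEnvironment,
    exposure: Exposure,
    params: KineticParams,
    *,
    method: Literal["full", "qss"] = "full",
    rtol: float = 1e-8,
    atol: float = 1e-12,
    n_points: int = 256,
) -> DepletionTrace:
    """Integrate the depletion model over the delivery of one exposure.

    Parameters
    ----------
    method:
        ``"full"`` integrates the coupled radical/oxygen system;
        ``"qss"`` integrates the quasi-steady-state oxygen-only reduction.

    Returns
    -------
    DepletionTrace
        Trace over ``t in [0, duration]`` with ``end_pO2`` evaluated at the
        point where the full dose has been applied.
    """
    if rtol <= 0 or atol <= 0:
        raise DomainError("solver tolerances must be positive")
    if n_points < 2:
        raise DomainError("n_points must be >= 2")
    if method not in ("full", "qss"):
        raise DomainError(f"unknown method {method!r}")

    c0 = pressure_to_concentration(env.initial_pO2, params)
    c_amb = pressure_to_concentration(env.ambient_pO2, params)
    duration = exposure.duration

    if duration == 0.0:
        times = np.array([0.0])
        return DepletionTrace(
            times=times,
            pO2=np.full_like(times, env.initial_pO2),
            radical_conc=np.zeros_like(times),
            end_pO2=env.initial_pO2,
            method=method,
            params=params,
        )

    g = params.g_consumption
    ddot = exposure.dose_rate
    kc = params.k_capture
    kd = params.k_decay
    kr = params.recovery_rate
    m = params.metabolic_rate
    k_half = params.half_capture_concentration

    def clamp_oxygen_derivative(c: float, dc: float) -> float:
        # Oxygen cannot go negative; sources remain active at the clamp.
        if c <= 0.0 and dc < 0.0:
            return 0.0
        return dc

    if method == "full":

        def rhs(t: float, y: np.ndarray) -> list[float]:
            r, c = y
            c_eff = max(c, 0.0)
            dr = g * ddot - kc * r * c_eff - kd * r
            dc = -kc * r * c_eff + kr * (c_amb - c_eff) - m
            return [dr, clamp_oxygen_derivative(c, dc)]

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            r, c = y
            c_eff = max(c, 0.0)
            return np.array(
                [
                    [-kc * c_eff - kd, -kc * r],
                    [-kc * c_eff, -kc * r - kr],
                ]
            )

        y0 = [0.0, c0]
    else:

        def rhs(t: float, y: np.ndarray) -> list[float]:
            (c,) = y
            c_eff = max(c, 0.0)
            dc = -g * ddot * c_eff / (c_eff + k_half) + kr * (c_amb - c_eff) - m
            return [clamp_oxygen_derivative(c, dc)]

        def jac(t: float, y: np.ndarray) -> np.ndarray:
            (c,) = y
            c_eff = max(c, 0.0)
            return np.array(
                [[-g * ddot * k_half / (c_eff + k_half) ** 2 - kr]]
            )

        y0 = [c0]

    times = _time_grid(duration, n_points)
    sol = solve_ivp(
        rhs,
        (0.0, duration),
        y0,
        method="Radau",
        jac=jac,
        t_eval=times,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        reached = float(sol.t[-1]) if sol.t.size else 0.0
        raise IntegrationError(f"depletion integration failed: {sol.message}", reached)

    if method == "full":
        radicals = np.maximum(sol.y[0], 0.0)
        conc = np.maximum(sol.y[1], 0.0)
    else:
        conc = np.maximum(sol.y[0], 0.0)
        # Reconstructed QSS radical level, for trace compatibility.
        denom = kd + kc * conc
        with np.errstate(divide="ignore"):
            radicals = np.where(denom > 0, g * ddot / np.maximum(denom, 1e-300), 0.0)

    pO2 = conc / params.solubility
    return DepletionTrace(
        times=sol.t,
        pO2=pO2,
        radical_conc=radicals,
        end_pO2=float(pO2[-1]),
        method=method,
        params=params,
    )
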