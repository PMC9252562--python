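"""Two-risk-group SEIAR transmission kernel with class-specific contacts.

The kernel advances the population one day at a time. Within a day, flows
are computed simultaneously from the current state using exponential daily
transition probabilities: new infections leave S_i at rate
``1 - exp(-lambda_i)`` where the force of infection is

    lambda_1 = beta * C_S1 * Phi / Theta
    lambda_2 = epsilon * beta * C_S2 * Phi / Theta

with the infectious mixing numerator

    Phi = rho * (C_E1 E1 + C_E2 E2) + alpha * (C_A1 A1 + C_A2 A2) + C_I I

and the total population activity Theta = sum_h C^h h. Exposed individuals
progress with probability 1 - exp(-kappa), splitting a fraction sigma to
the asymptomatic class of their own group and 1 - sigma to the shared
symptomatic class; asymptomatic and symptomatic individuals recover with
probability 1 - exp(-gamma).
"""

from __future__ import annotations

from dataclasses import dataclass, field
import math
from typing import Any

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .params import (
    CONTACT_FIELDS,
    STATE_FIELDS,
    ContactProfile,
    DiseaseParams,
    EpidemicState,
)

__all__ = [
    "DegenerateMixingError",
    "mixing_fraction",
    "step",
    "simulate_constant",
    "r0",
    "attack_rate",
    "final_size",
    "SimulationResult",
]

# array indices into the canonical compartment order
_S1, _S2, _E1, _E2, _A1, _A2, _I, _R = range(8)


class DegenerateMixingError(ValueError):
    """Total population activity Theta = sum_h C^h h is zero.

    Raised instead of silently returning 0 so that configuration errors
    (all contacts zero, or an empty state) surface immediately.
    """


def _mixing_arrays(y: np.ndarray, c: np.ndarray, dp: DiseaseParams) -> float:
    theta = float(np.dot(c, y))
    if theta <= 0.0:
        raise DegenerateMixingError(
            f"total population activity is {theta}; cannot form mixing fraction"
        )
    phi = (
        dp.rho * (c[_E1] * y[_E1] + c[_E2] * y[_E2])
        + dp.alpha * (c[_A1] * y[_A1] + c[_A2] * y[_A2])
        + c[_I] * y[_I]
    )
    return phi / theta


def mixing_fraction(
    state: EpidemicState, contacts: ContactProfile, dparams: DiseaseParams
) -> float:
    """Fraction of contact activity met with infectious individuals, Phi/Theta.

    Weighted by the relative infectiousness rho (exposed) and alpha
    (asymptomatic). Dimensionless, in [0, max(rho, alpha, 1)].

    Raises
    ------
    DegenerateMixingError
        If the total activity Theta is zero.
    """
    return _mixing_arrays(state.as_array(), contacts.as_array(), dparams)


def _step_arrays(y: np.ndarray, c: np.ndarray, dp: DiseaseParams) -> tuple[np.ndarray, float, float]:
    """One-day update on raw arrays. Returns (new_state, lambda1, lambda2)."""
    mix = _mixing_arrays(y, c, dp)
    lam1 = dp.beta * c[_S1] * mix
    lam2 = dp.epsilon * dp.beta * c[_S2] * mix

    inf1 = y[_S1] * -math.expm1(-lam1)
    inf2 = y[_S2] * -math.expm1(-lam2)
    p_e = -math.expm1(-dp.kappa)
    p_r = -math.expm1(-dp.gamma)
    out_e1 = y[_E1] * p_e
    out_e2 = y[_E2] * p_e
    out_a1 = y[_A1] * p_r
    out_a2 = y[_A2] * p_r
    out_i = y[_I] * p_r

    out = y.copy()
    out[_S1] -= inf1
    out[_S2] -= inf2
    out[_E1] += inf1 - out_e1
    out[_E2] += inf2 - out_e2
    out[_A1] += dp.sigma * out_e1 - out_a1
    out[_A2] += dp.sigma * out_e2 - out_a2
    out[_I] += (1.0 - dp.sigma) * (out_e1 + out_e2) - out_i
    out[_R] += out_a1 + out_a2 + out_i
    return out, lam1, lam2


def step(
    state: EpidemicState, contacts: ContactProfile, dparams: DiseaseParams
) -> EpidemicState:
    """Advance the epidemic one day under the given contact profile."""
    y0 = state.as_array()
    y, _, _ = _step_arrays(y0, contacts.as_array(), dparams)
    if abs(y.sum() - y0.sum()) > 1e-12:
        raise RuntimeError("compartment mass not conserved by step")
    return EpidemicState.from_array(y)


@dataclass
class SimulationResult:
    """Time-indexed trajectory of a simulation plus summary metrics.

    ``states`` has one row per recorded day in compartment order
    (S1, S2, E1, E2, A1, A2, I, R); ``contacts`` the realized contact
    profile applied on that day; ``lambdas`` the daily forces of infection
    for the two groups. Row ``t`` holds the state at the start of day ``t``
    together with the contacts and hazards that drive the transition to
    day ``t + 1``.
    """

    days: np.ndarray
    states: np.ndarray
    contacts: np.ndarray
    lambdas: np.ndarray
    converged: bool
    config: dict[str, Any] = field(default_factory=dict)

    @property
    def final_state(self) -> EpidemicState:
        return EpidemicState.from_array(self.states[-1])

    @property
    def attack_rate(self) -> float:
        return attack_rate(self)

    @property
    def c_star(self) -> float:
        return float(self.config.get("b", 48.0)) / 2.0

    def min_contact(self, group: int) -> tuple[float, int]:
        """Minimum susceptible contact rate of a group and the day it occurs."""
        col = 0 if group == 1 else 1
        idx = int(np.argmin(self.contacts[:, col]))
        return float(self.contacts[idx, col]), int(self.days[idx])

    @property
    def peak_day(self) -> int:
        """Day of maximum infectious prevalence E + A + I."""
        prev = self.states[:, 2:7].sum(axis=1)
        return int(self.days[int(np.argmax(prev))])

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a tidy DataFrame, one row per day."""
        df = pd.DataFrame(self.states, columns=list(STATE_FIELDS))
        df.insert(0, "day", self.days)
        for j, name in enumerate(CONTACT_FIELDS):
            df[name] = self.contacts[:, j]
        df["lambda1"] = self.lambdas[:, 0]
        df["lambda2"] = self.lambdas[:, 1]
        return df

    def to_csv(self, path) -> None:
        """Write the trajectory CSV (10 significant digits, header row)."""
        cols = (
            ["day"]
            + list(STATE_FIELDS)
            + ["C_S1", "C_S2", "C_I", "lambda1", "lambda2"]
        )
        self.to_frame()[cols].to_csv(path, index=False, float_format="%.10g")

    def summary(self) -> dict[str, Any]:
        min1, day1 = self.min_contact(1)
        min2, day2 = self.min_contact(2)
        return {
            "attack_rate": self.attack_rate,
            "min_C_S1": min1,
            "min_C_S1_day": day1,
            "min_C_S2": min2,
            "min_C_S2_day": day2,
            "peak_day": self.peak_day,
            "days": int(self.days[-1]),
            "converged": self.converged,
        }


def simulate_constant(
    state0: EpidemicState,
    dparams: DiseaseParams,
    b: float = 48.0,
    horizon_days: int = 1000,
    stop_tol: float = 1e-7,
) -> SimulationResult:
    """Run the constant-contacts model: every class at C* = b/2 each day.

    Iterates until the infectious mass E + A + I falls below ``stop_tol``
    or ``horizon_days`` is reached; non-convergence is flagged on the
    result, not fatal.
    """
    c_star = b / 2.0
    c = np.full(8, c_star)
    y = state0.as_array()
    states = [y]
    lams = []
    converged = False
    t = 0
    while t < horizon_days:
        if y[2:7].sum() < stop_tol:
            converged = True
            break
        y, lam1, lam2 = _step_arrays(y, c, dparams)
        lams.append((lam1, lam2))
        states.append(y)
        t += 1
    else:
        converged = y[2:7].sum() < stop_tol
    lams.append((lams[-1] if lams else (0.0, 0.0)))
    n = len(states)
    return SimulationResult(
        days=np.arange(n),
        states=np.asarray(states),
        contacts=np.full((n, 8), c_star),
        lambdas=np.asarray(lams, dtype=float).reshape(n, 2) if n > 1 else np.zeros((1, 2)),
        converged=converged,
        config={"b": b, "stop_tol": stop_tol, "model": "constant"},
    )


def r0(dparams: DiseaseParams, b: float = 48.0, kernel: str = "continuous") -> float:
    """Basic reproduction number of the homogeneous (p = 1) model at C* = b/2.

    Next-generation-matrix value: a newly infected individual spends a mean
    latent period in E transmitting at relative rate rho, then with
    probability sigma a mean infectious period in A at relative rate alpha,
    otherwise in I at relative rate 1, each period at contact rate C*:

        R0 = beta * C* * (rho * T_E + (sigma * alpha + 1 - sigma) * T_inf)

    ``kernel="continuous"`` uses exponential residence times T_E = 1/kappa,
    T_inf = 1/gamma (the conventional ODE linearization). ``kernel="discrete"``
    uses the daily-update geometric residence times 1/(1 - e^-kappa) and
    1/(1 - e^-gamma), which is the value consistent with the daily kernel's
    final-size equation.
    """
    c_star = b / 2.0
    if kernel == "continuous":
        t_e = 1.0 / dparams.kappa
        t_inf = 1.0 / dparams.gamma
    elif kernel == "discrete":
        t_e = 1.0 / -math.expm1(-dparams.kappa)
        t_inf = 1.0 / -math.expm1(-dparams.gamma)
    else:
        raise ValueError(f"unknown kernel {kernel!r}; use 'continuous' or 'discrete'")
    return dparams.beta * c_star * (
        dparams.rho * t_e
        + (dparams.sigma * dparams.alpha + 1.0 - dparams.sigma) * t_inf
    )


def attack_rate(result: SimulationResult) -> float:
    """Final epidemic size: 1 - S1(T) - S2(T) at the last recorded day."""
    s = result.states[-1]
    return float(1.0 - s[_S1] - s[_S2])


def final_size(r0_value: float, seed: float = 0.0) -> float:
    """Positive root z of the implicit final-size equation z = 1 - exp(-R0 z).

    For R0 <= 1 (and zero seed) the only root is 0. Used as the analytic
    oracle for constant-contacts homogeneous runs.
    """
    if r0_value <= 1.0 and seed == 0.0:
        return 0.0

    def f(z: float) -> float:
        return z - (1.0 - (1.0 - seed) * math.exp(-r0_value * z))

    return float(brentq(f, 1e-12 if seed == 0 else seed / 2, 1.0 - 1e-12, xtol=1e-12))
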