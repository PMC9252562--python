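"""Per-group finite-horizon contact-choice Markov decision problem.

Each day, susceptible individuals of risk group i pick the contact rate
maximizing expected utility over a planning horizon of tau_i days,

    V_k(S_i) = max_C { u(C) + delta * [ (1 - P(C)) V_{k+1}(S_i)
                                        + P(C) V_{k+1}(E_i) ] },

with u(C) = (bC - C^2)^nu and perceived daily infection probability
P(C) = 1 - exp(-beta_i * C * phi * Phi/Theta). The mixing fraction
Phi/Theta is frozen at the currently observed state and contact profile
and held constant over the horizon (constant-prevalence projection); the
reporting level phi scales only the perceived infectious pool, not the
total activity. Exposed and asymptomatic individuals, lacking symptoms,
perceive themselves as susceptible and adopt the same contact rate;
symptomatic and recovered individuals solve static problems at C* = b/2.

The decision-maker is atomistic: their own C does not perturb Theta, and
contacts above C* = b/2 are dominated (lower utility, higher risk), so the
search domain is (0, b/2].
"""

from __future__ import annotations

from dataclasses import dataclass
import math

import numpy as np
import pandas as pd

from .kernel import _mixing_arrays
from .params import BehaviorParams, ContactProfile, DiseaseParams, EpidemicState

__all__ = [
    "PerceivedEnvironment",
    "ValueTable",
    "utility",
    "perceived_infection_probability",
    "progression_probabilities",
    "terminal_static_values",
    "solve_group_policy",
    "annual_to_daily_discount",
]

_GOLD = (math.sqrt(5.0) - 1.0) / 2.0
_N_GRID = 1024
_XATOL = 1e-6  # absolute tolerance on the optimal contact rate


@dataclass(frozen=True)
class PerceivedEnvironment:
    """What a decision-maker observes: the epidemic state frozen at today,
    the latest realized contact profile for all classes, and the risk
    group (1 = risk-taker, 2 = risk-evader) doing the deciding."""

    state: EpidemicState
    contacts: ContactProfile
    group: int

    def __post_init__(self) -> None:
        if self.group not in (1, 2):
            raise ValueError("group must be 1 (risk-taker) or 2 (risk-evader)")


@dataclass
class ValueTable:
    """Backward-induction values V_k(h) for one risk group.

    Arrays are indexed by backward step k = 0..tau+1 (row tau+1 holds the
    terminal value); ``C_hat`` holds the optimizer chosen at steps 0..tau.
    """

    V_S: np.ndarray
    V_E: np.ndarray
    V_A: np.ndarray
    V_I: np.ndarray
    V_R: np.ndarray
    C_hat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        n = len(self.C_hat)
        return pd.DataFrame(
            {
                "k": np.arange(n),
                "V_S": self.V_S[:n],
                "V_E": self.V_E[:n],
                "V_A": self.V_A[:n],
                "V_I": self.V_I[:n],
                "V_R": self.V_R[:n],
                "C_hat": self.C_hat,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")


def utility(C: float, b: float, nu: float) -> float:
    """Single-peaked contact utility u(C) = (bC - C^2)^nu on [0, b].

    Zero at both boundaries, maximized at the disease-free optimum C* = b/2.
    """
    if not 0.0 <= C <= b:
        raise ValueError(f"contact rate {C} outside [0, {b}]")
    base = C * (b - C)
    if base <= 0.0:
        return 0.0
    return base**nu


def perceived_infection_probability(
    C: float,
    env: PerceivedEnvironment,
    dparams: DiseaseParams,
    phi: float = 1.0,
) -> float:
    """Perceived daily probability of infection at contact rate C.

    1 - exp(-beta_i * C * phi * Phi/Theta) with beta_1 = beta and
    beta_2 = epsilon * beta; Phi/Theta is computed from the frozen
    environment, so the decision variable C does not enter Theta.
    """
    mix = _mixing_arrays(env.state.as_array(), env.contacts.as_array(), dparams)
    beta_i = dparams.beta if env.group == 1 else dparams.epsilon * dparams.beta
    return -math.expm1(-beta_i * C * phi * mix)


def progression_probabilities(dparams: DiseaseParams) -> tuple[float, float, float]:
    """Daily progression probabilities (P_E, P_AR, P_IR).

    P_E = 1 - e^-kappa leaves the exposed class; P_AR = P_IR = 1 - e^-gamma
    recover from the asymptomatic and symptomatic classes.
    """
    p_e = -math.expm1(-dparams.kappa)
    p_r = -math.expm1(-dparams.gamma)
    return p_e, p_r, p_r


def terminal_static_values(
    horizon: int,
    bparams: BehaviorParams,
    dparams: DiseaseParams,
    group: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Expected utilities of symptomatic and recovered individuals.

    Neither faces any further infection risk, so both recursions are
    independent of the epidemic state and solvable up front:

        V_k(R) = u(C*) + delta * V_{k+1}(R)
        V_k(I) = u_I + delta * [(1 - P_IR) V_{k+1}(I) + P_IR V_{k+1}(R)]

    with u_I = 0 under ``symptomatic_utility="zero"`` (default: symptomatic
    individuals earn nothing while infectious) or u(C*) under ``"full"``.
    Returns arrays (V_I, V_R) indexed by backward step k = 0..horizon+1;
    row horizon+1 holds the terminal value. Equivalently, in closed form,
    V_k(R) = sum_{j=0..horizon-k} delta^j u(C*) above the terminal constant.
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    u_star = utility(bparams.c_star, bparams.b, bparams.nu(group))
    u_i = 0.0 if bparams.symptomatic_utility == "zero" else u_star
    _, _, p_ir = progression_probabilities(dparams)
    delta = bparams.delta

    v_i = np.empty(horizon + 2)
    v_r = np.empty(horizon + 2)
    v_i[horizon + 1] = bparams.terminal_value
    v_r[horizon + 1] = bparams.terminal_value
    for k in range(horizon, -1, -1):
        v_r[k] = u_star + delta * v_r[k + 1]
        v_i[k] = u_i + delta * ((1.0 - p_ir) * v_i[k + 1] + p_ir * v_r[k + 1])
    return v_i, v_r


def _golden_max(f, lo: float, hi: float, xatol: float = _XATOL) -> float:
    """Golden-section maximizer of a unimodal scalar function on [lo, hi]."""
    x1 = hi - _GOLD * (hi - lo)
    x2 = lo + _GOLD * (hi - lo)
    f1, f2 = f(x1), f(x2)
    while hi - lo > xatol:
        if f1 < f2:
            lo, x1, f1 = x1, x2, f2
            x2 = lo + _GOLD * (hi - lo)
            f2 = f(x2)
        else:
            hi, x2, f2 = x2, x1, f1
            x1 = hi - _GOLD * (hi - lo)
            f1 = f(x1)
    return 0.5 * (lo + hi)


def _argmax_contact(
    hazard: float,
    v_s_next: float,
    v_e_next: float,
    b: float,
    nu: float,
    delta: float,
    c_grid: np.ndarray,
    u_grid: np.ndarray,
    p_grid: np.ndarray,
) -> float:
    """Maximize u(C) + delta[(1-P(C)) V_S' + P(C) V_E'] over C in (0, b/2].

    P(C) = 1 - exp(-hazard * C). Dense-grid argmax bracketing followed by
    golden-section refinement to 1e-6 contacts; ties broken toward the
    larger contact rate (the disease-free optimum b/2).
    """
    c_star = b / 2.0
    theta = delta * (v_s_next - v_e_next)
    if hazard <= 0.0 or theta <= 0.0:
        # no perceived risk, or infection costs nothing: utility alone decides
        return c_star
    obj = u_grid - theta * p_grid
    # last argmax = tie toward larger C
    i = len(obj) - 1 - int(np.argmax(obj[::-1]))
    if i == len(c_grid) - 1:
        return c_star
    lo = c_grid[max(i - 1, 0)]
    hi = c_grid[min(i + 1, len(c_grid) - 1)]

    def f(c: float) -> float:
        return (c * (b - c)) ** nu - theta * -math.expm1(-hazard * c)

    c_hat = _golden_max(f, lo, hi)
    if f(c_star) >= f(c_hat) - 1e-12:
        return c_star
    return c_hat


def solve_group_policy(
    env: PerceivedEnvironment,
    dparams: DiseaseParams,
    bparams: BehaviorParams,
) -> tuple[float, ValueTable]:
    """Backward induction over the group's planning horizon.

    Solves the finite-horizon decision problem for the group named by
    ``env.group`` against the frozen environment (constant-prevalence
    projection: the same perceived hazard applies at every step of the
    horizon). Returns the contact rate applied today by the group's
    susceptible, exposed and asymptomatic classes, plus the full table of
    state values and per-step optimizers.
    """
    group = env.group
    nu = bparams.nu(group)
    tau = bparams.tau(group)
    b = bparams.b
    delta = bparams.delta
    c_star = bparams.c_star

    mix = _mixing_arrays(env.state.as_array(), env.contacts.as_array(), dparams)
    beta_i = dparams.beta if group == 1 else dparams.epsilon * dparams.beta
    hazard = beta_i * bparams.phi * mix

    p_e, p_ar, _ = progression_probabilities(dparams)
    v_i, v_r = terminal_static_values(tau, bparams, dparams, group=group)

    v_s = np.empty(tau + 2)
    v_e = np.empty(tau + 2)
    v_a = np.empty(tau + 2)
    v_s[tau + 1] = v_e[tau + 1] = v_a[tau + 1] = bparams.terminal_value
    c_hat = np.empty(tau + 1)

    c_grid = np.linspace(c_star / _N_GRID, c_star, _N_GRID)
    u_grid = (c_grid * (b - c_grid)) ** nu
    p_grid = -np.expm1(-hazard * c_grid)

    sigma = dparams.sigma
    for k in range(tau, -1, -1):
        c_k = _argmax_contact(
            hazard, v_s[k + 1], v_e[k + 1], b, nu, delta, c_grid, u_grid, p_grid
        )
        c_hat[k] = c_k
        u_c = (c_k * (b - c_k)) ** nu
        p_se = -math.expm1(-hazard * c_k)
        v_s[k] = u_c + delta * ((1.0 - p_se) * v_s[k + 1] + p_se * v_e[k + 1])
        v_e[k] = u_c + delta * (
            (1.0 - p_e) * v_e[k + 1]
            + p_e * (sigma * v_a[k + 1] + (1.0 - sigma) * v_i[k + 1])
        )
        v_a[k] = u_c + delta * ((1.0 - p_ar) * v_a[k + 1] + p_ar * v_r[k + 1])

    table = ValueTable(V_S=v_s, V_E=v_e, V_A=v_a, V_I=v_i, V_R=v_r, C_hat=c_hat)
    return float(c_hat[0]), table


def annual_to_daily_discount(annual_rate: float) -> float:
    """Daily discount factor from an annual discount rate.

    delta = (1 - annual_rate)^(1/365); e.g. a 5%/year rate gives 0.99986.
    """
    if not 0.0 <= annual_rate < 1.0:
        raise ValueError("annual_rate must be in [0, 1)")
    return (1.0 - annual_rate) ** (1.0 / 365.0)
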