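"""Domain types for the two-risk-group SEIAR model with adaptive contacts.

The population is split into risk-takers (group 1) and risk-evaders
(group 2). Each group has its own susceptible, exposed and asymptomatic
compartments; symptomatic and recovered individuals form single shared
compartments because behavior is assumed homogeneous in those health states.
All compartments are population fractions of a closed population.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
import math

import numpy as np

__all__ = [
    "EpidemicState",
    "DiseaseParams",
    "ContactProfile",
    "BehaviorParams",
    "STATE_FIELDS",
    "CONTACT_FIELDS",
]

#: canonical compartment order, shared by arrays and CSV output
STATE_FIELDS = ("S1", "S2", "E1", "E2", "A1", "A2", "I", "R")
CONTACT_FIELDS = ("C_S1", "C_S2", "C_E1", "C_E2", "C_A1", "C_A2", "C_I", "C_R")

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class EpidemicState:
    """Population fractions in the eight health/risk compartments.

    Invariants: every field is non-negative and the fields sum to 1 within
    1e-12 (closed population, no births or deaths).
    """

    S1: float = 0.0
    S2: float = 0.0
    E1: float = 0.0
    E2: float = 0.0
    A1: float = 0.0
    A2: float = 0.0
    I: float = 0.0
    R: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        vals = self.as_array()
        if np.any(vals < -_SUM_TOL):
            bad = [f for f, v in zip(STATE_FIELDS, vals) if v < -_SUM_TOL]
            raise ValueError(f"negative compartment(s): {bad}")
        total = float(vals.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"compartments sum to {total!r}, expected 1")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "EpidemicState":
        return cls(**dict(zip(STATE_FIELDS, map(float, arr))))

    @property
    def infectious(self) -> float:
        """Total currently-infected fraction E + A + I."""
        return self.E1 + self.E2 + self.A1 + self.A2 + self.I

    @property
    def susceptible(self) -> float:
        return self.S1 + self.S2


@dataclass(frozen=True)
class DiseaseParams:
    """Transmission and progression constants.

    beta    per-contact transmission likelihood
    kappa   incubation rate (1/day); mean latent period 1/kappa days
    gamma   recovery rate (1/day); mean infectious period 1/gamma days
    rho     relative infectiousness of exposed individuals, in [0, 1]
    alpha   relative infectiousness of asymptomatic individuals, in [0, 1]
    sigma   fraction of infections that remain asymptomatic, in [0, 1]
    epsilon risk-evader per-contact infection-risk scalar, in [0, 1]
            (1 means precautionary behaviors give no protection)
    """

    beta: float = 0.01324
    kappa: float = 1.0 / 5.0
    gamma: float = 1.0 / 9.0
    rho: float = 0.25
    alpha: float = 0.4
    sigma: float = 0.5
    epsilon: float = 0.7

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.kappa <= 0 or self.gamma <= 0:
            raise ValueError("kappa and gamma must be > 0")
        for name in ("rho", "alpha", "sigma", "epsilon"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass(frozen=True)
class ContactProfile:
    """Realized daily contact rates for all eight classes (contacts/day)."""

    C_S1: float
    C_S2: float
    C_E1: float
    C_E2: float
    C_A1: float
    C_A2: float
    C_I: float
    C_R: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in CONTACT_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ContactProfile":
        return cls(**dict(zip(CONTACT_FIELDS, map(float, arr))))

    @classmethod
    def uniform(cls, c: float) -> "ContactProfile":
        """All classes at the same contact rate ``c``."""
        return cls(*([float(c)] * 8))

    def validate(self, b: float | None = None) -> None:
        vals = self.as_array()
        if np.any(vals < 0):
            raise ValueError("contact rates must be non-negative")
        if b is not None and np.any(vals > b + 1e-9):
            raise ValueError(f"contact rate exceeds maximum b={b}")


@dataclass(frozen=True)
class BehaviorParams:
    """Decision-model constants.

    b          maximum feasible contacts per day; the disease-free optimum
               is C* = b/2 for the utility u(C) = (bC - C^2)^nu
    nu1, nu2   utility shape for risk-takers / risk-evaders; smaller nu
               means a smaller utility loss from cutting contacts
    tau1, tau2 planning horizons in days (non-negative integers)
    delta      daily discount factor in (0, 1]
    phi        reporting level: fraction of the infectious population that
               is visible to decision-makers, in [0, 1]; distorts perceived
               risk only, never actual transmission
    p          proportion of risk-takers in the population, in [0, 1]
    symptomatic_utility  "zero" (symptomatic individuals earn no utility
               while infectious) or "full" (they earn u(C*))
    terminal_value  value assigned beyond the planning horizon; a
               state-independent constant leaves all decisions unchanged
    """

    b: float = 48.0
    nu1: float = 0.1
    nu2: float = 0.05
    tau1: int = 14
    tau2: int = 14
    delta: float = 0.99986
    phi: float = 1.0
    p: float = 0.5
    symptomatic_utility: str = "zero"
    terminal_value: float = 0.0

    def __post_init__(self) -> None:
        if self.b <= 0:
            raise ValueError("b must be > 0")
        for name in ("nu1", "nu2"):
            v = getattr(self, name)
            if not 0.0 < v <= 1.0:
                raise ValueError(f"{name}={v} outside (0, 1]")
        for name in ("tau1", "tau2"):
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")
        if not 0.0 < self.delta <= 1.0:
            raise ValueError("delta must be in (0, 1]")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must be in [0, 1]")
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("p must be in [0, 1]")
        if self.symptomatic_utility not in ("zero", "full"):
            raise ValueError("symptomatic_utility must be 'zero' or 'full'")

    @property
    def c_star(self) -> float:
        """Disease-free optimal contact rate b/2."""
        return self.b / 2.0

    def nu(self, group: int) -> float:
        return self.nu1 if group == 1 else self.nu2

    def tau(self, group: int) -> int:
        return int(self.tau1 if group == 1 else self.tau2)
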