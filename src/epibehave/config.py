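"""Scenario configuration: flat key-value files and baseline defaults.

A scenario is a flat mapping whose keys use the standard symbol names:
disease (beta, kappa, gamma, rho, alpha, sigma, epsilon), behavior (b, nu1,
nu2, tau1, tau2, delta, phi, p), initial conditions (i0, seed_split) and run
control (t_max, stop_tol). Files are YAML (JSON is a YAML subset, so plain
JSON also loads). Unknown keys are rejected to surface typos.

The baseline values reproduce a reproduction number of 2.4 for the
homogeneous constant-contacts model (beta = 0.01324, C* = 24).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
import logging
from pathlib import Path

import yaml

from .params import BehaviorParams, DiseaseParams, EpidemicState

__all__ = ["ScenarioConfig", "load_config", "DEFAULTS"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one simulation scenario."""

    # disease
    beta: float = 0.01324
    kappa: float = 1.0 / 5.0
    gamma: float = 1.0 / 9.0
    rho: float = 0.25
    alpha: float = 0.4
    sigma: float = 0.5
    epsilon: float = 0.7
    # behavior
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
    # initial conditions and run control
    i0: float = 1e-4
    seed_split: str = "proportional"
    t_max: int = 1000
    stop_tol: float = 1e-7
    # reserved for forward compatibility; the pipeline is fully deterministic
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.i0 < 1.0:
            raise ValueError("i0 must be in (0, 1)")
        if self.seed_split not in ("proportional", "rt", "re"):
            raise ValueError("seed_split must be proportional, rt or re")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        if self.seed is not None:
            logger.info("config key 'seed' is unused: the pipeline is deterministic")
        # trigger parameter validation
        self.disease()
        self.behavior()

    def disease(self) -> DiseaseParams:
        return DiseaseParams(
            beta=self.beta,
            kappa=self.kappa,
            gamma=self.gamma,
            rho=self.rho,
            alpha=self.alpha,
            sigma=self.sigma,
            epsilon=self.epsilon,
        )

    def behavior(self) -> BehaviorParams:
        return BehaviorParams(
            b=self.b,
            nu1=self.nu1,
            nu2=self.nu2,
            tau1=self.tau1,
            tau2=self.tau2,
            delta=self.delta,
            phi=self.phi,
            p=self.p,
            symptomatic_utility=self.symptomatic_utility,
            terminal_value=self.terminal_value,
        )

    def initial_state(self) -> EpidemicState:
        """Seed i0 into the exposed compartments.

        ``seed_split="proportional"`` (default) splits the seed by group
        size: E1(0) = p*i0, E2(0) = (1-p)*i0; "rt"/"re" place it entirely
        in one group (capped by that group's size).
        """
        p, i0 = self.p, self.i0
        if self.seed_split == "proportional":
            e1, e2 = p * i0, (1.0 - p) * i0
        elif self.seed_split == "rt":
            if p <= 0:
                raise ValueError("seed_split='rt' with p=0: no risk-takers to seed")
            e1, e2 = i0, 0.0
        else:
            if p >= 1:
                raise ValueError("seed_split='re' with p=1: no risk-evaders to seed")
            e1, e2 = 0.0, i0
        return EpidemicState(S1=p - e1, S2=(1.0 - p) - e2, E1=e1, E2=e2)

    def replace(self, **kwargs) -> "ScenarioConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)


DEFAULTS = ScenarioConfig()


def load_config(path=None, **overrides) -> ScenarioConfig:
    """Load a scenario file (or the baseline defaults) and apply overrides."""
    cfg = ScenarioConfig.from_yaml(path) if path else DEFAULTS
    return cfg.replace(**overrides) if overrides else cfg
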