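"""Parameter-sweep engine and scenario presets for the result surfaces.

Sweeps run the adaptive simulation (and optionally its constant-contacts
counterpart) over the Cartesian product of named parameter grids and return
a tidy table, one row per grid point. Presets encode the published
experiment layouts: single scenarios at p = 0.33 / 0.66, the (p, epsilon)
attack-rate surface, its variation with the asymptomatic fraction, reporting
level trajectories and surfaces, and the planning-horizon grids. The whole
pipeline is deterministic: repeated runs produce byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import itertools
import logging
import math

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import ScenarioConfig
from .coupled import contact_reduction_at_peak, group_attack_rates, simulate_adaptive
from .kernel import attack_rate, simulate_constant

__all__ = [
    "SweepSpec",
    "sweep",
    "preset_fig",
    "iso_attack_curve",
    "optimal_horizons",
    "PRESET_IDS",
]

logger = logging.getLogger(__name__)

#: fixed column order of sweep tables, after the axis columns
RESULT_COLUMNS = [
    "attack_rate",
    "attack_rate_rt",
    "attack_rate_re",
    "attack_rate_constant",
    "min_C_S1",
    "min_C_S2",
    "peak_day",
    "converged",
]

PRESET_IDS = ("3A", "3B", "4", "5", "6", "7", "8")


@dataclass(frozen=True)
class SweepSpec:
    """A named set of parameter axes over a base scenario.

    ``axes`` maps config keys to grids; rows are produced in lexicographic
    order over the axes (itertools.product of the grids as given).
    """

    axes: dict[str, tuple]
    base: ScenarioConfig = field(default_factory=ScenarioConfig)
    include_constant: bool = True
    workers: int = 1

    def __post_init__(self) -> None:
        known = set(ScenarioConfig.__dataclass_fields__)
        for name, grid in self.axes.items():
            if name not in known:
                raise ValueError(f"axis {name!r} is not a config key")
            if len(grid) == 0:
                raise ValueError(f"axis {name!r} has an empty grid")
        # validate every grid point's legal range up front
        for point in self.points():
            self.base.replace(**point)

    def points(self) -> list[dict]:
        names = list(self.axes)
        return [
            dict(zip(names, combo))
            for combo in itertools.product(*(self.axes[n] for n in names))
        ]


def _run_point(base: ScenarioConfig, point: dict, include_constant: bool) -> dict:
    row = dict(point)
    cfg = base.replace(**point)
    try:
        res = simulate_adaptive(cfg)
        overall, g1, g2 = group_attack_rates(res, cfg.p)
        row.update(
            attack_rate=overall,
            attack_rate_rt=g1,
            attack_rate_re=g2,
            min_C_S1=res.min_contact(1)[0],
            min_C_S2=res.min_contact(2)[0],
            peak_day=res.peak_day,
            converged=res.converged,
        )
        if include_constant:
            cres = simulate_constant(
                cfg.initial_state(), cfg.disease(), cfg.b, cfg.t_max, cfg.stop_tol
            )
            row["attack_rate_constant"] = attack_rate(cres)
        else:
            row["attack_rate_constant"] = math.nan
        row["error"] = ""
    except Exception as exc:
        logger.warning("sweep point %s failed: %s", point, exc)
        for col in RESULT_COLUMNS:
            row.setdefault(col, math.nan)
        row["converged"] = False
        row["error"] = str(exc)
    return row


def sweep(spec: SweepSpec) -> pd.DataFrame:
    """Evaluate every grid point; failed points are flagged, not fatal."""
    points = spec.points()
    if spec.workers > 1:
        rows = Parallel(n_jobs=spec.workers)(
            delayed(_run_point)(spec.base, pt, spec.include_constant) for pt in points
        )
    else:
        rows = [_run_point(spec.base, pt, spec.include_constant) for pt in points]
    cols = list(spec.axes) + RESULT_COLUMNS + ["error"]
    return pd.DataFrame(rows, columns=cols)


def preset_fig(figure: str, base: ScenarioConfig | None = None):
    """Preset encodings of the published experiments.

    "3A"/"3B": single scenarios (p = 0.33 / 0.66, epsilon = 0.7) — returned
    as a list of ScenarioConfig. "4": (p, epsilon) surface. "5": the same
    surface at asymptomatic fractions 0.25/0.5/0.75. "6": contact-rate
    trajectories at reporting levels 0.25/0.5/1.0. "7": (phi, p) surface.
    "8": planning-horizon (tau1, tau2) grids at p in {0.33, 0.5, 0.75}.
    """
    base = base or ScenarioConfig()
    fig = str(figure).upper()
    p_grid = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
    eps_grid = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
    phi_grid = tuple(np.round(np.arange(0.0, 1.0001, 0.05), 10))
    tau_grid = tuple(range(1, 31))
    if fig == "3A":
        return [base.replace(p=0.33, epsilon=0.7)]
    if fig == "3B":
        return [base.replace(p=0.66, epsilon=0.7)]
    if fig == "4":
        return SweepSpec(axes={"p": p_grid, "epsilon": eps_grid}, base=base)
    if fig == "5":
        return SweepSpec(
            axes={"sigma": (0.25, 0.5, 0.75), "p": p_grid, "epsilon": eps_grid},
            base=base,
        )
    if fig == "6":
        return [base.replace(phi=v) for v in (0.25, 0.5, 1.0)]
    if fig == "7":
        return SweepSpec(axes={"phi": phi_grid, "p": p_grid}, base=base)
    if fig == "8":
        return [
            SweepSpec(
                axes={"tau1": tau_grid, "tau2": tau_grid},
                base=base.replace(p=p),
                include_constant=False,
            )
            for p in (0.33, 0.5, 0.75)
        ]
    raise ValueError(f"unknown preset {figure!r}; expected one of {PRESET_IDS}")


def _attack_at(base: ScenarioConfig, **kwargs) -> float:
    return attack_rate(simulate_adaptive(base.replace(**kwargs)))


def iso_attack_curve(
    base: ScenarioConfig,
    reference: tuple[float, float],
    p_grid,
    tol: float = 1e-3,
    max_iter: int = 40,
) -> pd.DataFrame:
    """Reporting level phi*(p) holding the attack rate at a reference value.

    The reference attack rate is computed at (p0, phi0). For each p in
    ``p_grid``, bisection on phi in [0, 1] finds the reporting level whose
    attack rate matches the reference within ``tol`` (absolute). Because the
    attack rate is non-increasing in phi, the bracket is checked first; if
    no phi in [0, 1] can achieve the reference the point is returned as a
    boundary marker (phi_star = NaN, flag set).
    """
    p0, phi0 = reference
    ref = _attack_at(base, p=p0, phi=phi0)
    rows = []
    for p in p_grid:
        a_lo = _attack_at(base, p=p, phi=0.0)  # highest attainable attack rate
        a_hi = _attack_at(base, p=p, phi=1.0)  # lowest
        if a_lo < a_hi - tol:
            rows.append(
                {"p": p, "phi_star": math.nan, "attack_rate": math.nan,
                 "flag": "non-monotone"}
            )
            continue
        if ref > a_lo + tol or ref < a_hi - tol:
            rows.append(
                {"p": p, "phi_star": math.nan, "attack_rate": math.nan,
                 "flag": "out-of-range"}
            )
            continue
        lo, hi = 0.0, 1.0
        a_mid, mid = a_lo, 0.0
        for _ in range(max_iter):
            mid = 0.5 * (lo + hi)
            a_mid = _attack_at(base, p=p, phi=mid)
            if abs(a_mid - ref) <= tol:
                break
            if a_mid > ref:  # too little reporting: attack too high
                lo = mid
            else:
                hi = mid
        rows.append({"p": p, "phi_star": mid, "attack_rate": a_mid, "flag": ""})
    return pd.DataFrame(rows, columns=["p", "phi_star", "attack_rate", "flag"])


def optimal_horizons(
    base: ScenarioConfig, tau1_grid, tau2_grid, workers: int = 1
) -> tuple[int, int, pd.DataFrame]:
    """Planning-horizon pair minimizing the attack rate over a (tau1, tau2) grid.

    Ties are broken toward the smaller tau1 + tau2, then the smaller tau1.
    Returns (tau1*, tau2*, grid table) where the table has one row per pair.
    """
    spec = SweepSpec(
        axes={"tau1": tuple(int(t) for t in tau1_grid),
              "tau2": tuple(int(t) for t in tau2_grid)},
        base=base,
        include_constant=False,
        workers=workers,
    )
    table = sweep(spec)
    best = min(
        table.itertuples(index=False),
        key=lambda r: (
            r.attack_rate if not math.isnan(r.attack_rate) else math.inf,
            r.tau1 + r.tau2,
            r.tau1,
        ),
    )
    return int(best.tau1), int(best.tau2), table
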