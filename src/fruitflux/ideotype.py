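"""Constrained multi-objective design of virtual genotypes (ideotypes).

Searches the 11-parameter space (the eight calibrated parameters plus
initial masses and the soluble-sugar intercept) for genotypes that maximise
ripe dry-matter content under control irrigation while minimising the
fresh-mass loss caused by water deficit, subject to a dry-matter ceiling of
10% under both treatments and a fruit-size class window on the control
fresh mass.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fruitflux import _kernel as K
from fruitflux import moea
from fruitflux.calibration import PENALTY, decode, encode, transform_bounds
from fruitflux.model_core import (
    IDEOTYPE_BOUNDS,
    IDEOTYPE_PARAM_ORDER,
    EnvSeries,
    GenericParams,
    GenotypeParams,
    PlantInputs,
    build_constants,
)

__all__ = [
    "SIZE_CLASSES", "IdeotypeProblem", "IdeotypeSolution",
    "ideotype_objectives", "design", "filter_ideotypes",
    "DM_CEILING", "DM_SELECT_MIN", "LOSS_SELECT_MAX",
]

#: fruit-size classes by final fresh weight under control conditions, g
SIZE_CLASSES: dict[str, tuple[float, float]] = {
    "large": (100.0, 300.0),
    "medium": (20.0, 80.0),
    "small": (5.0, 15.0),
}

DM_CEILING = 10.0      # dry-matter content constraint, percent, both treatments
DM_SELECT_MIN = 8.0    # selection threshold on dmC, percent (inclusive)
LOSS_SELECT_MAX = 15.0  # selection threshold on loss, percent (inclusive)


@dataclass
class IdeotypeSolution:
    """One designed genotype and its outcome under both treatments."""

    x: np.ndarray          # 11-vector in natural units
    dmC: float             # ripe dry-matter content under control, percent
    dmWD: float            # same under water deficit, percent
    loss: float            # fresh-mass loss index, percent
    fwC: float             # ripe fresh mass under control, g
    feasible: bool
    selected: bool = False
    seed: int = 0
    repeat: int = 0

    @property
    def params(self) -> GenotypeParams:
        return GenotypeParams.from_vector(self.x, mode="ideotype")

    def to_dict(self) -> dict:
        d = {name: float(v) for name, v in zip(IDEOTYPE_PARAM_ORDER, self.x)}
        d.update(dmC=self.dmC, dmWD=self.dmWD, loss=self.loss, fwC=self.fwC,
                 feasible=self.feasible, selected=self.selected,
                 seed=self.seed, repeat=self.repeat)
        return d


def _loss_percent(fw_c: float, fw_wd: float, form: str) -> float:
    rel = (fw_c - fw_wd) / fw_c
    if form == "squared":
        return 100.0 * rel * rel
    if form == "plain":
        return 100.0 * rel
    raise ValueError("lossForm must be 'plain' or 'squared'")


class IdeotypeProblem:
    """MOEA problem: objectives (-dmC, loss) with dm and size constraints.

    The genotypic initial masses (w0, s0) and sugar intercept (bssrat) are
    part of the decision vector and are shared by both treatments; only the
    non-genotypic plant inputs differ between C and WD.
    """

    def __init__(self, size_class: str, inputs_c: PlantInputs,
                 inputs_wd: PlantInputs, env: EnvSeries,
                 generic: Optional[GenericParams] = None,
                 ripe_daa: int = 53, loss_form: str = "plain",
                 bounds: Optional[dict] = None, t0: float = 192.0):
        if size_class not in SIZE_CLASSES:
            raise ValueError(f"unknown size class {size_class!r}")
        if loss_form not in ("plain", "squared"):
            raise ValueError("lossForm must be 'plain' or 'squared'")
        self.size_class = size_class
        self.fw_window = SIZE_CLASSES[size_class]
        self.loss_form = loss_form
        self.generic = generic if generic is not None else GenericParams()
        self.bounds_natural = bounds if bounds is not None else IDEOTYPE_BOUNDS
        self.bounds = transform_bounds(self.bounds_natural, IDEOTYPE_PARAM_ORDER)
        self.t0 = t0
        self.ripe_daa = ripe_daa
        self.n_steps = int(round((ripe_daa * 24.0 - t0)))
        env = env.hourly()
        self._env_t = env.T
        self._env_rh = env.RH
        self._env_t0 = float(env.t[0])
        self._inputs = {"C": inputs_c, "WD": inputs_wd}

    def outcome(self, x_natural: np.ndarray) -> Optional[dict[str, float]]:
        """Simulate both treatments for an 11-vector; None on failure."""
        x = np.asarray(x_natural, dtype=float)
        pg = x[:8]
        s0, w0, bssrat = x[8], x[9], x[10]
        res = {}
        for trt, inputs in self._inputs.items():
            pc = build_constants(self.generic, inputs)
            pc[K.IC_BSSRAT] = bssrat
            status, traj = K.integrate(pg, pc, w0, s0, self.t0, self.n_steps,
                                       1.0, 1.0 / 64.0, self._env_t,
                                       self._env_rh, self._env_t0)
            if status != K.STATUS_OK:
                return None
            w, s = traj[-1, K.COL_W], traj[-1, K.COL_S]
            res[f"fw{trt}"] = float(w + s)
            res[f"dm{trt}"] = float(100.0 * s / (w + s))
        res["loss"] = _loss_percent(res["fwC"], res["fwWD"], self.loss_form)
        return res

    def constraints(self, outcome: dict[str, float]) -> np.ndarray:
        lo, hi = self.fw_window
        return np.array([
            outcome["dmC"] - DM_CEILING,
            outcome["dmWD"] - DM_CEILING,
            lo - outcome["fwC"],
            outcome["fwC"] - hi,
        ])

    def evaluate(self, z: np.ndarray):
        out = self.outcome(decode(z, IDEOTYPE_PARAM_ORDER))
        if out is None:
            return np.array([PENALTY, PENALTY]), np.full(4, PENALTY)
        f = np.array([-out["dmC"], out["loss"]])
        return f, self.constraints(out)


def ideotype_objectives(x, inputs_c: PlantInputs, inputs_wd: PlantInputs,
                        env: EnvSeries, size_class: str = "medium",
                        loss_form: str = "plain",
                        generic: Optional[GenericParams] = None,
                        ripe_daa: int = 53):
    """Outcome (dmC, loss, constraint vector) of one 11-parameter vector."""
    problem = IdeotypeProblem(size_class, inputs_c, inputs_wd, env, generic,
                              ripe_daa=ripe_daa, loss_form=loss_form)
    out = problem.outcome(np.asarray(x, dtype=float))
    if out is None:
        raise RuntimeError("simulation failed for the given parameter vector")
    return out["dmC"], out["loss"], problem.constraints(out)


def design(problem: IdeotypeProblem, moea_config: Optional[moea.MoeaConfig] = None,
           n_repeats: int = 20, base_seed: int = 0) -> list[IdeotypeSolution]:
    """Repeated NSGA-II runs; merged non-dominated archive of designs."""
    config = moea_config if moea_config is not None else moea.MoeaConfig()
    merged: list[moea.ParetoSolution] = []
    for repeat in range(n_repeats):
        seed = base_seed + repeat
        cfg = dataclasses.replace(config, seed=seed)
        _, archive = moea.nsga2_run(problem, cfg)
        merged.extend(
            moea.ParetoSolution(decode(ind.x, IDEOTYPE_PARAM_ORDER),
                                ind.f.copy(), ind.g.copy(), seed=seed,
                                repeat=repeat)
            for ind in archive)
    front = moea.nondominated_subset(merged)
    solutions = []
    for sol in front:
        out = problem.outcome(sol.x)
        if out is None:
            continue
        g = problem.constraints(out)
        solutions.append(IdeotypeSolution(
            x=np.asarray(sol.x, dtype=float), dmC=out["dmC"], dmWD=out["dmWD"],
            loss=out["loss"], fwC=out["fwC"], feasible=bool(np.all(g <= 0.0)),
            seed=sol.seed, repeat=sol.repeat))
    return filter_ideotypes(solutions)


def filter_ideotypes(archive: Sequence[IdeotypeSolution]) -> list[IdeotypeSolution]:
    """Flag solutions meeting the selection thresholds (dmC >= 8, loss <= 15)."""
    out = []
    for sol in archive:
        selected = bool(sol.feasible and sol.dmC >= DM_SELECT_MIN
                        and sol.loss <= LOSS_SELECT_MAX)
        out.append(dataclasses.replace(sol, selected=selected))
    return out


def archive_to_frame(archive: Sequence[IdeotypeSolution]) -> pd.DataFrame:
    return pd.DataFrame([sol.to_dict() for sol in archive])
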