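"""Per-genotype parameter estimation against fresh/dry mass time courses.

Eight genotypic parameters are estimated by minimising two objectives, the
mean normalised RMSE of fresh and dry mass under control and the same
under water deficit, with a single parameter vector shared across the two
treatments (genotype dependent, environment independent).  The search runs
repeated NSGA-II passes in a transformed space (log10 for wide-ranged
parameters) and the final solution is picked from the merged non-dominated
archive by the min-max criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from fruitflux import _kernel as K
from fruitflux import moea
from fruitflux.model_core import (
    CALIBRATION_BOUNDS,
    CALIBRATION_PARAM_ORDER,
    LOG_SCALE_PARAMS,
    EnvSeries,
    GenericParams,
    GenotypeParams,
    PlantInputs,
    build_constants,
)

__all__ = [
    "nrmse", "objectives", "objective_components", "calibrate",
    "select_minmax", "CalibrationProblem", "CalibResult",
    "transform_bounds", "encode", "decode", "PENALTY",
]

PENALTY = 1.0e6  # objective value substituted when a simulation fails


def nrmse(obs, sim) -> float:
    """Normalised root-mean-square error, percent of the observed mean.

    One entry per sampled fruit: stages with more fruits weigh more.
    """
    obs = np.asarray(obs, dtype=float)
    sim = np.asarray(sim, dtype=float)
    if obs.size == 0 or obs.shape != sim.shape:
        raise ValueError("obs and sim must be equal-length, non-empty")
    mean_obs = obs.mean()
    if mean_obs <= 0:
        raise ValueError("mean of observations must be strictly positive")
    return float(100.0 * math.sqrt(np.mean((obs - sim) ** 2)) / mean_obs)


# -- search-space transforms ------------------------------------------------

def transform_bounds(bounds: dict[str, tuple[float, float]],
                     order: Sequence[str] = CALIBRATION_PARAM_ORDER) -> np.ndarray:
    """Box bounds in search space: log10 for wide-ranged parameters."""
    out = np.empty((len(order), 2))
    for i, name in enumerate(order):
        lo, hi = bounds[name]
        if name in LOG_SCALE_PARAMS:
            out[i] = (math.log10(lo), math.log10(hi))
        else:
            out[i] = (lo, hi)
    return out


def encode(x_natural: np.ndarray,
           order: Sequence[str] = CALIBRATION_PARAM_ORDER) -> np.ndarray:
    z = np.asarray(x_natural, dtype=float).copy()
    for i, name in enumerate(order):
        if name in LOG_SCALE_PARAMS:
            z[i] = math.log10(z[i])
    return z


def decode(z: np.ndarray,
           order: Sequence[str] = CALIBRATION_PARAM_ORDER) -> np.ndarray:
    x = np.asarray(z, dtype=float).copy()
    for i, name in enumerate(order):
        if name in LOG_SCALE_PARAMS:
            x[i] = 10.0 ** x[i]
    return x


# -- observation handling ---------------------------------------------------

def _treatment_arrays(obs: pd.DataFrame, treatment: str, t0: float, dt: float):
    """Grid indices and observed values for one treatment, sorted by daa."""
    sub = obs[obs["treatment"] == treatment]
    if sub.empty:
        raise ValueError(f"no observations for treatment {treatment}")
    t_obs = sub["daa"].to_numpy(dtype=float) * 24.0
    idx = np.round((t_obs - t0) / dt).astype(np.int64)
    if np.any(idx < 0):
        raise ValueError("observations before the simulation start (8 daa)")
    return idx, sub["fresh_g"].to_numpy(dtype=float), sub["dry_g"].to_numpy(dtype=float)


class CalibrationProblem:
    """MOEA problem wrapper: decode, simulate both treatments, score NRMSE."""

    def __init__(self, obs: pd.DataFrame, inputs_c: PlantInputs,
                 inputs_wd: PlantInputs, env: EnvSeries,
                 generic: Optional[GenericParams] = None,
                 bounds: Optional[dict] = None, t0: float = 192.0,
                 dt: float = 1.0):
        self.generic = generic if generic is not None else GenericParams()
        self.bounds_natural = bounds if bounds is not None else CALIBRATION_BOUNDS
        self.bounds = transform_bounds(self.bounds_natural)
        self.t0 = t0
        self.dt = dt
        env = env.hourly()
        self._env_t = env.T
        self._env_rh = env.RH
        self._env_t0 = float(env.t[0])
        self._obs = {}
        max_t = 0.0
        for trt, inputs in (("C", inputs_c), ("WD", inputs_wd)):
            idx, fresh, dry = _treatment_arrays(obs, trt, t0, dt)
            pc = build_constants(self.generic, inputs)
            self._obs[trt] = (idx, fresh, dry, pc, inputs.w0obs, inputs.s0obs)
            max_t = max(max_t, t0 + idx.max() * dt)
        self.n_steps = int(round((max_t - t0) / dt))
        self.failures: list[np.ndarray] = []

    def components(self, x_natural: np.ndarray) -> Optional[dict[str, float]]:
        """Four NRMSE components for a natural-unit parameter vector."""
        pg = np.asarray(x_natural, dtype=float)
        out = {}
        for trt, (idx, fresh, dry, pc, w0, s0) in self._obs.items():
            status, traj = K.integrate(pg, pc, w0, s0, self.t0, self.n_steps,
                                       self.dt, 1.0 / 64.0, self._env_t,
                                       self._env_rh, self._env_t0)
            if status != K.STATUS_OK:
                return None
            sim_w = traj[idx, K.COL_W]
            sim_s = traj[idx, K.COL_S]
            out[f"f{trt}"] = nrmse(fresh, sim_w + sim_s)
            out[f"d{trt}"] = nrmse(dry, sim_s)
        return out

    def evaluate(self, z: np.ndarray):
        comp = self.components(decode(z))
        if comp is None:
            self.failures.append(np.asarray(z).copy())
            return np.array([PENALTY, PENALTY]), np.zeros(0)
        f1 = 0.5 * (comp["fC"] + comp["dC"])
        f2 = 0.5 * (comp["fWD"] + comp["dWD"])
        return np.array([f1, f2]), np.zeros(0)


def objective_components(x, obs, inputs_c, inputs_wd, env,
                         generic: Optional[GenericParams] = None,
                         t0: float = 192.0) -> Optional[dict[str, float]]:
    problem = CalibrationProblem(obs, inputs_c, inputs_wd, env, generic, t0=t0)
    return problem.components(np.asarray(x, dtype=float))


def objectives(x, obs, inputs_c, inputs_wd, env,
               generic: Optional[GenericParams] = None,
               t0: float = 192.0) -> tuple[float, float]:
    """Aggregated objectives (f1, f2): mean fresh/dry NRMSE per treatment."""
    comp = objective_components(x, obs, inputs_c, inputs_wd, env, generic, t0)
    if comp is None:
        return PENALTY, PENALTY
    return (0.5 * (comp["fC"] + comp["dC"]), 0.5 * (comp["fWD"] + comp["dWD"]))


def select_minmax(archive: Sequence[moea.ParetoSolution]) -> moea.ParetoSolution:
    """Min-max pick: minimise the worse of the two objectives.

    Ties broken by smaller f1+f2, then lexicographically smallest x.
    """
    if not archive:
        raise ValueError("archive must be non-empty")
    return min(archive, key=lambda s: (max(s.f), float(np.sum(s.f)),
                                       tuple(np.asarray(s.x, float))))


@dataclass
class CalibResult:
    """Outcome of one genotype's calibration."""

    genotype_id: str
    archive: list[moea.ParetoSolution]
    chosen: moea.ParetoSolution
    components: dict[str, float]     # fC, dC, fWD, dWD of the chosen solution
    seeds: list[int] = field(default_factory=list)

    @property
    def chosen_params(self) -> GenotypeParams:
        return GenotypeParams.from_vector(self.chosen.x)

    @property
    def f1(self) -> float:
        return float(self.chosen.f[0])

    @property
    def f2(self) -> float:
        return float(self.chosen.f[1])


def calibrate(obs: pd.DataFrame, inputs_c: PlantInputs, inputs_wd: PlantInputs,
              env: EnvSeries, moea_config: Optional[moea.MoeaConfig] = None,
              n_repeats: int = 10, generic: Optional[GenericParams] = None,
              genotype_id: str = "", base_seed: int = 0) -> CalibResult:
    """Estimate the eight genotypic parameters for one genotype.

    Runs ``n_repeats`` independent NSGA-II passes (seeds base_seed..+n-1),
    merges their archives, reduces to the joint non-dominated set and picks
    the min-max solution.
    """
    config = moea_config if moea_config is not None else moea.MoeaConfig()
    problem = CalibrationProblem(obs, inputs_c, inputs_wd, env, generic)
    merged: list[moea.ParetoSolution] = []
    seeds = []
    for repeat in range(n_repeats):
        seed = base_seed + repeat
        seeds.append(seed)
        cfg = moea.MoeaConfig(
            pop_size=config.pop_size, generations=config.generations,
            eta_crossover=config.eta_crossover, p_crossover=config.p_crossover,
            eta_mutation=config.eta_mutation, p_mutation=config.p_mutation,
            seed=seed)
        _, archive = moea.nsga2_run(problem, cfg)
        merged.extend(
            moea.ParetoSolution(decode(ind.x), ind.f.copy(), ind.g.copy(),
                                seed=seed, repeat=repeat)
            for ind in archive)
    archive = moea.nondominated_subset(merged)
    chosen = select_minmax(archive)
    comp = problem.components(np.asarray(chosen.x, dtype=float))
    if comp is None:
        raise RuntimeError(f"chosen solution fails to simulate for {genotype_id}")
    return CalibResult(genotype_id, archive, chosen, comp, seeds)


def archive_correlations(archive: Sequence[moea.ParetoSolution],
                         max_spread: float = 1.0) -> pd.DataFrame:
    """Diagnostic: parameter correlations among near-optimal archive solutions.

    Only solutions whose worst objective lies within ``max_spread`` NRMSE
    points of the archive's best are included (solutions with similar
    objective values).  Returns a parameter-by-parameter Pearson correlation
    matrix (NaN where a parameter does not vary); this is a reported
    diagnostic, not a gate.
    """
    if not archive:
        raise ValueError("archive must be non-empty")
    best = min(max(s.f) for s in archive)
    xs = np.array([s.x for s in archive if max(s.f) <= best + max_spread])
    names = list(CALIBRATION_PARAM_ORDER[:xs.shape[1]])
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(xs, rowvar=False) if xs.shape[0] > 1 else np.full(
            (xs.shape[1], xs.shape[1]), np.nan)
    return pd.DataFrame(np.atleast_2d(corr), index=names, columns=names)


def summarize_components(results: Sequence[CalibResult]) -> pd.DataFrame:
    """Population-level NRMSE summary (mean/sd/min/max per component)."""
    rows = []
    labels = {"fC": "fresh weight C", "dC": "dry weight C",
              "fWD": "fresh weight WD", "dWD": "dry weight WD"}
    for key, label in labels.items():
        vals = np.array([r.components[key] for r in results])
        rows.append({"component": label, "mean": vals.mean(),
                     "sd": vals.std(ddof=1) if vals.size > 1 else 0.0,
                     "min": vals.min(), "max": vals.max()})
    return pd.DataFrame(rows)
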