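"""Virtual populations emulating the study's phenotyping design.

Generates per-genotype "true" parameter vectors inside the calibration
bounds, treatment-specific plant inputs, a greenhouse-like hourly climate,
and noisy per-fruit fresh/dry mass observations following the sampling
scheme: 3 fruits in each of three early windows and 15-20 fruits at the
ripe stage, under control (C) and water-deficit (WD) treatments.

Water deficit is emulated through its measured consequences on the model
inputs (more negative stem water potentials, smaller initial mass, higher
non-sugar osmotic pressure), which is exactly how the calibration consumes
the treatment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from fruitflux.model_core import (
    CALIBRATION_BOUNDS,
    LOG_SCALE_PARAMS,
    EnvSeries,
    GenericParams,
    GenotypeParams,
    PlantInputs,
    SimulationError,
    simulate,
)

__all__ = [
    "SyntheticDesign", "SyntheticTruth", "sample_genotype", "make_environment",
    "make_treatment_inputs", "make_truth", "generate_observations",
    "default_base_inputs", "default_environment",
]

log = logging.getLogger(__name__)

OBS_COLUMNS = ("genotype", "treatment", "daa", "fruit_id", "fresh_g", "dry_g")

#: default WD construction: offsets applied to the control inputs
WD_PSI_SHIFT = -3.0      # bar, applied to both predawn and midday potentials
WD_W0_SCALE = 0.8        # initial water mass reduction
WD_PIOTHER_SCALE = 1.3   # osmotic adjustment of non-sugar solutes


@dataclass
class SyntheticDesign:
    """Sampling design of a virtual phenotyping campaign."""

    n_genotypes: int = 100
    sampling_scheme: tuple = (((8, 10), 3), ((12, 15), 3), ((20, 25), 3))
    ripe_fruits: tuple[int, int] = (15, 20)       # inclusive range of fruit counts
    ripe_daa_range: tuple[int, int] = (45, 60)    # inclusive, per-genotype fixed daa
    noise_cv: float = 0.05                        # multiplicative lognormal CV
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be non-negative")
        for _, n_fruits in self.sampling_scheme:
            if n_fruits < 1:
                raise ValueError("every sampling stage needs >= 1 fruit")


@dataclass
class SyntheticTruth:
    """Ground truth of a virtual population: parameters, inputs, ripe dates."""

    genotypes: dict[str, GenotypeParams]
    inputs: dict[str, dict[str, PlantInputs]]  # genotype -> {"C": ..., "WD": ...}
    ripe_daa: dict[str, int]
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "seed": self.seed,
            "genotypes": {
                gid: {
                    "params": dataclasses.asdict(g),
                    "ripe_daa": self.ripe_daa[gid],
                    "inputs": {trt: dataclasses.asdict(pi)
                               for trt, pi in self.inputs[gid].items()},
                }
                for gid, g in self.genotypes.items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        genotypes, inputs, ripe = {}, {}, {}
        for gid, rec in payload["genotypes"].items():
            genotypes[gid] = GenotypeParams(**rec["params"])
            inputs[gid] = {trt: PlantInputs(**pi) for trt, pi in rec["inputs"].items()}
            ripe[gid] = int(rec["ripe_daa"])
        return cls(genotypes, inputs, ripe, payload.get("seed", 0))


def default_base_inputs() -> PlantInputs:
    """Control-treatment plant inputs of the virtual greenhouse."""
    return PlantInputs(
        psiStemPredawn=-2.0, psiStemMidday=-6.0, Cp=0.2, rhoSurf=10.0,
        piOther=3.5, assrat=0.0075, bssrat=0.13, w0obs=0.5, s0obs=0.05,
        treatment="C")


def sample_genotype(bounds: dict[str, tuple[float, float]],
                    rng: np.random.Generator) -> GenotypeParams:
    """Draw one parameter vector: log-uniform for wide-ranged parameters."""
    values = {}
    for name, (lo, hi) in bounds.items():
        if name in LOG_SCALE_PARAMS:
            values[name] = float(10.0 ** rng.uniform(math.log10(lo), math.log10(hi)))
        else:
            values[name] = float(rng.uniform(lo, hi))
    return GenotypeParams(**values)


def make_environment(n_days: int, rng: Optional[np.random.Generator] = None,
                     t_min: float = 18.0, t_max: float = 28.0,
                     rh_min: float = 0.5, rh_max: float = 0.8,
                     jitter: float = 0.0) -> EnvSeries:
    """Hourly sinusoidal greenhouse climate: T peaks at 14:00, RH in antiphase."""
    if n_days < 1:
        raise ValueError("n_days must be >= 1")
    t = np.arange(0.0, n_days * 24.0 + 1.0)
    phase = np.cos(2.0 * np.pi * (t - 14.0) / 24.0)
    temp = 0.5 * (t_min + t_max) + 0.5 * (t_max - t_min) * phase
    rh = 0.5 * (rh_min + rh_max) - 0.5 * (rh_max - rh_min) * phase
    if jitter > 0:
        if rng is None:
            raise ValueError("jitter requires an rng")
        day = (t // 24).astype(int)
        offsets = rng.normal(0.0, jitter, size=day.max() + 1)
        temp = temp + offsets[day]
    return EnvSeries(t, temp, np.clip(rh, 0.0, 1.0))


def default_environment(n_days: int = 62) -> EnvSeries:
    return make_environment(n_days)


def make_treatment_inputs(base: PlantInputs, treatment: str,
                          psi_shift: float = WD_PSI_SHIFT,
                          w0_scale: float = WD_W0_SCALE,
                          pi_other_scale: float = WD_PIOTHER_SCALE) -> PlantInputs:
    """Derive treatment inputs from the control baseline.

    C returns the baseline unchanged (treatment label set); WD applies the
    configured offsets.  Cp is identical across treatments.
    """
    if treatment not in ("C", "WD"):
        raise ValueError("treatment must be 'C' or 'WD'")
    if treatment == "C":
        return dataclasses.replace(base, treatment="C")
    return dataclasses.replace(
        base,
        psiStemPredawn=base.psiStemPredawn + psi_shift,
        psiStemMidday=base.psiStemMidday + psi_shift,
        w0obs=base.w0obs * w0_scale,
        piOther=base.piOther * pi_other_scale,
        treatment="WD")


def make_truth(design: SyntheticDesign,
               base_inputs: Optional[PlantInputs] = None,
               bounds: Optional[dict] = None) -> SyntheticTruth:
    """Draw true parameter vectors and per-genotype treatment inputs."""
    rng = np.random.default_rng(design.seed)
    base = base_inputs if base_inputs is not None else default_base_inputs()
    bounds = bounds if bounds is not None else CALIBRATION_BOUNDS
    genotypes, inputs, ripe = {}, {}, {}
    for i in range(design.n_genotypes):
        gid = f"G{i + 1:03d}"
        genotypes[gid] = sample_genotype(bounds, rng)
        w0 = float(10.0 ** rng.uniform(math.log10(0.13), math.log10(1.0)))
        s0 = float(w0 * rng.uniform(0.07, 0.12))
        geno_base = dataclasses.replace(base, w0obs=w0, s0obs=s0)
        inputs[gid] = {trt: make_treatment_inputs(geno_base, trt) for trt in ("C", "WD")}
        ripe[gid] = int(rng.integers(design.ripe_daa_range[0],
                                     design.ripe_daa_range[1] + 1))
    return SyntheticTruth(genotypes, inputs, ripe, design.seed)


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    """Multiplicative noise with unit mean and the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size=size)


def generate_observations(truth: SyntheticTruth, design: SyntheticDesign,
                          env: Optional[EnvSeries] = None,
                          generic: Optional[GenericParams] = None,
                          t0: float = 192.0) -> pd.DataFrame:
    """Simulate every genotype x treatment and sample noisy fruit observations.

    Observation noise is independent multiplicative lognormal on the fresh
    mass and on the dry-matter content; dry mass is their product, which
    keeps dry < fresh by construction.
    """
    rng = np.random.default_rng(design.seed + 1)
    env = env if env is not None else default_environment(
        math.ceil(design.ripe_daa_range[1]) + 2)
    generic = generic if generic is not None else GenericParams()
    rows = []
    for gid, genotype in truth.genotypes.items():
        ripe_daa = truth.ripe_daa[gid]
        try:
            trajectories = {
                trt: simulate(genotype, truth.inputs[gid][trt], env, t0,
                              ripe_daa * 24.0, generic=generic, genotype_id=gid)
                for trt in ("C", "WD")
            }
        except SimulationError as exc:
            log.warning("dropping genotype %s: %s", gid, exc)
            continue
        for trt, traj in trajectories.items():
            stages = [(lo, hi, n) for (lo, hi), n in design.sampling_scheme]
            n_ripe = int(rng.integers(design.ripe_fruits[0], design.ripe_fruits[1] + 1))
            stages.append((ripe_daa, ripe_daa, n_ripe))
            fruit_id = 0
            for lo, hi, n_fruits in stages:
                for _ in range(n_fruits):
                    daa = int(rng.integers(lo, hi + 1))
                    state = traj.at_time(min(daa * 24.0, traj.t[-1]))
                    fm = state.fresh_mass * _lognormal_factor(rng, design.noise_cv)
                    dmc = state.dry_matter_content * _lognormal_factor(rng, design.noise_cv)
                    dmc = min(dmc, 0.95)
                    fruit_id += 1
                    rows.append((gid, trt, daa, f"{gid}-{trt}-{fruit_id}",
                                 float(fm), float(fm * dmc)))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)
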