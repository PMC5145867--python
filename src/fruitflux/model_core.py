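"""Biophysical simulation of water and dry-matter accumulation in one fruit.

The model tracks two state variables, the mass of water ``w`` and the dry
mass ``s`` of a growing fruit:

    dw/dt = Ux + Up + rw*Rf - Tf
    ds/dt = Us - Rf

Water enters from the stem through the pedicel xylem (``Ux``) and phloem
(``Up``), each pathway being a series combination of a pedicel conductance
and a composite-membrane conductance proportional to the fruit surface
area.  Sugar enters by three parallel mechanisms (active Michaelis-Menten
uptake, solvent mass flow, passive diffusion), and is lost to growth and
maintenance respiration (``Rf``); water is lost by surface transpiration
(``Tf``).  Irreversible volume growth follows the Lockhart law
``dV/dt = V*phi*(Pf - Y)`` above the yield threshold, which closes an
algebraic equation for the turgor pressure ``Pf`` at every instant.

Units: g, h, bar, cm, degrees Celsius.  Times are hours since anthesis;
days-after-anthesis conversions (factor 24) happen only at I/O boundaries.
"""

from __future__ import annotations

import dataclasses
import hashlib
import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from fruitflux import _kernel as K

__all__ = [
    "GenotypeParams", "GenericParams", "PlantInputs", "EnvSeries",
    "FruitState", "FruitTrajectory", "SimulationError",
    "CALIBRATION_BOUNDS", "IDEOTYPE_BOUNDS", "LOG_SCALE_PARAMS",
    "CALIBRATION_PARAM_ORDER", "IDEOTYPE_PARAM_ORDER",
    "soluble_sugar_fraction", "reflection_coefficient", "active_uptake",
    "fruit_geometry", "osmotic_pressure", "water_fluxes", "sugar_flux",
    "transpiration", "respiration_coupled", "solve_turgor", "step",
    "simulate", "stem_water_potential", "volume_balance_rate",
    "turgor_residual",
]

GAMMA_SPHERE = (36.0 * math.pi) ** (1.0 / 3.0)  # surface of a unit-volume sphere

#: box bounds for the eight parameters estimated during calibration
CALIBRATION_BOUNDS: dict[str, tuple[float, float]] = {
    "phiMax": (1.0e-4, 0.01),
    "Lp": (5.0e-4, 0.4),
    "nuM": (0.002, 0.15),
    "tstar": (10.0, 900.0),
    "tauA": (5.0, 900.0),
    "tauS": (5.0e-6, 1.5e-5),
    "lp1": (5.0e-5, 0.1),
    "rxp": (0.1, 0.6),
}

#: box bounds for the eleven parameters searched during ideotype design
IDEOTYPE_BOUNDS: dict[str, tuple[float, float]] = {
    "phiMax": (0.002, 0.02),
    "Lp": (0.02, 0.6),
    "nuM": (0.002, 0.2),
    "tstar": (10.0, 900.0),
    "tauA": (72.0, 900.0),
    "tauS": (1.5e-6, 2.0e-5),
    "lp1": (0.002, 0.2),
    "rxp": (0.1, 0.8),
    "s0": (0.019, 0.086),
    "w0": (0.126, 1.0),
    "bssrat": (0.043, 0.22),
}

#: parameters whose bounds span >= 2 decades; searched/sampled on log10 scale
LOG_SCALE_PARAMS = frozenset({"phiMax", "Lp", "nuM", "lp1"})

CALIBRATION_PARAM_ORDER = ("phiMax", "Lp", "nuM", "tstar", "tauA", "tauS", "lp1", "rxp")
IDEOTYPE_PARAM_ORDER = CALIBRATION_PARAM_ORDER + ("s0", "w0", "bssrat")


class SimulationError(RuntimeError):
    """Raised when the integrator or turgor solver cannot proceed."""


@dataclass
class GenotypeParams:
    """Genotype-specific parameters (the phenotypic fingerprint).

    The three trailing fields are only used in ideotype mode, where initial
    masses and the soluble-sugar intercept are part of the search space.
    The xylem conductances are always derived: ``lx = rxp*Lp`` and
    ``lx1 = rxp*lp1``.
    """

    phiMax: float       # maximal cell-wall extensibility, bar^-1 h^-1
    Lp: float           # composite-membrane phloem water conductivity, g cm^-2 bar^-1 h^-1
    nuM: float          # maximal active sugar uptake rate, g h^-1
    tstar: float        # active-uptake decline onset, h
    tauA: float         # active-uptake decline time scale, h
    tauS: float         # reflection-coefficient rise rate, h^-2
    lp1: float          # pedicel phloem conductance, g bar^-1 h^-1
    rxp: float          # xylem:phloem conductivity ratio, dimensionless
    s0: Optional[float] = None      # initial dry mass, g (ideotype mode)
    w0: Optional[float] = None      # initial water mass, g (ideotype mode)
    bssrat: Optional[float] = None  # soluble-sugar fraction intercept (ideotype mode)

    @property
    def lx(self) -> float:
        return self.rxp * self.Lp

    @property
    def lx1(self) -> float:
        return self.rxp * self.lp1

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.phiMax, self.Lp, self.nuM, self.tstar, self.tauA,
             self.tauS, self.lp1, self.rxp], dtype=np.float64)

    @classmethod
    def from_vector(cls, x, mode: str = "calibration") -> "GenotypeParams":
        order = CALIBRATION_PARAM_ORDER if mode == "calibration" else IDEOTYPE_PARAM_ORDER
        x = np.asarray(x, dtype=float)
        if x.size != len(order):
            raise ValueError(f"expected {len(order)} parameters, got {x.size}")
        return cls(**dict(zip(order, x.tolist())))

    def to_vector(self, mode: str = "calibration") -> np.ndarray:
        order = CALIBRATION_PARAM_ORDER if mode == "calibration" else IDEOTYPE_PARAM_ORDER
        return np.array([getattr(self, name) for name in order], dtype=float)

    def validate(self, mode: str = "calibration") -> None:
        bounds = CALIBRATION_BOUNDS if mode == "calibration" else IDEOTYPE_BOUNDS
        for name, (lo, hi) in bounds.items():
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{name} is required in {mode} mode")
            if not (lo <= value <= hi):
                raise ValueError(f"{name}={value} outside bounds [{lo}, {hi}]")

    def digest(self) -> str:
        payload = ",".join(f"{f.name}={getattr(self, f.name)}" for f in dataclasses.fields(self))
        return hashlib.sha1(payload.encode()).hexdigest()[:12]


@dataclass
class GenericParams:
    """Non-genotypic model constants.

    Defaults are configuration values, not measurements: they are chosen so
    that a mid-bounds genotype ripens inside the observed 5-160 g fresh-mass
    envelope, and every one of them can be overridden from the run config.
    """

    Km: float = 0.3           # Michaelis constant of active uptake, g g^-1
    ps: float = 2.0e-4        # diffusion permeability per membrane area, g cm^-2 h^-1
    ap: float = 0.15          # phloem vascular-to-surface area ratio
    ax: float = 0.15          # xylem vascular-to-surface area ratio
    qg: float = 0.2           # growth respiration coefficient
    qm20: float = 3.0e-4      # maintenance respiration at 20 C, h^-1
    Q10: float = 1.9          # respiration temperature factor
    Y: float = 2.0            # Lockhart yield threshold, bar
    tauPhi: float = 600.0     # wall-extensibility decay time scale, h
    Hf: float = 0.996         # fruit internal relative humidity
    rhoS: float = 1.6         # dry-matter density, g cm^-3
    Msugar: float = 180.0     # molar mass of transported sugar, g mol^-1
    gammaA: float = GAMMA_SPHERE  # surface-volume allometry coefficient
    rw: float = 9.0 / 16.0    # respiratory dry-mass-to-water conversion (fixed)
    active_uptake_scaling: str = "none"  # "none" (absolute g/h) or "dry_mass"

    def validate(self) -> None:
        if self.rw != 9.0 / 16.0:
            raise ValueError("rw is fixed at 9/16")
        if not (0.0 < self.Hf <= 1.0):
            raise ValueError("Hf must be in (0, 1]")
        for name in ("Km", "ps", "ap", "ax", "qm20", "Q10", "Y", "tauPhi",
                     "rhoS", "Msugar", "gammaA"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.qg < 0:
            raise ValueError("qg must be non-negative")
        if self.active_uptake_scaling not in ("none", "dry_mass"):
            raise ValueError("active_uptake_scaling must be 'none' or 'dry_mass'")


@dataclass
class PlantInputs:
    """Treatment-specific measured inputs driving the simulator."""

    psiStemPredawn: float   # bar, <= 0
    psiStemMidday: float    # bar, <= psiStemPredawn
    Cp: float               # phloem sap sugar concentration, g sugar / g water
    rhoSurf: float          # fruit surface conductance to water vapour, cm h^-1
    piOther: float          # osmotic pressure of non-sugar solutes, bar
    assrat: float           # soluble-sugar fraction slope, day^-1
    bssrat: float           # soluble-sugar fraction intercept
    w0obs: float            # measured initial water mass, g
    s0obs: float            # measured initial dry mass, g
    treatment: str = "C"    # "C" or "WD"

    def validate(self) -> None:
        if not (self.psiStemMidday <= self.psiStemPredawn <= 0.0):
            raise ValueError("require psiStemMidday <= psiStemPredawn <= 0")
        if self.Cp <= 0 or self.rhoSurf <= 0:
            raise ValueError("Cp and rhoSurf must be strictly positive")
        if self.w0obs <= 0 or self.s0obs <= 0:
            raise ValueError("initial masses must be strictly positive")
        if self.treatment not in ("C", "WD"):
            raise ValueError("treatment must be 'C' or 'WD'")


@dataclass
class EnvSeries:
    """Hourly climate series: time (h since anthesis), temperature, humidity."""

    t: np.ndarray
    T: np.ndarray
    RH: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=np.float64)
        self.T = np.asarray(self.T, dtype=np.float64)
        self.RH = np.asarray(self.RH, dtype=np.float64)
        if not (self.t.shape == self.T.shape == self.RH.shape):
            raise ValueError("t, T, RH must have identical shapes")
        if self.t.size < 2:
            raise ValueError("need at least two climate records")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time stamps must be strictly increasing")
        if np.any(self.RH < 0) or np.any(self.RH > 1):
            raise ValueError("RH must lie in [0, 1]")

    def hourly(self) -> "EnvSeries":
        """Resample onto a uniform 1 h grid (the kernel's native layout)."""
        if np.allclose(np.diff(self.t), 1.0):
            return self
        grid = np.arange(math.floor(self.t[0]), math.ceil(self.t[-1]) + 1.0)
        return EnvSeries(grid, np.interp(grid, self.t, self.T),
                         np.interp(grid, self.t, self.RH))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_h": self.t, "T_C": self.T, "RH": self.RH})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EnvSeries":
        df = pd.read_csv(path)
        missing = {"t_h", "T_C", "RH"} - set(df.columns)
        if missing:
            raise ValueError(f"env CSV missing columns: {sorted(missing)}")
        return cls(df["t_h"].to_numpy(), df["T_C"].to_numpy(), df["RH"].to_numpy())


@dataclass
class FruitState:
    """Instantaneous fruit state plus diagnostic fluxes (g h^-1)."""

    t: float
    w: float
    s: float
    Pf: float
    regime: str = "static"  # "growing" | "static"
    Ux: float = 0.0
    Up: float = 0.0
    Us: float = 0.0
    Tf: float = 0.0
    Rf: float = 0.0

    @property
    def fresh_mass(self) -> float:
        return self.w + self.s

    @property
    def dry_matter_content(self) -> float:
        return self.s / (self.w + self.s)


@dataclass
class FruitTrajectory:
    """Hourly fruit states from the simulation start to the stated end."""

    t: np.ndarray
    w: np.ndarray
    s: np.ndarray
    Pf: np.ndarray
    regime: np.ndarray  # 1.0 growing, 0.0 static
    Ux: np.ndarray
    Up: np.ndarray
    Us: np.ndarray
    Tf: np.ndarray
    Rf: np.ndarray
    genotype_id: str = ""
    treatment: str = ""
    param_hash: str = ""

    @property
    def fresh_mass(self) -> np.ndarray:
        return self.w + self.s

    @property
    def dry_matter_content(self) -> np.ndarray:
        return self.s / (self.w + self.s)

    def at_time(self, t: float) -> FruitState:
        """State at grid time t (must lie on the integration grid)."""
        idx = int(round((t - self.t[0]) / (self.t[1] - self.t[0])))
        if not (0 <= idx < self.t.size) or abs(self.t[idx] - t) > 1e-9:
            raise ValueError(f"t={t} not on the trajectory grid")
        return self.state_at_index(idx)

    def state_at_index(self, i: int) -> FruitState:
        return FruitState(
            t=float(self.t[i]), w=float(self.w[i]), s=float(self.s[i]),
            Pf=float(self.Pf[i]),
            regime="growing" if self.regime[i] > 0.5 else "static",
            Ux=float(self.Ux[i]), Up=float(self.Up[i]), Us=float(self.Us[i]),
            Tf=float(self.Tf[i]), Rf=float(self.Rf[i]))

    def final_state(self) -> FruitState:
        return self.state_at_index(len(self.t) - 1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_h": self.t, "w_g": self.w, "s_g": self.s,
            "fm_g": self.fresh_mass, "dm_frac": self.dry_matter_content,
            "Pf_bar": self.Pf, "Ux": self.Ux, "Up": self.Up, "Us": self.Us,
            "Tf": self.Tf, "Rf": self.Rf,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# elementary operations (thin wrappers over the compiled kernel)
# ---------------------------------------------------------------------------

def soluble_sugar_fraction(t: float, assrat: float, bssrat: float) -> float:
    """Soluble-sugar fraction of dry mass, assrat*t/24 + bssrat clipped to [0, 1]."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(K.ssrat_at(t, assrat, bssrat))


def reflection_coefficient(t: float, tauS: float) -> float:
    """Composite-membrane reflection coefficient 1 - exp(-tauS*t^2)."""
    if t < 0 or tauS <= 0:
        raise ValueError("require t >= 0 and tauS > 0")
    return float(K.sigma_p_at(t, tauS))


def active_uptake(t: float, Cp: float, nuM: float, tstar: float, tauA: float,
                  Km: float) -> float:
    """Michaelis-Menten active sugar uptake with a logistic decline in time."""
    if Cp <= 0:
        raise ValueError("Cp must be strictly positive")
    return float(K.active_uptake_rate(t, tstar, tauA, nuM) * Cp / (Km + Cp))


def fruit_geometry(w: float, s: float, rhoS: float, gammaA: float) -> tuple[float, float]:
    """Fruit volume (cm^3, water density 1) and surface area (cm^2)."""
    if w <= 0 or s < 0:
        raise ValueError("require w > 0 and s >= 0")
    v, af = K.geometry(w, s, rhoS, gammaA)
    return float(v), float(af)


def osmotic_pressure(w: float, s: float, t: float, T: float, piOther: float,
                     assrat: float, bssrat: float, Msugar: float) -> float:
    """Fruit osmotic pressure (bar): van 't Hoff sugar term plus other solutes."""
    if w <= 0:
        raise ValueError("w must be strictly positive")
    cf = K.ssrat_at(t, assrat, bssrat) * s / w
    return float(K.osmotic_pressure_sugar(cf, T, Msugar) + piOther)


def stem_water_potential(t: float, psiPredawn: float, psiMidday: float) -> float:
    """Diurnal stem water potential (cosine course, max 05:00, min 13:00)."""
    return float(K.stem_water_potential_at(t, psiPredawn, psiMidday))


def transpiration(Af: float, T: float, RH: float, rhoSurf: float, Hf: float) -> float:
    """Surface transpiration, g h^-1, floored at zero (no condensation gain)."""
    if Af <= 0:
        raise ValueError("Af must be strictly positive")
    tf = Af * rhoSurf * K.sat_vapour_density(T) * (Hf - RH)
    return float(max(tf, 0.0))


def respiration_coupled(Us: float, s: float, T: float, qg: float, qm20: float,
                        Q10: float) -> tuple[float, float]:
    """Solve ds/dt and Rf from Rf = qg*ds/dt + qm(T)*s and ds/dt = Us - Rf."""
    if s <= 0:
        raise ValueError("s must be strictly positive")
    qm = qm20 * Q10 ** ((T - 20.0) / 10.0)
    dsdt = (Us - qm * s) / (1.0 + qg)
    return float(dsdt), float(Us - dsdt)


def _conductances(w, s, genotype: GenotypeParams, generic: GenericParams):
    _, af = K.geometry(w, s, generic.rhoS, generic.gammaA)
    kx = 1.0 / (1.0 / genotype.lx1 + 1.0 / (generic.ax * af * genotype.lx))
    kp = 1.0 / (1.0 / genotype.lp1 + 1.0 / (generic.ap * af * genotype.Lp))
    return af, kx, kp


def water_fluxes(Pf: float, w: float, s: float, t: float,
                 genotype: GenotypeParams, inputs: PlantInputs,
                 generic: GenericParams, T: float) -> tuple[float, float]:
    """Xylem and phloem water inflows (g h^-1) at turgor Pf.

    Each pathway is the series combination of a pedicel conductance and a
    membrane conductance proportional to the fruit surface; the implied
    vasculature-node potential conserves flow exactly.
    """
    for v in (Pf, w, s, t, T):
        if not math.isfinite(v):
            raise ValueError("non-finite input to water_fluxes")
    _, kx, kp = _conductances(w, s, genotype, generic)
    cf = K.ssrat_at(t, inputs.assrat, inputs.bssrat) * s / w
    pi_f = K.osmotic_pressure_sugar(cf, T, generic.Msugar) + inputs.piOther
    pi_p = K.osmotic_pressure_sugar(inputs.Cp, T, generic.Msugar)
    sig = K.sigma_p_at(t, genotype.tauS)
    psi = K.stem_water_potential_at(t, inputs.psiStemPredawn, inputs.psiStemMidday)
    ux = kx * (psi + pi_f - Pf)
    up = kp * (psi + pi_p - sig * (pi_p - pi_f) - Pf)
    return float(ux), float(up)


def sugar_flux(Up: float, w: float, s: float, t: float,
               genotype: GenotypeParams, inputs: PlantInputs,
               generic: GenericParams) -> tuple[float, float, float, float]:
    """Sugar inflow components (Ua, Um, Ud, Us), g h^-1.

    Mass flow uses the mean of phloem and fruit concentrations and carries no
    solute when phloem flow is reversed (Up <= 0).
    """
    cf = K.ssrat_at(t, inputs.assrat, inputs.bssrat) * s / w
    sig = K.sigma_p_at(t, genotype.tauS)
    nu = K.active_uptake_rate(t, genotype.tstar, genotype.tauA, genotype.nuM)
    if generic.active_uptake_scaling == "dry_mass":
        nu *= s
    ua = nu * inputs.Cp / (generic.Km + inputs.Cp)
    um = (1.0 - sig) * 0.5 * (inputs.Cp + cf) * max(Up, 0.0)
    _, af = K.geometry(w, s, generic.rhoS, generic.gammaA)
    ud = generic.ps * generic.ap * af * (inputs.Cp - cf)
    return float(ua), float(um), float(ud), float(ua + um + ud)


def volume_balance_rate(Pf: float, w: float, s: float, t: float,
                        genotype: GenotypeParams, inputs: PlantInputs,
                        generic: GenericParams, T: float, RH: float) -> float:
    """dV/dt implied by the mass balance at turgor Pf (cm^3 h^-1)."""
    ux, up = water_fluxes(Pf, w, s, t, genotype, inputs, generic, T)
    _, _, _, us = sugar_flux(up, w, s, t, genotype, inputs, generic)
    dsdt, rf = respiration_coupled(us, s, T, generic.qg, generic.qm20, generic.Q10)
    _, af = K.geometry(w, s, generic.rhoS, generic.gammaA)
    tf = transpiration(af, T, RH, inputs.rhoSurf, generic.Hf)
    dwdt = ux + up + generic.rw * rf - tf
    return dwdt + dsdt / generic.rhoS


def solve_turgor(w: float, s: float, t: float, genotype: GenotypeParams,
                 inputs: PlantInputs, generic: GenericParams,
                 T: float, RH: float) -> tuple[float, str]:
    """Turgor pressure closing the Lockhart/mass-balance system.

    Returns (Pf, regime); regime is "growing" when the Lockhart root exceeds
    the yield threshold, otherwise the static branch (dV/dt = 0, floored at
    Pf = 0) applies.
    """
    pg = genotype.to_array()
    pc = build_constants(generic, inputs, genotype)
    d = K.derivs(t, w, s, T, RH, pg, pc)
    if not math.isfinite(d[2]):
        raise SimulationError(f"turgor solve failed at t={t}, w={w}, s={s}")
    return float(d[2]), ("growing" if d[3] > 0.5 else "static")


def turgor_residual(Pf: float, regime: str, w: float, s: float, t: float,
                    genotype: GenotypeParams, inputs: PlantInputs,
                    generic: GenericParams, T: float, RH: float) -> float:
    """Defect of the turgor equation at Pf (cm^3 h^-1); 0 for an exact root."""
    dvdt = volume_balance_rate(Pf, w, s, t, genotype, inputs, generic, T, RH)
    if regime == "growing":
        v, _ = K.geometry(w, s, generic.rhoS, generic.gammaA)
        phi = genotype.phiMax * math.exp(-t / generic.tauPhi)
        return float(v * phi * (Pf - generic.Y) - dvdt)
    if Pf == 0.0:
        return 0.0  # floored branch: dV/dt takes whatever value it has at Pf=0
    return float(dvdt)


def build_constants(generic: GenericParams, inputs: PlantInputs,
                    genotype: Optional[GenotypeParams] = None) -> np.ndarray:
    """Pack generic constants and plant inputs into the kernel's flat layout.

    Genotype-level overrides of bssrat (ideotype mode) take precedence over
    the measured input value.
    """
    pc = np.empty(K.N_IC, dtype=np.float64)
    pc[K.IC_KM] = generic.Km
    pc[K.IC_PS] = generic.ps
    pc[K.IC_AP] = generic.ap
    pc[K.IC_AX] = generic.ax
    pc[K.IC_QG] = generic.qg
    pc[K.IC_QM20] = generic.qm20
    pc[K.IC_Q10] = generic.Q10
    pc[K.IC_Y] = generic.Y
    pc[K.IC_TAUPHI] = generic.tauPhi
    pc[K.IC_HF] = generic.Hf
    pc[K.IC_RHOS] = generic.rhoS
    pc[K.IC_MSUGAR] = generic.Msugar
    pc[K.IC_GAMMAA] = generic.gammaA
    pc[K.IC_RW] = generic.rw
    pc[K.IC_CP] = inputs.Cp
    pc[K.IC_PSI_PRE] = inputs.psiStemPredawn
    pc[K.IC_PSI_MID] = inputs.psiStemMidday
    pc[K.IC_RHOSURF] = inputs.rhoSurf
    pc[K.IC_PIOTHER] = inputs.piOther
    pc[K.IC_ASSRAT] = inputs.assrat
    bssrat = inputs.bssrat
    if genotype is not None and genotype.bssrat is not None:
        bssrat = genotype.bssrat
    pc[K.IC_BSSRAT] = bssrat
    pc[K.IC_UPTAKE_SCALING] = 1.0 if generic.active_uptake_scaling == "dry_mass" else 0.0
    return pc


def step(state: FruitState, dt: float, genotype: GenotypeParams,
         inputs: PlantInputs, env: EnvSeries, generic: Optional[GenericParams] = None,
         dt_min: float = 1.0 / 64.0) -> FruitState:
    """Advance one step of size dt with positivity-guarded step halving."""
    if dt <= 0:
        raise ValueError("dt must be strictly positive")
    generic = generic if generic is not None else GenericParams()
    env = env.hourly()
    pg = genotype.to_array()
    pc = build_constants(generic, inputs, genotype)
    status, out = K.integrate(pg, pc, state.w, state.s, state.t, 1, dt, dt_min,
                              env.T, env.RH, float(env.t[0]))
    if status == K.STATUS_DT_UNDERFLOW:
        raise SimulationError(
            f"step size underflow below {dt_min} h at t={state.t} "
            f"(w={state.w}, s={state.s}): non-physical inputs")
    row = out[1]
    return FruitState(
        t=state.t + dt, w=float(row[K.COL_W]), s=float(row[K.COL_S]),
        Pf=float(row[K.COL_PF]),
        regime="growing" if row[K.COL_REGIME] > 0.5 else "static",
        Ux=float(row[K.COL_UX]), Up=float(row[K.COL_UP]),
        Us=float(row[K.COL_US]), Tf=float(row[K.COL_TF]), Rf=float(row[K.COL_RF]))


def simulate(genotype: GenotypeParams, inputs: PlantInputs, env: EnvSeries,
             t0: float = 192.0, t_end: float = 1272.0,
             generic: Optional[GenericParams] = None, dt: float = 1.0,
             dt_min: float = 1.0 / 64.0, genotype_id: str = "") -> FruitTrajectory:
    """Simulate one fruit from t0 (default 8 daa) to t_end.

    Initial masses come from the genotype (ideotype mode) when set, else
    from the measured inputs.  Deterministic: no randomness anywhere.
    """
    if t_end < t0:
        raise ValueError("t_end must be >= t0")
    generic = generic if generic is not None else GenericParams()
    env = env.hourly()
    w0 = genotype.w0 if genotype.w0 is not None else inputs.w0obs
    s0 = genotype.s0 if genotype.s0 is not None else inputs.s0obs
    n_steps = int(round((t_end - t0) / dt))
    pg = genotype.to_array()
    pc = build_constants(generic, inputs, genotype)
    status, out = K.integrate(pg, pc, w0, s0, t0, n_steps, dt, dt_min,
                              env.T, env.RH, float(env.t[0]))
    if status == K.STATUS_DT_UNDERFLOW:
        raise SimulationError(
            f"simulation failed for genotype '{genotype_id or genotype.digest()}' "
            f"({inputs.treatment}): step underflow")
    t = t0 + dt * np.arange(n_steps + 1)
    return FruitTrajectory(
        t=t, w=out[:, K.COL_W], s=out[:, K.COL_S], Pf=out[:, K.COL_PF],
        regime=out[:, K.COL_REGIME], Ux=out[:, K.COL_UX], Up=out[:, K.COL_UP],
        Us=out[:, K.COL_US], Tf=out[:, K.COL_TF], Rf=out[:, K.COL_RF],
        genotype_id=genotype_id, treatment=inputs.treatment,
        param_hash=genotype.digest())
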