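"""Seawater carbonate chemistry: Gran alkalinity and CO2-system speciation.

Two jobs:

1. Total alkalinity (A_T) from open-cell acid titrations via the classical
   Gran linearization: past the carbonic-acid equivalence point the function
   F(v) = (V0 + v) * 10^(-pH) is linear in acid volume v and crosses zero at
   the equivalence volume, so A_T = C_acid * v_eq / sample mass.

2. Full speciation of the CO2 system from a (pH, A_T) pair at given
   temperature and salinity, including the calcite saturation state
   Omega_calc = [Ca2+][CO3 2-]/Ksp.

Constants: K1/K2 default to the Mehrbach refit of Dickson & Millero (1987);
Lueker et al. (2000, total scale) is available via ``k1k2=\"lueker\"``.
KB is Dickson (1990), Kw Millero (1995), Ksp(calcite) Mucci (1983),
total borate Uppstrom (1974), total calcium scales linearly with salinity
(0.010282 * S/35 mol/kg). Sulfate and fluoride are not carried: at the pH
range of interest (>6) their alkalinity contributions are negligible, and
the measured pH is inserted against the constants as given (a configurable
``ph_scale_offset`` allows an NBS-to-total shift if desired).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats as sps

from .errors import (
    CarbonateSolverError,
    ConstantRangeError,
    NoEquivalencePointError,
    TitrationError,
)


def seawater_density(salinity: float, temp: float) -> float:
    """Seawater density in kg/L at one atmosphere (Millero & Poisson 1981).

    ``temp`` in degrees C, ``salinity`` in practical units.
    """
    t = temp
    s = salinity
    rho0 = (999.842594 + 6.793952e-2 * t - 9.095290e-3 * t**2
            + 1.001685e-4 * t**3 - 1.120083e-6 * t**4 + 6.536332e-9 * t**5)
    a = (0.824493 - 4.0899e-3 * t + 7.6438e-5 * t**2
         - 8.2467e-7 * t**3 + 5.3875e-9 * t**4)
    b = -5.72466e-3 + 1.0227e-4 * t - 1.6546e-6 * t**2
    c = 4.8314e-4
    return (rho0 + a * s + b * s**1.5 + c * s**2) / 1000.0


@dataclass(frozen=True)
class ConstantSet:
    """Equilibrium constants and conservative totals for one (T, S)."""

    K1: float
    K2: float
    KB: float
    Kw: float
    Ksp_calcite: float
    BT: float              # total borate, mol/kg
    CaT: float             # total calcium, mol/kg
    temp: float
    salinity: float
    k1k2: str


def constants(temp: float, salinity: float, k1k2: str = "dm87") -> ConstantSet:
    """Evaluate the equilibrium-constant set at ``temp`` (C), ``salinity``.

    ``k1k2`` selects the carbonic-acid formulation: ``"dm87"`` (Dickson &
    Millero 1987 refit of Mehrbach; default) or ``"lueker"`` (Lueker et al.
    2000, total scale).
    """
    if not (0.0 <= salinity <= 45.0) or not (0.0 <= temp <= 40.0):
        raise ConstantRangeError(
            f"(T={temp} C, S={salinity}) outside the fitted range 0-40 C, 0-45"
        )
    T = temp + 273.15
    S = salinity
    lnT = np.log(T)
    if k1k2 == "lueker":
        pK1 = 3633.86 / T - 61.2172 + 9.67770 * lnT - 0.011555 * S + 0.0001152 * S**2
        pK2 = 471.78 / T + 25.9290 - 3.16967 * lnT - 0.01781 * S + 0.0001122 * S**2
    elif k1k2 == "dm87":
        pK1 = 3670.7 / T - 62.008 + 9.7944 * lnT - 0.0118 * S + 0.000116 * S**2
        pK2 = 1394.7 / T + 4.777 - 0.0184 * S + 0.000118 * S**2
    else:
        raise ValueError(f"unknown K1/K2 formulation {k1k2!r}")
    lnKB = ((-8966.90 - 2890.53 * S**0.5 - 77.942 * S + 1.728 * S**1.5
             - 0.0996 * S**2) / T
            + 148.0248 + 137.1942 * S**0.5 + 1.62142 * S
            - (24.4344 + 25.085 * S**0.5 + 0.2474 * S) * lnT
            + 0.053105 * S**0.5 * T)
    lnKw = (148.9802 - 13847.26 / T - 23.6521 * lnT
            + (118.67 / T - 5.977 + 1.0495 * lnT) * S**0.5 - 0.01615 * S)
    log10Ksp = (-171.9065 - 0.077993 * T + 2839.319 / T + 71.595 * np.log10(T)
                + (-0.77712 + 0.0028426 * T + 178.34 / T) * S**0.5
                - 0.07711 * S + 0.0041249 * S**1.5)
    return ConstantSet(
        K1=float(10.0**-pK1),
        K2=float(10.0**-pK2),
        KB=float(np.exp(lnKB)),
        Kw=float(np.exp(lnKw)),
        Ksp_calcite=float(10.0**log10Ksp),
        BT=0.0004157 * S / 35.0,
        CaT=0.010282 * S / 35.0,
        temp=float(temp),
        salinity=float(salinity),
        k1k2=k1k2,
    )


@dataclass(frozen=True)
class CarbonateState:
    """Solved CO2-system speciation. Concentrations in umol/kg except h (mol/kg)."""

    ph: float
    at: float
    dic: float
    co2: float
    hco3: float
    co3: float
    boh4: float
    oh: float
    h: float
    omega_calcite: float
    temp: float
    salinity: float

    def summary(self) -> str:
        return "\n".join([
            "CO2-system solution",
            "-------------------",
            f"pH (as given):   {self.ph:.3f}",
            f"A_T:             {self.at:.1f} umol/kg",
            f"DIC:             {self.dic:.1f} umol/kg",
            f"CO2*:            {self.co2:.1f} umol/kg",
            f"HCO3-:           {self.hco3:.1f} umol/kg",
            f"CO3 2-:          {self.co3:.1f} umol/kg",
            f"Omega_calcite:   {self.omega_calcite:.2f}",
            f"T = {self.temp:.1f} C, S = {self.salinity:.1f}",
        ])


def solve_from_ph_alk(ph: float, at: float, temp: float, salinity: float,
                      ph_scale_offset: float = 0.0,
                      k1k2: str = "dm87") -> CarbonateState:
    """Speciate the CO2 system from measured pH and total alkalinity.

    ``at`` in umol/kg. The proton concentration is 10^-(ph + ph_scale_offset);
    A_T is partitioned into HCO3-, CO3 2-, B(OH)4-, OH- and H+, and
    Omega_calc = CaT * [CO3 2-] / Ksp.
    """
    if at <= 0:
        raise CarbonateSolverError("total alkalinity must be positive")
    if not (6.0 < ph < 9.5):
        raise CarbonateSolverError(f"pH {ph} outside the supported range (6, 9.5)")
    k = constants(temp, salinity, k1k2=k1k2)
    h = 10.0 ** -(ph + ph_scale_offset)
    at_mol = at * 1e-6
    boh4 = k.BT * k.KB / (k.KB + h)
    oh = k.Kw / h
    alk_c = at_mol - boh4 - oh + h          # carbonate alkalinity
    if alk_c <= 0:
        raise CarbonateSolverError(
            "no solution: carbonate alkalinity non-positive after borate/water terms"
        )
    co3 = alk_c / (h / k.K2 + 2.0)
    hco3 = co3 * h / k.K2
    co2 = hco3 * h / k.K1
    omega = k.CaT * co3 / k.Ksp_calcite
    return CarbonateState(
        ph=float(ph),
        at=float(at),
        dic=float((co2 + hco3 + co3) * 1e6),
        co2=float(co2 * 1e6),
        hco3=float(hco3 * 1e6),
        co3=float(co3 * 1e6),
        boh4=float(boh4 * 1e6),
        oh=float(oh * 1e6),
        h=float(h),
        omega_calcite=float(omega),
        temp=float(temp),
        salinity=float(salinity),
    )


def alkalinity_from_state(state: CarbonateState) -> float:
    """Recompute A_T (umol/kg) from a solved speciation (closure check)."""
    return state.hco3 + 2.0 * state.co3 + state.boh4 + state.oh - state.h * 1e6


@dataclass(frozen=True)
class TitrationCurve:
    """One acid-titration record: cumulative acid volume vs measured pH."""

    acid_volumes: np.ndarray      # mL, strictly increasing
    ph_readings: np.ndarray
    sample_mass: float            # kg of seawater titrated
    acid_conc: float = 0.1       # mol/L
    temp: float = 24.0
    salinity: float = 35.0

    def __post_init__(self):
        object.__setattr__(self, "acid_volumes", np.asarray(self.acid_volumes, dtype=float))
        object.__setattr__(self, "ph_readings", np.asarray(self.ph_readings, dtype=float))
        v, p = self.acid_volumes, self.ph_readings
        if v.shape != p.shape or v.ndim != 1:
            raise TitrationError("acid_volumes and ph_readings must match in length")
        if len(v) < 8:
            raise TitrationError("a titration curve needs at least 8 points")
        if np.any(np.diff(v) <= 0):
            raise TitrationError("acid volumes must be strictly increasing")
        # overall monotone decrease, with slack for electrode noise
        if p[-1] >= p[0] or np.any(np.diff(p) > 0.05):
            raise TitrationError("pH readings must decrease (beyond noise) with added acid")
        if self.sample_mass <= 0 or self.acid_conc <= 0:
            raise TitrationError("sample mass and acid concentration must be positive")

    @classmethod
    def from_volume(cls, acid_volumes, ph_readings, sample_volume_ml: float,
                    acid_conc: float = 0.1, temp: float = 24.0,
                    salinity: float = 35.0) -> "TitrationCurve":
        """Build from a sample volume (mL), converting to mass via rho(S, T)."""
        mass = sample_volume_ml * 1e-3 * seawater_density(salinity, temp)
        return cls(acid_volumes, ph_readings, sample_mass=mass,
                   acid_conc=acid_conc, temp=temp, salinity=salinity)

    @property
    def sample_volume_ml(self) -> float:
        return self.sample_mass / seawater_density(self.salinity, self.temp) * 1e3


@dataclass(frozen=True)
class TitrationResults:
    """Gran fit output for one titration curve."""

    at: float             # umol/kg
    v_eq: float           # mL
    gran_fit_r2: float
    n_used: int

    def summary(self) -> str:
        return "\n".join([
            "Gran titration fit",
            "------------------",
            f"A_T:              {self.at:.1f} umol/kg",
            f"equivalence vol.: {self.v_eq:.4f} mL",
            f"Gran fit R^2:     {self.gran_fit_r2:.5f}  (n = {self.n_used})",
        ])


class GranTitration:
    """Gran-linearization model of an acid titration.

    Fits a straight line to the Gran function F(v) = (V0 + v) * 10^(-pH)
    over the acid-side linear region (default: points with pH in [3.0, 3.5];
    if fewer than ``min_points`` fall there, the contiguous window of that
    size with the smallest linear-fit residual is used) and reads the
    equivalence volume from the x-intercept.

    Residual bicarbonate at pH 3-3.5 curves the plain Gran function and
    biases v_eq a few permil low, so after the first pass the fit is
    refined with the compensated Gran function
    F = (V0 + v) * ([H+] - [HCO3-] - [B(OH)4-] - [OH-]), which is exactly
    linear in v for a closed-system carbonate sample; the DIC needed for
    the correction is speciated from the sample's initial pH and the
    previous-pass alkalinity (``correction_passes=0`` restores the plain
    Gran estimator).
    """

    def __init__(self, curve: TitrationCurve, ph_window: tuple[float, float] = (3.0, 3.5),
                 min_points: int = 5, correction_passes: int = 2,
                 k1k2: str = "dm87"):
        self.curve = curve
        self.ph_window = (float(ph_window[0]), float(ph_window[1]))
        self.min_points = int(min_points)
        self.correction_passes = int(correction_passes)
        self.k1k2 = k1k2
        if float(np.min(curve.ph_readings)) > 3.5:
            raise NoEquivalencePointError(
                "titration does not reach pH 3.5; no acid-side Gran region"
            )

    def fit(self) -> TitrationResults:
        c = self.curve
        v0_ml = c.sample_volume_ml
        v, p = self._fit_points()
        h = 10.0 ** (-p)

        def gran_fit(correction):
            F = (v0_ml + v) * (h - correction)
            res = sps.linregress(v, F)
            if res.slope <= 0:
                raise TitrationError("Gran function is not increasing in the fit region")
            v_eq = -res.intercept / res.slope
            if not (0.0 < v_eq < c.acid_volumes[-1]):
                raise NoEquivalencePointError(
                    f"equivalence volume {v_eq:.3f} mL outside the titrated range"
                )
            return v_eq, float(res.rvalue) ** 2

        v_eq, r2 = gran_fit(0.0)
        ph0 = float(c.ph_readings[0])
        can_correct = self.correction_passes > 0 and 6.0 < ph0 < 9.5
        if can_correct:
            k = constants(c.temp, c.salinity, k1k2=self.k1k2)
            m0 = c.sample_mass
            for _ in range(self.correction_passes):
                at_est = c.acid_conc * v_eq * 1e-3 / m0          # mol/kg
                try:
                    state = solve_from_ph_alk(ph0, at_est * 1e6, c.temp,
                                              c.salinity, k1k2=self.k1k2)
                except CarbonateSolverError:
                    break
                dic0 = state.dic * 1e-6                          # mol/kg
                mass = m0 + (v * 1e-3) * 1.0                     # ~1 kg/L acid
                dic_v = dic0 * m0 / mass
                bt_v = k.BT * m0 / mass
                denom = h * h + k.K1 * h + k.K1 * k.K2
                hco3 = dic_v * k.K1 * h / denom
                boh4 = bt_v * k.KB / (k.KB + h)
                v_eq, r2 = gran_fit(hco3 + boh4 + k.Kw / h)
        at = c.acid_conc * v_eq * 1e-3 / c.sample_mass * 1e6
        return TitrationResults(at=float(at), v_eq=float(v_eq),
                                gran_fit_r2=r2, n_used=int(len(v)))

    def _fit_points(self):
        c = self.curve
        lo, hi = self.ph_window
        sel = (c.ph_readings >= lo) & (c.ph_readings <= hi)
        if sel.sum() >= self.min_points:
            return c.acid_volumes[sel], c.ph_readings[sel]
        return self._best_window()

    def _best_window(self):
        """Contiguous acid-side window of min_points with smallest residual."""
        c = self.curve
        acid_side = np.where(c.ph_readings <= 4.0)[0]
        if len(acid_side) < self.min_points:
            raise NoEquivalencePointError(
                "fewer acid-side points than the minimum Gran window"
            )
        v0_ml = c.sample_volume_ml
        best, best_rss = None, np.inf
        idx = acid_side
        w = self.min_points
        for start in range(0, len(idx) - w + 1):
            sub = idx[start:start + w]
            v, p = c.acid_volumes[sub], c.ph_readings[sub]
            F = (v0_ml + v) * 10.0 ** (-p)
            A = np.vstack([v, np.ones_like(v)]).T
            coef, rss, *_ = np.linalg.lstsq(A, F, rcond=None)
            rss = float(rss[0]) if len(rss) else 0.0
            if rss < best_rss:
                best_rss, best = rss, (v, p)
        return best


def gran_alkalinity(curve: TitrationCurve,
                    ph_window: tuple[float, float] = (3.0, 3.5)) -> TitrationResults:
    """Functional wrapper around :class:`GranTitration`."""
    return GranTitration(curve, ph_window=ph_window).fit()


def mean_alkalinity(curves) -> tuple[float, float]:
    """Process duplicate titration tubes independently; return (mean, sd) A_T."""
    ats = np.array([gran_alkalinity(c).at for c in curves])
    return float(np.mean(ats)), float(np.std(ats, ddof=1)) if len(ats) > 1 else 0.0


def _alk_at_h(h: float, dic: float, bt: float, k: ConstantSet) -> float:
    """Total alkalinity (mol/kg) of a solution of given DIC and borate at [H+] h."""
    d = h * h + k.K1 * h + k.K1 * k.K2
    hco3 = dic * k.K1 * h / d
    co3 = dic * k.K1 * k.K2 / d
    boh4 = bt * k.KB / (k.KB + h)
    return hco3 + 2.0 * co3 + boh4 + k.Kw / h - h


def ph_from_alk_dic(at: float, dic: float, k: ConstantSet, bt: float | None = None) -> float:
    """pH of a closed-system sample of given A_T and DIC (both mol/kg).

    Root-solved on pH in [1.5, 12]; used by the forward titration simulator.
    """
    if bt is None:
        bt = k.BT
    f = lambda ph: _alk_at_h(10.0**-ph, dic, bt, k) - at
    return float(optimize.brentq(f, 1.5, 12.0, xtol=1e-10))
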