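"""Chamber incubation rates: photosynthesis, respiration, calcification.

Sealed-chamber endpoint measurements (start/end O2 and total alkalinity over
a fixed incubation) are converted to surface-area-normalized rates:

* net O2 exchange, control-corrected: positive in light (net photosynthesis),
  negative in darkness (respiration);
* maximum gross photosynthesis P_max = net light rate + dark respiration
  magnitude (the standard light/dark bottle construction);
* calcification by the alkalinity-anomaly principle: each mole of CaCO3
  precipitated draws down total alkalinity by two equivalents, so
  G = -dA_T / 2 scaled by the seawater mass in the chamber;
* daily net calcification as the photoperiod-weighted sum of the hourly
  light and dark rates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import IncubationError, MissingControlError
from . import stats as rstats


@dataclass(frozen=True)
class Photoperiod:
    """Hours of light and dark summing to a 24-h day."""

    h_light: float = 14.0
    h_dark: float = 10.0

    def __post_init__(self):
        if not np.isclose(self.h_light + self.h_dark, 24.0):
            raise IncubationError("photoperiod must sum to 24 h")
        if self.h_light < 0 or self.h_dark < 0:
            raise IncubationError("photoperiod hours must be non-negative")


@dataclass(frozen=True)
class IncubationRecord:
    """Endpoints of one sealed-chamber incubation phase.

    Oxygen in umol/L, alkalinity in umol/kg, duration in hours, chamber
    volume in litres, surface area of the incubated specimen in cm^2.
    ``control_delta_o2`` is the O2 change observed in a blank chamber over
    the same duration (umol/L); alkalinity controls default to zero.
    """

    species_id: str
    treatment: str                 # "ambient" | "low_ph"
    phase: str                     # "light" | "dark"
    o2_start: float | None = None
    o2_end: float | None = None
    at_start: float | None = None
    at_end: float | None = None
    duration: float = 0.5
    chamber_volume: float = 0.150
    water_density: float = 1.0233   # kg/L
    surface_area: float = 10.0
    control_delta_o2: float | None = None
    control_delta_at: float = 0.0
    replicate: int = 0

    def __post_init__(self):
        if self.treatment not in ("ambient", "low_ph"):
            raise IncubationError(f"unknown treatment {self.treatment!r}")
        if self.phase not in ("light", "dark"):
            raise IncubationError(f"unknown phase {self.phase!r}")
        if self.duration <= 0 or self.chamber_volume <= 0 or self.surface_area <= 0:
            raise IncubationError("duration, volume and surface area must be positive")


@dataclass(frozen=True)
class RateSet:
    """Derived rates for one specimen (or one species mean).

    O2 rates in umol O2 cm^-2 h^-1; calcification in umol CaCO3 cm^-2 h^-1
    (negative = net dissolution); daily net calcification in
    umol CaCO3 cm^-2 day^-1.
    """

    species_id: str
    treatment: str
    p_net: float
    dark_respiration: float        # positive magnitude
    g_light: float
    g_dark: float
    photoperiod: Photoperiod = field(default_factory=Photoperiod)
    replicate: int = 0

    @property
    def p_max_gross(self) -> float:
        return self.p_net + self.dark_respiration

    @property
    def g_net_daily(self) -> float:
        return daily_net_calcification(self.g_light, self.g_dark, self.photoperiod)


def oxygen_rate(rec: IncubationRecord, *, require_control: bool = True) -> float:
    """Control-corrected O2 exchange rate, umol O2 cm^-2 h^-1, signed.

    rate = ((O2_end - O2_start) - control) * V / (SA * t). Dark incubations
    yield negative rates (respiratory uptake).
    """
    if rec.o2_start is None or rec.o2_end is None:
        raise IncubationError("oxygen endpoints missing")
    control = rec.control_delta_o2
    if control is None:
        if require_control:
            raise MissingControlError(
                "no control incubation; pass require_control=False to proceed uncorrected"
            )
        warnings.warn("no O2 control incubation; proceeding with zero correction")
        control = 0.0
    delta = (rec.o2_end - rec.o2_start) - control
    return float(delta * rec.chamber_volume / (rec.surface_area * rec.duration))


def gross_photosynthesis(p_net_light: float, dark_resp_magnitude: float) -> float:
    """P_max = net light O2 rate + dark respiration magnitude."""
    if dark_resp_magnitude < 0:
        raise IncubationError("dark respiration magnitude must be >= 0")
    return float(p_net_light + dark_resp_magnitude)


def calcification_from_alkalinity(rec: IncubationRecord) -> float:
    """Calcification rate from the alkalinity anomaly, umol CaCO3 cm^-2 h^-1.

    G = -(dA_T - control)/2 * (V * rho) / (SA * t); positive = net
    precipitation, negative = net dissolution.
    """
    if rec.at_start is None or rec.at_end is None:
        raise IncubationError("alkalinity endpoints missing")
    delta_at = (rec.at_end - rec.at_start) - rec.control_delta_at
    mass = rec.chamber_volume * rec.water_density       # kg of seawater
    return float(-delta_at / 2.0 * mass / (rec.surface_area * rec.duration))


def daily_net_calcification(g_light: float, g_dark: float,
                            pp: Photoperiod = Photoperiod()) -> float:
    """Photoperiod-weighted daily net calcification, umol CaCO3 cm^-2 day^-1."""
    return float(pp.h_light * g_light + pp.h_dark * g_dark)


def rates_from_records(records, pp: Photoperiod = Photoperiod(),
                       require_control: bool = True) -> list[RateSet]:
    """Pair light/dark records per (species, treatment, replicate) into RateSets.

    Daily net calcification is computed per replicate and only then averaged
    downstream; a mean-of-means variant is available via
    :func:`summarize_rates`.
    """
    keyed: dict[tuple, dict[str, IncubationRecord]] = {}
    for r in records:
        keyed.setdefault((r.species_id, r.treatment, r.replicate), {})[r.phase] = r
    out = []
    for (sp, tr, rep), phases in sorted(keyed.items()):
        if "light" not in phases or "dark" not in phases:
            raise IncubationError(
                f"replicate {rep} of {sp}/{tr} lacks a light or dark phase"
            )
        p_net = oxygen_rate(phases["light"], require_control=require_control)
        dr = -oxygen_rate(phases["dark"], require_control=require_control)
        out.append(RateSet(
            species_id=sp, treatment=tr, replicate=rep,
            p_net=p_net, dark_respiration=dr,
            g_light=calcification_from_alkalinity(phases["light"]),
            g_dark=calcification_from_alkalinity(phases["dark"]),
            photoperiod=pp,
        ))
    return out


_RESPONSES = ("p_max_gross", "dark_respiration", "g_light", "g_dark", "g_net_daily")


def rates_dataframe(rate_sets) -> pd.DataFrame:
    """Tidy per-replicate rates table."""
    rows = []
    for rs in rate_sets:
        rows.append({
            "species": rs.species_id, "treatment": rs.treatment,
            "replicate": rs.replicate, "p_net": rs.p_net,
            "p_max_gross": rs.p_max_gross, "dark_respiration": rs.dark_respiration,
            "g_light": rs.g_light, "g_dark": rs.g_dark,
            "g_net_daily": rs.g_net_daily,
        })
    return pd.DataFrame(rows)


def summarize_rates(rate_sets, g_net_from_means: bool = False) -> pd.DataFrame:
    """Mean +/- SE per species x treatment, one row per group.

    ``g_net_from_means=True`` reports daily net calcification computed from
    the group-mean hourly rates instead of the per-replicate mean.
    """
    df = rates_dataframe(rate_sets)
    g = df.groupby(["species", "treatment"])
    out = g[list(_RESPONSES)].agg(["mean", "sem", "count"])
    out.columns = [f"{a}_{b}" for a, b in out.columns]
    if g_net_from_means:
        pp = rate_sets[0].photoperiod if rate_sets else Photoperiod()
        out["g_net_daily_mean"] = (pp.h_light * out["g_light_mean"]
                                   + pp.h_dark * out["g_dark_mean"])
    return out.reset_index()


def oa_comparison(rate_sets, alpha: float = 0.05) -> dict:
    """Species x pH-treatment comparison of the four physiological responses.

    Runs a two-way ANOVA (species, treatment, interaction) per response and,
    per species, a one-way ambient-vs-low-pH contrast with Newman-Keuls
    letters. Assumption-check failures are reported, never fatal.
    """
    df = rates_dataframe(rate_sets)
    if df["species"].nunique() < 2 or df["treatment"].nunique() != 2:
        raise IncubationError("need >= 2 species and exactly 2 treatments")
    counts = df.groupby(["species", "treatment"]).size()
    if counts.nunique() > 1:
        warnings.warn("unbalanced species x treatment design")
    result: dict = {"anova": {}, "per_species": {}, "assumptions": {}}
    for resp in ("p_max_gross", "dark_respiration", "g_light", "g_dark"):
        result["anova"][resp] = rstats.two_way_anova(
            df, response=resp, factor_a="species", factor_b="treatment"
        )
        groups = [grp[resp].to_numpy() for _, grp in df.groupby(["species", "treatment"])]
        result["assumptions"][resp] = rstats.assumption_checks(groups)
        per_sp = {}
        for sp, sub in df.groupby("species"):
            pair = [g[resp].to_numpy() for _, g in sub.groupby("treatment")]
            an = rstats.one_way_anova(pair)
            letters = rstats.newman_keuls(pair, alpha=alpha)
            per_sp[sp] = {"anova": an, "letters": letters}
        result["per_species"][resp] = per_sp
    return result
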