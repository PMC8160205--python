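"""Microsensor depth-profile analysis.

Turns raw O2 / pH microprofiles measured from a thallus surface (depth 0)
into the overlying water column into three derived surface quantities:

* effective diffusive boundary layer (DBL) thickness, by extrapolating the
  linear near-surface concentration gradient to the bulk concentration
  (Jorgensen & Revsbech's effective-DBL construction);
* diffusive O2 flux across the DBL from Fick's first law, J = -D dC/dz;
* the surface pH anomaly dpH = pH_surface - pH_bulk.

Depth convention: z = 0 at the thallus surface, increasing away from the
surface, in micrometres. Sign convention for fluxes: positive = efflux out
of the thallus (net O2 production); dark respiratory influx is negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import (
    AnalyteMismatchError,
    DBLOutOfRangeError,
    DegenerateGradientError,
    ProfileError,
    ProfileMismatchError,
    TooFewPointsError,
)

#: Molecular diffusion coefficient of O2 in seawater used throughout, m^2 s^-1.
DEFAULT_D_O2 = 2.01e-9

#: Conversion factor: (umol L^-1 um^-1) * (m^2 s^-1) -> umol cm^-2 h^-1.
#: 1 umol/L/um = 1e3 mol m^-4; 1 mol m^-2 s^-1 = 1e6/1e4*3600 umol cm^-2 h^-1.
_GRAD_FLUX_FACTOR = 3.6e8


@dataclass(frozen=True)
class Microprofile:
    """One depth-resolved microsensor trace at a tip or base location.

    ``depths`` are micrometres with z=0 at the thallus surface, strictly
    increasing away from it; ``values`` are umol/L for oxygen or pH units.
    """

    species_id: str
    location: str          # "tip" | "base"
    condition: str         # "light" | "dark"
    analyte: str           # "oxygen" | "ph"
    depths: np.ndarray
    values: np.ndarray
    flow_note: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.location not in ("tip", "base"):
            raise ProfileError(f"unknown location {self.location!r}")
        if self.condition not in ("light", "dark"):
            raise ProfileError(f"unknown condition {self.condition!r}")
        if self.analyte not in ("oxygen", "ph"):
            raise ProfileError(f"unknown analyte {self.analyte!r}")
        if self.depths.ndim != 1 or self.depths.shape != self.values.shape:
            raise ProfileError("depths and values must be 1-D and the same length")
        if len(self.depths) < 5:
            raise TooFewPointsError("a profile needs at least 5 points")
        if self.depths[0] != 0.0:
            raise ProfileError("first depth must be 0 (thallus surface)")
        if np.any(np.diff(self.depths) <= 0):
            raise ProfileError("depths must be strictly increasing")
        if self.analyte == "oxygen" and np.any(self.values < 0):
            raise ProfileError("oxygen concentrations must be non-negative")

    @property
    def n(self) -> int:
        return len(self.depths)


def average_profiles(profiles: Sequence[Microprofile]) -> Microprofile:
    """Point-wise mean of consecutive replicate profiles on a common grid.

    Field practice measures two consecutive profiles per spot; they are
    averaged after grid alignment. All profiles must share metadata and
    an identical depth grid.
    """
    if not profiles:
        raise ProfileError("no profiles to average")
    first = profiles[0]
    for p in profiles[1:]:
        if (p.species_id, p.location, p.condition, p.analyte) != (
            first.species_id, first.location, first.condition, first.analyte
        ):
            raise ProfileMismatchError("replicate profiles must share metadata")
        if not np.array_equal(p.depths, first.depths):
            raise ProfileError("replicate profiles must share the depth grid")
    mean_values = np.mean([p.values for p in profiles], axis=0)
    return Microprofile(
        species_id=first.species_id,
        location=first.location,
        condition=first.condition,
        analyte=first.analyte,
        depths=first.depths.copy(),
        values=mean_values,
        flow_note=first.flow_note,
    )


@dataclass(frozen=True)
class BulkEstimate:
    """Bulk-water value read from the outer end of a profile."""

    value: float
    stationary: bool
    slope_p: float
    n_outer: int


def estimate_bulk(profile: Microprofile, n_outer: int = 3, alpha: float = 0.05) -> BulkEstimate:
    """Bulk concentration as the mean of the ``n_outer`` outermost points.

    The stationarity flag is True when the slope over those points is
    statistically indistinguishable from zero (t-test, p > alpha); a
    non-stationary tail is reported, not fatal.
    """
    if n_outer < 2:
        raise TooFewPointsError("n_outer must be at least 2")
    if profile.n < n_outer:
        raise TooFewPointsError(
            f"profile has {profile.n} points, fewer than n_outer={n_outer}"
        )
    z = profile.depths[-n_outer:]
    v = profile.values[-n_outer:]
    value = float(np.mean(v))
    if n_outer < 3 or np.allclose(v, v[0]):
        # two points (no residual df) or an exactly flat tail
        stationary, slope_p = True, float("nan")
    else:
        fit = sps.linregress(z, v)
        slope_p = float(fit.pvalue)
        stationary = bool(slope_p > alpha)
    return BulkEstimate(value=value, stationary=stationary, slope_p=slope_p, n_outer=n_outer)


@dataclass(frozen=True)
class DBLResults:
    """Effective-DBL fit results for one profile.

    ``thickness`` is the effective DBL thickness delta (um); the linear
    near-surface gradient extrapolated from z=0 reaches ``bulk_value`` at
    z = delta.
    """

    thickness: float            # um
    surface_value: float        # analyte units at z=0 (fitted intercept)
    surface_gradient: float     # analyte units per um (dC/dz at the surface)
    bulk_value: float
    fit_r2: float
    n_fit: int
    analyte: str
    slope_p: float = field(default=float("nan"))

    def summary(self) -> str:
        lines = [
            "Effective DBL fit",
            "-----------------",
            f"analyte:          {self.analyte}",
            f"DBL thickness:    {self.thickness:.1f} um",
            f"surface value:    {self.surface_value:.4g}",
            f"surface gradient: {self.surface_gradient:.4g} per um",
            f"bulk value:       {self.bulk_value:.4g}",
            f"fit R^2:          {self.fit_r2:.4f}  (n = {self.n_fit})",
        ]
        return "\n".join(lines)


class DBLModel:
    """Linear near-surface model of a microprofile.

    Fits a straight line to the points within ``fit_window_um`` of the
    surface and extrapolates it to the bulk concentration; the depth at
    which the line meets the bulk is the effective DBL thickness.

    Parameters
    ----------
    profile :
        The measured microprofile.
    bulk :
        Bulk-water concentration. If None, taken from :func:`estimate_bulk`.
    fit_window_um :
        Near-surface window used for the linear fit (default 100 um,
        matching a 25-um in-DBL sampling grid: >= 4 points + surface).
    noise_alpha :
        Significance level for the slope t-test below which the gradient
        is considered real; otherwise the profile has no definable DBL.
    """

    def __init__(self, profile: Microprofile, bulk: float | None = None,
                 fit_window_um: float = 100.0, noise_alpha: float = 0.05):
        self.profile = profile
        self.bulk = float(estimate_bulk(profile).value if bulk is None else bulk)
        if not np.isfinite(self.bulk):
            raise ProfileError("bulk value must be finite")
        self.fit_window_um = float(fit_window_um)
        self.noise_alpha = float(noise_alpha)

    def fit(self) -> DBLResults:
        z_all, v_all = self.profile.depths, self.profile.values
        sel = z_all <= self.fit_window_um
        z, v = z_all[sel], v_all[sel]
        if len(z) < 3:
            raise TooFewPointsError(
                f"only {len(z)} points within {self.fit_window_um} um of the surface"
            )
        if np.allclose(v, v[0]):
            raise DegenerateGradientError("profile is constant within the fit window")
        fit = sps.linregress(z, v)
        slope, intercept = float(fit.slope), float(fit.intercept)
        r2 = float(fit.rvalue) ** 2
        slope_p = float(fit.pvalue)
        # noise-free collinear points give stderr 0 -> p = 0, which passes
        if not np.isfinite(slope_p) or slope_p > self.noise_alpha or slope == 0.0:
            raise DegenerateGradientError(
                f"surface gradient indistinguishable from zero (p = {slope_p:.3g})"
            )
        thickness = (self.bulk - intercept) / slope
        if not (0.0 < thickness <= z_all[-1]):
            raise DBLOutOfRangeError(
                f"extrapolated DBL thickness {thickness:.0f} um outside the "
                f"measured range (0, {z_all[-1]:.0f}] um"
            )
        return DBLResults(
            thickness=float(thickness),
            surface_value=intercept,
            surface_gradient=slope,
            bulk_value=self.bulk,
            fit_r2=r2,
            n_fit=int(len(z)),
            analyte=self.profile.analyte,
            slope_p=slope_p,
        )


def estimate_dbl(profile: Microprofile, bulk: float | None = None,
                 fit_window_um: float = 100.0) -> DBLResults:
    """Functional wrapper around :class:`DBLModel`."""
    return DBLModel(profile, bulk=bulk, fit_window_um=fit_window_um).fit()


@dataclass(frozen=True)
class FluxResult:
    """Diffusive O2 flux across the DBL.

    Positive flux = efflux from the thallus (net O2 production in light);
    respiratory influx in darkness is negative.
    """

    flux: float                    # umol O2 cm^-2 h^-1, signed
    diffusion_coefficient: float   # m^2 s^-1

    @property
    def magnitude(self) -> float:
        """Unsigned flux, as reported in per-figure summaries."""
        return abs(self.flux)

    @property
    def direction(self) -> str:
        return "efflux" if self.flux >= 0 else "influx"


def fick_flux(dbl: DBLResults, D: float = DEFAULT_D_O2) -> FluxResult:
    """Fick's-law flux J = -D dC/dz from a fitted oxygen DBL gradient.

    The fitted gradient is umol L^-1 um^-1; J is returned in
    umol O2 cm^-2 h^-1. A gradient decreasing away from the surface
    (negative dC/dz) gives a positive flux (efflux).
    """
    if dbl.analyte != "oxygen":
        raise AnalyteMismatchError("Fick flux requires an oxygen-profile DBL fit")
    if D <= 0:
        raise ValueError("diffusion coefficient must be positive")
    flux = -D * dbl.surface_gradient * _GRAD_FLUX_FACTOR
    return FluxResult(flux=float(flux), diffusion_coefficient=float(D))


@dataclass(frozen=True)
class DeltaPh:
    """Surface pH anomaly dpH = pH_surface - pH_bulk for one profile."""

    delta_ph: float
    ph_surface: float
    ph_bulk: float
    species_id: str | None = None
    location: str | None = None
    condition: str | None = None


def delta_ph(profile: Microprofile, bulk_ph: float) -> DeltaPh:
    """Surface pH anomaly from a pH microprofile.

    pH_surface is the measured value at depth 0; dpH = pH_S - pH_B.
    """
    if profile.analyte != "ph":
        raise AnalyteMismatchError("delta_ph requires a pH profile")
    ph_s = float(profile.values[0])
    return DeltaPh(
        delta_ph=ph_s - float(bulk_ph),
        ph_surface=ph_s,
        ph_bulk=float(bulk_ph),
        species_id=profile.species_id,
        location=profile.location,
        condition=profile.condition,
    )


def diel_ph_range(light: DeltaPh, dark: DeltaPh) -> float:
    """Total diel surface-pH swing, light dpH minus dark dpH.

    Both anomalies must refer to the same species and location. The swing
    is expected (not enforced) to be >= 0 for photosynthesizers; a small
    positive dark anomaly at some tips is a real observation the pipeline
    must tolerate.
    """
    if light.species_id is not None and dark.species_id is not None:
        if (light.species_id, light.location) != (dark.species_id, dark.location):
            raise ProfileMismatchError(
                "light and dark anomalies refer to different species/locations"
            )
    return float(light.delta_ph - dark.delta_ph)
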