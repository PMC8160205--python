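"""Seeded generators for every input kind the pipeline consumes.

Each generator inverts the corresponding estimator's forward model and
records the complete ground truth, so every stage has a recovery test with
no external data. All randomness flows from a single integer seed.

Study conditions emulated (defaults):

* microprofiles sampled at 25-um intervals inside the DBL and 100-um
  intervals outside, to at least 600 um, in a ~2 cm/s flow chamber;
* 0.1 M HCl titrations of ~12 mL seawater samples, electrode noise
  sigma = 0.003 pH;
* 150-mL sealed chambers, 30-min light then dark phases, n = 5 specimens
  per species, ambient (pH 8.12, A_T 2378) vs low-pH (pH 7.698, A_T 2377)
  treatments;
* branched rhodolith phantoms: a spherical core with cylindrical,
  hemispherically capped protuberances at the three species' reported
  protuberance dimensions (L. crispatum ~15 x 2 mm, L. atlanticum
  ~7.5 x 3.5 mm, M. erubescens ~2.75 x 1.5 mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import carbonate
from .carbonate import ConstantSet, TitrationCurve, constants, ph_from_alk_dic, seawater_density
from .errors import ResolutionError, RhodolithError, TitrationError
from .incubation import IncubationRecord
from .morphology import VoxelVolume
from .profiles import DEFAULT_D_O2, Microprofile

_GRAD_FLUX_FACTOR = 3.6e8    # (umol/L/um)*(m^2/s) -> umol cm^-2 h^-1

#: Bulk-water anchors for the simulated study.
BULK_O2_UMOL_L = 210.0
BULK_PH = 8.12
AMBIENT_AT = 2378.0
LOW_PH = 7.698
LOW_PH_AT = 2377.0
TEMP_C = 24.0
SALINITY = 35.0

#: Linear dependence of base-DBL thickness on protuberance length (um, um/mm):
#: longer protuberances create deeper low-flow gaps between branches.
DBL_BASE_INTERCEPT_UM = 150.0
DBL_BASE_SLOPE_UM_PER_MM = 20.0
DBL_TIP_UM = 130.0


@dataclass(frozen=True)
class SpeciesPreset:
    """Ground-truth physiology and morphology for one rhodolith species.

    Rates are the reported species means; the surface-pH anomalies pin
    specific tip/base values consistent with the reported tip/base ranges
    and whose tip/base means equal the reported light/dark species means.
    """

    name: str
    protuberance_length: float      # mm
    protuberance_diameter: float    # mm
    p_max: float                    # umol O2 cm^-2 h^-1 (gross)
    dr: float                       # umol O2 cm^-2 h^-1 (magnitude)
    g_light: float                  # umol CaCO3 cm^-2 h^-1
    g_dark: float
    delta_ph_light_tip: float
    delta_ph_light_base: float
    delta_ph_dark_tip: float
    delta_ph_dark_base: float
    n_protuberances: int = 10
    # low-pH (short-term acidification) effect structure: dark calcification
    # shifts strongly negative in all species; metabolic stimulation only in
    # the high-metabolism species; light calcification unchanged.
    low_ph_g_dark: float = -0.06
    low_ph_p_max_factor: float = 1.0
    low_ph_dr_factor: float = 1.0

    def __post_init__(self):
        if self.protuberance_length <= 0 or self.protuberance_diameter <= 0:
            raise RhodolithError("protuberance dimensions must be positive")

    @property
    def p_net(self) -> float:
        return self.p_max - self.dr

    @property
    def dbl_base_um(self) -> float:
        return DBL_BASE_INTERCEPT_UM + DBL_BASE_SLOPE_UM_PER_MM * self.protuberance_length

    @property
    def dbl_tip_um(self) -> float:
        return DBL_TIP_UM

    def delta_ph_mean(self, condition: str) -> float:
        if condition == "light":
            return 0.5 * (self.delta_ph_light_tip + self.delta_ph_light_base)
        return 0.5 * (self.delta_ph_dark_tip + self.delta_ph_dark_base)


#: The three studied species. Protuberance dimensions are the reported
#: mid-range values; rates are the reported ambient species means.
PRESETS: dict[str, SpeciesPreset] = {
    "L_crispatum": SpeciesPreset(
        name="L_crispatum", protuberance_length=15.0, protuberance_diameter=2.0,
        p_max=0.50, dr=0.10, g_light=0.12, g_dark=0.04,
        delta_ph_light_tip=0.22, delta_ph_light_base=0.50,
        delta_ph_dark_tip=0.04, delta_ph_dark_base=-0.0382,
        n_protuberances=10, low_ph_g_dark=-0.06,
    ),
    "L_atlanticum": SpeciesPreset(
        name="L_atlanticum", protuberance_length=7.5, protuberance_diameter=3.5,
        p_max=0.61, dr=0.18, g_light=0.19, g_dark=-0.06,
        delta_ph_light_tip=0.32, delta_ph_light_base=0.78,
        delta_ph_dark_tip=-0.06, delta_ph_dark_base=-0.40,
        n_protuberances=10, low_ph_g_dark=-0.15,
        low_ph_p_max_factor=1.15, low_ph_dr_factor=1.4,
    ),
    "M_erubescens": SpeciesPreset(
        name="M_erubescens", protuberance_length=2.75, protuberance_diameter=1.5,
        p_max=0.52, dr=0.14, g_light=0.08, g_dark=-0.01,
        delta_ph_light_tip=0.20, delta_ph_light_base=0.46,
        delta_ph_dark_tip=0.01, delta_ph_dark_base=-0.13,
        n_protuberances=45, low_ph_g_dark=-0.06,
    ),
}


# ------------------------------------------------------------- microprofiles

def simulate_microprofile(bulk: float, dbl_thickness: float, flux: float,
                          D: float = DEFAULT_D_O2, noise_sd: float = 0.0,
                          seed: int | np.random.Generator = 0,
                          species_id: str = "synthetic", location: str = "tip",
                          condition: str = "light",
                          curvature: float = 0.0) -> tuple[Microprofile, dict]:
    """Steady-state O2 microprofile with an imposed DBL thickness and flux.

    Linear within [0, delta] with gradient set by the flux (Fick inversion),
    constant at ``bulk`` beyond; sampled at 25-um steps inside the DBL and
    100-um steps outside, to at least 600 um. ``curvature`` (0..1) bends the
    in-DBL segment quadratically while preserving the surface gradient, to
    stress-test the linear estimator.
    """
    if dbl_thickness <= 0:
        raise RhodolithError("DBL thickness must be positive")
    if dbl_thickness < 50.0:
        raise RhodolithError("grid too coarse: DBL thinner than two 25-um steps")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    gradient = -flux / (D * _GRAD_FLUX_FACTOR)       # umol/L per um
    surface = bulk - gradient * dbl_thickness
    depths = _profile_grid(dbl_thickness)
    inside = depths <= dbl_thickness
    values = np.where(inside, surface + gradient * depths, bulk)
    if curvature:
        z = depths[inside] / dbl_thickness
        # cubic bend with zero value *and* slope at the surface and zero
        # value at z = delta, so only the interior of the DBL is distorted
        bend = curvature * gradient * dbl_thickness * (z**2 - z**3)
        values = values.copy()
        values[inside] += bend
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    values = np.clip(values, 0.0, None)
    profile = Microprofile(
        species_id=species_id, location=location, condition=condition,
        analyte="oxygen", depths=depths, values=values, flow_note="2 cm s-1",
    )
    truth = {"bulk": bulk, "dbl_thickness": dbl_thickness, "flux": flux,
             "surface_value": surface, "gradient": gradient, "D": D,
             "noise_sd": noise_sd}
    return profile, truth


def simulate_ph_profile(bulk_ph: float, dbl_thickness: float, delta_ph: float,
                        noise_sd: float = 0.0,
                        seed: int | np.random.Generator = 0,
                        species_id: str = "synthetic", location: str = "tip",
                        condition: str = "light") -> tuple[Microprofile, dict]:
    """pH microprofile: linear from (bulk + delta_ph) at the surface to bulk."""
    if dbl_thickness < 50.0:
        raise RhodolithError("grid too coarse: DBL thinner than two 25-um steps")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    surface = bulk_ph + delta_ph
    depths = _profile_grid(dbl_thickness)
    gradient = (bulk_ph - surface) / dbl_thickness
    values = np.where(depths <= dbl_thickness, surface + gradient * depths, bulk_ph)
    if noise_sd > 0:
        values = values + rng.normal(0.0, noise_sd, size=values.shape)
    profile = Microprofile(
        species_id=species_id, location=location, condition=condition,
        analyte="ph", depths=depths, values=values, flow_note="2 cm s-1",
    )
    truth = {"bulk_ph": bulk_ph, "dbl_thickness": dbl_thickness,
             "delta_ph": delta_ph, "surface_ph": surface, "noise_sd": noise_sd}
    return profile, truth


def _profile_grid(dbl_thickness: float) -> np.ndarray:
    """25-um steps inside the DBL, 100-um steps outside, to >= 600 um."""
    inner = np.arange(0.0, dbl_thickness + 1e-9, 25.0)
    start_out = inner[-1] + 100.0
    z_max = max(600.0, dbl_thickness + 300.0)
    outer = np.arange(start_out, z_max + 1e-9, 100.0)
    return np.concatenate([inner, outer])


# ---------------------------------------------------------------- titrations

def simulate_titration(at_true: float, dic: float = 2100.0,
                       sample_mass: float | None = None,
                       sample_volume_ml: float = 12.0,
                       acid_conc: float = 0.1, increment: float = 0.01,
                       noise_sd_ph: float = 0.0, temp: float = TEMP_C,
                       salinity: float = SALINITY,
                       seed: int | np.random.Generator = 0,
                       k1k2: str = "dm87",
                       acid_density: float = 1.0) -> tuple[TitrationCurve, dict]:
    """Forward-simulate a closed-system HCl titration of a seawater sample.

    ``at_true`` and ``dic`` in umol/kg. After each cumulative acid addition
    the sample pH is solved from the charge balance with dilution tracked by
    mass; Gaussian electrode noise is added to the pH readings. Titration
    stops once the mixture passes pH ~2.9, comfortably beyond the
    carbonic-acid equivalence point.
    """
    if at_true <= 0 or dic <= 0:
        raise TitrationError("A_T and DIC must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = constants(temp, salinity, k1k2=k1k2)
    m0 = sample_mass if sample_mass is not None else (
        sample_volume_ml * 1e-3 * seawater_density(salinity, temp))
    at_mol = at_true * 1e-6 * m0          # total alkalinity, moles
    dic_mol = dic * 1e-6 * m0
    bt_mol = k.BT * m0
    v_eq_ml = at_mol / acid_conc * 1e3
    # excess acid to reach pH ~2.9 in the final mixture
    v_excess_ml = 10**-2.9 * (m0 + v_eq_ml * 1e-3 * acid_density) / acid_conc * 1e3
    v_max = v_eq_ml + 1.15 * v_excess_ml
    volumes = np.arange(0.0, v_max + increment, increment)
    ph = np.empty_like(volumes)
    for i, v in enumerate(volumes):
        mass = m0 + v * 1e-3 * acid_density
        alk_c = (at_mol - acid_conc * v * 1e-3) / mass
        ph[i] = ph_from_alk_dic(alk_c, dic_mol / mass, k, bt=bt_mol / mass)
    if ph[-1] > 3.5:
        raise TitrationError("insufficient acid: final pH above 3.5")
    if noise_sd_ph > 0:
        ph = ph + rng.normal(0.0, noise_sd_ph, size=ph.shape)
    curve = TitrationCurve(acid_volumes=volumes, ph_readings=ph, sample_mass=m0,
                           acid_conc=acid_conc, temp=temp, salinity=salinity)
    truth = {"at_true": at_true, "dic": dic, "sample_mass": m0,
             "v_eq_ml": v_eq_ml, "acid_conc": acid_conc,
             "noise_sd_ph": noise_sd_ph, "k1k2": k1k2}
    return curve, truth


# --------------------------------------------------------------- incubations

def simulate_incubation(preset: SpeciesPreset, phase: str, treatment: str = "ambient",
                        seed: int | np.random.Generator = 0,
                        noise_o2: float = 0.0, noise_at: float = 0.0,
                        chamber_volume: float = 0.150, duration: float = 0.5,
                        surface_area: float = 30.0, temp: float = TEMP_C,
                        salinity: float = SALINITY,
                        replicate: int = 0,
                        rate_cv: float = 0.0) -> tuple[IncubationRecord, dict]:
    """Sealed-chamber endpoints generated by inverting the rate equations.

    The low-pH treatment applies the preset's effect structure (strongly
    negative dark calcification in all species; metabolic stimulation only
    where configured; light calcification unchanged). ``rate_cv`` adds
    between-specimen lognormal variation to the true rates before the
    endpoint (measurement) noise ``noise_o2`` / ``noise_at`` is applied.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if phase == "light":
        o2_rate = preset.p_net
        g_rate = preset.g_light
        if treatment == "low_ph":
            o2_rate = preset.p_max * preset.low_ph_p_max_factor - preset.dr * preset.low_ph_dr_factor
    elif phase == "dark":
        o2_rate = -preset.dr
        g_rate = preset.g_dark
        if treatment == "low_ph":
            o2_rate = -preset.dr * preset.low_ph_dr_factor
            g_rate = preset.low_ph_g_dark
    else:
        raise RhodolithError(f"unknown phase {phase!r}")
    if rate_cv > 0:
        o2_rate *= rng.lognormal(0.0, rate_cv)
        # additive jitter for calcification: dark rates can cross zero
        g_scale = abs(g_rate) if g_rate != 0 else 0.05
        g_rate += rng.normal(0.0, rate_cv * g_scale)
    rho = seawater_density(salinity, temp)
    o2_start = BULK_O2_UMOL_L
    at_start = AMBIENT_AT if treatment == "ambient" else LOW_PH_AT
    delta_o2 = o2_rate * surface_area * duration / chamber_volume
    delta_at = -2.0 * g_rate * surface_area * duration / (chamber_volume * rho)
    e = (lambda s: rng.normal(0.0, s)) if (noise_o2 > 0 or noise_at > 0) else (lambda s: 0.0)
    rec = IncubationRecord(
        species_id=preset.name, treatment=treatment, phase=phase,
        o2_start=o2_start + e(noise_o2), o2_end=o2_start + delta_o2 + e(noise_o2),
        at_start=at_start + e(noise_at), at_end=at_start + delta_at + e(noise_at),
        duration=duration, chamber_volume=chamber_volume, water_density=rho,
        surface_area=surface_area, control_delta_o2=0.0, control_delta_at=0.0,
        replicate=replicate,
    )
    truth = {"o2_rate": o2_rate, "g_rate": g_rate, "phase": phase,
             "treatment": treatment, "at_start": at_start,
             "at_end": at_start + delta_at, "density": rho}
    return rec, truth


# ------------------------------------------------------------------- volumes

def _fibonacci_directions(n: int, rng: np.random.Generator) -> np.ndarray:
    """n quasi-uniform unit vectors, randomly rotated (seeded)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    dirs = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
    # random rotation via QR of a Gaussian matrix
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return dirs @ q.T


def simulate_rhodolith_volume(preset: SpeciesPreset, core_radius: float = 5.0,
                              n_protuberances: int | None = None,
                              voxel_size: float = 250.0,
                              seed: int | np.random.Generator = 0,
                              fg_intensity: float = 170.0,
                              bg_intensity: float = 30.0,
                              noise_sd: float = 0.0) -> tuple[VoxelVolume, dict]:
    """Rasterized branched-rhodolith phantom with exact analytic SA and V.

    Geometry: a spherical core of ``core_radius`` (mm) plus radially oriented
    cylindrical protuberances with hemispherical caps at the preset's length
    and diameter, placed on seeded quasi-uniform directions. Protuberances
    are mutually disjoint by construction (quasi-uniform spacing), so the
    union's surface area and volume have closed forms, recorded in truth.

    Returns a grayscale volume (two intensity modes plus optional Gaussian
    noise) ready for the filter/segment/measure chain.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if core_radius <= 0:
        raise RhodolithError("core radius must be positive")
    n = preset.n_protuberances if n_protuberances is None else int(n_protuberances)
    r_p = preset.protuberance_diameter / 2.0      # mm
    length = preset.protuberance_length           # mm beyond the core surface
    if preset.protuberance_diameter * 1000.0 < 4.0 * voxel_size:
        raise ResolutionError(
            f"protuberance diameter {preset.protuberance_diameter} mm spans "
            f"fewer than 4 voxels at {voxel_size} um"
        )
    if r_p >= core_radius:
        raise RhodolithError("protuberance radius must be smaller than the core radius")
    dirs = _fibonacci_directions(n, rng) if n > 0 else np.zeros((0, 3))
    R = core_radius
    vs_mm = voxel_size / 1000.0
    extent = R + length + r_p + 2 * vs_mm
    n_vox = int(np.ceil(2 * extent / vs_mm))
    axis = (np.arange(n_vox) - (n_vox - 1) / 2.0) * vs_mm
    mask = np.zeros((n_vox,) * 3, dtype=bool)
    # core sphere
    xx = axis[:, None, None]
    yy = axis[None, :, None]
    zz = axis[None, None, :]
    mask |= (xx**2 + yy**2 + zz**2) <= R**2
    # protuberances: capsules from 0.8R u to (R + length - r_p) u, radius r_p
    for u in dirs:
        a = 0.8 * R
        b = R + length - r_p
        _rasterize_capsule(mask, axis, u, a, b, r_p)
    # analytic truth (radial capsules, mutually disjoint outside the core)
    cap_h = R - np.sqrt(R**2 - r_p**2)
    sa = (4 * np.pi * R**2
          - n * 2 * np.pi * R * cap_h
          + n * 2 * np.pi * r_p * (R + length - r_p - np.sqrt(R**2 - r_p**2))
          + n * 2 * np.pi * r_p**2)
    vol = ((4.0 / 3.0) * np.pi * R**3
           + n * (np.pi * r_p**2 * (R + length - r_p)
                  - (2 * np.pi / 3.0) * (R**3 - (R**2 - r_p**2) ** 1.5)
                  + (2.0 / 3.0) * np.pi * r_p**3))
    grid = np.where(mask, fg_intensity, bg_intensity).astype(np.float32)
    if noise_sd > 0:
        grid = grid + rng.normal(0.0, noise_sd, size=grid.shape).astype(np.float32)
    volume = VoxelVolume(grid, voxel_size, provenance=f"synthetic:{preset.name}")
    truth = {"surface_area_mm2": float(sa), "volume_mm3": float(vol),
             "sa_v": float(sa / vol), "core_radius": R, "n_protuberances": n,
             "protuberance_length": length, "protuberance_radius": r_p,
             "directions": dirs, "mask": mask}
    return volume, truth


def _rasterize_capsule(mask: np.ndarray, axis: np.ndarray, u: np.ndarray,
                       a: float, b: float, r: float) -> None:
    """OR a capsule (segment a*u..b*u dilated by r) into mask, in place."""
    p0, p1 = a * u, b * u
    lo = np.minimum(p0, p1) - r
    hi = np.maximum(p0, p1) + r
    idx = [np.searchsorted(axis, l) for l in lo], [np.searchsorted(axis, h, "right") for h in hi]
    sl = tuple(slice(max(0, i), min(len(axis), j)) for i, j in zip(idx[0], idx[1]))
    sub_axes = [axis[s] for s in sl]
    X = sub_axes[0][:, None, None]
    Y = sub_axes[1][None, :, None]
    Z = sub_axes[2][None, None, :]
    d = p1 - p0
    L2 = float(d @ d)
    # parameter of the closest point on the segment, clamped to [0, 1]
    t = ((X - p0[0]) * d[0] + (Y - p0[1]) * d[1] + (Z - p0[2]) * d[2]) / L2
    t = np.clip(t, 0.0, 1.0)
    dx = X - (p0[0] + t * d[0])
    dy = Y - (p0[1] + t * d[1])
    dz = Z - (p0[2] + t * d[2])
    mask[sl] |= (dx * dx + dy * dy + dz * dz) <= r * r


def monte_carlo_volume(truth: dict, n_samples: int = 200_000,
                       seed: int = 0) -> tuple[float, float]:
    """Seeded Monte-Carlo check of a phantom's union volume.

    Samples points uniformly in the bounding box and tests them against the
    constructive geometry (sphere plus capsules), independently of both the
    closed-form volume and the rasterized mask. Returns (estimate, standard
    error) in mm^3.
    """
    rng = np.random.default_rng(seed)
    R = truth["core_radius"]
    length = truth["protuberance_length"]
    r_p = truth["protuberance_radius"]
    extent = R + length + r_p
    pts = rng.uniform(-extent, extent, size=(n_samples, 3))
    inside = np.einsum("ij,ij->i", pts, pts) <= R**2
    for u in truth["directions"]:
        p0 = 0.8 * R * np.asarray(u)
        p1 = (R + length - r_p) * np.asarray(u)
        d = p1 - p0
        t = np.clip((pts - p0) @ d / (d @ d), 0.0, 1.0)
        closest = p0 + t[:, None] * d
        diff = pts - closest
        inside |= np.einsum("ij,ij->i", diff, diff) <= r_p**2
    box_vol = (2 * extent) ** 3
    frac = inside.mean()
    est = frac * box_vol
    se = box_vol * np.sqrt(frac * (1 - frac) / n_samples)
    return float(est), float(se)


# ------------------------------------------------------------ whole study

@dataclass(frozen=True)
class SimProfileSpot:
    """Consecutive replicate profiles measured at one spot."""

    species_id: str
    individual: int
    spot: int
    location: str
    condition: str
    analyte: str
    profiles: tuple[Microprofile, ...]
    truth: dict


@dataclass
class StudyBundle:
    """Everything the pipeline consumes, plus complete generating truth."""

    seed: int
    microprofiles: list[SimProfileSpot] = field(default_factory=list)
    incubations: list[IncubationRecord] = field(default_factory=list)
    titrations: list[tuple[dict, TitrationCurve]] = field(default_factory=list)
    volumes: list[tuple[dict, VoxelVolume]] = field(default_factory=list)
    truth: dict = field(default_factory=dict)


def simulate_study(seed: int = 0, noise_scale: float = 1.0,
                   n_individuals: int = 3, spots_per_individual: int = 2,
                   n_incubation_reps: int = 5, n_volumes: int = 5,
                   include_titrations: bool = True,
                   volume_voxel_um: float = 350.0,
                   presets: dict[str, SpeciesPreset] | None = None) -> StudyBundle:
    """Full crossed synthetic study for the three species.

    ``noise_scale`` multiplies every measurement-noise sigma (0 = noise-free
    and with no between-individual variation, so every estimator must recover
    the truth exactly up to grid effects). Defaults follow the study design:
    3 individuals x 2 spots x {tip, base} x {light, dark} microprofiles with
    two consecutive profiles per spot, 5 chamber replicates x 2 treatments x
    2 phases with duplicate titration tubes per endpoint, 5 CT volumes per
    species.
    """
    presets = dict(PRESETS) if presets is None else presets
    rng = np.random.default_rng(seed)
    bundle = StudyBundle(seed=seed)
    prof_noise_o2 = 1.0 * noise_scale
    prof_noise_ph = 0.005 * noise_scale
    endpoint_noise_o2 = 1.0 * noise_scale
    endpoint_noise_at = 2.0 * noise_scale
    titration_noise_ph = 0.003 * noise_scale
    individual_cv = 0.08 * noise_scale
    rate_cv = 0.10 * noise_scale

    truth: dict = {"presets": {k: asdict(v) for k, v in presets.items()},
                   "noise_scale": noise_scale, "bulk_o2": BULK_O2_UMOL_L,
                   "bulk_ph": BULK_PH, "photoperiod": (14.0, 10.0)}

    for name, sp in presets.items():
        for ind in range(n_individuals):
            ind_factor = rng.lognormal(0.0, individual_cv) if individual_cv > 0 else 1.0
            for location in ("tip", "base"):
                dbl = (sp.dbl_tip_um if location == "tip" else sp.dbl_base_um) * ind_factor
                for condition in ("light", "dark"):
                    if condition == "light":
                        flux = sp.p_max * (1.0 if location == "tip" or name == "L_atlanticum" else 0.8)
                        dph = sp.delta_ph_light_tip if location == "tip" else sp.delta_ph_light_base
                    else:
                        flux = -sp.dr
                        dph = sp.delta_ph_dark_tip if location == "tip" else sp.delta_ph_dark_base
                    for spot in range(spots_per_individual):
                        reps, t = [], None
                        for _ in range(2):   # two consecutive profiles per spot
                            p, t = simulate_microprofile(
                                BULK_O2_UMOL_L, dbl, flux, noise_sd=prof_noise_o2,
                                seed=rng, species_id=name, location=location,
                                condition=condition)
                            reps.append(p)
                        bundle.microprofiles.append(SimProfileSpot(
                            name, ind, spot, location, condition, "oxygen",
                            tuple(reps), t))
                        reps_ph, t_ph = [], None
                        for _ in range(2):
                            p, t_ph = simulate_ph_profile(
                                BULK_PH, dbl, dph, noise_sd=prof_noise_ph,
                                seed=rng, species_id=name, location=location,
                                condition=condition)
                            reps_ph.append(p)
                        bundle.microprofiles.append(SimProfileSpot(
                            name, ind, spot, location, condition, "ph",
                            tuple(reps_ph), t_ph))

        for treatment in ("ambient", "low_ph"):
            for rep in range(n_incubation_reps):
                for phase in ("light", "dark"):
                    rec, rec_truth = simulate_incubation(
                        sp, phase, treatment, seed=rng,
                        noise_o2=endpoint_noise_o2, noise_at=endpoint_noise_at,
                        replicate=rep, rate_cv=rate_cv)
                    bundle.incubations.append(rec)
                    truth.setdefault("incubations", []).append(
                        {"species": name, **rec_truth, "replicate": rep})
                    if include_titrations:
                        for which, at_val in (("start", rec_truth["at_start"]),
                                              ("end", rec_truth["at_end"])):
                            for tube in range(2):
                                curve, ct = simulate_titration(
                                    at_val, noise_sd_ph=titration_noise_ph,
                                    seed=rng)
                                meta = {"species": name, "treatment": treatment,
                                        "phase": phase, "replicate": rep,
                                        "endpoint": which, "tube": tube,
                                        "at_true": ct["at_true"]}
                                bundle.titrations.append((meta, curve))

        for i in range(n_volumes):
            # small seeded size variation: real specimens differ in core size
            core = 5.0 * (rng.lognormal(0.0, 0.05) if n_volumes > 1 else 1.0)
            vol, vt = simulate_rhodolith_volume(sp, core_radius=core,
                                                voxel_size=volume_voxel_um,
                                                seed=rng)
            vt = {k: v for k, v in vt.items() if k != "mask"}
            bundle.volumes.append(({"species": name, "replicate": i, **vt}, vol))

    bundle.truth = truth
    return bundle
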