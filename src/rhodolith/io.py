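"""Readers and writers for the pipeline's plain-text dialects and volumes.

Profile CSV: header ``depth_um,value`` preceded by ``# key: value`` comment
lines (species, location, condition, analyte, bulk when known). Titration
CSV: ``acid_ml,ph`` with ``# sample_mass_kg``, ``# acid_conc_M``,
``# temp_C``, ``# salinity`` headers. Incubations: one row per
chamber-phase. Volumes: multi-page TIFF with the voxel size (um) in the
image description.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .carbonate import TitrationCurve
from .incubation import IncubationRecord
from .morphology import VoxelVolume
from .profiles import Microprofile


def _read_commented_csv(path) -> tuple[dict, pd.DataFrame]:
    meta: dict[str, str] = {}
    rows: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                meta[key.strip()] = value.strip()
            elif line.strip():
                rows.append(line)
    from io import StringIO
    df = pd.read_csv(StringIO("\n".join(rows)))
    return meta, df


def _write_commented_csv(path, meta: dict, df: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False)


# ---------------------------------------------------------------- profiles

def read_profile_csv(path) -> tuple[Microprofile, dict]:
    """Read one microprofile; returns (profile, metadata incl. optional bulk)."""
    meta, df = _read_commented_csv(path)
    depths = df["depth_um"].to_numpy(dtype=float)
    values = df["value"].to_numpy(dtype=float)
    # profiles measured downward (surface last) are re-indexed on read
    if depths[0] > depths[-1]:
        depths, values = depths[::-1].copy(), values[::-1].copy()
    profile = Microprofile(
        species_id=meta.get("species", "unknown"),
        location=meta.get("location", "tip"),
        condition=meta.get("condition", "light"),
        analyte=meta.get("analyte", "oxygen"),
        depths=depths, values=values,
        flow_note=meta.get("flow") or None,
    )
    return profile, meta


def write_profile_csv(path, profile: Microprofile, bulk: float | None = None,
                      extra_meta: dict | None = None) -> None:
    meta = {
        "species": profile.species_id, "location": profile.location,
        "condition": profile.condition, "analyte": profile.analyte,
    }
    if profile.flow_note:
        meta["flow"] = profile.flow_note
    if bulk is not None:
        meta["bulk"] = repr(float(bulk))
    if extra_meta:
        meta.update(extra_meta)
    df = pd.DataFrame({"depth_um": profile.depths, "value": profile.values})
    _write_commented_csv(path, meta, df)


# --------------------------------------------------------------- titrations

def read_titration_csv(path) -> tuple[TitrationCurve, dict]:
    meta, df = _read_commented_csv(path)
    curve = TitrationCurve(
        acid_volumes=df["acid_ml"].to_numpy(dtype=float),
        ph_readings=df["ph"].to_numpy(dtype=float),
        sample_mass=float(meta["sample_mass_kg"]),
        acid_conc=float(meta.get("acid_conc_M", 0.1)),
        temp=float(meta.get("temp_C", 24.0)),
        salinity=float(meta.get("salinity", 35.0)),
    )
    return curve, meta


def write_titration_csv(path, curve: TitrationCurve,
                        extra_meta: dict | None = None) -> None:
    meta = {
        "sample_mass_kg": repr(curve.sample_mass),
        "acid_conc_M": repr(curve.acid_conc),
        "temp_C": repr(curve.temp),
        "salinity": repr(curve.salinity),
    }
    if extra_meta:
        meta.update({k: str(v) for k, v in extra_meta.items()})
    df = pd.DataFrame({"acid_ml": curve.acid_volumes, "ph": curve.ph_readings})
    _write_commented_csv(path, meta, df)


# -------------------------------------------------------------- incubations

_INCUBATION_COLS = [
    "species_id", "treatment", "phase", "replicate", "o2_start", "o2_end",
    "at_start", "at_end", "duration", "chamber_volume", "water_density",
    "surface_area", "control_delta_o2", "control_delta_at",
]


def read_incubations_csv(path) -> list[IncubationRecord]:
    df = pd.read_csv(path, comment="#")
    records = []
    for _, row in df.iterrows():
        kwargs = {c: row[c] for c in _INCUBATION_COLS if c in df.columns}
        for key in ("species_id", "treatment", "phase"):
            kwargs[key] = str(kwargs[key])
        if "replicate" in kwargs:
            kwargs["replicate"] = int(kwargs["replicate"])
        records.append(IncubationRecord(**kwargs))
    return records


def write_incubations_csv(path, records) -> None:
    df = pd.DataFrame([asdict(r) for r in records])
    df = df[[c for c in _INCUBATION_COLS if c in df.columns]]
    df.to_csv(path, index=False)


# ------------------------------------------------------------------ volumes

def write_volume_tiff(path, vol: VoxelVolume) -> None:
    desc = json.dumps({"voxel_size_um": vol.voxel_size, "provenance": vol.provenance})
    tifffile.imwrite(path, np.asarray(vol.grid, dtype=np.float32), description=desc)


def read_volume_tiff(path, voxel_size_um: float | None = None) -> VoxelVolume:
    with tifffile.TiffFile(path) as tf:
        grid = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = {}
    try:
        meta = json.loads(desc)
    except (json.JSONDecodeError, TypeError):
        pass
    vs = voxel_size_um if voxel_size_um is not None else meta.get("voxel_size_um")
    if vs is None:
        raise ValueError(f"{path}: voxel size not in metadata; pass voxel_size_um")
    return VoxelVolume(grid, float(vs), provenance=str(meta.get("provenance", "")))


# ------------------------------------------------------------------- bundle

def write_bundle(bundle, out_dir) -> Path:
    """Write a simulated study to a directory in the pipeline's dialects.

    Layout: ``profiles/*.csv``, ``titrations/*.csv``, ``incubations.csv``,
    ``volumes/*.tif`` and ``truth.json`` (numpy arrays stripped).
    """
    out = Path(out_dir)
    (out / "profiles").mkdir(parents=True, exist_ok=True)
    (out / "titrations").mkdir(exist_ok=True)
    (out / "volumes").mkdir(exist_ok=True)
    for spot in bundle.microprofiles:
        for i, prof in enumerate(spot.profiles):
            name = (f"{spot.species_id}_i{spot.individual}_s{spot.spot}_"
                    f"{spot.location}_{spot.condition}_{spot.analyte}_r{i}.csv")
            bulk = spot.truth.get("bulk", spot.truth.get("bulk_ph"))
            write_profile_csv(out / "profiles" / name, prof, bulk=bulk,
                              extra_meta={"individual": spot.individual,
                                          "spot": spot.spot, "replicate": i})
    for meta, curve in bundle.titrations:
        name = (f"{meta['species']}_{meta['treatment']}_{meta['phase']}_"
                f"rep{meta['replicate']}_{meta['endpoint']}_tube{meta['tube']}.csv")
        write_titration_csv(out / "titrations" / name, curve,
                            extra_meta={k: meta[k] for k in
                                        ("species", "treatment", "phase",
                                         "replicate", "endpoint", "tube")})
    if bundle.incubations:
        write_incubations_csv(out / "incubations.csv", bundle.incubations)
    for meta, vol in bundle.volumes:
        name = f"{meta['species']}_rep{meta['replicate']}.tif"
        write_volume_tiff(out / "volumes" / name, vol)
    truth = _strip_arrays({"seed": bundle.seed, **bundle.truth,
                           "volumes": [m for m, _ in bundle.volumes]})
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, default=float)
    return out


def _strip_arrays(obj):
    if isinstance(obj, dict):
        return {k: _strip_arrays(v) for k, v in obj.items()
                if not isinstance(v, np.ndarray)}
    if isinstance(obj, (list, tuple)):
        return [_strip_arrays(v) for v in obj if not isinstance(v, np.ndarray)]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
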