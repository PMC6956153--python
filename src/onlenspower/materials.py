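"""Hydrogel material characterisation from uniaxial tensile data.

A rectangular hydrogel strip of initial length ``L0`` and cross-section
``A0`` is strained at constant rate while force is recorded.  Engineering
stress ``sigma = F / A0`` and engineering strain ``eps = (L1 - L0) / L0``
are formed, and the elastic modulus is the least-squares gradient of the
stress-strain line.  Soft lens hydrogels are linear elastic over the load
range encountered on-eye, so the whole record is fitted by default; a
strain window can restrict the fit.

Units are fixed at mm / N / MPa (1 N/mm^2 == 1 MPa).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TensileSample",
    "TensileRecord",
    "StressStrainCurve",
    "HydrogelMaterial",
    "ModulusFit",
    "compute_stress",
    "compute_strain",
    "fit_modulus",
    "builtin_materials",
    "get_material",
    "synth_tensile",
    "pooled_modulus",
    "read_tensile_csv",
    "write_tensile_csv",
    "materials_to_frame",
    "write_materials_json",
]

#: nominal strain rate used in the tensile protocol: 10 % per minute
DEFAULT_STRAIN_RATE = 0.10 / 60.0  # 1/s


class InvalidSampleError(ValueError):
    """Raised when strip dimensions are non-physical."""


class FitError(RuntimeError):
    """Raised when the stress-strain data cannot support a slope fit."""


@dataclass(frozen=True)
class TensileSample:
    """Geometry of one rectangular tensile strip (mm)."""

    initial_length: float
    width: float
    thickness: float

    def __post_init__(self) -> None:
        if min(self.initial_length, self.width, self.thickness) <= 0:
            raise InvalidSampleError(
                "strip dimensions must all be positive, got "
                f"L0={self.initial_length}, w={self.width}, t={self.thickness}"
            )

    @property
    def cross_section(self) -> float:
        """Initial cross-section area A0 = width x thickness (mm^2)."""
        return self.width * self.thickness


@dataclass(frozen=True)
class TensileRecord:
    """Force/extension readings at recorded time increments."""

    time: np.ndarray  # s
    force: np.ndarray  # N
    length: np.ndarray  # instantaneous strip length L1, mm

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        f = np.asarray(self.force, dtype=float)
        length = np.asarray(self.length, dtype=float)
        if not (t.shape == f.shape == length.shape):
            raise ValueError("time, force and length must have equal shapes")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "force", f)
        object.__setattr__(self, "length", length)

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class StressStrainCurve:
    """Engineering stress (MPa) against engineering strain."""

    strain: np.ndarray
    stress: np.ndarray

    def __post_init__(self) -> None:
        eps = np.asarray(self.strain, dtype=float)
        sig = np.asarray(self.stress, dtype=float)
        if eps.shape != sig.shape:
            raise ValueError("strain and stress must have equal length")
        if eps.size >= 2 and np.any(np.diff(eps) < 0):
            raise ValueError("strain must be non-decreasing")
        object.__setattr__(self, "strain", eps)
        object.__setattr__(self, "stress", sig)


@dataclass(frozen=True)
class HydrogelMaterial:
    """A lens hydrogel: optical and mechanical constants.

    ``modulus`` is the value used in simulation.  The catalogue carries
    both the manufacturer datasheet modulus and the modulus measured in
    the in-vivo-load-range tensile protocol; the measured value is the
    default because lenses on-eye never approach the failure loads the
    datasheet figures come from.
    """

    short_name: str
    water_content: float  # %
    refractive_index: float  # wet
    modulus: float  # MPa, value used in simulation
    poisson: float = 0.49
    modulus_source: str = "measured"
    modulus_measured: float | None = None  # MPa
    modulus_measured_sd: float | None = None  # MPa, spread across 3 strips
    modulus_manufacturer: float | None = None  # MPa

    def __post_init__(self) -> None:
        if not 0 < self.poisson < 0.5:
            raise ValueError(f"Poisson ratio out of (0, 0.5): {self.poisson}")
        if self.modulus <= 0:
            raise ValueError(f"modulus must be positive: {self.modulus}")
        if not 1 < self.refractive_index < 2:
            raise ValueError(f"implausible refractive index: {self.refractive_index}")

    def with_modulus_source(self, source: str) -> "HydrogelMaterial":
        """Return a copy whose simulation modulus comes from *source*."""
        if source == "measured":
            e = self.modulus_measured
        elif source == "manufacturer":
            e = self.modulus_manufacturer
        else:
            raise ValueError("modulus_source must be 'measured' or 'manufacturer'")
        if e is None:
            raise ValueError(f"{self.short_name} has no {source} modulus")
        return replace(self, modulus=e, modulus_source=source)


@dataclass(frozen=True)
class ModulusFit:
    """Least-squares modulus estimate with its standard error."""

    modulus: float  # MPa
    stderr: float  # MPa
    intercept: float  # MPa
    n_points: int
    r_value: float = field(default=float("nan"))


def compute_stress(record: TensileRecord, sample: TensileSample) -> np.ndarray:
    """Engineering stress sigma_t = F / A0, in MPa."""
    a0 = sample.cross_section
    if a0 <= 0:
        raise InvalidSampleError("cross-section A0 must be positive")
    return np.asarray(record.force, dtype=float) / a0


def compute_strain(record: TensileRecord, sample: TensileSample) -> np.ndarray:
    """Engineering strain eps = (L1 - L0) / L0 (dimensionless)."""
    l0 = sample.initial_length
    if l0 <= 0:
        raise InvalidSampleError("initial length L0 must be positive")
    return (np.asarray(record.length, dtype=float) - l0) / l0


def stress_strain_curve(record: TensileRecord, sample: TensileSample) -> StressStrainCurve:
    """Reduce a force-extension record to a stress-strain curve."""
    return StressStrainCurve(
        strain=compute_strain(record, sample),
        stress=compute_stress(record, sample),
    )


def fit_modulus(
    curve: StressStrainCurve,
    strain_window: tuple[float, float] | None = None,
) -> ModulusFit:
    """Elastic modulus as the gradient of the stress-strain line.

    Parameters
    ----------
    curve
        Stress-strain data; all points are used unless a window is given.
    strain_window
        Optional ``(lo, hi)`` strain bounds restricting the fit.
    """
    eps = curve.strain
    sig = curve.stress
    if strain_window is not None:
        lo, hi = strain_window
        keep = (eps >= lo) & (eps <= hi)
        eps, sig = eps[keep], sig[keep]
    if np.unique(eps).size < 2:
        raise FitError("need at least two distinct strain values to fit a slope")
    res = stats.linregress(eps, sig)
    return ModulusFit(
        modulus=float(res.slope),
        stderr=float(res.stderr),
        intercept=float(res.intercept),
        n_points=int(eps.size),
        r_value=float(res.rvalue),
    )


def pooled_modulus(
    curves: Sequence[StressStrainCurve],
    strain_window: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Per-strip fits averaged into one material modulus.

    Returns ``(mean, sd)`` across strips, matching the usual
    "E +/- sd over three samples" presentation.
    """
    fits = [fit_modulus(c, strain_window) for c in curves]
    values = np.array([f.modulus for f in fits])
    return float(values.mean()), float(values.std(ddof=1)) if len(fits) > 1 else 0.0


# --- built-in catalogue ----------------------------------------------------

_CATALOGUE = (
    HydrogelMaterial(
        short_name="H77p0-Clear",
        water_content=77.0,
        refractive_index=1.3739,
        modulus=0.195,
        modulus_measured=0.195,
        modulus_measured_sd=0.027,
        modulus_manufacturer=0.17,
    ),
    HydrogelMaterial(
        short_name="SiH74p5-Blue",
        water_content=74.5,
        refractive_index=1.3753,
        modulus=0.277,
        modulus_measured=0.277,
        modulus_measured_sd=0.019,
        modulus_manufacturer=0.35,
    ),
    HydrogelMaterial(
        short_name="SiH74p5-Clear",
        water_content=74.5,
        refractive_index=1.3749,
        modulus=0.279,
        modulus_measured=0.279,
        modulus_measured_sd=0.01,
        modulus_manufacturer=0.35,
    ),
    HydrogelMaterial(
        short_name="H64p0-Clear",
        water_content=64.0,
        refractive_index=1.3920,
        modulus=0.457,
        modulus_measured=0.457,
        modulus_measured_sd=0.013,
        modulus_manufacturer=0.37,
    ),
)


def builtin_materials(modulus_source: str = "measured") -> list[HydrogelMaterial]:
    """The four catalogue hydrogels.

    Each entry carries both the manufacturer datasheet modulus and the
    tensile-test modulus; ``modulus_source`` selects which one drives
    simulation (measured by default).
    """
    return [m.with_modulus_source(modulus_source) for m in _CATALOGUE]


def get_material(short_name: str, modulus_source: str = "measured") -> HydrogelMaterial:
    """Look one catalogue material up by its short name."""
    for m in builtin_materials(modulus_source):
        if m.short_name == short_name:
            return m
    names = [m.short_name for m in _CATALOGUE]
    raise KeyError(f"unknown material {short_name!r}; known: {names}")


# --- synthetic record generator --------------------------------------------


def synth_tensile(
    material: HydrogelMaterial,
    sample: TensileSample,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int | None = None,
    strain_rate: float = DEFAULT_STRAIN_RATE,
    max_strain: float = 0.2,
) -> TensileRecord:
    """Generate a linear-elastic force-extension record for a strip.

    Emulates a constant-strain-rate pull (default 10 % per minute) of a
    rectangular strip of *material*: strain grows linearly with time,
    stress follows ``sigma = E * eps`` plus optional additive Gaussian
    noise of ``noise_sd`` MPa, and forces are recovered through the strip
    cross-section.  What it does *not* emulate: machine compliance, slack
    take-up at low strain, viscoelastic relaxation, or failure.

    Deterministic for a fixed ``seed``.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_points < 2:
        raise ValueError("need at least two record points")
    t_end = max_strain / strain_rate
    time = np.linspace(0.0, t_end, n_points)
    eps = strain_rate * time
    sigma = material.modulus * eps
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sigma = sigma + rng.normal(0.0, noise_sd, size=n_points)
    force = sigma * sample.cross_section
    length = sample.initial_length * (1.0 + eps)
    return TensileRecord(time=time, force=force, length=length)


# --- IO ---------------------------------------------------------------------

_CSV_COLUMNS = ["time_s", "force_N", "length_mm"]


def write_tensile_csv(record: TensileRecord, path: str | Path) -> None:
    """Write a record as CSV with columns time_s, force_N, length_mm."""
    pd.DataFrame(
        {"time_s": record.time, "force_N": record.force, "length_mm": record.length}
    ).to_csv(path, index=False)


def read_tensile_csv(path: str | Path) -> TensileRecord:
    """Read a record written by :func:`write_tensile_csv`."""
    df = pd.read_csv(path)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"tensile CSV missing columns {missing}")
    return TensileRecord(
        time=df["time_s"].to_numpy(),
        force=df["force_N"].to_numpy(),
        length=df["length_mm"].to_numpy(),
    )


def materials_to_frame(materials: Sequence[HydrogelMaterial] | None = None) -> pd.DataFrame:
    """Catalogue as a DataFrame (exportable with ``.to_csv``)."""
    mats = list(materials) if materials is not None else builtin_materials()
    return pd.DataFrame(
        {
            "short_name": [m.short_name for m in mats],
            "water_content_pct": [m.water_content for m in mats],
            "refractive_index_wet": [m.refractive_index for m in mats],
            "modulus_MPa": [m.modulus for m in mats],
            "modulus_source": [m.modulus_source for m in mats],
            "modulus_measured_MPa": [m.modulus_measured for m in mats],
            "modulus_measured_sd_MPa": [m.modulus_measured_sd for m in mats],
            "modulus_manufacturer_MPa": [m.modulus_manufacturer for m in mats],
            "poisson": [m.poisson for m in mats],
        }
    )


def write_materials_json(path: str | Path, materials: Sequence[HydrogelMaterial] | None = None) -> None:
    """Dump the catalogue as JSON."""
    frame = materials_to_frame(materials)
    Path(path).write_text(json.dumps(frame.to_dict(orient="records"), indent=2))
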