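"""Factorial sweep of the design -> conform -> ray-trace pipeline.

Runs the full grid (materials x lens types x powers x diameters),
collects the effective power change (EPC) per cell, and reproduces the
statistical treatment used for such data: a split of the power axis into
a lower (< 5 D) and upper (>= 5 D) region, pooled-variance two-sample
t-tests between materials within each region, and per-material Pearson
correlations of EPC against lens power.  Clinical acceptability is the
quarter-diopter trial-lens step: ``|EPC| <= 0.25 D``.

Everything here is deterministic for a fixed configuration: the
pipeline itself has no random element (only the synthetic tensile
generator elsewhere in the package is seeded).
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .conformance import CornealModel, LoadCase, conform
from .design import LensDesignSpec, build_lens
from .materials import HydrogelMaterial, builtin_materials, get_material
from .raytrace import DEFAULT_FIT_APERTURE, trace_lens

__all__ = [
    "ACCEPTABLE_EPC",
    "REGION_THRESHOLD",
    "SweepConfig",
    "run_cell",
    "run_sweep",
    "region_split",
    "pairwise_ttests",
    "correlations",
    "acceptability",
    "acceptable_intervals",
    "report",
]

logger = logging.getLogger("onlenspower.sweep")

ACCEPTABLE_EPC = 0.25  # D, |EPC| bound from quarter-diopter trial steps
REGION_THRESHOLD = 5.0  # D; >= 5 D is the "high power" region


@dataclass(frozen=True)
class SweepConfig:
    """Grid and settings of one sweep run."""

    materials: tuple[str, ...] = (
        "H77p0-Clear",
        "SiH74p5-Blue",
        "SiH74p5-Clear",
        "H64p0-Clear",
    )
    lens_types: tuple[str, ...] = ("spherical", "cylindrical")
    powers: tuple[float, ...] = tuple(float(p) for p in range(-10, 21))
    diameters: tuple[float, ...] = (13.5, 14.0, 14.5)
    cornea_k: float = 43.7  # D
    tear_pressure: float = 0.0436  # Pa
    eyelid_pressure_mmhg: float = 8.0
    friction_mu: float = 0.01
    modulus_source: str = "measured"
    pupil_semi_aperture: float = 1.5  # mm
    n_rings: int = 6
    fit_aperture: float = DEFAULT_FIT_APERTURE
    baseline: str = "traced"  # "traced" undeformed power, or "labelled"
    power_method: str = "slope"  # or "crossing"
    ballast: bool = True
    n_meridians: int = 360
    n_radial: int = 101
    seed: int = 0  # carried for provenance; the pipeline is seed-free
    outdir: str = "sweep_out"

    def load_case(self) -> LoadCase:
        from .conformance import MMHG_TO_PA

        return LoadCase(
            tear_pressure=self.tear_pressure,
            eyelid_pressure=self.eyelid_pressure_mmhg * MMHG_TO_PA,
            friction_mu=self.friction_mu,
        )

    def cornea(self) -> CornealModel:
        return CornealModel(keratometry=self.cornea_k)

    def material_objects(self) -> list[HydrogelMaterial]:
        return [get_material(m, self.modulus_source) for m in self.materials]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SweepConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - fields
        if unknown:
            raise ValueError(f"unknown sweep config keys: {sorted(unknown)}")
        for key in ("materials", "lens_types", "powers", "diameters"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        for key in ("materials", "lens_types", "powers", "diameters"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def _lens_spec(
    config: SweepConfig, material: HydrogelMaterial, lens_type: str, power: float, diameter: float
) -> LensDesignSpec:
    if lens_type == "spherical":
        sph, cyl = power, 0.0
    elif lens_type == "cylindrical":
        # the cylinder carries the swept power; no spherical component
        sph, cyl = 0.0, power
    else:
        raise ValueError(f"unknown lens type {lens_type!r}")
    return LensDesignSpec(
        diameter=diameter,
        sph=sph,
        cyl=cyl,
        cyl_axis=90.0,
        refractive_index=material.refractive_index,
        ballast=config.ballast,
        n_meridians=config.n_meridians,
        n_radial=config.n_radial,
    )


def run_cell(
    config: SweepConfig,
    material: HydrogelMaterial,
    lens_type: str,
    power: float,
    diameter: float,
) -> dict:
    """Design, conform and trace one sweep cell; returns a record dict."""
    spec = _lens_spec(config, material, lens_type, power, diameter)
    lens = build_lens(spec)
    conformed = conform(lens, config.cornea(), material, config.load_case())
    trace_kwargs = dict(
        pupil_semi_aperture=config.pupil_semi_aperture,
        n_rings=config.n_rings,
        fit_aperture=config.fit_aperture,
    )
    base_bundle = trace_lens(lens, material.refractive_index, **trace_kwargs)
    conf_bundle = trace_lens(conformed, material.refractive_index, **trace_kwargs)
    traced = conf_bundle.power(config.power_method)
    if config.baseline == "traced":
        baseline = base_bundle.power(config.power_method)
    elif config.baseline == "labelled":
        baseline = power if lens_type == "spherical" else power / 2.0
    else:
        raise ValueError("baseline must be 'traced' or 'labelled'")
    epc = traced - baseline
    return {
        "material": material.short_name,
        "lens_type": lens_type,
        "diameter": diameter,
        "power": power,
        "epc": epc,
        "traced_power": traced,
        "baseline_power": baseline,
        "within_acceptable": bool(abs(epc) <= ACCEPTABLE_EPC),
        "conformance_weight": conformed.weight,
        "stiffness_number": conformed.stiffness,
        "final_tc_mm": lens.final_tc,
        "rays": conf_bundle.entry_xy.shape[0],
        "error": "",
    }


def run_sweep(config: SweepConfig, progress: bool = False) -> pd.DataFrame:
    """Run the full factorial sweep; per-cell failures are recorded, not fatal."""
    records = []
    materials = config.material_objects()
    cells = list(
        itertools.product(materials, config.lens_types, config.diameters, config.powers)
    )
    n_failed = 0
    for idx, (material, lens_type, diameter, power) in enumerate(cells):
        try:
            rec = run_cell(config, material, lens_type, power, diameter)
        except Exception as exc:  # noqa: BLE001 - per-cell isolation is the point
            n_failed += 1
            logger.warning(
                "cell failed: %s %s D=%.1f P=%+.1f: %s",
                material.short_name, lens_type, diameter, power, exc,
            )
            rec = {
                "material": material.short_name,
                "lens_type": lens_type,
                "diameter": diameter,
                "power": power,
                "epc": np.nan,
                "traced_power": np.nan,
                "baseline_power": np.nan,
                "within_acceptable": False,
                "conformance_weight": np.nan,
                "stiffness_number": np.nan,
                "final_tc_mm": np.nan,
                "rays": 0,
                "error": f"{type(exc).__name__}: {exc}",
            }
        records.append(rec)
        if progress and (idx + 1) % 25 == 0:
            logger.info("sweep progress: %d/%d cells", idx + 1, len(cells))
    if n_failed == len(cells):
        raise RuntimeError("every sweep cell failed; see the log for details")
    return pd.DataFrame.from_records(records)


def region_split(
    table: pd.DataFrame, threshold: float = REGION_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition at lens power < threshold vs >= threshold.

    The boundary power belongs to the upper ("5-20 D") region.
    """
    lower = table[table["power"] < threshold].reset_index(drop=True)
    upper = table[table["power"] >= threshold].reset_index(drop=True)
    return lower, upper


def pairwise_ttests(
    region_table: pd.DataFrame, equal_var: bool = True
) -> pd.DataFrame:
    """Pooled-variance two-sample t-tests of EPC between material pairs.

    Performed separately per (lens_type, diameter); EPC values pool
    across the powers of the region.  ``equal_var=False`` switches to
    Welch's test.  No multiple-testing correction is applied.
    """
    rows = []
    grouped = region_table.dropna(subset=["epc"]).groupby(["lens_type", "diameter"])
    for (lens_type, diameter), sub in grouped:
        mats = sorted(sub["material"].unique())
        for a, b in itertools.combinations(mats, 2):
            xa = sub.loc[sub["material"] == a, "epc"].to_numpy()
            xb = sub.loc[sub["material"] == b, "epc"].to_numpy()
            if len(xa) < 2 or len(xb) < 2:
                continue
            scale = 1.0 + abs(xa.mean()) + abs(xb.mean())
            degenerate = xa.std(ddof=1) < 1e-12 * scale and xb.std(ddof=1) < 1e-12 * scale
            if degenerate:
                # limiting behaviour: identical constants are maximally
                # similar, distinct constants maximally different
                p = 1.0 if np.isclose(xa.mean(), xb.mean()) else 0.0
                t = 0.0 if p == 1.0 else np.inf
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=equal_var)
            rows.append(
                {
                    "lens_type": lens_type,
                    "diameter": diameter,
                    "material_a": a,
                    "material_b": b,
                    "t": float(t),
                    "p_value": float(p),
                    "significant": bool(p <= 0.05),
                    "degenerate": degenerate,
                }
            )
    return pd.DataFrame.from_records(rows)


def correlations(region_table: pd.DataFrame) -> pd.DataFrame:
    """Pearson r of EPC against lens power per (material, lens_type, diameter).

    Zero-variance EPC yields a missing value (undefined correlation),
    not zero.
    """
    rows = []
    grouped = region_table.dropna(subset=["epc"]).groupby(
        ["material", "lens_type", "diameter"]
    )
    for (material, lens_type, diameter), sub in grouped:
        if len(sub) < 3:
            continue
        x = sub["power"].to_numpy()
        y = sub["epc"].to_numpy()
        if np.std(y) == 0 or np.std(x) == 0:
            r = np.nan
            logger.info(
                "constant EPC for %s %s D=%.1f: correlation undefined",
                material, lens_type, diameter,
            )
        else:
            r = float(stats.pearsonr(x, y).statistic)
        rows.append(
            {
                "material": material,
                "lens_type": lens_type,
                "diameter": diameter,
                "n": len(sub),
                "pearson_r": r,
            }
        )
    return pd.DataFrame.from_records(rows)


def acceptability(table: pd.DataFrame) -> pd.DataFrame:
    """Annotate |EPC| <= 0.25 D acceptability (boundary inclusive)."""
    out = table.copy()
    out["within_acceptable"] = out["epc"].abs() <= ACCEPTABLE_EPC
    out.loc[out["epc"].isna(), "within_acceptable"] = False
    return out


def acceptable_intervals(table: pd.DataFrame) -> pd.DataFrame:
    """Largest contiguous acceptable power interval per material cell."""
    annotated = acceptability(table)
    rows = []
    for (material, lens_type, diameter), sub in annotated.groupby(
        ["material", "lens_type", "diameter"]
    ):
        sub = sub.sort_values("power")
        best: tuple[float, float] | None = None
        run_start = None
        prev_power = None
        for _, rec in sub.iterrows():
            if rec["within_acceptable"]:
                if run_start is None:
                    run_start = rec["power"]
                prev_power = rec["power"]
            else:
                if run_start is not None and (
                    best is None or prev_power - run_start > best[1] - best[0]
                ):
                    best = (run_start, prev_power)
                run_start = None
        if run_start is not None and (
            best is None or prev_power - run_start > best[1] - best[0]
        ):
            best = (run_start, prev_power)
        rows.append(
            {
                "material": material,
                "lens_type": lens_type,
                "diameter": diameter,
                "acceptable_from": best[0] if best else np.nan,
                "acceptable_to": best[1] if best else np.nan,
            }
        )
    return pd.DataFrame.from_records(rows)


def report(table: pd.DataFrame, config: SweepConfig, outdir: str | Path | None = None) -> dict[str, Path]:
    """Write EPC tables, statistics and per-diameter plots.

    Emits the long-format EPC CSV, region-wise t-test and correlation
    CSVs, the acceptable-interval summary, EPC-vs-power plots per
    (lens type, diameter), and the run configuration.  Re-running with
    the same table and config reproduces the CSVs byte for byte.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(outdir if outdir is not None else config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    annotated = acceptability(table)
    paths["epc"] = out / "epc_long.csv"
    annotated.to_csv(paths["epc"], index=False, float_format="%.6g")

    lower, upper = region_split(annotated)
    tt = pd.concat(
        [
            pairwise_ttests(lower).assign(region="power<5D"),
            pairwise_ttests(upper).assign(region="power>=5D"),
        ],
        ignore_index=True,
    )
    paths["ttests"] = out / "ttests.csv"
    tt.to_csv(paths["ttests"], index=False, float_format="%.6g")

    corr = pd.concat(
        [
            correlations(lower).assign(region="power<5D"),
            correlations(upper).assign(region="power>=5D"),
        ],
        ignore_index=True,
    )
    paths["correlations"] = out / "correlations.csv"
    corr.to_csv(paths["correlations"], index=False, float_format="%.6g")

    paths["intervals"] = out / "acceptable_intervals.csv"
    acceptable_intervals(annotated).to_csv(paths["intervals"], index=False, float_format="%.6g")

    for lens_type in annotated["lens_type"].unique():
        for diameter in sorted(annotated["diameter"].unique()):
            sub = annotated[
                (annotated["lens_type"] == lens_type)
                & (annotated["diameter"] == diameter)
            ]
            if sub.empty:
                continue
            fig, ax = plt.subplots(figsize=(7, 4.5))
            for material, mat_sub in sub.groupby("material"):
                mat_sub = mat_sub.sort_values("power")
                ax.plot(mat_sub["power"], mat_sub["epc"], marker="o", ms=3, label=material)
            ax.axhspan(-ACCEPTABLE_EPC, ACCEPTABLE_EPC, color="0.9", zorder=0)
            ax.axvline(REGION_THRESHOLD, color="0.6", ls="--", lw=0.8)
            ax.set_xlabel(f"{lens_type} lens power (D)")
            ax.set_ylabel("EPC (D)")
            ax.set_title(f"EPC vs power, D = {diameter} mm ({lens_type})")
            ax.legend(fontsize=8)
            fig.tight_layout()
            p = out / f"epc_{lens_type}_D{str(diameter).replace('.', 'p')}.png"
            fig.savefig(p, dpi=120)
            plt.close(fig)
            paths[f"plot_{lens_type}_{diameter}"] = p

    paths["config"] = out / "config.yaml"
    config.to_yaml(paths["config"])
    # the report footer records that p-values are uncorrected
    paths["notes"] = out / "NOTES.txt"
    paths["notes"].write_text(
        "t-tests are pooled-variance two-sample tests; no multiple-testing "
        "correction is applied.\n"
    )
    return paths
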