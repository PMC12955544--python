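"""End-to-end orchestration: validated run configs, the simulate ->
quantify -> profile -> report pipeline, and side-by-side comparison of
runs.

A run is fully described by a YAML config (phantom fill, acquisition
protocol, reconstruction sweep, analysis options, seed); the report it
produces carries tidy metric tables, figures regenerable from those
tables, and a provenance record (config hash, seed, package version)
that makes a run reproducible bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .core import VoxelGrid, Volume, read_nifti, write_nifti
from .isotopes import get_isotope
from .phantom import (BodyContour, PhantomFill, PhantomSpec, background_mask,
                      default_nema_spec, sphere_masks)
from .profiles import max_relative_intensity_difference, resolution_curve, sphere_profiles
from .quantify import (contrast, counts_to_concentration, iteration_sweep,
                       qf_for, recovery_coefficients)
from .simulate import ScanProtocol, pet_protocol

log = logging.getLogger("nemaiq")


# -- config schema ---------------------------------------------------------

class PhantomConfig(BaseModel):
    isotope: str = "99mTc"
    sphere_concentration_kbq_ml: float = Field(236.0, gt=0)
    background_concentration_kbq_ml: float = Field(23.7, ge=0)
    contour_mode: Literal["nema", "elliptical"] = "nema"

    def build(self) -> PhantomSpec:
        fill = PhantomFill(self.isotope, self.sphere_concentration_kbq_ml,
                           self.background_concentration_kbq_ml)
        return default_nema_spec(fill, BodyContour(mode=self.contour_mode))


class ProtocolConfig(BaseModel):
    """Acquisition defaults follow the dual-head 64-view, 27-s, 180-deg
    SPECT protocol; modality PET switches to the 360-deg emulation."""

    modality: Literal["SPECT", "PET"] = "SPECT"
    n_heads: int = Field(2, ge=1)
    views_per_head: int = Field(64, ge=1)
    arc_per_head_deg: float = 180.0
    time_per_view_s: float = Field(27.0, gt=0)
    sensitivity_cps_per_bq: float = Field(1e-4, gt=0)
    detector_fwhm_mm: float | None = Field(None, ge=0,
                                           description="default: isotope catalog value")
    attenuation_mu_per_mm: float = Field(0.0, ge=0)
    scatter_fraction: float = Field(0.0, ge=0)

    def build(self, isotope: str) -> ScanProtocol:
        fwhm = self.detector_fwhm_mm
        if fwhm is None:
            fwhm = get_isotope(isotope).default_psf_fwhm_mm
        if self.modality == "PET":
            return pet_protocol(detector_fwhm_mm=fwhm,
                                sensitivity_cps_per_bq=self.sensitivity_cps_per_bq,
                                attenuation_mu_per_mm=self.attenuation_mu_per_mm,
                                scatter_fraction=self.scatter_fraction)
        return ScanProtocol(modality="SPECT", n_heads=self.n_heads,
                            views_per_head=self.views_per_head,
                            arc_per_head_deg=self.arc_per_head_deg,
                            time_per_view_s=self.time_per_view_s,
                            sensitivity_cps_per_bq=self.sensitivity_cps_per_bq,
                            detector_fwhm_mm=fwhm,
                            attenuation_mu_per_mm=self.attenuation_mu_per_mm,
                            scatter_fraction=self.scatter_fraction)


class ReconConfig(BaseModel):
    iterations: tuple[int, ...] = (1, 2, 4, 8, 16, 32)
    subsets: int = Field(4, ge=1)
    post_filter_fwhm_mm: float = Field(8.40, ge=0)
    resolution_modeling: bool = False

    @model_validator(mode="after")
    def _nonempty(self):
        if not self.iterations:
            raise ValueError("iterations list must be non-empty")
        return self


class GridConfig(BaseModel):
    shape: tuple[int, int, int] = (48, 96, 96)
    spacing_mm: tuple[float, float, float] = (4.8, 4.8, 4.8)

    def build(self) -> VoxelGrid:
        return VoxelGrid(self.shape, self.spacing_mm)


class AnalysisConfig(BaseModel):
    sphere_margin_mm: float = Field(0.0, ge=0)
    edge_margin_mm: float = Field(0.0, ge=0)
    profile_axis: tuple[float, float, float] = (0.0, 0.0, 1.0)
    report_iterations: int | None = Field(
        None, description="iteration count used for profiles/contrast; "
                          "default: the largest in the sweep")


class RunConfig(BaseModel):
    """Validated end-to-end run description (YAML-serializable)."""

    phantom: PhantomConfig = PhantomConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    recon: ReconConfig = ReconConfig()
    grid: GridConfig = GridConfig()
    analysis: AnalysisConfig = AnalysisConfig()
    seed: int | None = 0
    noise: bool = True
    input_image: str | None = Field(
        None, description="path to an externally reconstructed NIfTI counts "
                          "volume; skips the simulation stage")
    label: str | None = None

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(text) or {})

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(self.model_dump_json()), sort_keys=False)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(
            self.model_dump_json(exclude_none=False).encode()).hexdigest()[:16]


def load_preset(name: str) -> RunConfig:
    """Load one of the shipped per-isotope preset configs."""
    from importlib import resources
    path = resources.files("nemaiq.data.presets").joinpath(f"{name}.yaml")
    try:
        return RunConfig.from_yaml(path.read_text())
    except FileNotFoundError:
        avail = [p.name[:-5] for p in resources.files("nemaiq.data.presets").iterdir()
                 if p.name.endswith(".yaml")]
        raise KeyError(f"no preset {name!r}; available: {', '.join(sorted(avail))}")


# -- report ----------------------------------------------------------------

@dataclass
class RunReport:
    config: RunConfig
    metrics: pd.DataFrame                 # per (iterations, sphere) RC/contrast/CV
    profiles: pd.DataFrame                # long-format line profiles
    resolution: pd.DataFrame | None       # apparent size vs diameter (cold runs)
    intensity_differences: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def label(self) -> str:
        return self.config.label or self.config.phantom.isotope

    def save(self, out_dir: str | Path, figures: bool = True) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.metrics.to_csv(out / "metrics.csv", index=False)
        self.profiles.to_csv(out / "profiles.csv", index=False)
        if self.resolution is not None:
            self.resolution.to_csv(out / "resolution.csv", index=False)
        self.intensity_differences.to_csv(out / "intensity_differences.csv",
                                          index=False)
        (out / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        (out / "config.yaml").write_text(self.config.to_yaml())
        if figures:
            save_figures(self, out)
        return out


def save_figures(report: RunReport, out_dir: Path) -> list[Path]:
    """Standard figures, each drawn purely from the stored tables."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    paths = []
    m = report.metrics

    fig, ax = plt.subplots(figsize=(5, 4))
    for it, sub in m.groupby("iterations"):
        s = sub.sort_values("diameter_mm")
        ax.plot(s["diameter_mm"], s["rc"], "o-", label=f"{it}i")
    ax.set_xlabel("sphere diameter (mm)")
    ax.set_ylabel("recovery coefficient")
    ax.axhline(1.0, color="0.7", ls="--", lw=1)
    ax.legend(title="iterations", fontsize=8)
    ax.set_title(f"{report.label}: RC vs diameter")
    paths.append(out_dir / "rc_vs_diameter.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if m["contrast"].notna().any():
        fig, ax = plt.subplots(figsize=(5, 4))
        last = m[m["iterations"] == m["iterations"].max()].sort_values("diameter_mm")
        ax.plot(last["diameter_mm"], last["contrast"], "s-")
        ax.set_xlabel("sphere diameter (mm)")
        ax.set_ylabel("contrast C")
        ax.set_title(f"{report.label}: contrast vs diameter")
        paths.append(out_dir / "contrast_vs_diameter.png")
        fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
        plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for d, sub in report.profiles.groupby("diameter_mm"):
        ax.plot(sub["position_mm"], sub["normalized_value"], label=f"{d:g} mm")
    ax.set_xlabel("position (mm)")
    ax.set_ylabel("relative intensity")
    ax.legend(fontsize=7)
    ax.set_title(f"{report.label}: line profiles")
    paths.append(out_dir / "line_profiles.png")
    fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
    plt.close(fig)

    if report.resolution is not None:
        fig, ax = plt.subplots(figsize=(5, 4))
        r = report.resolution.sort_values("diameter_mm")
        ax.plot(r["diameter_mm"], r["apparent_size_mm"], "o-", label="measured")
        lim = [0, r["diameter_mm"].max() * 1.2]
        ax.plot(lim, lim, "--", color="0.6", label="ideal")
        ax.set_xlabel("true diameter (mm)")
        ax.set_ylabel("apparent size (mm)")
        ax.legend()
        ax.set_title(f"{report.label}: spatial resolution")
        paths.append(out_dir / "resolution_curve.png")
        fig.savefig(paths[-1], dpi=120, bbox_inches="tight")
        plt.close(fig)
    return paths


def run(config: RunConfig, out_dir: str | Path | None = None,
        save_volumes: bool = False) -> RunReport:
    """Execute a config end to end: simulate (or load an external
    reconstruction), quantify the iteration sweep, profile the spheres,
    and assemble the report.  Deterministic for a fixed config + seed.
    """
    spec = config.phantom.build()
    protocol = config.protocol.build(spec.fill.isotope)
    grid = config.grid.build()
    seed = config.seed if config.noise else None
    iters = tuple(sorted(set(config.recon.iterations)))
    log.info("run %s: isotope=%s modality=%s grid=%s", config.config_hash,
             spec.fill.isotope, protocol.modality, grid.shape)

    external: Volume | None = None
    if config.input_image is not None:
        external = read_nifti(config.input_image)
        if external.unit not in ("counts", "kBq/mL"):
            raise ValueError("external image must declare counts or kBq/mL")
        grid = external.grid

    masks = sphere_masks(spec, grid)
    bg = background_mask(spec, grid, config.analysis.sphere_margin_mm,
                         config.analysis.edge_margin_mm)
    qf = qf_for(protocol, grid)

    if external is None:
        log.info("simulating: %d projections, sweep %s", protocol.n_projections, iters)
        report_iters = config.analysis.report_iterations or max(iters)
        sweep_iters = tuple(sorted(set(iters) | {report_iters}))
        metrics, study = iteration_sweep(
            spec, protocol, grid, seed=seed, iterations_list=sweep_iters,
            subsets=config.recon.subsets,
            post_filter_fwhm_mm=config.recon.post_filter_fwhm_mm,
            resolution_modeling=config.recon.resolution_modeling,
            return_study=True)
        metrics = metrics[metrics["iterations"].isin(iters)].reset_index(drop=True)
        image = counts_to_concentration(study.checkpoint_volumes[report_iters], qf)
    else:
        image = external if external.unit == "kBq/mL" else \
            counts_to_concentration(external, qf)
        rcs = recovery_coefficients(image, masks, spec)
        cons = {c.diameter_mm: c for c in contrast(image, masks, bg, spec)} \
            if not spec.fill.is_cold else {}
        rows = [{"isotope": spec.fill.isotope, "modality": protocol.modality,
                 "iterations": 0, "subsets": config.recon.subsets,
                 "post_filter_fwhm_mm": config.recon.post_filter_fwhm_mm,
                 "resolution_modeling": config.recon.resolution_modeling,
                 "diameter_mm": r.diameter_mm, "measured_kbq_ml": r.measured_kbq_ml,
                 "true_kbq_ml": r.true_kbq_ml, "rc": r.rc,
                 "contrast": cons[r.diameter_mm].contrast if cons else np.nan,
                 "background_cv": np.nan}
                for r in rcs]
        metrics = pd.DataFrame(rows)

    profs = sphere_profiles(image, spec, axis=config.analysis.profile_axis)
    true_conc = spec.fill.sphere_concentration
    prof_rows = []
    for d, p in profs.items():
        for pos, val in zip(p.positions_mm, p.values):
            prof_rows.append({"diameter_mm": d, "position_mm": pos, "value": val,
                              "normalized_value": val / true_conc})
    profiles_df = pd.DataFrame(prof_rows)
    intensity = max_relative_intensity_difference(profs, reference=true_conc)

    resolution = None
    if spec.fill.is_cold:
        curve = resolution_curve(image, spec, axis=config.analysis.profile_axis)
        resolution = curve.to_frame()

    provenance = {"config_hash": config.config_hash, "seed": config.seed,
                  "noise": config.noise, "package_version": __version__,
                  "qf_bq_per_ml_per_count": qf.value,
                  "external_input": config.input_image}
    report = RunReport(config, metrics, profiles_df, resolution, intensity,
                       provenance)
    if out_dir is not None:
        report.save(out_dir)
        if save_volumes and external is None:
            write_nifti(study.truth, Path(out_dir) / "truth.nii.gz")
            write_nifti(study.reconstruction, Path(out_dir) / "reconstruction.nii.gz")
    return report


def compare_runs(reports: list[RunReport]) -> pd.DataFrame:
    """Long-format table for side-by-side comparison of runs, keyed by
    (label, isotope, modality, iterations, diameter)."""
    if len(reports) < 2:
        raise ValueError("need at least two reports to compare")
    sphere_sets = [set(r.metrics["diameter_mm"].unique()) for r in reports]
    common = set.intersection(*sphere_sets)
    if not common:
        raise ValueError("reports have disjoint sphere sets")
    frames = []
    for r in reports:
        m = r.metrics[r.metrics["diameter_mm"].isin(common)].copy()
        m.insert(0, "label", r.label)
        frames.append(m)
    return pd.concat(frames, ignore_index=True)
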