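"""End-to-end orchestration: phantom cohorts, per-patient analysis, summaries.

A run is driven by a :class:`RunConfig`, proceeds patient by patient with
continue-on-error isolation (the emulated cohort itself has heterogeneous
modality availability), and records a manifest with the config hash,
package version, per-output checksums and all warnings, so identical
configs and inputs reproduce identical outputs.

The numbered scripts under ``analysis/`` are thin drivers over the
functions here; tests and the acceptance script call them directly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .correlation import (CorrelationResult, RegionSpec, cohort_summary,
                          partition_regions, patient_correlation_matrix)
from .dynamic_maps import (IntegrationWindow, mean_activity_map,
                           signal_enhancement_series)
from .grids_io import (DynamicSeries, ParametricMap, ROIMask, read_volume,
                       write_map, write_series)
from .kinetics import AIFModel, ToftsFitConfig, fit_aif, fit_tofts_map, \
    fit_tofts_regional
from .normalization import InjectionRecord, to_suv, to_tbr
from .phantom import PhantomConfig, PhantomDataset, make_phantom

__all__ = [
    "AnalysisSettings",
    "PatientData",
    "RunConfig",
    "RunManifest",
    "patient_from_phantom",
    "save_phantom",
    "load_phantom",
    "analyze_patient",
    "analyze_cohort",
    "run_phantom_cohort",
    "run_analysis",
    "write_median_matrix",
]

#: modality labels as they appear in correlation tables
MAP_LABELS = ("FDG", "FMISO", "A_FMISO", "dS_DCE", "ADC")


@dataclass(frozen=True)
class AnalysisSettings:
    """Analysis-stage knobs shared across patients."""

    washin_window: IntegrationWindow = IntegrationWindow(0.0, 240.0)
    dce_bolus_start: float = 29.0  # s; the 0-4 min p.i. window starts here
    dce_baseline_frames: int = 10
    region_spec: RegionSpec = field(default_factory=RegionSpec)
    fit_dce: bool = False  # voxel/regional Tofts fitting (slow) on top of dS_DCE
    tofts: ToftsFitConfig = field(default_factory=ToftsFitConfig)

    @property
    def dce_window(self) -> IntegrationWindow:
        return IntegrationWindow(self.dce_bolus_start, self.dce_bolus_start + 240.0)


@dataclass
class PatientData:
    """One patient's co-registered inputs on the analysis (PET) grid."""

    patient_id: str
    fdg: ParametricMap | None
    fmiso: ParametricMap | None
    adc: ParametricMap | None
    washin_series: DynamicSeries | None
    dce_series: DynamicSeries | None
    masks: dict[str, ROIMask]
    injection: InjectionRecord
    available: tuple[str, ...] = MAP_LABELS


def patient_from_phantom(ds: PhantomDataset, patient_id: str,
                         available: tuple[str, ...] = MAP_LABELS) -> PatientData:
    """View a phantom dataset as an analysis-ready patient."""
    return PatientData(
        patient_id=patient_id,
        fdg=ds.maps["FDG"] if "FDG" in available else None,
        fmiso=ds.maps["FMISO"] if "FMISO" in available else None,
        adc=ds.maps["ADC"] if "ADC" in available else None,
        washin_series=ds.fmiso_washin_series if "A_FMISO" in available else None,
        dce_series=ds.dce_series if "dS_DCE" in available else None,
        masks=ds.masks,
        injection=InjectionRecord(ds.config.injected_activity_mbq,
                                  ds.config.body_weight_kg),
        available=available,
    )


# ---------------------------------------------------------------------------
# Phantom persistence (directory of NIfTI volumes + one config file)
# ---------------------------------------------------------------------------

def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def save_phantom(ds: PhantomDataset, out_dir) -> Path:
    """Write a phantom as NIfTI volumes plus a YAML config capturing the seed."""
    out_dir = Path(out_dir)
    for name, pmap in ds.maps.items():
        write_map(pmap, out_dir / "maps" / f"{name}.nii")
    for name, pmap in ds.truth.items():
        write_map(pmap, out_dir / "truth" / f"{name}.nii")
    for name, mask in ds.masks.items():
        write_map(ParametricMap(mask.grid, mask.membership.astype(float),
                                "bool", name), out_dir / "masks" / f"{name}.nii")
    write_series(ds.dce_series, out_dir / "series" / "dce.nii")
    write_series(ds.fmiso_washin_series, out_dir / "series" / "fmiso_washin.nii")
    cfg = _jsonable(asdict(ds.config))
    cfg["warnings"] = list(ds.warnings)
    (out_dir / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    return out_dir


def load_phantom(patient_dir, patient_id: str | None = None,
                 available: tuple[str, ...] = MAP_LABELS) -> PatientData:
    """Load a saved phantom directory back into an analysis-ready patient."""
    patient_dir = Path(patient_dir)
    cfg = yaml.safe_load((patient_dir / "config.yaml").read_text())

    def mask(name):
        m = read_volume(patient_dir / "masks" / f"{name}.nii")
        return ROIMask(m.grid, m.values > 0.5, name)

    return PatientData(
        patient_id=patient_id or patient_dir.name,
        fdg=read_volume(patient_dir / "maps" / "FDG.nii"),
        fmiso=read_volume(patient_dir / "maps" / "FMISO.nii"),
        adc=read_volume(patient_dir / "maps" / "ADC.nii"),
        washin_series=read_volume(patient_dir / "series" / "fmiso_washin.nii"),
        dce_series=read_volume(patient_dir / "series" / "dce.nii"),
        masks={"GTV": mask("GTV"), "muscle": mask("muscle"),
               "carotid": mask("carotid")},
        injection=InjectionRecord(cfg["injected_activity_mbq"],
                                  cfg["body_weight_kg"]),
        available=available,
    )


# ---------------------------------------------------------------------------
# Per-patient analysis
# ---------------------------------------------------------------------------

def _carotid_curve(enh: DynamicSeries, carotid: ROIMask) -> np.ndarray:
    return enh.frames[:, carotid.membership].mean(axis=1)


def analyze_patient(patient: PatientData,
                    settings: AnalysisSettings = AnalysisSettings()):
    """Derive all maps for one patient and correlate at both levels.

    Returns ``(voxel_result, regional_result, derived_maps, warnings)``.
    Derived maps: SUV-normalized FDG, TBR-normalized FMISO, wash-in mean
    activity (A_FMISO), mean DCE enhancement (dS_DCE), ADC, and -- when
    ``settings.fit_dce`` -- extended Tofts parameter maps with matching
    regional fits.
    """
    gtv = patient.masks["GTV"]
    warnings_out: list[str] = []
    maps: dict[str, ParametricMap] = {}

    if patient.fdg is not None:
        maps["FDG"] = to_suv(patient.fdg, patient.injection)
    if patient.fmiso is not None:
        maps["FMISO"] = to_tbr(patient.fmiso, patient.masks["muscle"])
    if patient.adc is not None:
        maps["ADC"] = patient.adc.with_values(patient.adc.values, name="ADC")
    if patient.washin_series is not None:
        abar = mean_activity_map(patient.washin_series, settings.washin_window)
        maps["A_FMISO"] = abar.with_values(abar.values, name="A_FMISO")

    enh = None
    if patient.dce_series is not None:
        enh = signal_enhancement_series(patient.dce_series,
                                        settings.dce_baseline_frames)
        ds = mean_activity_map(enh, settings.dce_window)
        maps["dS_DCE"] = ds.with_values(ds.values, name="dS_DCE")

    regional_values = None
    if settings.fit_dce and enh is not None:
        curve = _carotid_curve(enh, patient.masks["carotid"])
        aif = fit_aif(curve, enh.frame_starts)
        fit_cfg = ToftsFitConfig(
            baseline_frames=settings.dce_baseline_frames,
            scale=settings.tofts.scale, refine=settings.tofts.refine,
            init=settings.tofts.init,
            multistart_rss_factor=settings.tofts.multistart_rss_factor,
            max_nfev=settings.tofts.max_nfev)
        kt, ve, vp, diag = fit_tofts_map(patient.dce_series, gtv, aif, fit_cfg)
        maps["Ktrans"], maps["ve"], maps["vp"] = kt, ve, vp
        if diag["nonconverged_fraction"] > 0.5:
            warnings_out.append(
                f"{diag['nonconverged_fraction']:.0%} of Tofts fits non-converged")
        regions = partition_regions(gtv, settings.region_spec)
        if regions:
            reg_params = fit_tofts_regional(patient.dce_series, regions, aif,
                                            fit_cfg)
            regional_values = {
                "Ktrans": np.array([p.ktrans if p else np.nan for p in reg_params]),
                "ve": np.array([p.ve if p else np.nan for p in reg_params]),
                "vp": np.array([p.vp if p else np.nan for p in reg_params]),
            }

    if len(maps) < 2:
        raise ValueError(f"patient {patient.patient_id}: fewer than two maps")
    voxel = patient_correlation_matrix(maps, gtv, level="voxel",
                                       patient_id=patient.patient_id)
    regional = patient_correlation_matrix(maps, gtv, level="regional",
                                          spec=settings.region_spec,
                                          patient_id=patient.patient_id,
                                          regional_values=regional_values)
    if regional.excluded:
        warnings_out.append(
            f"patient {patient.patient_id} excluded from regional analysis: "
            f"{regional.exclusion_reason}")
    return voxel, regional, maps, warnings_out


def analyze_cohort(patients: list[PatientData],
                   settings: AnalysisSettings = AnalysisSettings()):
    """Analyze every patient with continue-on-error isolation.

    Returns ``(results, summary, failures, warnings)`` where ``results``
    holds one voxel-level and one regional-level CorrelationResult per
    successful patient.  The run fails only if every patient fails.
    """
    results: list[CorrelationResult] = []
    failures: dict[str, str] = {}
    warnings_out: list[str] = []
    for patient in patients:
        try:
            voxel, regional, _maps, warns = analyze_patient(patient, settings)
        except Exception as exc:
            failures[patient.patient_id] = f"{type(exc).__name__}: {exc}"
            continue
        results.extend([voxel, regional])
        warnings_out.extend(warns)
    if patients and not results:
        raise RuntimeError(f"all patients failed: {failures}")
    summary = cohort_summary(results)
    return results, summary, failures, warnings_out


# ---------------------------------------------------------------------------
# Run configuration and manifests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RunConfig:
    """A reproducible run: synthetic cohort spec, analysis settings, output dir."""

    output_dir: str
    seed: int = 0
    n_patients: int = 8
    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    settings: AnalysisSettings = field(default_factory=AnalysisSettings)
    available: tuple[tuple[str, ...], ...] | None = None  # per-patient modality sets
    overwrite: bool = False

    def patient_seeds(self) -> list[int]:
        ss = np.random.SeedSequence(self.seed)
        return [int(c.generate_state(1)[0] % (2 ** 31)) for c in
                ss.spawn(self.n_patients)]


@dataclass
class RunManifest:
    """Provenance record: config hash, version, per-output checksums, warnings."""

    config_hash: str
    version: str
    stage: str
    outputs: dict[str, str] = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1, sort_keys=True))
        return path


def _config_hash(config) -> str:
    blob = json.dumps(_jsonable(asdict(config)), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _prepare_output(config: RunConfig) -> Path:
    out = Path(config.output_dir)
    if out.exists() and any(out.iterdir()) and not config.overwrite:
        raise FileExistsError(
            f"output directory {out} is not empty; pass overwrite=True")
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_phantom_cohort(config: RunConfig):
    """Generate and write one phantom per synthetic patient; return datasets + manifest."""
    out = _prepare_output(config)
    seeds = config.patient_seeds()
    manifest = RunManifest(config_hash=_config_hash(config), version=__version__,
                           stage="phantom", seeds=seeds)
    datasets: list[PhantomDataset] = []
    from dataclasses import replace
    for i, seed in enumerate(seeds):
        pid = f"P{i + 1:02d}"
        ds = make_phantom(replace(config.phantom, seed=seed))
        datasets.append(ds)
        pdir = save_phantom(ds, out / pid)
        for f in sorted(pdir.rglob("*")):
            if f.is_file():
                manifest.outputs[str(f.relative_to(out))] = _checksum(f)
        manifest.warnings.extend(f"{pid}: {w}" for w in ds.warnings)
    manifest.write(out / "manifest.json")
    return datasets, manifest


def write_median_matrix(summary: pd.DataFrame, labels=MAP_LABELS) -> pd.DataFrame:
    """Square cohort matrix: voxel medians in the upper triangle, regional lower."""
    m = pd.DataFrame(np.full((len(labels), len(labels)), np.nan),
                     index=labels, columns=labels)
    np.fill_diagonal(m.values, 1.0)
    for _, row in summary.iterrows():
        a, b = row["pair"].split("/")
        if a not in labels or b not in labels:
            continue
        i, j = labels.index(a), labels.index(b)
        hi, lo = min(i, j), max(i, j)
        if row["level"] == "voxel":
            m.iloc[hi, lo] = row["median_r"]
        else:
            m.iloc[lo, hi] = row["median_r"]
    return m


def run_analysis(config: RunConfig, patients: list[PatientData] | None = None):
    """Full analysis over a cohort; writes tidy CSVs, the median matrix and a manifest.

    When ``patients`` is None the synthetic cohort is generated in memory
    from the config (one seed per patient).  Per-patient failures are
    recorded and skipped; the run fails only if all patients fail.
    """
    out = _prepare_output(config)
    if patients is None:
        from dataclasses import replace
        seeds = config.patient_seeds()
        avail = config.available or tuple(MAP_LABELS for _ in seeds)
        patients = [
            patient_from_phantom(make_phantom(replace(config.phantom, seed=s)),
                                 f"P{i + 1:02d}", tuple(avail[i]))
            for i, s in enumerate(seeds)
        ]
    results, summary, failures, warns = analyze_cohort(patients, config.settings)

    per_patient = pd.concat([r.to_frame() for r in results], ignore_index=True)
    per_patient.to_csv(out / "per_patient_correlations.csv", index=False)
    summary.to_csv(out / "cohort_summary.csv", index=False)
    matrix = write_median_matrix(summary)
    matrix.to_csv(out / "cohort_median_matrix.csv")

    manifest = RunManifest(config_hash=_config_hash(config), version=__version__,
                           stage="analysis", seeds=config.patient_seeds(),
                           warnings=warns + [f"failed {k}: {v}"
                                             for k, v in failures.items()])
    for f in ("per_patient_correlations.csv", "cohort_summary.csv",
              "cohort_median_matrix.csv"):
        manifest.outputs[f] = _checksum(out / f)
    manifest.write(out / "manifest.json")
    return results, summary, manifest
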