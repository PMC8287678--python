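"""Configuration and the subject-level / study-level pipeline drivers.

``run_subject`` takes a surface with a time-resolved wall-shear field (from a
file pair or a synthetic zonal preset), computes the apex-patch wall metrics
and writes an annotated VTK surface plus one cohort-CSV row.  ``run_study``
takes (or generates) a cohort table and writes the full statistical report.
Every run drops a machine-readable provenance record (config, seed, package
and library versions, config hash) next to its outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, geometry, synthetic_data, wall_metrics
from .cohort_stats import CohortReport, analyze_cohort, validate_cohort

__all__ = ["PipelineConfig", "run_subject", "run_study", "SUBJECT_FIELD_NAMES"]

#: point-data array names written to annotated VTK surfaces
SUBJECT_FIELD_NAMES = ("TAWSS", "OSI", "WSSG_P", "WSSG_Q", "WSSG_MAG", "WSSG_SIGN")


@dataclass
class PipelineConfig:
    """Tunable knobs of the analysis, with the study defaults.

    patch_radius (mm) and percentile define the apex patch and its high-WSS
    region; area_weighted switches region averages between area weights and
    plain vertex means; the envelope parameters feed the digitiser.
    """

    patch_radius: float = 5.0
    patch_metric: str = "geodesic"
    percentile: float = 98.0
    area_weighted: bool = True
    envelope_threshold: float = 0.2
    smooth_window: int = 5
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def hash(self) -> str:
        canon = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _provenance(config: PipelineConfig, extra: dict | None = None) -> dict:
    import scipy

    rec = {
        "package": "apexshear",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
    }
    rec.update(extra or {})
    return rec


def run_subject(mesh: geometry.SurfaceMesh | str | Path,
                fieldsrc: wall_metrics.TimeResolvedWallField | str | None,
                config: PipelineConfig | None = None,
                subject_id: str = "subject", group: str = "case",
                out_dir: str | Path | None = None) -> dict:
    """Wall-metric row for one subject.

    ``mesh`` is a SurfaceMesh or a mesh file path; ``fieldsrc`` is a
    TimeResolvedWallField, or the name of a zonal preset ("case_like" /
    "control_like") to generate one on the mesh.  Returns the cohort-CSV row
    dict; when ``out_dir`` is given, also writes the annotated VTK surface
    and the provenance record.
    """
    config = config or PipelineConfig()
    try:
        if not isinstance(mesh, geometry.SurfaceMesh):
            mesh = geometry.load_surface_mesh(mesh)
    except geometry.MeshError as exc:
        raise geometry.MeshError(f"[geometry] {exc}") from exc
    if isinstance(fieldsrc, str):
        params = {"case_like": synthetic_data.case_like_params,
                  "control_like": synthetic_data.control_like_params}
        if fieldsrc not in params:
            raise ValueError(f"[synthetic_data] unknown zonal preset {fieldsrc!r}")
        fieldsrc = synthetic_data.make_zonal_wss_field(mesh, params[fieldsrc](),
                                                       seed=config.seed)
    field = fieldsrc
    if field is None:
        raise ValueError("[wall_metrics] no wall-shear field provided")
    if mesh.apex_vertex is None:
        raise geometry.MeshError("[geometry] mesh has no apex vertex; cannot place the patch")

    tawss = wall_metrics.time_averaged_wss(field)
    osi_vals, _ = wall_metrics.osi(field)
    frame = wall_metrics.wss_frame(field)
    wssg = wall_metrics.wssg_field(tawss, frame, mesh)
    areas = geometry.vertex_areas(mesh)
    patch = geometry.extract_apex_patch(mesh, radius=config.patch_radius,
                                        metric=config.patch_metric)
    branch = wall_metrics.select_branch(mesh, tawss, patch)
    region = wall_metrics.high_wss_region(tawss, patch, percentile=config.percentile)
    region = region[mesh.branch_labels[region] == branch]
    if len(region) == 0:
        # percentile threshold attained only off the selected branch: fall back
        # to thresholding within the branch part of the patch
        sub = patch.vertex_indices[mesh.branch_labels[patch.vertex_indices] == branch]
        sub_patch = geometry.ApexPatch(vertex_indices=sub, radius=patch.radius,
                                       center=patch.center, metric=patch.metric)
        region = wall_metrics.high_wss_region(tawss, sub_patch, percentile=config.percentile)
    metrics = wall_metrics.region_metrics(region, tawss, wssg, osi_vals, areas,
                                          area_weighted=config.area_weighted)
    row = metrics.to_row(subject_id, group)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        point_data = {
            "TAWSS": tawss,
            "OSI": osi_vals,
            "WSSG_P": wssg.d_tau_dp,
            "WSSG_Q": wssg.d_tau_dq,
            "WSSG_MAG": wssg.magnitude,
            "WSSG_SIGN": wssg.sign,
        }
        geometry.save_surface_mesh(out_dir / f"{subject_id}.vtk", mesh, point_data)
        prov = _provenance(config, {
            "stage": "run_subject", "subject_id": subject_id, "group": group,
            "branch": branch, "patch_vertices": int(len(patch)),
            "region_vertices": int(metrics.region_size),
        })
        (out_dir / f"{subject_id}_provenance.json").write_text(json.dumps(prov, indent=2))
    return row


def run_study(table: pd.DataFrame | str | Path | None,
              config: PipelineConfig | None = None,
              out_dir: str | Path = "study_report",
              cohort_params: synthetic_data.CohortParams | None = None) -> CohortReport:
    """Full case-control analysis; writes the report files to ``out_dir``.

    ``table`` is a cohort DataFrame or CSV path; pass ``None`` with
    ``cohort_params`` to analyse a generated synthetic cohort.  Outputs:
    group_comparisons.csv, contingency.json, regression.csv, roc_points.csv,
    roc_summary.json, provenance.json.
    """
    config = config or PipelineConfig()
    if table is None:
        params = cohort_params or synthetic_data.CohortParams(seed=config.seed)
        df = synthetic_data.make_cohort(params)
    elif isinstance(table, (str, Path)):
        df = pd.read_csv(table)
    else:
        df = table.copy()
    validate_cohort(df)
    report = analyze_cohort(df)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report.group_comparisons.to_csv(out / "group_comparisons.csv", index=False)
    or_, lo, hi, corrected = report.odds_ratio
    (out / "contingency.json").write_text(json.dumps({
        "case_dir_pos": report.contingency.a, "control_dir_pos": report.contingency.b,
        "case_dir_neg": report.contingency.c, "control_dir_neg": report.contingency.d,
        "fisher_p": report.fisher_p,
        "odds_ratio": or_, "ci95": [lo, hi], "haldane_corrected": corrected,
    }, indent=2))
    reg = report.univariate.copy()
    reg["analysis"] = "univariate"
    if report.multivariate is not None:
        m = report.multivariate
        multi = pd.DataFrame({
            "metric": m.names[1:], "OR": m.odds_ratios[1:], "ci_low": m.ci_low[1:],
            "ci_high": m.ci_high[1:], "p": m.p_values[1:], "analysis": "multivariate",
        })
        reg = pd.concat([reg, multi], ignore_index=True)
    reg.to_csv(out / "regression.csv", index=False)
    roc_rows = []
    for name, rr in (("WSSG", report.roc_wssg), ("combined", report.roc_combined)):
        if rr is None:
            continue
        roc_rows.append(pd.DataFrame({
            "curve": name, "threshold": rr.thresholds,
            "sensitivity": rr.sensitivities, "specificity": rr.specificities,
        }))
    if roc_rows:
        pd.concat(roc_rows, ignore_index=True).to_csv(out / "roc_points.csv", index=False)
    (out / "roc_summary.json").write_text(json.dumps({
        name: {"auc": rr.auc, "optimal_cutoff": rr.optimal_cutoff,
               "sensitivity": rr.optimal_sensitivity, "specificity": rr.optimal_specificity}
        for name, rr in (("WSSG", report.roc_wssg), ("combined", report.roc_combined))
        if rr is not None
    }, indent=2))
    prov = _provenance(config, {
        "stage": "run_study", "n_case": int((df["group"] == "case").sum()),
        "n_control": int((df["group"] == "control").sum()),
        "selected_variables": report.selected, "notes": report.notes,
    })
    (out / "provenance.json").write_text(json.dumps(prov, indent=2))
    return report
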