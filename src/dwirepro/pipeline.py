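"""End-to-end orchestration: simulate -> fit -> ROI -> reproducibility.

Two pipelines mirror the two arms of a multi-centre study:

* the phantom arm scans one ice-water phantom on every scanner, fits
  ADC / IVIM / DTI in the water tubes and summarises the per-scanner
  means with a group CV (plus leave-one-scanner-out recomputations, the
  standard check when one site's phantom was not at temperature);
* the volunteer arm produces the long measurement table (simulated or
  loaded) and runs the mixed-model variance-component analysis per
  metric and region, combined and per field strength.

Every run writes a manifest (config snapshot, version, per-stage counts,
warnings) sufficient to re-execute it; identical config and seed give
byte-identical reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

import dwirepro
from dwirepro.schemes import AcquisitionScheme, IVIM_BVALUES, dti_scheme
from dwirepro.phantom import PhantomSpec, generate_phantom_image
from dwirepro.study import StudyDesign, replica_study_design, generate_multicentre_study
from dwirepro.fitting import fit_volume
from dwirepro.roi import erode_mask, roi_mean
from dwirepro.repro import group_cv, subgroup_analysis, summarize_report
from dwirepro.io import save_table, save_json

__all__ = ["RunConfig", "run_phantom_pipeline", "run_volunteer_pipeline"]


class ConfigError(ValueError):
    """Invalid run configuration."""


@dataclass
class RunConfig:
    """One pipeline run: exactly one input source, mandatory seed for
    generator modes, optional output directory."""

    mode: str  # "phantom" | "volunteer-study" | "table-only"
    seed: int | None = None
    out_dir: str | None = None
    # generator specs / loaded inputs
    phantom_spec: PhantomSpec | None = None
    scanner_sigmas: dict = dc_field(default_factory=dict)
    scanner_water_offset: dict = dc_field(default_factory=dict)
    design: StudyDesign | None = None
    table: pd.DataFrame | None = None
    scanner_means: dict | None = None  # table-only phantom input
    models: tuple = ("adc", "ivim", "dti")

    def __post_init__(self):
        sources = [self.phantom_spec is not None or self.scanner_means is not None,
                   self.design is not None,
                   self.table is not None]
        if sum(sources) != 1:
            raise ConfigError("exactly one input source per run")
        generating = self.phantom_spec is not None or self.design is not None
        if generating and self.seed is None:
            raise ConfigError("seed is mandatory for generator modes")


def _manifest(config: RunConfig, stage_counts: dict, warnings_list: list) -> dict:
    return {
        "version": dwirepro.__version__,
        "mode": config.mode,
        "seed": config.seed,
        "stages": stage_counts,
        "warnings": warnings_list,
    }


def _write_outputs(out_dir, tables: dict, manifest: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    save_json(manifest, out / "manifest.json")


def phantom_group_report(scanner_means: dict) -> dict:
    """Group-CV report from per-scanner phantom means.

    ``scanner_means``: scanner id -> metric -> mean. Returns a dict with
    an overall table (mean/SD/CV per metric) and a leave-one-out table
    (one row per excluded scanner per metric).
    """
    metrics = sorted({m for v in scanner_means.values() for m in v})
    overall_rows, loo_rows = [], []
    for m in metrics:
        have = {s: v[m] for s, v in scanner_means.items() if m in v}
        g = group_cv(have.values())
        overall_rows.append({"metric": m, "n_scanners": g.n, "mean": g.mean,
                             "sd": g.sd, "cv_pct": g.cv})
        for excl in sorted(have):
            rest = [x for s, x in have.items() if s != excl]
            if len(rest) < 2:
                continue
            gx = group_cv(rest)
            loo_rows.append({"metric": m, "excluded": excl, "mean": gx.mean,
                             "sd": gx.sd, "cv_pct": gx.cv})
    per_scanner = pd.DataFrame(
        [{"scanner": s, "metric": m, "mean": v}
         for s, mv in sorted(scanner_means.items()) for m, v in sorted(mv.items())]
    )
    return {
        "phantom_per_scanner": per_scanner,
        "phantom_overall": pd.DataFrame(overall_rows),
        "phantom_leave_one_out": pd.DataFrame(loo_rows),
    }


def run_phantom_pipeline(config: RunConfig) -> dict:
    """Phantom arm: simulate per-scanner volumes (or take per-scanner
    means) and produce the group reproducibility report."""
    warnings_list: list = []
    counts: dict = {}

    if config.scanner_means is not None:
        scanner_means = config.scanner_means
        counts["scanners"] = len(scanner_means)
    else:
        if config.phantom_spec is None:
            raise ConfigError("phantom mode needs a phantom spec or means table")
        spec = config.phantom_spec
        scheme = AcquisitionScheme(np.array(IVIM_BVALUES))
        tensor_scheme = dti_scheme(n_directions=15, b=1000.0, n_b0=1)
        scanner_means = {}
        sigmas = config.scanner_sigmas or {"A": 0.0}
        root = np.random.SeedSequence(int(config.seed))
        children = root.spawn(len(sigmas))
        for child, (sid, sigma) in zip(children, sorted(sigmas.items())):
            sub_seed = int(child.generate_state(1)[0] % (2**31))
            wd = spec.water_d + config.scanner_water_offset.get(sid, 0.0)
            sspec = PhantomSpec(
                n_water_tubes=spec.n_water_tubes, water_d=wd,
                sucrose_d=spec.sucrose_d,
                tube_radius_vox=spec.tube_radius_vox,
                image_shape=spec.image_shape,
                voxel_size_mm=spec.voxel_size_mm, s0=spec.s0,
            )
            vol, labels = generate_phantom_image(sspec, scheme, sigma, sub_seed)
            water = np.isin(labels, sspec.water_labels)
            water = erode_mask(water) if spec.tube_radius_vox >= 3 else water
            means: dict = {}
            maps, _ = fit_volume(vol, scheme, "adc", mask=water)
            means["ADC"], _ = roi_mean(maps["adc"], water)
            means["ADC"] *= 1e3  # report on the printed 1e-3 scale
            if "ivim" in config.models:
                maps, log_i = fit_volume(vol, scheme, "ivim", mask=water)
                means["D"], _ = roi_mean(maps["d"], water)
                means["D"] *= 1e3
                means["f"], _ = roi_mean(maps["f"], water)
                if log_i["non_converged"]:
                    warnings_list.append(
                        f"{sid}: {log_i['non_converged']} non-converged IVIM voxels"
                    )
            if "dti" in config.models:
                tvol, tlabels = generate_phantom_image(
                    sspec, tensor_scheme, sigma, sub_seed + 1
                )
                twater = np.isin(tlabels, sspec.water_labels)
                twater = erode_mask(twater) if spec.tube_radius_vox >= 3 else twater
                maps, _ = fit_volume(tvol, tensor_scheme, "dti", mask=twater)
                means["MD"], _ = roi_mean(maps["md"], twater)
                means["MD"] *= 1e3
                means["FA"], _ = roi_mean(maps["fa"], twater)
            scanner_means[sid] = means
        counts["scanners"] = len(scanner_means)

    report = phantom_group_report(scanner_means)
    counts["report_rows"] = int(sum(len(df) for df in report.values()))
    manifest = _manifest(config, counts, warnings_list)
    if config.out_dir:
        _write_outputs(config.out_dir, report, manifest)
    report["manifest"] = manifest
    return report


def run_volunteer_pipeline(config: RunConfig) -> dict:
    """Volunteer arm: measurement table -> variance components -> CV/ICC
    report (combined and per field strength)."""
    warnings_list: list = []
    counts: dict = {}
    truth = None

    if config.design is not None:
        table, truth = generate_multicentre_study(config.design, config.seed)
        field_strength = {s.scanner_id: s.field_strength
                          for s in config.design.scanners}
    elif config.table is not None:
        table = config.table
        field_strength = {}
    else:
        raise ConfigError("volunteer mode needs a design or a table")
    counts["table_rows"] = len(table)

    results = []
    for metric in sorted(table["metric"].unique()):
        for region in sorted(table["region"].unique()):
            if field_strength:
                res = subgroup_analysis(table, field_strength, metric, region)
                results.extend(res.values())
            else:
                from dwirepro.repro import analyse_metric_region, StatsError
                try:
                    results.append(analyse_metric_region(table, metric, region))
                except StatsError as exc:
                    warnings_list.append(f"{metric}/{region}: {exc}")
    for r in results:
        if r.valid and not r.volunteer_estimable:
            warnings_list.append(
                f"{r.metric}/{r.region}/{r.subgroup}: volunteer component NE"
            )
    report_df = summarize_report(results)
    out = {"measurement_table": table, "repro_report": report_df}

    if truth is not None:
        recovery = []
        offsets = truth["scanner_offsets"]
        for r in results:
            if not r.valid or r.subgroup != "all":
                continue
            true_inter = float(np.std([offsets[s][r.metric] for s in offsets],
                                      ddof=1))
            recovery.append({
                "metric": r.metric, "region": r.region,
                "true_sigma_inter": true_inter,
                "est_sigma_inter": r.sigma_inter,
                "true_sigma_volunteer": truth["volunteer_sd"][r.metric],
                "est_sigma_volunteer": r.sigma_volunteer,
                "true_sigma_intra": truth["residual_sd"][r.metric],
                "est_sigma_intra": r.sigma_intra,
            })
        out["recovery"] = pd.DataFrame(recovery)

    counts["report_rows"] = len(report_df)
    manifest = _manifest(config, counts, warnings_list)
    if config.out_dir:
        _write_outputs(config.out_dir, out, manifest)
    out["manifest"] = manifest
    return out
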