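"""Stage runners binding the library into an end-to-end pipeline.

Each stage is a plain function taking a :class:`PipelineConfig`; the CLI is
a thin wrapper. Stage outputs are files under ``config.out_dir`` so any
stage can be re-run in isolation; with identical config and seed every
stage's CSV output is byte-identical across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .config import PipelineConfig
from .dki import FitConfig, fit_volume, smooth_dwi
from .gradients import make_scheme
from .histo import quantify_labeling, read_micrograph
from .mrs import filter_crlb, load_metabolite_table, ratio_to_tcr
from .roi import ROIMask, complete_case_filter, extract_roi_mean, normalize_to_baseline
from .stats import fisher_lsd, mixed_anova
from .synthetic import (
    CohortSpec,
    make_cohort_table,
    make_histo_image,
    make_metabolite_table,
    make_phantom,
    two_block_field,
)

__all__ = [
    "stage_simulate",
    "stage_fit",
    "stage_roi",
    "stage_mrs",
    "stage_histo",
    "stage_stats",
    "run_all",
]


def _out(config: PipelineConfig) -> Path:
    p = Path(config.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


def stage_simulate(config: PipelineConfig) -> dict:
    """Generate every synthetic input: phantom DWI, cohort CSV, metabolite
    CSV and a labeled micrograph, all seeded from ``config.seed``."""
    out = _out(config)
    scheme = make_scheme(
        config.n_directions, config.shell_bvalues, config.n_b0, seed=config.seed
    )
    field = two_block_field(
        config.phantom_shape,
        s0=config.phantom_s0,
        md=config.phantom_md,
        kapp_a=config.phantom_kapp[0],
        kapp_b=config.phantom_kapp[1],
    )
    series, field = make_phantom(
        field,
        scheme,
        sigma=config.noise_sigma,
        seed=config.seed,
        voxel_size=config.voxel_size,
    )
    paths = dio.write_dwi(series, out / "phantom")

    import nibabel as nib

    labels = np.ones(config.phantom_shape, dtype=np.int16)
    labels[config.phantom_shape[0] // 2 :] = 2
    label_path = out / "phantom_labels.nii"
    nib.save(nib.Nifti1Image(labels, series.affine), label_path)
    paths["labels"] = label_path

    spec = CohortSpec(
        n_per_group=config.n_per_group,
        groups=config.groups,
        timepoints=config.timepoints,
        means=config.cohort_means(),
        between_sd=config.cohort_between_sd,
        within_sd=config.cohort_within_sd,
        seed=config.seed,
    )
    cohort = make_cohort_table(spec)
    dio.write_cohort_csv(cohort, out / "cohort.csv")
    paths["cohort"] = out / "cohort.csv"

    met = make_metabolite_table(
        ["NAA", "Ins", "Tau", "Gln"], [10.0, 5.5, 6.0, 3.0], [5.0, 8.0, 19.0, 25.0],
        seed=config.seed,
    )
    met.to_csv(out / "metabolites.csv", index=False)
    paths["metabolites"] = out / "metabolites.csv"

    import tifffile

    img = make_histo_image(
        (180, 225),
        background_level=1000.0,
        labeled_fraction=config.histo_labeled_fraction,
        label_multiple=config.histo_label_multiple,
        seed=config.seed,
    )
    tifffile.imwrite(out / "micrograph.tif", img)
    paths["micrograph"] = out / "micrograph.tif"
    return paths


def stage_fit(config: PipelineConfig) -> dict:
    """Smooth and reconstruct the phantom series into MD/FA/MK maps."""
    out = _out(config)
    series = dio.read_dwi(
        out / "phantom.nii", out / "phantom.bval", out / "phantom.bvec",
        mask_path=(out / "phantom_mask.nii")
        if (out / "phantom_mask.nii").exists()
        else None,
    )
    smoothed = smooth_dwi(series, config.fwhm_mm)
    maps = fit_volume(
        smoothed,
        FitConfig(
            kapp_clamp=config.kapp_clamp,
            signal_floor=config.signal_floor,
            mode=config.fit_mode,
        ),
    )
    return dio.write_param_maps(
        maps, out / "maps", config={"fwhm_mm": config.fwhm_mm, **config.to_dict()}
    )


def stage_roi(config: PipelineConfig) -> dict:
    """Extract per-region map means from the fitted maps."""
    out = _out(config)
    maps = dio.read_param_maps(out / "maps")
    masks = dio.load_roi_masks(
        out / "phantom_labels.nii",
        {1: {"region": "block_low", "side": "midline"},
         2: {"region": "block_high", "side": "midline"}},
    )
    rows = []
    for mask in masks:
        for measure in ("MD", "FA", "MK"):
            rv = extract_roi_mean(maps, mask, measure)
            rows.append(
                dict(
                    region=mask.region,
                    side=mask.side,
                    measure=measure,
                    value=rv.value,
                    n_used=rv.n_used,
                    n_excluded=rv.n_excluded,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(out / "roi_means.csv", index=False)
    return {"roi_means": out / "roi_means.csv"}


def stage_mrs(config: PipelineConfig) -> dict:
    """Gate the metabolite table on CRLB and compute tCr ratios."""
    out = _out(config)
    records, _ = load_metabolite_table(out / "metabolites.csv")
    retained, excluded = filter_crlb(records, config.crlb_threshold)
    ratios = ratio_to_tcr(retained)
    ratios.to_csv(out / "metabolite_ratios.csv", index=False)
    log = {
        "threshold_percent": config.crlb_threshold,
        "retained": [r.name for r in retained],
        "excluded": [r.name for r in excluded],
    }
    (out / "mrs_log.json").write_text(json.dumps(log, indent=2))
    return {"ratios": out / "metabolite_ratios.csv", "log": out / "mrs_log.json"}


def stage_histo(config: PipelineConfig) -> dict:
    """Quantify percent labeled area in the micrograph."""
    out = _out(config)
    img = read_micrograph(out / "micrograph.tif")
    h, w = img.shape
    # the synthetic micrograph has < 50% labeling, so the whole-frame median
    # is the background level; real data would pass an unlabeled rectangle
    result = quantify_labeling(
        img,
        roi_rect=(0, h, 0, w),
        background_roi=(0, h, 0, w),
        multiplier=config.histo_multiplier,
        region="hippocampus",
        background_stat="median",
    )
    df = pd.DataFrame([result.__dict__])
    df.to_csv(out / "histo_quant.csv", index=False)
    return {"histo": out / "histo_quant.csv"}


def stage_stats(config: PipelineConfig, table: pd.DataFrame | None = None) -> dict:
    """Normalize, filter to complete cases, run the split-plot ANOVA + LSD."""
    out = _out(config)
    if table is None:
        table = dio.read_cohort_csv(out / "cohort.csv")
    norm = normalize_to_baseline(table, config.baseline_label)
    post_times = [t for t in config.timepoints if t != config.baseline_label]
    analysis_times = (
        list(config.timepoints) if config.include_baseline_level else post_times
    )
    filtered, dropped = complete_case_filter(norm, set(config.timepoints))
    analysed = filtered[filtered["time"].isin(analysis_times)]
    anova_rows, posthoc_rows, report_lines = [], [], []
    for (region, measure), sub in analysed.groupby(["region", "measure"]):
        res = mixed_anova(sub, value_col="normalized_value")
        for e in res.effects():
            anova_rows.append(
                dict(region=region, measure=measure, effect=e.name,
                     SS=e.ss, df=e.df, MS=e.ms, F=e.F, p=e.p)
            )
        report_lines.append(f"[{region} / {measure}]")
        report_lines.append(res.report())
        for row in fisher_lsd(
            sub, res, alpha=config.alpha, value_col="normalized_value",
            mode=config.posthoc_mode,
        ):
            posthoc_rows.append(
                dict(region=region, measure=measure, time=row.time,
                     mean_difference=row.mean_difference, se=row.se,
                     t=row.t, df=row.df, p=row.p, significant=row.significant)
            )
    pd.DataFrame(anova_rows).to_csv(out / "anova.csv", index=False)
    pd.DataFrame(posthoc_rows).to_csv(out / "posthoc.csv", index=False)
    if dropped:
        report_lines.append(f"dropped incomplete subjects: {', '.join(dropped)}")
    (out / "stats_report.txt").write_text("\n".join(report_lines) + "\n")
    return {
        "anova": out / "anova.csv",
        "posthoc": out / "posthoc.csv",
        "report": out / "stats_report.txt",
    }


_STAGES = {
    "simulate": stage_simulate,
    "fit": stage_fit,
    "roi": stage_roi,
    "mrs": stage_mrs,
    "histo": stage_histo,
    "stats": stage_stats,
}


def run_all(config: PipelineConfig) -> dict:
    """simulate -> fit -> roi -> mrs -> histo -> stats on one synthetic study."""
    outputs = {}
    for name in ("simulate", "fit", "roi", "mrs", "histo", "stats"):
        try:
            outputs[name] = _STAGES[name](config)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return outputs
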