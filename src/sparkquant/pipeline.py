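"""End-to-end orchestration over synthetic inputs, with provenance.

``run_pipeline`` executes every stage on generator output at the
configured study conditions, writes each stage's tables (CSV/JSON) under
the output directory and records a manifest with parameters and output
hashes. Deterministic given the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from sparkquant import (
    calibration, coloc, detection, expression, fusion, phase, synthetic, timecourse,
)
from sparkquant.config import PipelineConfig

log = logging.getLogger(__name__)
__version__ = "0.1.0"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def run_pipeline(config: PipelineConfig, out_dir=None) -> dict:
    """Run every stage on synthetic data; returns the result bundle."""
    config.validate()
    seed = config.seed
    out = Path(out_dir or config["paths"]["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    img_cfg = config["imaging"]

    # calibration ---------------------------------------------------------
    gt = synthetic.ImagingGroundTruth(seed=seed, csat_nM=img_cfg["csat_nM"],
                                      partition_ratio=img_cfg["partition_ratio"],
                                      pixel_size_um=img_cfg["pixel_size_um"],
                                      psf_sigma_um=img_cfg["psf_sigma_um"],
                                      condensate_radius_um=img_cfg["condensate_radius_um"])
    dilution = synthetic.generate_dilution_table(gt)
    curve = calibration.fit_standard_curve(dilution)
    _write_csv(dilution, out / "calibration" / "dilution_series.csv")
    curve.to_json(out / "calibration" / "standard_curve.json")
    results["calibration"] = curve

    # detection + phase curve --------------------------------------------
    rng = np.random.default_rng(seed)
    concs = np.geomspace(5, 500, 100) * np.exp(rng.normal(0, 0.05, 100))
    cells, truth = synthetic.generate_cell_images(gt, concs)
    meas = detection.measure_cells([c.stack for c in cells], curve=curve,
                                   k_sigma=config["detection"]["k_sigma"],
                                   min_size=config["detection"]["min_size"])
    meas["concentration_nM"] = meas["concentration_nM"].clip(lower=1e-3)
    _write_csv(meas, out / "detection" / "cell_measurements.csv")
    curve_obj = phase.build_phase_curve(meas, condition="untreated")
    est = phase.estimate_csat(curve_obj, n_bootstrap=config["phase"]["n_bootstrap"],
                              seed=seed, zero_level=config["phase"]["zero_level"])
    (out / "phase").mkdir(exist_ok=True)
    (out / "phase" / "csat.json").write_text(json.dumps(est.__dict__, indent=2))
    results["csat"] = est

    # fusion --------------------------------------------------------------
    fus_cfg = config["fusion"]
    fgt = synthetic.FusionGroundTruth(seed=seed, n_events=fus_cfg["n_events"],
                                      frame_interval_s=fus_cfg["frame_interval_s"])
    movies, ftruth = synthetic.generate_fusion_movie(fgt)
    fits = []
    for m in movies:
        fits.extend(fusion.fit_all(fusion.track_fusion_events(m),
                                   rms_tolerance=fus_cfg["rms_tolerance"]))
    summary = fusion.summarize_inverse_capillary_velocity(fits)
    _write_csv(pd.DataFrame([f.__dict__ for f in fits]), out / "fusion" / "fits.csv")
    (out / "fusion" / "summary.json").write_text(json.dumps(summary, indent=2))
    results["fusion"] = summary

    # colocalization ------------------------------------------------------
    stacks, ctruth = synthetic.generate_coloc_channels(13, seed=seed, gt=gt)
    pairs = []
    for s in stacks:
        labels, bg = detection.segment_cell(s.channel(0))
        mask = labels > 0
        ref = detection.detect_condensates(s.channel(0), mask, background=bg)
        oth = detection.detect_condensates(s.channel(1), mask, background=bg)
        pairs.append((ref, oth))
    cres = coloc.match_puncta(pairs, rule=config["coloc"]["rule"],
                              min_overlap=config["coloc"]["min_overlap"])
    _write_csv(cres.per_cell, out / "coloc" / "per_cell.csv")
    results["coloc"] = cres

    # dissolution time course --------------------------------------------
    movie, dtruth = synthetic.generate_dissolution_series(gt)
    tc = timecourse.measure_timecourse(movie)
    summ = timecourse.dissolution_summary(tc, epsilon=config["timecourse"]["epsilon"])
    _write_csv(tc.table, out / "timecourse" / "trace.csv")
    (out / "timecourse" / "summary.json").write_text(json.dumps(summ.__dict__, indent=2))
    results["dissolution"] = summ

    # qPCR ----------------------------------------------------------------
    ct = synthetic.generate_ct_table({"CTGF": 0.16, "CYR61": 0.30}, seed=seed,
                                     reference_gene=config["qpcr"]["reference_gene"])
    qres = expression.ddct(ct, ["CTGF", "CYR61"], config["qpcr"]["reference_gene"],
                           "control")
    _write_csv(qres.table, out / "qpcr" / "ddct.csv")
    results["qpcr"] = qres

    # differential expression ---------------------------------------------
    de_cfg = config["de"]
    counts, design, gtruth = synthetic.generate_study_counts(seed=seed)
    contrasts = {
        "condensed_vs_control": ("condensed", "control"),
        "diffuse_vs_control": ("diffuse", "control"),
        "condensed_vs_diffuse": ("condensed", "diffuse"),
    }
    de_results = {}
    for name, (t_, c_) in contrasts.items():
        r = expression.de_test(counts, design, test_condition=t_, control_condition=c_,
                               p_threshold=de_cfg["p_threshold"],
                               lfc_threshold=de_cfg["lfc_threshold"],
                               fdr_threshold=de_cfg["fdr_threshold"])
        r.table.to_csv(out / "de" / f"{name}.tsv", sep="\t") if (out / "de").exists() else None
        (out / "de").mkdir(exist_ok=True)
        r.table.to_csv(out / "de" / f"{name}.tsv", sep="\t")
        de_results[name] = r
    comp = expression.compare_contrasts(de_results, primary="condensed_vs_control",
                                        ps_contrast="condensed_vs_diffuse")
    (out / "de" / "comparison.json").write_text(json.dumps(
        {"intersections": comp.intersections,
         "further_enhanced_fraction_pct": comp.further_enhanced_fraction_pct,
         "n_up": {k: len(v) for k, v in comp.up.items()},
         "n_down": {k: len(v) for k, v in comp.down.items()}}, indent=2))
    results["de"] = de_results
    results["comparison"] = comp

    # manifest ------------------------------------------------------------
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": config.params,
        "outputs": {str(p.relative_to(out)): _sha256(p)
                    for p in sorted(out.rglob("*")) if p.is_file() and p.name != "manifest.json"},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    results["manifest"] = manifest
    return results
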