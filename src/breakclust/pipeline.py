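"""End-to-end orchestration: proximity -> background GAM -> adjusted curve
-> peaks -> driver candidates, with a reproducibility manifest.

Every stage is also runnable standalone on the previous stage's
serialized output (see :mod:`breakclust.cli`); staged and monolithic
execution produce identical results because intermediates are written
at full float precision.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariates as cov_mod
from . import gam, peaks as peaks_mod, proximity
from .drivers import annotate_drivers, read_elements, read_enhancer_links
from .io import (IntervalTrack, read_interval_track, read_sv_table,
                 sv_to_breakpoints, write_manifest, write_results)

logger = logging.getLogger(__name__)

FLOAT_FMT = "%.17g"       # full precision: staged == monolithic, bit for bit


def derive_tad_tracks(master_tads: pd.DataFrame, tad_sets: list,
                      chrom_mark_track: IntervalTrack,
                      boundary_width: int = 50_000, seed: int = 0) -> dict:
    """TAD recurrence, boundary recurrence and segment-class tracks.

    Recurrence of each master TAD across the sample panel (70% overlap
    rule) is segmented into runs of constant value; boundary intervals
    get their own recurrence; segments are classified by chromatin
    coverage.
    """
    rec = cov_mod.tad_recurrence(tad_sets, master_tads)
    tads = master_tads.copy()
    tads["recurrence"] = rec
    segments = cov_mod.segment_tads_by_recurrence(tads)
    seg_track = IntervalTrack(
        name="TAD_recurr", kind="numeric",
        data=segments.rename(columns={"recurrence": "value"}))
    bounds = cov_mod.tad_boundaries(master_tads, width=boundary_width)
    brec = cov_mod.tad_recurrence(
        tad_sets and [cov_mod.tad_boundaries(t, width=boundary_width)
                      for t in tad_sets], bounds)
    bdf = bounds.copy()
    bdf["value"] = brec
    # overlapping boundary flanks: keep the more recurrent one
    bdf = bdf.sort_values(["chrom", "start"]).reset_index(drop=True)
    tadb_track = IntervalTrack(name="TADB_recurr", kind="numeric", data=bdf)
    classes = cov_mod.classify_tad_segments(segments, chrom_mark_track,
                                            random_state=seed)
    cls_df = segments[["chrom", "start", "end"]].copy()
    cls_df["value"] = classes
    cls_track = IntervalTrack(name="TADsegm_class", kind="factor", data=cls_df,
                              levels=cov_mod.TAD_SEGMENT_CLASSES)
    return {"TAD_recurr": seg_track, "TADB_recurr": tadb_track,
            "TADsegm_class": cls_track}


@dataclass
class PipelineResult:
    """Everything the five stages compute, plus the audit log."""

    bp_table: pd.DataFrame
    curves: dict
    covariates: pd.DataFrame | None
    fit: gam.GAMFit | None
    adjusted: dict
    peaks: pd.DataFrame
    elements: pd.DataFrame
    params: dict
    log: dict = field(default_factory=dict)


def run_pipeline(sv_df: pd.DataFrame, tracks: dict | None = None,
                 genes: pd.DataFrame | None = None,
                 tad_sets: list | None = None,
                 master_tads: pd.DataFrame | None = None,
                 elements: pd.DataFrame | None = None,
                 enhancer_links: dict | None = None,
                 known_genes=None, fasta=None,
                 spec: gam.GAMSpec | None = None,
                 span_alpha: float = 0.2, fdr: float = 0.2,
                 min_points: int = proximity.MIN_BREAKPOINTS,
                 boundary_width: int = 50_000, seed: int = 0,
                 intercept_only: bool = False) -> PipelineResult:
    """Run all five stages in memory.

    ``intercept_only`` drops every covariate from the background model
    (the expected curve becomes the cohort mean), which is useful to
    quantify how much the covariate correction sharpens peak calling.
    """
    params = {"span_alpha": span_alpha, "fdr": fdr, "min_points": min_points,
              "boundary_width": boundary_width, "seed": seed,
              "intercept_only": intercept_only}
    log: dict = {"n_sv": int(len(sv_df)),
                 "n_dropped_chrom": sv_df.attrs.get("n_dropped_chrom", 0)}

    bp_table = sv_to_breakpoints(sv_df)
    curves = proximity.curves_from_breakpoints(bp_table, span_alpha=span_alpha,
                                               min_points=min_points)
    modeled = sorted(curves)
    log["chromosomes_modeled"] = modeled
    log["chromosomes_skipped"] = sorted(set(bp_table["chrom"]) - set(modeled))
    if not modeled:
        raise RuntimeError("no chromosome has enough breakpoints to model")

    bp_model = pd.concat(
        [bp_table[bp_table["chrom"] == c] for c in modeled], ignore_index=True)
    response = np.concatenate([curves[c].smoothed for c in modeled])

    tracks = dict(tracks or {})
    if master_tads is not None and tad_sets:
        tracks.update(derive_tad_tracks(master_tads, tad_sets,
                                        tracks.get("ChromMark"),
                                        boundary_width=boundary_width,
                                        seed=seed))
    if intercept_only:
        model_spec = gam.GAMSpec()
        covariates = pd.DataFrame(index=bp_model.index)
        fit = gam.fit_background(covariates, response, spec=model_spec)
        log["missing_covariates"] = {}
    else:
        covariates = cov_mod.annotate_breakpoints(bp_model, tracks,
                                                  genes=genes, fasta=fasta)
        log["missing_covariates"] = covariates.attrs.get("missing_counts", {})
        fit = gam.fit_background(covariates, response, spec=spec,
                                 blocks=bp_model["chrom"].to_numpy())
    log["explained_deviance"] = float(fit.explained_deviance)
    log["edf"] = float(fit.edf)

    expected = fit.fitted_bpp
    adjusted = {}
    start = 0
    for c in modeled:
        n = len(curves[c].positions)
        adjusted[c] = peaks_mod.adjust_curve(curves[c], expected[start:start + n])
        start += n

    peak_table = peaks_mod.detect_peaks(adjusted, bp_table, fdr=fdr)
    log["n_peaks"] = int(len(peak_table))
    log["n_significant"] = int(peak_table["recurrent_significant"].sum()) \
        if len(peak_table) else 0

    if elements is not None and len(peak_table):
        element_scores = annotate_drivers(
            peak_table, elements, sv_df, bp_table,
            known_cancer_genes=known_genes, enhancer_links=enhancer_links)
    else:
        element_scores = pd.DataFrame(columns=pd.Index([], dtype=str))
    return PipelineResult(bp_table=bp_table, curves=curves,
                          covariates=covariates, fit=fit, adjusted=adjusted,
                          peaks=peak_table, elements=element_scores,
                          params=params, log=log)


# ---------------------------------------------------------------------------
# annotation-directory loading (the layout simulate.write_annotations emits)

TRACK_KINDS = {"FS": "binary", "LAD": "binary", "repClass": "factor",
               "ChromMark": "factor", "RT": "numeric", "GC": "numeric"}


def load_annotations(anndir):
    """Load the covariate/annotation directory into pipeline inputs."""
    out = {"tracks": {}, "genes": None, "tad_sets": [], "master_tads": None,
           "elements": None, "enhancer_links": None}
    for name, kind in TRACK_KINDS.items():
        p = os.path.join(anndir, f"{name}.bed")
        if os.path.exists(p):
            out["tracks"][name] = read_interval_track(p, kind=kind, name=name)
    p = os.path.join(anndir, "genes.bed")
    if os.path.exists(p):
        raw = pd.read_csv(p, sep="\t", header=None)
        out["genes"] = raw.rename(columns={0: "chrom", 1: "start", 2: "end",
                                           3: "gene_symbol"})
    tad_dir = os.path.join(anndir, "tads")
    if os.path.isdir(tad_dir):
        for f in sorted(os.listdir(tad_dir)):
            raw = pd.read_csv(os.path.join(tad_dir, f), sep="\t", header=None)
            out["tad_sets"].append(
                raw.rename(columns={0: "chrom", 1: "start", 2: "end"}))
    p = os.path.join(anndir, "master_tads.bed")
    if os.path.exists(p):
        raw = pd.read_csv(p, sep="\t", header=None)
        out["master_tads"] = raw.rename(columns={0: "chrom", 1: "start", 2: "end"})
    p = os.path.join(anndir, "elements.tsv")
    if os.path.exists(p):
        out["elements"] = read_elements(p)
    p = os.path.join(anndir, "enhancer_links.tsv")
    if os.path.exists(p) and os.path.getsize(p):
        out["enhancer_links"] = read_enhancer_links(p)
    return out


def run_all(sv_path, anndir, outdir, cohort_filter=None, seed: int = 0,
            span_alpha: float = 0.2, fdr: float = 0.2,
            min_points: int = proximity.MIN_BREAKPOINTS,
            intercept_only: bool = False, known_genes=None) -> PipelineResult:
    """File-level entry point: read inputs, run, write results + manifest."""
    sv_df = read_sv_table(sv_path, cohort_filter=cohort_filter)
    ann = load_annotations(anndir)
    result = run_pipeline(
        sv_df, tracks=ann["tracks"], genes=ann["genes"],
        tad_sets=ann["tad_sets"], master_tads=ann["master_tads"],
        elements=ann["elements"], enhancer_links=ann["enhancer_links"],
        known_genes=known_genes, span_alpha=span_alpha, fdr=fdr,
        min_points=min_points, seed=seed, intercept_only=intercept_only)
    os.makedirs(outdir, exist_ok=True)
    write_results(result.peaks, result.elements, outdir)
    write_curve_table(result, os.path.join(outdir, "adjusted_curve.tsv"))
    write_fit_reports(result, outdir)
    write_manifest(os.path.join(outdir, "manifest.json"),
                   params=result.params, inputs={"sv_table": sv_path},
                   log=result.log)
    return result


def write_fit_reports(result: PipelineResult, outdir) -> None:
    """GAM summary (JSON), partial-effect grids and PRs QQ data (TSV)."""
    import json

    fit = result.fit
    summary = {"explained_deviance": float(fit.explained_deviance),
               "edf": float(fit.edf), "phi": float(fit.phi),
               "lambdas": {k: float(v) for k, v in fit.lambdas.items()},
               "converged": bool(fit.converged),
               "terms": gam.term_significance(fit).to_dict(orient="records")}
    with open(os.path.join(outdir, "gam_summary.json"), "w") as fh:
        json.dump(summary, fh, indent=2, default=str)

    parts = []
    for t in fit.design.terms:
        if t.kind != "smooth":
            continue
        x = result.covariates[t.vars[0]].to_numpy(float) \
            if t.vars[0] in result.covariates else None
        if x is None:
            continue
        grid = np.linspace(np.nanmin(x), np.nanmax(x), 50)
        pe = gam.partial_effects(fit, t.name, grid)
        pe.insert(0, "term", t.name)
        parts.append(pe)
    if parts:
        pd.concat(parts, ignore_index=True).to_csv(
            os.path.join(outdir, "partial_effects.tsv"), sep="\t", index=False,
            float_format="%.6g")

    pk = result.peaks
    if len(pk) and pk["p_value"].notna().any():
        from scipy import stats as sps
        prs = np.sort(pk["prs"].to_numpy())
        prs = prs[prs > 0]
        null = peaks_mod.fit_gamma_null(prs)
        qth = sps.gamma.ppf((np.arange(1, len(prs) + 1) - 0.5) / len(prs),
                            null.shape, scale=null.scale)
        pd.DataFrame({"empirical": prs, "theoretical": qth}).to_csv(
            os.path.join(outdir, "qq_prs.tsv"), sep="\t", index=False,
            float_format="%.6g")


def write_curve_table(result: PipelineResult, path) -> None:
    """Serialize observed / expected / adjusted curves per breakpoint."""
    parts = []
    for c in sorted(result.adjusted):
        cur = result.curves[c]
        adj = result.adjusted[c]
        parts.append(pd.DataFrame({
            "chrom": c, "pos": cur.positions.astype(np.int64),
            "bpp": cur.observed, "bppc": cur.smoothed,
            "expected": cur.smoothed - adj.values, "adjusted": adj.values}))
    pd.concat(parts, ignore_index=True).to_csv(path, sep="\t", index=False,
                                               float_format=FLOAT_FMT)
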