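"""Rank functional elements inside significant peaks.

Within each significantly recurrent peak, every annotated element
(coding sequence, enhancer, CTCF insulator, lncRNA) is scored by

    ERS_SV = (Nsmp_E / Nsmp) * (Nsv_E / L_E)

where Nsv_E counts SVs in the peak whose genomic extent overlaps the
element, and — for coding genes, which can be disrupted by a break
inside the gene body even when no SV "covers" them —

    ERS_BP = (Nsmp_E / Nsmp) * (Nbp_E / L_E)

with Nbp_E the peak breakpoints falling inside the element.  For CDS
the larger of the two is the ranking score.  The top-scoring element of
each class is reported per peak; an optional known-cancer-gene list
breaks ties across classes.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import ELEMENT_COLUMNS, FormatError

logger = logging.getLogger(__name__)

ELEMENT_CLASSES = ("CDS", "enhancer", "CTCF-insulator", "lncRNA")


def read_elements(path) -> pd.DataFrame:
    """Read element annotations: BED-like TSV with
    (chrom, start, end, element_id, element_class[, gene_symbol])."""
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 5:
        raise FormatError("element file needs >= 5 columns")
    df = pd.DataFrame({
        "chrom": raw[0],
        "start": pd.to_numeric(raw[1]).astype(np.int64),
        "end": pd.to_numeric(raw[2]).astype(np.int64),
        "element_id": raw[3],
        "element_class": raw[4],
        "gene_symbol": raw[5] if raw.shape[1] > 5 else None,
    })
    bad = ~df["element_class"].isin(ELEMENT_CLASSES)
    if bad.any():
        raise FormatError(
            f"unknown element class {df['element_class'][bad].iloc[0]!r}")
    if (df["end"] <= df["start"]).any():
        raise FormatError("element with non-positive length")
    return df


def read_enhancer_links(path) -> dict:
    """Two-column TSV mapping enhancer element_id -> target gene symbol."""
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(raw[0], raw[1]))


def ers_sv(n_smp_e: int, n_smp: int, n_sv_e: int, length: int) -> float:
    """Element SV rearrangement score."""
    if length <= 0:
        raise ValueError("element length must be positive")
    if n_smp <= 0:
        raise ValueError("peak must contain at least one donor")
    return (n_smp_e / n_smp) * (n_sv_e / length)


def ers_bp(n_smp_e: int, n_smp: int, n_bp_e: int, length: int) -> float:
    """Element breakpoint rearrangement score (coding genes)."""
    if length <= 0:
        raise ValueError("element length must be positive")
    if n_smp <= 0:
        raise ValueError("peak must contain at least one donor")
    return (n_smp_e / n_smp) * (n_bp_e / length)


def sv_overlaps_interval(sv_row, chrom: str, start: int, end: int) -> bool:
    """Does one SV's genomic extent touch [start, end) on ``chrom``?

    Intra-chromosomal events use the span between their two breakends;
    a translocation has no contiguous span, so either breakend falling
    inside the interval counts.
    """
    c1, p1 = sv_row["chr_from"], sv_row["chr_from_bkpt_start"]
    c2, p2 = sv_row["chr_to"], sv_row["chr_to_bkpt_start"]
    if c1 == c2 and sv_row["variant_type"] != "TRA":
        if c1 != chrom:
            return False
        lo, hi = (p1, p2) if p1 <= p2 else (p2, p1)
        return lo < end and hi >= start
    return (c1 == chrom and start <= p1 < end) or \
           (c2 == chrom and start <= p2 < end)


def score_elements_in_peak(peak_row, elements: pd.DataFrame, sv_df: pd.DataFrame,
                           bp_table: pd.DataFrame) -> pd.DataFrame:
    """ERS scores for every element overlapping one peak's region."""
    chrom = peak_row["chrom"]
    p_start, p_end = peak_row["start"], peak_row["end"]
    n_smp = int(peak_row["n_smp"])
    bp_in_peak = bp_table[(bp_table["chrom"] == chrom)
                          & (bp_table["pos"] >= p_start)
                          & (bp_table["pos"] <= p_end)]
    sv_keys = set(zip(bp_in_peak["donor_id"], bp_in_peak["sv_id"]))
    key = list(zip(sv_df["donor_id"], sv_df["sv_id"]))
    svs_in_peak = sv_df[[k in sv_keys for k in key]]
    overlapping = elements[(elements["chrom"] == chrom)
                           & (elements["start"] <= p_end)
                           & (elements["end"] >= p_start)]
    rows = []
    for _, el in overlapping.iterrows():
        length = int(el["end"] - el["start"])
        hits = svs_in_peak[[
            sv_overlaps_interval(r, el["chrom"], el["start"], el["end"])
            for _, r in svs_in_peak.iterrows()
        ]] if len(svs_in_peak) else svs_in_peak
        n_sv_e = int(len(hits))
        n_smp_e = int(hits["donor_id"].nunique()) if n_sv_e else 0
        score_sv = ers_sv(n_smp_e, n_smp, n_sv_e, length)
        if el["element_class"] == "CDS":
            inside = bp_in_peak[(bp_in_peak["pos"] >= el["start"])
                                & (bp_in_peak["pos"] < el["end"])]
            n_bp_e = int(len(inside))
            score_bp = ers_bp(n_smp_e, n_smp, n_bp_e, length)
            best = max(score_sv, score_bp)
        else:
            n_bp_e, score_bp, best = 0, np.nan, score_sv
        rows.append({
            "peak_id": peak_row["peak_id"], "element_id": el["element_id"],
            "gene_symbol": el["gene_symbol"], "element_class": el["element_class"],
            "chrom": chrom, "start": int(el["start"]), "end": int(el["end"]),
            "n_smp_e": n_smp_e, "n_sv_e": n_sv_e, "n_bp_e": n_bp_e,
            "ers_sv": score_sv, "ers_bp": score_bp, "best_score": best,
        })
    return pd.DataFrame(rows)


def nominate_candidates(scores: pd.DataFrame, known_cancer_genes=None,
                        enhancer_links: dict | None = None) -> pd.DataFrame:
    """Rank scored elements and mark per-peak candidates.

    Within each peak and element class, elements are ranked by
    ``best_score`` (ties broken by higher Nsmp_E, then smaller length,
    then element id).  The rank-1 element of the peak's best class is
    marked ``most_likely``; when several classes tie at the top score,
    membership of the optional known-cancer-gene list (directly, or via
    an enhancer's target gene) decides.
    """
    if scores.empty:
        return pd.DataFrame(columns=ELEMENT_COLUMNS)
    known = set(known_cancer_genes or ())
    links = enhancer_links or {}
    scores = scores.copy()
    scores["_len"] = scores["end"] - scores["start"]
    scores = scores.sort_values(
        ["peak_id", "element_class", "best_score", "n_smp_e", "_len", "element_id"],
        ascending=[True, True, False, False, True, True], kind="mergesort")
    scores["rank_in_class"] = scores.groupby(
        ["peak_id", "element_class"]).cumcount() + 1
    scores["most_likely"] = False

    def linked_gene(row):
        if row["element_class"] == "enhancer":
            return links.get(row["element_id"], row["gene_symbol"])
        return row["gene_symbol"]

    for peak_id, sub in scores.groupby("peak_id"):
        top = sub[sub["rank_in_class"] == 1]
        if top.empty:
            continue
        best = top["best_score"].max()
        tied = top[np.isclose(top["best_score"], best)]
        if len(tied) > 1 and known:
            in_known = tied[[linked_gene(r) in known for _, r in tied.iterrows()]]
            pick = in_known.index[0] if len(in_known) else tied.index[0]
        else:
            pick = tied.index[0]
        scores.loc[pick, "most_likely"] = True
    return scores.drop(columns="_len")[ELEMENT_COLUMNS]


def annotate_drivers(peaks: pd.DataFrame, elements: pd.DataFrame,
                     sv_df: pd.DataFrame, bp_table: pd.DataFrame,
                     known_cancer_genes=None, enhancer_links=None,
                     significant_only: bool = True) -> pd.DataFrame:
    """Score and rank elements across all (significant) peaks."""
    if peaks.empty:
        return pd.DataFrame(columns=ELEMENT_COLUMNS)
    use = peaks[peaks["recurrent_significant"]] if significant_only else peaks
    parts = []
    for _, pk in use.iterrows():
        scored = score_elements_in_peak(pk, elements, sv_df, bp_table)
        if scored.empty:
            logger.info("peak %s contains no annotated element", pk["peak_id"])
            continue
        parts.append(scored)
    if not parts:
        return pd.DataFrame(columns=ELEMENT_COLUMNS)
    return nominate_candidates(pd.concat(parts, ignore_index=True),
                               known_cancer_genes, enhancer_links)
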