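"""Readers and writers for SV tables, interval tracks and result tables.

All genomic coordinates are held internally as 0-based half-open
intervals.  The 12-column SV table follows the PCAWG convention and is
1-based inclusive on disk; the conversion happens exactly once, on read.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Column names of the tab-separated SV input table, in file order.
SV_COLUMNS = [
    "cohort_code",
    "donor_id",
    "variant_type",
    "sv_id",
    "chr_from",
    "chr_from_bkpt_start",
    "chr_from_bkpt_end",
    "chr_from_strand",
    "chr_to",
    "chr_to_bkpt_start",
    "chr_to_bkpt_end",
    "chr_to_strand",
]

#: SV types accepted by the pipeline.
SV_TYPES = {"DEL", "DUP", "INS", "h2hINV", "t2tINV", "INV", "TRA"}

#: Chromosomes retained after filtering: autosomes and chromosome X.
ALLOWED_CHROMS = tuple(f"chr{i}" for i in range(1, 23)) + ("chrX",)


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def _normalize_chrom(c: str) -> str:
    c = str(c)
    return c if c.startswith("chr") else "chr" + c


def read_sv_table(path, cohort_filter: str | None = None) -> pd.DataFrame:
    """Read a 12-column SV table into a validated DataFrame.

    Rows with either breakend outside chr1..chr22/chrX are dropped; the
    drop count is logged and stored in ``df.attrs["n_dropped_chrom"]``.
    Coordinates are converted from 1-based inclusive to 0-based
    half-open.

    Parameters
    ----------
    path : str or file-like
        Tab-separated file with a header naming the 12 columns.
    cohort_filter : str, optional
        If given, keep only rows whose ``cohort_code`` matches.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse SV table {path!r}: {exc}") from exc
    if list(df.columns) != SV_COLUMNS:
        missing = [c for c in SV_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in SV_COLUMNS]
        raise FormatError(
            f"SV table must have exactly the 12 columns {SV_COLUMNS}; "
            f"missing={missing} extra={extra}"
        )
    if cohort_filter is not None:
        df = df[df["cohort_code"] == cohort_filter]
    df = df.copy()
    for col in ("chr_from_bkpt_start", "chr_from_bkpt_end",
                "chr_to_bkpt_start", "chr_to_bkpt_end"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            line = int(df.index[bad][0]) + 2  # header + 1-based
            raise FormatError(
                f"non-numeric coordinate in column {col!r} at line {line}"
            )
        df[col] = vals.astype(np.int64)
    df["chr_from"] = df["chr_from"].map(_normalize_chrom)
    df["chr_to"] = df["chr_to"].map(_normalize_chrom)

    keep = df["chr_from"].isin(ALLOWED_CHROMS) & df["chr_to"].isin(ALLOWED_CHROMS)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("dropped %d SV rows on chromosomes outside chr1..22,X", n_dropped)
    df = df[keep].reset_index(drop=True)

    # 1-based inclusive -> 0-based half-open
    for col in ("chr_from_bkpt_start", "chr_to_bkpt_start"):
        df[col] = df[col] - 1
    bad = (df["chr_from_bkpt_start"] > df["chr_from_bkpt_end"]) | (
        df["chr_to_bkpt_start"] > df["chr_to_bkpt_end"]
    )
    if bad.any():
        raise FormatError(f"breakend with start > end at row {int(df.index[bad][0])}")
    dup = df.duplicated(subset=["donor_id", "sv_id"])
    if dup.any():
        raise FormatError(
            f"duplicate sv_id within donor at row {int(df.index[dup][0])}"
        )
    df.attrs["n_dropped_chrom"] = n_dropped
    return df


def read_bedpe(path, cohort_code: str = "COHORT") -> pd.DataFrame:
    """Read a BEDPE file and map it onto the SV-table schema.

    Expects at least 10 columns (chrom1 start1 end1 chrom2 start2 end2
    name score strand1 strand2); the name field is used as ``sv_id``
    and, when formatted ``donor:svid``, split into donor and SV ids.
    BEDPE is already 0-based half-open, so coordinates pass through.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 10:
        raise FormatError("BEDPE needs >= 10 columns")
    name = raw[6].astype(str)
    donor = name.str.split(":", n=1).str[0]
    svid = name.str.split(":", n=1).str[-1]
    df = pd.DataFrame(
        {
            "cohort_code": cohort_code,
            "donor_id": donor,
            "variant_type": raw[7] if raw.shape[1] > 10 else "DEL",
            "sv_id": svid,
            "chr_from": raw[0].map(_normalize_chrom),
            "chr_from_bkpt_start": pd.to_numeric(raw[1]).astype(np.int64),
            "chr_from_bkpt_end": pd.to_numeric(raw[2]).astype(np.int64),
            "chr_from_strand": raw[8],
            "chr_to": raw[3].map(_normalize_chrom),
            "chr_to_bkpt_start": pd.to_numeric(raw[4]).astype(np.int64),
            "chr_to_bkpt_end": pd.to_numeric(raw[5]).astype(np.int64),
            "chr_to_strand": raw[9],
        }
    )
    keep = df["chr_from"].isin(ALLOWED_CHROMS) & df["chr_to"].isin(ALLOWED_CHROMS)
    df.attrs["n_dropped_chrom"] = int((~keep).sum())
    return df[keep].reset_index(drop=True)


def sv_to_breakpoints(records: pd.DataFrame) -> pd.DataFrame:
    """Decompose an SV table into a sorted per-chromosome breakpoint table.

    Every SV contributes exactly two breakpoints, one per breakend, at
    the breakend's start coordinate.  Identical coordinates from
    different donors are retained (each occurrence kept).  Output is
    sorted by (chrom, pos, donor_id, sv_id) — a stable, deterministic
    tie order for coincident positions.
    """
    ends = []
    for side in ("from", "to"):
        ends.append(
            pd.DataFrame(
                {
                    "chrom": records[f"chr_{side}"].to_numpy(),
                    "pos": records[f"chr_{side}_bkpt_start"].to_numpy(),
                    "donor_id": records["donor_id"].to_numpy(),
                    "sv_id": records["sv_id"].to_numpy(),
                    "variant_type": records["variant_type"].to_numpy(),
                    "breakend": 1 if side == "from" else 2,
                }
            )
        )
    bp = pd.concat(ends, ignore_index=True)
    bp = bp.sort_values(
        ["chrom", "pos", "donor_id", "sv_id", "breakend"], kind="mergesort"
    ).reset_index(drop=True)
    return bp


@dataclass
class IntervalTrack:
    """A named set of genomic intervals carrying a value or label.

    Intervals are half-open, 0-based, sorted per chromosome.  ``kind``
    is one of ``binary`` (value 1 on intervals), ``numeric`` or
    ``factor`` (string labels from a declared set).
    """

    name: str
    kind: str
    data: pd.DataFrame  # columns: chrom, start, end, value
    levels: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if self.kind not in ("binary", "numeric", "factor"):
            raise ValueError(f"unknown track kind {self.kind!r}")

    def chrom_arrays(self, chrom: str):
        """Return (starts, ends, values) arrays for one chromosome."""
        sub = self.data[self.data["chrom"] == chrom]
        return (
            sub["start"].to_numpy(np.int64),
            sub["end"].to_numpy(np.int64),
            sub["value"].to_numpy(),
        )

    def lookup(self, chrom, positions, default=None):
        """Point-in-interval lookup for sorted, non-overlapping intervals.

        Returns an array of values, with ``default`` where a position is
        covered by no interval.
        """
        positions = np.asarray(positions)
        starts, ends, values = self.chrom_arrays(chrom)
        if default is None:
            default = 0 if self.kind in ("binary", "numeric") else "none"
        out = np.full(positions.shape, default, dtype=object)
        if len(starts) == 0:
            return out
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, None)])
        out[ok] = values[idx[ok]]
        return out


def read_interval_track(path, kind: str, name: str | None = None,
                        levels: tuple = ()) -> IntervalTrack:
    """Read a BED3/BED4/bedGraph file as an :class:`IntervalTrack`.

    Three columns give a binary track; a fourth column gives labels
    (``factor``) or numbers (``numeric``).  Unsorted input is sorted
    with a warning; zero- or negative-length intervals are an error, as
    are overlapping intervals in a factor track.
    """
    raw = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if raw.shape[1] < 3:
        raise FormatError(f"{path}: BED-like file needs >= 3 columns")
    df = pd.DataFrame(
        {
            "chrom": raw[0].map(_normalize_chrom),
            "start": pd.to_numeric(raw[1]).astype(np.int64),
            "end": pd.to_numeric(raw[2]).astype(np.int64),
        }
    )
    if (df["start"] >= df["end"]).any():
        i = int(df.index[df["start"] >= df["end"]][0])
        raise FormatError(f"{path}: zero- or negative-length interval at row {i}")
    if kind == "binary" or raw.shape[1] == 3:
        df["value"] = 1
    elif kind == "numeric":
        df["value"] = pd.to_numeric(raw[3]).astype(float)
    else:
        df["value"] = raw[3].astype(str)
    sorted_df = df.sort_values(["chrom", "start"], kind="mergesort")
    if not sorted_df.index.equals(df.index):
        logger.warning("%s: intervals were not sorted; sorting", path)
    df = sorted_df.reset_index(drop=True)
    if kind == "factor":
        for _, sub in df.groupby("chrom"):
            if (sub["start"].to_numpy()[1:] < sub["end"].to_numpy()[:-1]).any():
                raise FormatError(f"{path}: overlapping intervals in factor track")
    track_name = name or os.path.splitext(os.path.basename(str(path)))[0]
    if kind == "factor" and not levels:
        levels = tuple(sorted(df["value"].unique()))
    return IntervalTrack(name=track_name, kind=kind, data=df, levels=tuple(levels))


def write_track(track: IntervalTrack, path) -> None:
    """Write an IntervalTrack back out as BED4/bedGraph."""
    track.data.to_csv(path, sep="\t", header=False, index=False)


PEAK_COLUMNS = [
    "chrom", "start", "end", "peak_id", "summit_pos", "summit_height",
    "peak_area", "peak_gr", "n_smp", "n_sv", "n_bp", "prs", "prs_sqrt",
    "p_value", "q_value", "ssrs", "ssrs_p", "ssrs_q",
    "recurrent_significant", "single_sample_significant", "single_or_two_sample",
]

ELEMENT_COLUMNS = [
    "peak_id", "element_id", "gene_symbol", "element_class", "chrom",
    "start", "end", "n_smp_e", "n_sv_e", "n_bp_e", "ers_sv", "ers_bp",
    "best_score", "rank_in_class", "most_likely",
]


def write_results(peaks: pd.DataFrame, elements: pd.DataFrame, outdir) -> dict:
    """Write the peak and element-score tables as TSV; return the paths.

    Numeric fields are written in full repr precision so a re-read
    round-trips to at least 6 decimals.
    """
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "peaks": os.path.join(outdir, "peaks.tsv"),
        "elements": os.path.join(outdir, "element_scores.tsv"),
    }
    pk = peaks if len(peaks) else pd.DataFrame(columns=PEAK_COLUMNS)
    el = elements if len(elements) else pd.DataFrame(columns=ELEMENT_COLUMNS)
    pk.to_csv(paths["peaks"], sep="\t", index=False, float_format="%.10g")
    el.to_csv(paths["elements"], sep="\t", index=False, float_format="%.10g")
    return paths


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path, params: dict, inputs: dict | None = None,
                   log: dict | None = None) -> None:
    """Write a JSON run manifest: parameters, seed, input checksums, log."""
    manifest = {
        "tool": "breakclust",
        "version": "0.1.0",
        "parameters": params,
        "inputs": {k: file_sha256(v) for k, v in (inputs or {}).items()
                   if v is not None and os.path.exists(str(v))},
        "log": log or {},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
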