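"""Per-breakpoint predictor assembly, including derived 3D-genome features.

Each breakpoint is annotated with the background-model predictors:
fragile-site and LAD membership, repeat class, 15-state chromatin mark,
replication timing, GC content (101-bp window), gene density (1-Mb
window), TAD and TAD-boundary recurrence across a panel of cell-type
TAD calls, and a three-level TAD-segment activity class.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .io import IntervalTrack

logger = logging.getLogger(__name__)

#: 15-state chromatin-mark vocabulary (Roadmap ChromHMM core model).
CHROMATIN_STATES = (
    "TssA", "TssAFlnk", "TxFlnk", "Tx", "TxWk", "EnhG", "Enh", "ZNF/Rpts",
    "Het", "TssBiv", "BivFlnk", "EnhBiv", "ReprPC", "ReprPCWk", "Quies",
)

#: Repeat-class vocabulary; "none" is the reference level outside repeats.
REPEAT_CLASSES = (
    "LTR", "LINE", "SINE", "LCR", "simple", "rDNA", "RNA-repeat",
    "satellite", "other", "unknown", "none",
)

TAD_SEGMENT_CLASSES = ("quiescent", "low-active", "active")

#: Fraction of the query TAD's length that a sample TAD must cover to count.
TAD_OVERLAP_FRACTION = 0.70


def _max_single_overlap(starts, ends, qs, qe):
    """Largest overlap of any single sorted interval with [qs, qe)."""
    if len(starts) == 0:
        return 0
    lo = np.searchsorted(ends, qs, side="right")
    hi = np.searchsorted(starts, qe, side="left")
    if lo >= hi:
        return 0
    ov = np.minimum(ends[lo:hi], qe) - np.maximum(starts[lo:hi], qs)
    return int(ov.max(initial=0))


def tad_recurrence(tad_sets, query_tads, overlap_fraction: float = TAD_OVERLAP_FRACTION):
    """Fraction of samples sharing each query TAD.

    A sample "contains" a query TAD when one of its own TADs overlaps at
    least ``overlap_fraction`` of the query TAD's length (the query's
    own length is the denominator, so nested calls still count).

    Parameters
    ----------
    tad_sets : list of DataFrame
        One per sample, columns (chrom, start, end).
    query_tads : DataFrame
        Columns (chrom, start, end).

    Returns
    -------
    ndarray of fractions in [0, 1], aligned with ``query_tads`` rows.
    """
    if len(tad_sets) == 0:
        raise ValueError("need at least one sample TAD set")
    by_sample = []
    for tads in tad_sets:
        per_chrom = {}
        for chrom, sub in tads.groupby("chrom"):
            sub = sub.sort_values("start")
            per_chrom[chrom] = (sub["start"].to_numpy(np.int64),
                                sub["end"].to_numpy(np.int64))
        by_sample.append(per_chrom)
    out = np.zeros(len(query_tads))
    for i, (chrom, qs, qe) in enumerate(
            zip(query_tads["chrom"], query_tads["start"], query_tads["end"])):
        need = overlap_fraction * (qe - qs)
        hits = 0
        for per_chrom in by_sample:
            starts, ends = per_chrom.get(chrom, (np.array([]), np.array([])))
            if _max_single_overlap(starts, ends, qs, qe) >= need:
                hits += 1
        out[i] = hits / len(tad_sets)
    return out


def segment_tads_by_recurrence(query_tads: pd.DataFrame) -> pd.DataFrame:
    """Partition TAD-covered territory into runs of constant recurrence.

    ``query_tads`` carries a ``recurrence`` column; overlapping TADs are
    cut at every TAD endpoint, each atomic piece takes the maximal
    recurrence among the TADs covering it, and adjacent pieces with
    equal value are merged.  Uncovered gaps are not emitted.
    """
    rows = []
    for chrom, sub in query_tads.groupby("chrom", sort=True):
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        rec = sub["recurrence"].to_numpy(float)
        cuts = np.unique(np.concatenate([starts, ends]))
        for a, b in zip(cuts[:-1], cuts[1:]):
            cover = (starts <= a) & (ends >= b)
            if not cover.any():
                continue
            rows.append((chrom, int(a), int(b), float(rec[cover].max())))
    seg = pd.DataFrame(rows, columns=["chrom", "start", "end", "recurrence"])
    # merge adjacent equal-valued segments
    merged = []
    for _, r in seg.iterrows():
        if (merged and merged[-1][0] == r["chrom"] and merged[-1][2] == r["start"]
                and merged[-1][3] == r["recurrence"]):
            merged[-1][2] = r["end"]
        else:
            merged.append([r["chrom"], r["start"], r["end"], r["recurrence"]])
    return pd.DataFrame(merged, columns=["chrom", "start", "end", "recurrence"])


def tad_boundaries(tads: pd.DataFrame, width: int = 50_000) -> pd.DataFrame:
    """Boundary intervals of ``width`` bp centred on each TAD endpoint."""
    half = width // 2
    pts = pd.concat([
        tads[["chrom"]].assign(pt=tads["start"]),
        tads[["chrom"]].assign(pt=tads["end"]),
    ])
    pts = pts.drop_duplicates().sort_values(["chrom", "pt"])
    return pd.DataFrame({
        "chrom": pts["chrom"].to_numpy(),
        "start": np.maximum(pts["pt"].to_numpy(np.int64) - half, 0),
        "end": pts["pt"].to_numpy(np.int64) + half,
    }).reset_index(drop=True)


def _coverage_fractions(segments: pd.DataFrame, track: IntervalTrack,
                        states=CHROMATIN_STATES) -> np.ndarray:
    """Per-segment coverage fraction of each factor level of a track."""
    state_index = {s: j for j, s in enumerate(states)}
    M = np.zeros((len(segments), len(states)))
    for chrom, sub in segments.groupby("chrom"):
        starts, ends, values = track.chrom_arrays(chrom)
        for i, (qs, qe) in zip(sub.index, zip(sub["start"], sub["end"])):
            if len(starts) == 0 or qe <= qs:
                continue
            lo = np.searchsorted(ends, qs, side="right")
            hi = np.searchsorted(starts, qe, side="left")
            ov = np.minimum(ends[lo:hi], qe) - np.maximum(starts[lo:hi], qs)
            for v, o in zip(values[lo:hi], ov):
                j = state_index.get(v)
                if j is not None and o > 0:
                    M[segments.index.get_loc(i), j] += o / (qe - qs)
    return M


_QUIES_STATES = ("Quies", "Het")
_ACTIVE_STATES = ("TssA", "Tx", "Enh")


def classify_tad_segments(segments: pd.DataFrame, chrom_mark_track: IntervalTrack,
                          random_state: int = 0) -> np.ndarray:
    """Label TAD segments quiescent / low-active / active from chromatin.

    Coverage fractions of the 15 chromatin states per segment are
    projected onto their top 3 principal components and clustered with
    k-means (k=3, fixed seed).  Clusters are named by mean coverage:
    highest Quies+Het mean is quiescent, highest TssA+Tx+Enh mean is
    active, the remainder low-active.  With fewer than 3 segments a
    direct coverage rule (majority of quiescent vs active states) is
    applied instead.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    M = _coverage_fractions(segments.reset_index(drop=True), chrom_mark_track)
    qi = [CHROMATIN_STATES.index(s) for s in _QUIES_STATES]
    ai = [CHROMATIN_STATES.index(s) for s in _ACTIVE_STATES]

    def direct_rule(row):
        q, a = row[qi].sum(), row[ai].sum()
        if q >= 0.5 and q >= a:
            return "quiescent"
        if a >= 0.5 and a > q:
            return "active"
        return "low-active"

    if len(segments) < 3:
        return np.array([direct_rule(r) for r in M])

    n_comp = min(3, M.shape[1], len(segments))
    Z = PCA(n_components=n_comp, random_state=random_state).fit_transform(M)
    km = KMeans(n_clusters=3, n_init=10, random_state=random_state).fit(Z)
    labels = km.labels_
    q_mean = np.array([M[labels == c][:, qi].sum(axis=1).mean() for c in range(3)])
    a_mean = np.array([M[labels == c][:, ai].sum(axis=1).mean() for c in range(3)])
    names = np.array(["low-active"] * 3, dtype=object)
    names[int(q_mean.argmax())] = "quiescent"
    # active = highest active-state mean among the remaining clusters
    rest = [c for c in range(3) if names[c] == "low-active"]
    names[rest[int(a_mean[rest].argmax())]] = "active"
    return names[labels]


def gc_content(fasta, chrom: str, positions, window: int = 101):
    """GC fraction of the ``window``-bp sequence centred at each position.

    ``fasta`` is a ``pyfaidx.Fasta`` (or any mapping of chrom to
    sequence string).  N bases are excluded from the denominator; a
    fully-N window yields NaN.
    """
    half = window // 2
    out = np.empty(len(positions))
    seq_full = str(fasta[chrom][:])
    L = len(seq_full)
    for i, pos in enumerate(positions):
        a, b = max(0, int(pos) - half), min(L, int(pos) + half + 1)
        s = seq_full[a:b].upper()
        gc = s.count("G") + s.count("C")
        acgt = gc + s.count("A") + s.count("T")
        out[i] = gc / acgt if acgt else np.nan
    return out


def gene_density(genes: pd.DataFrame, chrom: str, positions,
                 bin_size: int = 1_000_000) -> np.ndarray:
    """Genes per 1-Mb window: count of genes overlapping the bin of each
    position.  A gene spanning two bins counts in both."""
    positions = np.asarray(positions, dtype=np.int64)
    sub = genes[genes["chrom"] == chrom]
    if len(sub) == 0:
        return np.zeros(len(positions))
    gs = sub["start"].to_numpy(np.int64)
    ge = sub["end"].to_numpy(np.int64)
    bins = positions // bin_size
    out = np.empty(len(positions))
    uniq, inv = np.unique(bins, return_inverse=True)
    counts = np.array([
        int(((gs < (b + 1) * bin_size) & (ge > b * bin_size)).sum()) for b in uniq
    ])
    out[:] = counts[inv]
    return out


#: Covariate schema: name -> (kind, reference value when uncovered/missing).
COVARIATE_SCHEMA = {
    "FS": ("binary", 0),
    "LAD": ("binary", 0),
    "repClass": ("factor", "none"),
    "ChromMark": ("factor", "Quies"),
    "RT": ("numeric", np.nan),
    "GC": ("numeric", np.nan),
    "GeneDensity": ("numeric", np.nan),
    "TAD_recurr": ("numeric", 0.0),
    "TADB_recurr": ("numeric", 0.0),
    "TADsegm_class": ("factor", "quiescent"),
}


def annotate_breakpoints(bp_table: pd.DataFrame, tracks: dict,
                         genes: pd.DataFrame | None = None,
                         fasta=None) -> pd.DataFrame:
    """Assemble the covariate table, one row per breakpoint.

    ``tracks`` maps covariate names from :data:`COVARIATE_SCHEMA` to
    :class:`IntervalTrack` objects.  GeneDensity is derived from
    ``genes`` when given (else from a numeric track), GC from ``fasta``
    when given (else from a numeric track).  Positions covered by no
    interval take the schema's reference value; per-covariate
    missingness counts are stored in ``result.attrs["missing_counts"]``.
    """
    n = len(bp_table)
    cols = {}
    missing = {}
    for name, (kind, ref) in COVARIATE_SCHEMA.items():
        if name == "GeneDensity" and genes is not None:
            vals = np.empty(n)
            for chrom, sub in bp_table.groupby("chrom"):
                vals[bp_table["chrom"] == chrom] = gene_density(
                    genes, chrom, sub["pos"].to_numpy())
            cols[name] = vals
            missing[name] = 0
            continue
        if name == "GC" and fasta is not None:
            vals = np.empty(n)
            for chrom, sub in bp_table.groupby("chrom"):
                vals[bp_table["chrom"] == chrom] = gc_content(
                    fasta, chrom, sub["pos"].to_numpy())
            cols[name] = vals
            missing[name] = int(np.isnan(vals).sum())
            continue
        track = tracks.get(name)
        if track is None:
            logger.warning("covariate %s: no track supplied; reference value used", name)
            cols[name] = np.full(n, ref, dtype=object if kind == "factor" else float)
            missing[name] = n
            continue
        sentinel = "__missing__" if kind == "factor" else np.nan
        vals = np.empty(n, dtype=object)
        for chrom, sub in bp_table.groupby("chrom"):
            vals[(bp_table["chrom"] == chrom).to_numpy()] = track.lookup(
                chrom, sub["pos"].to_numpy(), default=sentinel)
        if kind == "factor":
            miss = vals == sentinel
            vals[miss] = ref
            cols[name] = vals.astype(str)
            missing[name] = int(miss.sum())
        else:
            arr = vals.astype(float)
            miss = np.isnan(arr)
            if not np.isnan(ref):
                arr[miss] = ref
            cols[name] = arr
            # outside a binary track's intervals is the value 0, not missing
            missing[name] = 0 if kind == "binary" else int(miss.sum())
    cov = pd.DataFrame(cols, index=bp_table.index)
    cov.attrs["missing_counts"] = missing
    return cov
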