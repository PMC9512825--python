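"""Synthetic SV cohorts and covariate tracks with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
piecewise-constant covariate tracks with realistic autocorrelation
(Markov-chain factor tracks, random-walk replication timing), a panel
of per-sample TAD partitions whose boundary conservation yields
Beta-like recurrence, background breakpoints drawn from an
inhomogeneous intensity that depends on the covariates through a
log-linear link (with multiplicative Gamma noise), and driver loci
injected at a stated prevalence with Gaussian breakpoint jitter.

Default conditions are scaled to a desk-size genome: twenty 25-Mb
chromosomes, 200 donors, 25 background SVs per donor (the per-donor
SV burden of a heavily rearranged cancer cohort, scaled so that each
chromosome carries a few hundred breakpoints and injected clusters
remain a small minority of all rows), five 100-kb driver loci at 25%
prevalence.  Every output is serializable in
exactly the formats the readers consume, and a given seed reproduces
the SV table byte for byte.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import CHROMATIN_STATES, REPEAT_CLASSES
from .io import SV_COLUMNS, IntervalTrack

BIN = 10_000                      # resolution of the intensity field (bp)


@dataclass
class Driver:
    """One injected driver locus."""

    chrom: str
    start: int
    end: int
    prevalence: float = 0.25
    sv_type: str = "DEL"
    jitter_sd: float = 5_000.0

    def __post_init__(self):
        if not 0 < self.prevalence <= 1:
            raise ValueError("prevalence must be in (0, 1]")
        if self.end <= self.start:
            raise ValueError("driver locus must have positive width")


def default_drivers(chrom_lengths: dict) -> list:
    """Five 100-kb loci spread round-robin over the genome, 25% prevalence."""
    chroms = sorted(chrom_lengths)
    fracs = [0.15, 0.45, 0.75, 0.3, 0.6]
    out = []
    for i, f in enumerate(fracs):
        chrom = chroms[i % len(chroms)]
        mid = int(f * chrom_lengths[chrom])
        out.append(Driver(chrom=chrom, start=mid - 50_000, end=mid + 50_000))
    return out


#: Log-linear coefficients of the background intensity.
DEFAULT_COEFS = {
    "RT": 0.35,          # later-replicating regions break more
    "GeneDensity": 0.04,
    "LAD": 0.4,
    "FS": 0.8,           # fragile sites are hotspots
    "active_chromatin": -0.3,
}

#: Background SV type mix (DEL-dominant, with translocations).
TYPE_MIX = {"DEL": 0.45, "DUP": 0.20, "INS": 0.05,
            "h2hINV": 0.10, "t2tINV": 0.10, "TRA": 0.10}

#: Median SV size (bp) and log-sd per intra-chromosomal type.
SIZE_MODEL = {"DEL": (30_000, 1.2), "DUP": (50_000, 1.2), "INS": (500, 0.8),
              "h2hINV": (40_000, 1.2), "t2tINV": (40_000, 1.2)}

_STRANDS = {"DEL": ("+", "-"), "DUP": ("-", "+"), "INS": ("+", "-"),
            "h2hINV": ("+", "+"), "t2tINV": ("-", "-"), "TRA": ("+", "-")}


@dataclass
class SimConfig:
    """Full specification of a synthetic cohort."""

    seed: int = 0
    cohort_code: str = "SIM"
    n_donors: int = 200
    chrom_lengths: dict = field(default_factory=lambda: {
        f"chr{i}": 25_000_000 for i in range(1, 21)})
    mean_svs_per_donor: float = 25.0
    drivers: list | None = None           # None -> default_drivers; [] -> none
    coefs: dict = field(default_factory=lambda: dict(DEFAULT_COEFS))
    noise_shape: float = 20.0             # Gamma overdispersion of intensity
    link: str = "log"                     # "log" or "identity"
    n_tad_samples: int = 37
    tad_boundary_conservation: tuple = (2.5, 1.0)   # Beta(a, b) per TAD/boundary

    def __post_init__(self):
        if self.drivers is None:
            self.drivers = default_drivers(self.chrom_lengths)
        for d in self.drivers:
            if d.end > self.chrom_lengths[d.chrom]:
                raise ValueError(f"driver locus outside {d.chrom}")
        if self.link not in ("log", "identity"):
            raise ValueError("link must be 'log' or 'identity'")


@dataclass
class SimAnnotations:
    """Everything the pipeline consumes besides the SV table."""

    tracks: dict                   # covariate name -> IntervalTrack
    genes: pd.DataFrame            # chrom, start, end, gene_symbol
    tad_sets: list                 # per-sample TAD DataFrames
    master_tads: pd.DataFrame      # the query TAD partition
    elements: pd.DataFrame         # element annotation table
    enhancer_links: dict


def _markov_track(rng, chrom_lengths, labels, base_freq, seg_len, name,
                  stay: float = 0.7) -> IntervalTrack:
    """Piecewise-constant factor track from a sticky Markov chain.

    Jumps resample from ``base_freq``, so the stationary label
    distribution equals ``base_freq``.
    """
    rows = []
    labels = list(labels)
    p = np.asarray(base_freq, dtype=float)
    p = p / p.sum()
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        pos = 0
        state = rng.choice(len(labels), p=p)
        while pos < L:
            length = max(int(rng.exponential(seg_len)), BIN)
            end = min(pos + length, L)
            rows.append((chrom, pos, end, labels[state]))
            if rng.random() > stay:
                state = rng.choice(len(labels), p=p)
            pos = end
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return IntervalTrack(name=name, kind="factor", data=df, levels=tuple(labels))


def _binary_intervals(rng, chrom_lengths, rate_per_mb, width_mean, name):
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n = rng.poisson(rate_per_mb * L / 1e6)
        starts = np.sort(rng.integers(0, L, size=n))
        for s in starts:
            w = max(int(rng.exponential(width_mean)), BIN)
            rows.append((chrom, int(s), min(int(s) + w, L), 1))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    # merge overlaps so the binary track stays non-overlapping
    merged = []
    for chrom, sub in df.groupby("chrom", sort=True):
        cur = None
        for _, r in sub.sort_values("start").iterrows():
            if cur is None or r["start"] > cur[2]:
                if cur:
                    merged.append(cur)
                cur = [chrom, r["start"], r["end"], 1]
            else:
                cur[2] = max(cur[2], r["end"])
        if cur:
            merged.append(cur)
    return IntervalTrack(name=name, kind="binary",
                         data=pd.DataFrame(merged, columns=df.columns))


def _rw_track(rng, chrom_lengths, bin_size, scale, name, smooth=5):
    """Numeric track from a smoothed Gaussian random walk."""
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n = int(np.ceil(L / bin_size))
        walk = np.cumsum(rng.normal(0, scale, size=n))
        if smooth > 1:
            kernel = np.ones(smooth) / smooth
            walk = np.convolve(walk, kernel, mode="same")
        walk = walk - walk.mean()
        for i, v in enumerate(walk):
            rows.append((chrom, i * bin_size, min((i + 1) * bin_size, L), float(v)))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "value"])
    return IntervalTrack(name=name, kind="numeric", data=df)


def _gc_track(rng, chrom_lengths, name="GC"):
    rows = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n = int(np.ceil(L / (10 * BIN)))
        x = 0.0
        vals = np.empty(n)
        for i in range(n):
            x = 0.9 * x + rng.normal(0, 0.02)
            vals[i] = np.clip(0.41 + x, 0.30, 0.60)
        for i, v in enumerate(vals):
            rows.append((chrom, i * 10 * BIN, min((i + 1) * 10 * BIN, L), float(v)))
    return IntervalTrack(name=name, kind="numeric",
                         data=pd.DataFrame(rows, columns=["chrom", "start", "end", "value"]))


def _simulate_genes(rng, chrom_lengths, per_mb=7.0):
    rows = []
    gi = 0
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n = rng.poisson(per_mb * L / 1e6)
        starts = np.sort(rng.integers(0, L, size=n))
        for s in starts:
            length = int(rng.lognormal(np.log(30_000), 1.0))
            rows.append((chrom, int(s), min(int(s) + max(length, 1_000), L),
                         f"GENE{gi:05d}"))
            gi += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_symbol"])


def _simulate_tads(rng, config):
    """Master TAD partition plus per-sample perturbed partitions."""
    master_rows = []
    boundaries = {}
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        pts = [0]
        while pts[-1] < L:
            pts.append(pts[-1] + int(np.clip(rng.exponential(1e6), 3e5, 4e6)))
        pts[-1] = L
        boundaries[chrom] = np.array(pts)
        for a, b in zip(pts[:-1], pts[1:]):
            master_rows.append((chrom, a, b))
    master = pd.DataFrame(master_rows, columns=["chrom", "start", "end"])
    a, b = config.tad_boundary_conservation
    conserve = {c: rng.beta(a, b, size=len(p)) for c, p in boundaries.items()}
    # per-TAD structural variability: a disrupted sample gains an internal
    # boundary, splitting the domain so neither piece covers 70% of it
    disrupt = {c: 1.0 - rng.beta(a, b, size=len(p) - 1)
               for c, p in boundaries.items()}
    tad_sets = []
    for _ in range(config.n_tad_samples):
        rows = []
        for chrom, pts in boundaries.items():
            keep = rng.random(len(pts)) < conserve[chrom]
            keep[0] = keep[-1] = True
            sample_pts = list(pts[keep].astype(float))
            jitter = rng.normal(0, 50_000, size=len(sample_pts))
            jitter[0] = jitter[-1] = 0
            sample_pts = list(np.asarray(sample_pts) + jitter)
            for t in np.flatnonzero(rng.random(len(pts) - 1) < disrupt[chrom]):
                lo, hi = pts[t], pts[t + 1]
                frac = rng.uniform(0.35, 0.65)
                sample_pts.append(lo + frac * (hi - lo))
            sample_pts = np.sort(np.clip(np.array(sample_pts), 0,
                                         config.chrom_lengths[chrom]))
            for s, e in zip(sample_pts[:-1], sample_pts[1:]):
                if e - s >= BIN:
                    rows.append((chrom, int(s), int(e)))
        tad_sets.append(pd.DataFrame(rows, columns=["chrom", "start", "end"]))
    return master, tad_sets


def _simulate_elements(rng, config, genes):
    """Element annotations; a CDS gene is planted at every driver locus.

    Background elements never intersect a driver locus: the planted
    element is the locus's only annotation, so recovery benchmarks have
    an unambiguous truth label (two co-deleted elements are otherwise
    indistinguishable to a rearrangement score).
    """
    rows = []
    ei = 0

    def in_driver(chrom, start, end):
        return any(d.chrom == chrom and start < d.end and end > d.start
                   for d in config.drivers)

    def add(chrom, start, end, cls, gene):
        nonlocal ei
        rows.append((chrom, int(start), int(end), f"{cls.replace('-', '')}_{ei:05d}",
                     cls, gene))
        ei += 1

    cds_mask = rng.random(len(genes)) < 0.3
    for _, g in genes[cds_mask].iterrows():
        if in_driver(g["chrom"], g["start"], g["end"]):
            continue
        add(g["chrom"], g["start"], g["end"], "CDS", g["gene_symbol"])
    links = {}
    for chrom in sorted(config.chrom_lengths):
        L = config.chrom_lengths[chrom]
        for cls, per_mb, width in (("enhancer", 2.0, 3_000),
                                   ("CTCF-insulator", 2.0, 500),
                                   ("lncRNA", 0.5, 10_000)):
            n = rng.poisson(per_mb * L / 1e6)
            for s in np.sort(rng.integers(0, L, size=n)):
                if in_driver(chrom, s, s + width):
                    continue
                gene = None
                if cls == "enhancer" and rng.random() < 0.5 and len(genes):
                    gene = genes["gene_symbol"].iloc[int(rng.integers(len(genes)))]
                add(chrom, s, min(s + width, L), cls, gene)
                if gene is not None:
                    links[rows[-1][3]] = gene
    for k, d in enumerate(config.drivers):
        add(d.chrom, d.start, d.end, "CDS", f"DRIVER{k:02d}")
    elements = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "element_id", "element_class",
                       "gene_symbol"])
    return elements.sort_values(["chrom", "start"]).reset_index(drop=True), links


def simulate_covariates(config: SimConfig) -> SimAnnotations:
    """Generate all covariate tracks and annotations for a config.

    Uses a dedicated random stream (seed + 1) so covariates are
    identical whether or not a cohort is drawn afterwards.
    """
    rng = np.random.default_rng(config.seed + 1)
    cl = config.chrom_lengths
    # Quies-heavy chromatin state mix
    freq = np.array([0.03, 0.02, 0.01, 0.05, 0.08, 0.02, 0.04, 0.01,
                     0.08, 0.01, 0.01, 0.02, 0.04, 0.08, 0.50])
    rep_freq = np.array([0.08, 0.17, 0.11, 0.02, 0.02, 0.01, 0.01,
                         0.02, 0.02, 0.04, 0.50])
    tracks = {
        "FS": _binary_intervals(rng, cl, rate_per_mb=0.05, width_mean=1.5e6,
                                name="FS"),
        "LAD": _binary_intervals(rng, cl, rate_per_mb=0.3, width_mean=1.2e6,
                                 name="LAD"),
        "repClass": _markov_track(rng, cl, REPEAT_CLASSES, rep_freq,
                                  seg_len=60_000, name="repClass"),
        "ChromMark": _markov_track(rng, cl, CHROMATIN_STATES, freq,
                                   seg_len=100_000, name="ChromMark"),
        "RT": _rw_track(rng, cl, bin_size=1_000_000, scale=0.3, name="RT"),
        "GC": _gc_track(rng, cl),
    }
    genes = _simulate_genes(rng, cl)
    master, tad_sets = _simulate_tads(rng, config)
    elements, links = _simulate_elements(rng, config, genes)
    return SimAnnotations(tracks=tracks, genes=genes, tad_sets=tad_sets,
                          master_tads=master, elements=elements,
                          enhancer_links=links)


def _intensity_field(config, ann):
    """Per-bin sampling probabilities of background breakends."""
    from .covariates import gene_density

    chroms = sorted(config.chrom_lengths)
    fields = {}
    for chrom in chroms:
        L = config.chrom_lengths[chrom]
        centers = np.arange(BIN // 2, L, BIN)
        lp = np.zeros(len(centers))
        c = config.coefs
        rt = ann.tracks["RT"].lookup(chrom, centers, default=0.0).astype(float)
        lad = ann.tracks["LAD"].lookup(chrom, centers, default=0).astype(float)
        fs = ann.tracks["FS"].lookup(chrom, centers, default=0).astype(float)
        marks = ann.tracks["ChromMark"].lookup(chrom, centers, default="Quies")
        active = np.isin(marks.astype(str), ("TssA", "Tx", "Enh")).astype(float)
        gd = gene_density(ann.genes, chrom, centers)
        lp += (c.get("RT", 0) * rt + c.get("LAD", 0) * lad
               + c.get("FS", 0) * fs + c.get("active_chromatin", 0) * active
               + c.get("GeneDensity", 0) * gd)
        if config.link == "log":
            w = np.exp(lp - lp.max())
        else:
            w = np.maximum(1.0 + lp, 1e-3)
        fields[chrom] = w
    return fields


def simulate_cohort(config: SimConfig, ann: SimAnnotations) -> pd.DataFrame:
    """Draw the SV cohort (internal 0-based schema, ready for decomposition).

    Per donor the background SV count is Poisson; first breakends
    follow the covariate-driven intensity (with per-bin multiplicative
    Gamma noise shared across donors); partner breakends sit at a
    log-normal type-specific distance, translocations jump to a
    different chromosome.  Driver loci then receive one SV in a
    Bernoulli(prevalence) subset of donors, breakends at the locus ends
    plus Gaussian jitter.
    """
    rng = np.random.default_rng(config.seed)
    fields = _intensity_field(config, ann)
    chroms = sorted(config.chrom_lengths)
    noisy = {}
    for chrom in chroms:
        w = fields[chrom] * rng.gamma(config.noise_shape,
                                      1.0 / config.noise_shape,
                                      size=len(fields[chrom]))
        noisy[chrom] = w
    chrom_w = np.array([noisy[c].sum() for c in chroms], dtype=float)
    chrom_p = chrom_w / chrom_w.sum()
    bin_p = {c: noisy[c] / noisy[c].sum() for c in chroms}

    types = list(TYPE_MIX)
    type_p = np.array([TYPE_MIX[t] for t in types])
    rows = []

    def draw_pos(rng, chrom):
        b = rng.choice(len(bin_p[chrom]), p=bin_p[chrom])
        return int(b) * BIN + int(rng.integers(0, BIN))

    for d in range(config.n_donors):
        donor = f"DO{d:04d}"
        n_sv = rng.poisson(config.mean_svs_per_donor)
        for k in range(n_sv):
            chrom = chroms[rng.choice(len(chroms), p=chrom_p)]
            pos1 = draw_pos(rng, chrom)
            t = types[rng.choice(len(types), p=type_p)]
            if t == "TRA" and len(chroms) > 1:
                others = [c for c in chroms if c != chrom]
                chrom2 = others[int(rng.integers(len(others)))]
                pos2 = draw_pos(rng, chrom2)
            else:
                if t == "TRA":
                    t = "DEL"
                med, sd = SIZE_MODEL[t]
                size = int(rng.lognormal(np.log(med), sd))
                direction = 1 if rng.random() < 0.5 else -1
                pos2 = int(np.clip(pos1 + direction * size, 0,
                                   config.chrom_lengths[chrom] - 1))
                chrom2 = chrom
            s1, s2 = _STRANDS[t]
            rows.append((config.cohort_code, donor, t, f"sv_{donor}_{k:04d}",
                         chrom, pos1, pos1 + 1, s1, chrom2, pos2, pos2 + 1, s2))
    # driver injection
    for j, drv in enumerate(config.drivers):
        carriers = np.flatnonzero(rng.random(config.n_donors) < drv.prevalence)
        for d in carriers:
            donor = f"DO{d:04d}"
            L = config.chrom_lengths[drv.chrom]
            p1 = int(np.clip(rng.normal(drv.start, drv.jitter_sd), 0, L - 2))
            p2 = int(np.clip(rng.normal(drv.end, drv.jitter_sd), 0, L - 1))
            if p2 <= p1:
                p2 = p1 + 1
            s1, s2 = _STRANDS[drv.sv_type]
            rows.append((config.cohort_code, donor, drv.sv_type,
                         f"sv_{donor}_drv{j}", drv.chrom, p1, p1 + 1, s1,
                         drv.chrom, p2, p2 + 1, s2))
    df = pd.DataFrame(rows, columns=[
        "cohort_code", "donor_id", "variant_type", "sv_id",
        "chr_from", "chr_from_bkpt_start", "chr_from_bkpt_end", "chr_from_strand",
        "chr_to", "chr_to_bkpt_start", "chr_to_bkpt_end", "chr_to_strand"])
    return df


def write_sv_table(sv_df: pd.DataFrame, path) -> None:
    """Serialize to the on-disk 12-column convention (1-based inclusive)."""
    out = sv_df.copy()
    out["chr_from_bkpt_start"] = out["chr_from_bkpt_start"] + 1
    out["chr_from_bkpt_end"] = out["chr_from_bkpt_end"]
    out["chr_to_bkpt_start"] = out["chr_to_bkpt_start"] + 1
    out["chr_to_bkpt_end"] = out["chr_to_bkpt_end"]
    out.to_csv(path, sep="\t", index=False, columns=SV_COLUMNS)


def write_annotations(ann: SimAnnotations, outdir) -> dict:
    """Serialize tracks, genes, TAD sets and elements under ``outdir``."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for name, track in ann.tracks.items():
        p = os.path.join(outdir, f"{name}.bed")
        track.data.to_csv(p, sep="\t", header=False, index=False)
        paths[name] = p
    p = os.path.join(outdir, "genes.bed")
    ann.genes.to_csv(p, sep="\t", header=False, index=False)
    paths["genes"] = p
    tad_dir = os.path.join(outdir, "tads")
    os.makedirs(tad_dir, exist_ok=True)
    for i, tads in enumerate(ann.tad_sets):
        tp = os.path.join(tad_dir, f"sample_{i:02d}.bed")
        tads.to_csv(tp, sep="\t", header=False, index=False)
    paths["tads"] = tad_dir
    p = os.path.join(outdir, "master_tads.bed")
    ann.master_tads.to_csv(p, sep="\t", header=False, index=False)
    paths["master_tads"] = p
    p = os.path.join(outdir, "elements.tsv")
    ann.elements.to_csv(p, sep="\t", header=False, index=False)
    paths["elements"] = p
    p = os.path.join(outdir, "enhancer_links.tsv")
    pd.Series(ann.enhancer_links).to_csv(p, sep="\t", header=False)
    paths["enhancer_links"] = p
    return paths


def simulate(config: SimConfig, outdir=None):
    """Covariates plus cohort in one call; optionally serialized."""
    ann = simulate_covariates(config)
    sv_df = simulate_cohort(config, ann)
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        write_sv_table(sv_df, os.path.join(outdir, "sv_table.tsv"))
        write_annotations(ann, os.path.join(outdir, "annotations"))
    return sv_df, ann
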