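"""Peak calling and significance on the adjusted proximity curve.

The adjusted curve (observed minus expected proximity) is segmented at
zero crossings; within each positive excursion the peak region is the
contiguous run around the summit where the curve stays above 75% of the
summit height.  Each peak is scored by its recurrence score

    PRs = (Nsmp / Nsv) * (Peak_A / Peak_GR)

which is large for tight clusters contributed by many donors through
few SVs.  The cohort-wide PRs values are fitted with a Gamma null by
maximum likelihood (the square-root transform is kept alongside as the
dispersion-reducing display scale for QQ plots); upper-tail p-values
pass through Benjamini-Hochberg with FDR < 0.2.  The single-sample score SSRs = N_BP / Nsmp flags peaks
whose breakpoint load comes from unexpectedly few donors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PEAK_COLUMNS

logger = logging.getLogger(__name__)

SUMMIT_FRACTION = 0.75       # peak region: curve >= this fraction of summit
FDR_THRESHOLD = 0.2
MIN_PEAKS_FOR_NULL = 10
AREA_SCALE = 1e6             # trapezoid area reported per-Mb


@dataclass
class AdjustedCurve:
    """Observed minus expected proximity on one chromosome's support."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.positions) != len(self.values):
            raise ValueError("positions and values must align")


def adjust_curve(observed, expected) -> AdjustedCurve:
    """Pointwise observed-minus-expected curve.

    ``observed`` is a :class:`~breakclust.proximity.ProximityCurve`;
    ``expected`` the aligned expected proximity values (same support).
    """
    expected = np.asarray(expected, dtype=float)
    if len(expected) != len(observed.positions):
        raise ValueError(
            f"{observed.chrom}: expected values ({len(expected)}) do not align "
            f"with curve support ({len(observed.positions)})")
    return AdjustedCurve(chrom=observed.chrom,
                         positions=np.asarray(observed.positions, dtype=float),
                         values=np.asarray(observed.smoothed, dtype=float) - expected)


@dataclass
class PeakRegion:
    """Geometry of one called peak (indices into the curve support)."""

    chrom: str
    first: int                  # first index of the region (inclusive)
    last: int                   # last index of the region (inclusive)
    summit_idx: int
    start: float                # genomic start of region
    end: float                  # genomic end of region
    summit_pos: float
    summit_height: float
    peak_area: float            # trapezoid integral over region, per Mb
    peak_gr: float              # genomic range of region (bp)


def call_peaks(adjusted: AdjustedCurve,
               summit_fraction: float = SUMMIT_FRACTION) -> list:
    """Segment positive excursions and extract summit-top regions.

    Returns peaks in left-to-right order.  An everywhere non-positive
    curve yields an empty list.
    """
    v = adjusted.values
    pos = adjusted.positions
    peaks = []
    positive = v > 0
    if not positive.any():
        return peaks
    # contiguous runs of positive values
    padded = np.r_[False, positive, False].astype(np.int8)
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1) - 1
    for s, e in zip(starts, ends):
        summit = s + int(np.argmax(v[s:e + 1]))
        h = v[summit]
        thr = summit_fraction * h
        lo = summit
        while lo > s and v[lo - 1] >= thr:
            lo -= 1
        hi = summit
        while hi < e and v[hi + 1] >= thr:
            hi += 1
        # region boundaries by linear interpolation at the threshold
        # crossing, so narrow summits keep a positive range and area
        if lo > 0 and v[lo - 1] < thr and pos[lo] > pos[lo - 1]:
            x_left = pos[lo] - (pos[lo] - pos[lo - 1]) * \
                (v[lo] - thr) / (v[lo] - v[lo - 1])
            xs = np.r_[x_left, pos[lo:hi + 1]]
            vs = np.r_[thr, v[lo:hi + 1]]
        else:
            xs = pos[lo:hi + 1]
            vs = v[lo:hi + 1]
        if hi < len(v) - 1 and v[hi + 1] < thr and pos[hi + 1] > pos[hi]:
            x_right = pos[hi] + (pos[hi + 1] - pos[hi]) * \
                (v[hi] - thr) / (v[hi] - v[hi + 1])
            xs = np.r_[xs, x_right]
            vs = np.r_[vs, thr]
        gr = float(xs[-1] - xs[0])
        if gr <= 0:
            gr = 1.0      # coincident support; keep the peak, unit range
        area = float(np.trapezoid(vs, xs)) / AREA_SCALE
        peaks.append(PeakRegion(
            chrom=adjusted.chrom, first=lo, last=hi, summit_idx=summit,
            start=float(xs[0]), end=float(xs[-1]), summit_pos=float(pos[summit]),
            summit_height=float(h), peak_area=area, peak_gr=gr))
    return peaks


def count_peak_members(peak: PeakRegion, bp_chrom: pd.DataFrame) -> dict:
    """Unique donors / SVs / breakpoints whose position lies in the region."""
    sel = bp_chrom[(bp_chrom["pos"] >= peak.start) & (bp_chrom["pos"] <= peak.end)]
    sv_key = sel["donor_id"].astype(str) + "\t" + sel["sv_id"].astype(str)
    return {"n_smp": int(sel["donor_id"].nunique()),
            "n_sv": int(sv_key.nunique()),
            "n_bp": int(len(sel))}


def peak_recurrence_score(n_smp: int, n_sv: int, peak_area: float,
                          peak_gr: float) -> tuple:
    """PRs and its square-root transform."""
    if n_sv == 0:
        raise ValueError("peak with no SVs cannot be scored")
    if peak_gr <= 0:
        raise ValueError("peak genomic range must be positive")
    prs = (n_smp / n_sv) * (peak_area / peak_gr)
    return prs, float(np.sqrt(prs))


@dataclass
class GammaNull:
    """MLE Gamma fit to a cohort's score distribution."""

    shape: float
    scale: float
    n: int

    @property
    def rate(self) -> float:
        return 1.0 / self.scale

    def sf(self, x):
        return stats.gamma.sf(x, self.shape, scale=self.scale)


def fit_gamma_null(values) -> GammaNull:
    """Maximum-likelihood Gamma fit (location fixed at 0).

    Degenerate input (fewer than two distinct values) is an error; the
    caller decides whether significance is skipped for small cohorts.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or np.ptp(v) == 0:
        raise ValueError("cannot fit a Gamma null to degenerate values")
    if (v <= 0).any():
        raise ValueError("Gamma null requires positive values")
    shape, _, scale = stats.gamma.fit(v, floc=0)
    return GammaNull(shape=float(shape), scale=float(scale), n=int(v.size))


def benjamini_hochberg(p_values, threshold: float = FDR_THRESHOLD):
    """Step-up BH q-values and the FDR flags at the given threshold."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q, q < threshold


def single_sample_score(n_bp: int, n_smp: int) -> float:
    """SSRs: average breakpoint contribution per donor within the peak."""
    if n_smp == 0:
        raise ValueError("peak with no donors cannot be scored")
    return n_bp / n_smp


def chi_squared_2x2(table):
    """Pearson chi-squared on a 2x2 table, df=1, no continuity correction."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue)


def detect_peaks(adjusted_curves: dict, bp_table: pd.DataFrame,
                 fdr: float = FDR_THRESHOLD,
                 min_peaks: int = MIN_PEAKS_FOR_NULL) -> pd.DataFrame:
    """Call, score and test peaks across all modeled chromosomes.

    Returns one row per peak with geometry, counts, PRs/SSRs and
    significance flags (columns of ``PEAK_COLUMNS``).  With fewer than
    ``min_peaks`` peaks in the cohort the Gamma null is skipped and
    p/q-values are missing.
    """
    rows = []
    for chrom in sorted(adjusted_curves):
        bp_chrom = bp_table[bp_table["chrom"] == chrom]
        for pk in call_peaks(adjusted_curves[chrom]):
            counts = count_peak_members(pk, bp_chrom)
            if counts["n_sv"] == 0:
                logger.warning("%s: peak at %d has no breakpoints; skipped",
                               chrom, int(pk.summit_pos))
                continue
            prs, prs_sqrt = peak_recurrence_score(
                counts["n_smp"], counts["n_sv"], pk.peak_area, pk.peak_gr)
            rows.append({
                "chrom": chrom, "start": pk.start, "end": pk.end,
                "summit_pos": pk.summit_pos, "summit_height": pk.summit_height,
                "peak_area": pk.peak_area, "peak_gr": pk.peak_gr,
                **counts, "prs": prs, "prs_sqrt": prs_sqrt,
                "ssrs": single_sample_score(counts["n_bp"], counts["n_smp"]),
            })
    peaks = pd.DataFrame(rows)
    if peaks.empty:
        return pd.DataFrame(columns=PEAK_COLUMNS)
    peaks.insert(3, "peak_id",
                 [f"peak_{i + 1:04d}" for i in range(len(peaks))])
    n = len(peaks)
    if n >= min_peaks:
        prs = peaks["prs"].to_numpy()
        null = fit_gamma_null(prs[prs > 0])    # degenerate zero-area peaks: p = 1
        peaks["p_value"] = np.where(prs > 0, null.sf(prs), 1.0)
        q, flag = benjamini_hochberg(peaks["p_value"].to_numpy(), fdr)
        peaks["q_value"] = q
        peaks["recurrent_significant"] = flag
        ssrs_null = fit_gamma_null(peaks["ssrs"].to_numpy())
        peaks["ssrs_p"] = ssrs_null.sf(peaks["ssrs"].to_numpy())
        qs, fs = benjamini_hochberg(peaks["ssrs_p"].to_numpy(), fdr)
        peaks["ssrs_q"] = qs
        peaks["single_sample_significant"] = fs
    else:
        logger.warning("only %d peaks (< %d): significance skipped", n, min_peaks)
        peaks["p_value"] = np.nan
        peaks["q_value"] = np.nan
        peaks["recurrent_significant"] = False
        peaks["ssrs_p"] = np.nan
        peaks["ssrs_q"] = np.nan
        peaks["single_sample_significant"] = False
    peaks["single_or_two_sample"] = peaks["n_smp"] <= 2
    return peaks[PEAK_COLUMNS]
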