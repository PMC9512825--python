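"""Breakpoint neighbor reachability and the smoothed proximity curve.

For the sorted breakpoints of one chromosome, each breakpoint's
neighbor reachability is the mean genomic distance to its flanking
neighbors,

    bpnr_i = (|pos_i - pos_{i-1}| + |pos_{i+1} - pos_i|) / 2,

reversed onto a proximity scale as ``bpp = -log10(bpnr + 1)`` so that
tight clusters score high, and smoothed along the chromosome by a
degree-2 LOESS with tricube weights (span = fraction of points).
The resulting curve is the substrate for background modeling and
peak calling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

#: Chromosomes need at least this many breakpoints for a reliable curve.
MIN_BREAKPOINTS = 100


class InsufficientBreakpoints(ValueError):
    """Too few breakpoints on a chromosome to smooth reliably."""


def compute_bpnr(positions) -> np.ndarray:
    """Neighbor reachability for sorted breakpoint positions.

    Interior breakpoints average the distance to both neighbors; the
    first and last use their single available neighbor, keeping the
    output aligned 1:1 with the input.

    Raises
    ------
    ValueError
        If fewer than 2 breakpoints are given or positions are not
        sorted.
    """
    pos = np.asarray(positions, dtype=np.float64)
    if pos.ndim != 1 or pos.size < 2:
        raise ValueError("need at least 2 sorted breakpoint positions")
    d = np.diff(pos)
    if (d < 0).any():
        raise ValueError("positions must be sorted ascending")
    bpnr = np.empty_like(pos)
    bpnr[0] = d[0]
    bpnr[-1] = d[-1]
    bpnr[1:-1] = (d[:-1] + d[1:]) / 2.0
    return bpnr


def proximity_transform(bpnr) -> np.ndarray:
    """Reverse-scale log transform: ``-log10(bpnr + 1)``.

    Zero distance maps to 0 (maximal proximity); larger distances map
    to increasingly negative values.
    """
    arr = np.asarray(bpnr, dtype=np.float64)
    if (arr < 0).any():
        raise ValueError("bpnr must be non-negative")
    return -np.log10(arr + 1.0)


def _nn_windows(x: np.ndarray, k: int) -> np.ndarray:
    """Left edge of the k-nearest-neighbour window for each sorted x.

    Two-pointer sweep: the window for x[i] is the contiguous run of k
    points minimizing the maximal distance to x[i].
    """
    n = x.size
    left = np.empty(n, dtype=np.intp)
    lo = 0
    for i in range(n):
        hi = lo + k - 1
        while hi + 1 < n and x[hi + 1] - x[i] < x[i] - x[lo]:
            lo += 1
            hi += 1
        left[i] = lo
    return left


def loess(x, y, span: float = 0.2, degree: int = 2,
          chunk: int = 2048) -> np.ndarray:
    """Locally weighted polynomial regression evaluated at the data points.

    Tricube weights over the ``ceil(span * n)`` nearest neighbours, one
    weighted least-squares polynomial of the given degree per
    evaluation point, no robustness iterations.  ``x`` must be sorted.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have the same length")
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    if (np.diff(x) < 0).any():
        raise ValueError("x must be sorted ascending")
    k = max(int(np.ceil(span * n)), degree + 1)
    k = min(k, n)
    left = _nn_windows(x, k)
    offsets = np.arange(k)
    fitted = np.empty(n)
    for c0 in range(0, n, chunk):
        c1 = min(c0 + chunk, n)
        idx = left[c0:c1, None] + offsets[None, :]          # (m, k)
        xw = x[idx] - x[c0:c1, None]
        yw = y[idx]
        h = np.abs(xw).max(axis=1, keepdims=True)
        h_safe = np.where(h > 0, h, 1.0)
        u = np.abs(xw) / h_safe
        w = np.clip(1.0 - u ** 3, 0.0, None) ** 3
        # degenerate window (all points coincident): weighted mean
        flat = (h[:, 0] == 0)
        xs = xw / h_safe                                     # scale to O(1)
        cols = [np.ones_like(xs)] + [xs ** p for p in range(1, degree + 1)]
        B = np.stack(cols, axis=2)                           # (m, k, d+1)
        WB = B * w[:, :, None]
        A = np.einsum("mkp,mkq->mpq", WB, B)
        b = np.einsum("mkp,mk->mp", WB, yw)
        A += 1e-10 * np.eye(degree + 1)[None, :, :]
        beta = np.linalg.solve(A, b[..., None])[..., 0]
        out = beta[:, 0]
        if flat.any():
            out[flat] = yw[flat].mean(axis=1)
        fitted[c0:c1] = out
    return fitted


@dataclass
class ProximityCurve:
    """LOESS-smoothed breakpoint proximity along one chromosome."""

    chrom: str
    positions: np.ndarray          # sorted breakpoint positions (bp)
    observed: np.ndarray           # bpp at each breakpoint
    smoothed: np.ndarray           # LOESS fit at each breakpoint
    span_alpha: float

    def __post_init__(self):
        if not (len(self.positions) == len(self.observed) == len(self.smoothed)):
            raise ValueError("positions/observed/smoothed must align")


def fit_bppc(positions, bpp, chrom: str = "", span_alpha: float = 0.2,
             min_points: int = MIN_BREAKPOINTS) -> ProximityCurve:
    """Fit the breakpoint proximity curve for one chromosome.

    Chromosomes with fewer than ``min_points`` breakpoints cannot be
    smoothed reliably and raise :class:`InsufficientBreakpoints`; the
    pipeline excludes them from modeling and peak calling.
    """
    positions = np.asarray(positions, dtype=np.float64)
    bpp = np.asarray(bpp, dtype=np.float64)
    if positions.size < min_points:
        raise InsufficientBreakpoints(
            f"{chrom or 'chromosome'}: {positions.size} breakpoints "
            f"(< {min_points}); curve not modeled"
        )
    smoothed = loess(positions, bpp, span=span_alpha, degree=2)
    return ProximityCurve(chrom=chrom, positions=positions, observed=bpp,
                          smoothed=smoothed, span_alpha=span_alpha)


def curves_from_breakpoints(bp_table, span_alpha: float = 0.2,
                            min_points: int = MIN_BREAKPOINTS) -> dict:
    """Per-chromosome proximity curves from a breakpoint table.

    Returns ``{chrom: ProximityCurve}``; chromosomes below the
    breakpoint minimum are logged and skipped.
    """
    curves = {}
    for chrom, sub in bp_table.groupby("chrom", sort=True):
        pos = sub["pos"].to_numpy(dtype=np.float64)
        if pos.size < max(min_points, 2):
            logger.info("%s: %d breakpoints, skipped", chrom, pos.size)
            continue
        bpp = proximity_transform(compute_bpnr(pos))
        curves[chrom] = fit_bppc(pos, bpp, chrom=chrom, span_alpha=span_alpha,
                                 min_points=min_points)
    return curves
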