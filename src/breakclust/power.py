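"""Binomial power model for detecting a recurrent peak.

A donor hits a peak of length ``L`` Mb by background alone with
probability ``p0 = 1 - (1 - mu * f_p)^L`` where ``mu`` is the cohort's
average SV rate per Mb per donor and ``f_p`` the peak breakpoint rate
factor (how much denser breakpoints are inside peaks than genome-wide).
With a driver of prevalence ``r`` and detection sensitivity ``s`` the
per-donor hit probability becomes ``p1 = 1 - (1 - p0)(1 - r s)``, and
the power at cohort size ``n`` is the binomial tail
``P(Bin(n, p1) >= m_min)``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def background_hit_prob(mu: float, f_p: float, L: float) -> float:
    """p0 = 1 - (1 - mu*f_p)^L: background hit probability per donor."""
    rate = mu * f_p
    if not 0 <= rate <= 1:
        raise ValueError("mu * f_p must lie in [0, 1]")
    if L < 0:
        raise ValueError("peak length must be non-negative")
    return 1.0 - (1.0 - rate) ** L


def alternative_hit_prob(p0: float, r: float, s: float) -> float:
    """p1 = 1 - (1 - p0)(1 - r*s): hit probability with a driver present."""
    for name, v in (("p0", p0), ("r", r), ("s", s)):
        if not 0 <= v <= 1:
            raise ValueError(f"{name} must lie in [0, 1]")
    return 1.0 - (1.0 - p0) * (1.0 - r * s)


@dataclass
class PowerParams:
    """Inputs of the detection-power calculation."""

    mu: float                 # average SV rate per Mb per donor
    f_p: float                # peak breakpoint rate factor
    L: float                  # peak length in Mb
    r: float                  # driver prevalence
    s: float = 0.9            # detection sensitivity
    m_min: int = 3            # recurrent donors defining a detectable peak

    def __post_init__(self):
        if self.m_min < 1:
            raise ValueError("m_min must be >= 1")
        background_hit_prob(self.mu, self.f_p, self.L)   # validates mu*f_p
        alternative_hit_prob(0.0, self.r, self.s)        # validates r, s


def significance_threshold(p0: float, n: int, m_min: int,
                           alpha: float = 0.05) -> int:
    """Donor count a peak must reach to stand out from background.

    The smallest m with ``P(Bin(n, p0) >= m) <= alpha``, floored at
    ``m_min``: in a longer peak (higher p0) more donors recur by chance,
    so the bar rises with the background.
    """
    if p0 <= 0:
        return m_min
    m_bg = int(stats.binom.isf(alpha, n, p0)) + 1
    return max(m_min, m_bg)


def detection_power(params: PowerParams, n: int,
                    background_calibrated: bool = False) -> float:
    """P(Bin(n, p1) >= m) at cohort size ``n``.

    With ``background_calibrated=False`` the required donor count is the
    fixed ``m_min``; with True it is raised to the background-calibrated
    significance threshold for this peak length.
    """
    p0 = background_hit_prob(params.mu, params.f_p, params.L)
    p1 = alternative_hit_prob(p0, params.r, params.s)
    if p1 == 0:
        return 0.0
    m = significance_threshold(p0, n, params.m_min) if background_calibrated \
        else params.m_min
    return float(stats.binom.sf(m - 1, n, p1))


def minimum_cohort_size(params: PowerParams, target: float = 0.9,
                        n_max: int = 100_000,
                        background_calibrated: bool = False) -> int | None:
    """Smallest cohort size reaching the target power, or None."""
    p0 = background_hit_prob(params.mu, params.f_p, params.L)
    p1 = alternative_hit_prob(p0, params.r, params.s)
    if p1 == 0:
        return None
    if not background_calibrated:
        if detection_power(params, n_max) < target:
            return None
        lo, hi = params.m_min, n_max   # power is monotone in n: bisect
        while lo < hi:
            mid = (lo + hi) // 2
            if detection_power(params, mid) >= target:
                hi = mid
            else:
                lo = mid + 1
        return int(lo)
    # the calibrated threshold grows with n, so scan forward
    for n in range(params.m_min, n_max + 1):
        if detection_power(params, n, background_calibrated=True) >= target:
            return int(n)
    return None


def power_table(params: PowerParams, n_values,
                prevalences=(0.02, 0.05, 0.25)) -> pd.DataFrame:
    """Power across cohort sizes for a grid of prevalences."""
    rows = []
    for r in prevalences:
        p = PowerParams(mu=params.mu, f_p=params.f_p, L=params.L, r=r,
                        s=params.s, m_min=params.m_min)
        for n in n_values:
            rows.append({"prevalence": r, "n": int(n),
                         "power": detection_power(p, int(n))})
    return pd.DataFrame(rows)


def power_over_lengths(params: PowerParams, lengths,
                       target: float = 0.9) -> pd.DataFrame:
    """Minimum cohort size across a range of peak lengths (Mb).

    Uses the background-calibrated threshold: a longer peak accumulates
    more chance recurrence, so the donor-count bar is higher and more
    samples are needed — narrow peaks need fewer donors for the same
    power.
    """
    rows = []
    for L in lengths:
        p = PowerParams(mu=params.mu, f_p=params.f_p, L=float(L), r=params.r,
                        s=params.s, m_min=params.m_min)
        rows.append({"L_mb": float(L),
                     "n_90": minimum_cohort_size(p, target=target,
                                                 background_calibrated=True)})
    return pd.DataFrame(rows)


def estimate_rates(sv_df, bp_table, peaks, genome_length_mb: float,
                   top_fraction: float = 0.02) -> tuple:
    """Estimate (mu, f_p, median L of top peaks) from a cohort.

    ``mu`` is the mean SV count per donor divided by the effective
    genome length; ``f_p`` the ratio of breakpoint density inside the
    top ``top_fraction`` of peaks (by PRs) to the genome-wide density.
    """
    n_donors = sv_df["donor_id"].nunique()
    mu = (len(sv_df) / n_donors) / genome_length_mb
    if peaks.empty:
        return mu, 1.0, np.nan
    k = max(int(np.ceil(top_fraction * len(peaks))), 1)
    top = peaks.nlargest(k, "prs")
    bp_in = 0
    for _, pk in top.iterrows():
        sub = bp_table[(bp_table["chrom"] == pk["chrom"])
                       & (bp_table["pos"] >= pk["start"])
                       & (bp_table["pos"] <= pk["end"])]
        bp_in += len(sub)
    top_len_mb = (top["end"] - top["start"]).to_numpy() / 1e6
    dens_in = bp_in / max(top_len_mb.sum(), 1e-9)
    dens_genome = len(bp_table) / genome_length_mb
    f_p = dens_in / dens_genome if dens_genome > 0 else 1.0
    return mu, f_p, float(np.median(top_len_mb))
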