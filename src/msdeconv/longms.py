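"""Length estimation for microsatellites longer than one read length.

No single read spans a long tract, so its length is inferred from local
coverage.  An analysis window WIN-bk of length L_Win is centered on the
tract breakpoint; read pairs in the window fall into five classes by
mate placement (both in the flanks: C; both inside the tract: T; one
flank one tract: O; one flank one breakpoint-spanning: S; one tract one
spanning: SO).  With L_aln the total spanning-read bases inside the
tract, the window coverage and the tract length satisfy

    C   = [2 (NUM_C + NUM_T + NUM_O + NUM_S + NUM_SO) L_read + L_aln] / L,
    L'' = [(2 NUM_T + NUM_O + NUM_SO) L_read + L_aln] / C,

with L = L' + L_Win.  Alternating the two equations from L' = 0 is a
contracting fixed-point iteration (tolerance delta = L'/100 + 1).  The
window is then grown 5000, 6000, .., 34000 bp, giving >= 30 length
estimates whose mean and variance define the mixed-sample length model
(normality checked by Shapiro-Wilk); the tumor component follows from
the moment equations

    mu = (1 - p) mu1 + p mu2,    sigma^2 = (1 - p) sigma1^2 + p sigma2^2,

and the MSI/MSS state from the same z-test as the short-tract path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import shapiro

from .mscall import MSCall
from .refscan import MicrosatelliteRegion
from .shortms import LengthDistribution, z_test_state

logger = logging.getLogger(__name__)

SIGMA2_FLOOR = 1.0  # bp^2; floor for degenerate sweep variances


@dataclass
class WindowConfig:
    """Window-sweep geometry."""

    l_win: int = 5_000
    step: int = 1_000
    s_max: int = 30
    l_read: int = 200
    l_max: int = 50_000
    k: int = 6
    max_iter: int = 100
    min_sweeps: int = 20

    def __post_init__(self) -> None:
        if self.l_win <= 2 * self.l_read:
            raise ValueError("window must exceed twice the read length")
        if self.s_max < 30:
            raise ValueError("at least 30 sweeps are required")

    @property
    def max_window(self) -> int:
        return self.l_win + (self.s_max - 1) * self.step


@dataclass
class PairCounts:
    """Per-window read-pair tallies."""

    NUM_C: int = 0
    NUM_T: int = 0
    NUM_O: int = 0
    NUM_S: int = 0
    NUM_SO: int = 0
    L_aln: int = 0

    def __post_init__(self) -> None:
        if min(self.NUM_C, self.NUM_T, self.NUM_O, self.NUM_S, self.NUM_SO, self.L_aln) < 0:
            raise ValueError("pair counts must be non-negative")

    @property
    def n_pairs(self) -> int:
        return self.NUM_C + self.NUM_T + self.NUM_O + self.NUM_S + self.NUM_SO


@dataclass
class SweepState:
    """Converged per-window estimates collected across the sweep."""

    l_set: list[float] = field(default_factory=list)
    windows: list[int] = field(default_factory=list)
    n_failed: int = 0


def classify_pairs(
    pairs: pd.DataFrame, window: tuple[int, int], region: MicrosatelliteRegion,
    l_read: int,
) -> PairCounts:
    """Assign read pairs to the five window classes.

    ``window`` is a half-open reference interval centered on the region
    breakpoint.  A flank mate belongs to the window when it lies fully
    inside it; tract and spanning mates belong when their breakpoint
    anchor falls in the window.  Spanning membership takes precedence
    over containment (a doubly-spanning pair is an SO-pair, so spanning
    bases are counted once).  Pairs with an unclassifiable mate are
    ignored.
    """
    lo, hi = window
    k1 = pairs["kind1"].to_numpy()
    k2 = pairs["kind2"].to_numpy()
    r1 = pairs["ref1"].to_numpy()
    r2 = pairs["ref2"].to_numpy()
    in1 = (r1 >= lo) & (r1 < hi)
    in2 = (r2 >= lo) & (r2 < hi)
    w1 = ((k1 == 0) | (k1 == 3)) & (r1 >= lo) & (r1 + l_read <= hi)
    w2 = ((k2 == 0) | (k2 == 3)) & (r2 >= lo) & (r2 + l_read <= hi)
    t1 = (k1 == 1) & in1
    t2 = (k2 == 1) & in2
    sp1 = (k1 == 2) & in1
    sp2 = (k2 == 2) & in2

    so = (sp1 & sp2) | (sp1 & t2) | (sp2 & t1)
    s = ~so & ((sp1 & w2) | (sp2 & w1))
    t = ~so & ~s & t1 & t2
    o = ~so & ~s & ~t & ((t1 & w2) | (t2 & w1))
    c = ~so & ~s & ~t & ~o & w1 & w2

    tb1 = pairs["tb1"].to_numpy()
    tb2 = pairs["tb2"].to_numpy()
    s_read = (so | s)
    l_aln = int((tb1 * (s_read & sp1)).sum() + (tb2 * (s_read & sp2)).sum())
    return PairCounts(
        NUM_C=int(c.sum()), NUM_T=int(t.sum()), NUM_O=int(o.sum()),
        NUM_S=int(s.sum()), NUM_SO=int(so.sum()), L_aln=l_aln,
    )


def coverage_estimate(counts: PairCounts, L: float, l_read: int) -> float:
    """Window coverage C = [2 N_pairs L_read + L_aln] / L."""
    if L <= 0:
        raise ValueError("target-area length must be positive")
    return (2.0 * counts.n_pairs * l_read + counts.L_aln) / L


def length_update(counts: PairCounts, C: float, l_read: int) -> float:
    """Tract length L'' = [(2 NUM_T + NUM_O + NUM_SO) L_read + L_aln] / C."""
    if C <= 0:
        raise ValueError("no coverage in window")
    return ((2.0 * counts.NUM_T + counts.NUM_O + counts.NUM_SO) * l_read + counts.L_aln) / C


def fixed_point_length(
    counts: PairCounts, l_win: int, l_read: int, max_iter: int = 100
) -> tuple[float, int, bool]:
    """Iterate coverage and length updates to a fixed point.

    From L' = 0, alternate C = SUM_bp / (L' + L_Win) and L'' = SUM_bp' / C
    until successive estimates differ by at most delta = L'/100 + 1.
    Returns (length, iterations, converged).
    """
    tract_evidence = 2.0 * counts.NUM_T + counts.NUM_O + counts.NUM_SO + counts.L_aln
    if counts.n_pairs == 0:
        return 0.0, 0, True
    if tract_evidence == 0:
        return 0.0, 0, True
    l_prime = 0.0
    for it in range(1, max_iter + 1):
        C = coverage_estimate(counts, l_prime + l_win, l_read)
        l_dprime = length_update(counts, C, l_read)
        delta = l_prime / 100.0 + 1.0
        if abs(l_dprime - l_prime) <= delta:
            return l_dprime, it, True
        l_prime = l_dprime
    logger.warning("fixed-point iteration did not converge in %d steps", max_iter)
    return l_prime, max_iter, False


def window_sweep(
    pairs: pd.DataFrame, region: MicrosatelliteRegion, config: WindowConfig
) -> SweepState:
    """>= 30 length estimates from windows of growing size.

    The window grows from l_win by ``step`` for ``s_max`` sweeps;
    each converged fixed-point estimate joins L_set, non-converged sweeps
    are skipped with a log entry.
    """
    state = SweepState()
    b = region.breakpoint
    for s in range(config.s_max):
        w = config.l_win + s * config.step
        counts = classify_pairs(pairs, (b - w // 2, b + w - w // 2), region, config.l_read)
        l_est, _, ok = fixed_point_length(counts, w, config.l_read, config.max_iter)
        if ok:
            state.l_set.append(l_est)
            state.windows.append(w)
        else:
            state.n_failed += 1
            logger.info("window %d bp at %s:%d did not converge", w, region.chrom, b)
    return state


def fit_and_check_normal(
    l_set: list[float] | np.ndarray, origin: str = "mixed"
) -> tuple[LengthDistribution, float]:
    """Gaussian fit of the sweep estimates plus a Shapiro-Wilk p-value.

    Non-normality (p < 0.01) is logged, not fatal; a zero-variance set is
    floored at 1 bp^2 and flagged.
    """
    x = np.asarray(l_set, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 sweep estimates")
    mu = float(x.mean())
    sigma2 = float(x.var(ddof=1))
    flagged = False
    if sigma2 < SIGMA2_FLOOR:
        sigma2, flagged = SIGMA2_FLOOR, True
    if np.ptp(x) == 0:
        sw_p = 0.0
    else:
        sw_p = float(shapiro(x).pvalue)
    if sw_p < 0.01:
        logger.info("sweep estimates deviate from normality (Shapiro-Wilk p=%.3g)", sw_p)
    dist = LengthDistribution(mu=mu, sigma2=sigma2, n_obs=x.size, origin=origin, flagged=flagged)
    return dist, sw_p


def deconvolve_moments(
    mixed: LengthDistribution, p: float, normal: LengthDistribution
) -> LengthDistribution:
    """Tumor component from the mixture moment equations.

    mu2 = (mu - (1-p) mu1) / p;  sigma2^2 = (sigma^2 - (1-p) sigma1^2) / p,
    floored at 1 bp^2 (and flagged) when the variance difference is
    non-positive.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("p must be in (0, 1]")
    mu2 = (mixed.mu - (1.0 - p) * normal.mu) / p
    s2 = (mixed.sigma2 - (1.0 - p) * normal.sigma2) / p
    flagged = False
    if s2 < SIGMA2_FLOOR:
        s2, flagged = SIGMA2_FLOOR, True
    return LengthDistribution(mu=mu2, sigma2=s2, n_obs=mixed.n_obs, origin="tumor",
                              flagged=flagged)


def convolve_moments(
    tumor: LengthDistribution, p: float, normal: LengthDistribution
) -> LengthDistribution:
    """Inverse of :func:`deconvolve_moments` (moment mixing)."""
    mu = (1.0 - p) * normal.mu + p * tumor.mu
    s2 = (1.0 - p) * normal.sigma2 + p * tumor.sigma2
    return LengthDistribution(mu=mu, sigma2=s2, n_obs=tumor.n_obs, origin="mixed")


def call_state_long(
    tumor: LengthDistribution,
    normal: LengthDistribution,
    region: MicrosatelliteRegion,
    alpha: float = 0.05,
    shapiro_p: float = math.nan,
    n_sweeps: int = 0,
    converged: bool = True,
) -> MSCall:
    """MSI/MSS state by the independent z-test (state NA when upstream
    estimation failed to converge)."""
    if not converged:
        return MSCall(chrom=region.chrom, breakpoint=region.breakpoint, unit=region.unit,
                      state="NA", shapiro_p=shapiro_p, n_sweeps=n_sweeps)
    call = z_test_state(tumor, normal, region=region, alpha=alpha)
    call.shapiro_p = shapiro_p
    call.n_sweeps = n_sweeps
    return call
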