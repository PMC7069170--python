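"""Length deconvolution of microsatellites shorter than one read length.

When a tract fits inside a read, every read spanning both flanks yields
an exact per-molecule tract length.  In a mixed tumor sample the length
set L = {l_1 .. l_N} is drawn from the two-component density

    f(x) = (1 - p) f1(x) + p f2(x),

where f1 = N(mu1, sigma1^2) is the normal-cell component (estimable from
the paired normal sample alone), f2 = N(mu2, sigma2^2) is the tumor
component, and p is the tumor purity.  With (p, mu1, sigma1) known, the
tumor parameters are the maximizers of the mixture likelihood; the score
equations are solved by an EM whose mixing weight is frozen at p and
whose first component is frozen at the normal fit, so only (mu2, sigma2)
update from responsibilities.  The MSI/MSS state is then a two-sided
z-test on mu2 - mu1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .refscan import MicrosatelliteRegion
from .mscall import MSCall

logger = logging.getLogger(__name__)

SIGMA_FLOOR = 0.5  # bp; degenerate tumor-component SD floor


@dataclass
class LengthDistribution:
    """Normal model N(mu, sigma2) of tract length with an origin tag."""

    mu: float
    sigma2: float
    n_obs: float
    origin: str = "mixed"  # "normal" | "tumor" | "mixed"
    flagged: bool = False

    @property
    def sigma(self) -> float:
        return math.sqrt(self.sigma2)


@dataclass
class LengthObservations:
    """Per-read tract lengths at one region."""

    region: MicrosatelliteRegion
    lengths: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.lengths.size < 1:
            raise ValueError("need at least one length observation")

    @property
    def n(self) -> int:
        return int(self.lengths.size)


def measure_tract_length(seq: str, offset: int, unit: str) -> int | None:
    """Tract length on a read, or None if the read does not span it.

    The tract starts at *offset* within the read and extends while the
    sequence continues with period len(unit).  A measurement is valid
    only when at least one flank base precedes the tract and at least
    one non-periodic base follows it (both flanks present on the read).
    """
    p = len(unit)
    n = len(seq)
    if offset < 1 or offset + p > n:
        return None
    rotations = {unit[i:] + unit[:i] for i in range(p)}
    if seq[offset : offset + p] not in rotations and p <= n - offset:
        # seed disagrees with the expected unit: not this region's tract
        return None
    end = offset + p
    while end < n and seq[end] == seq[end - p]:
        end += 1
    if end >= n:
        return None  # tract runs off the read: right flank missing
    return end - offset


def extract_lengths(
    spanning_reads: list[tuple[int, str]],
    region: MicrosatelliteRegion,
) -> LengthObservations:
    """Per-read tract lengths from breakpoint-spanning reads.

    *spanning_reads* holds (initial mapping position, sequence) pairs;
    the tract is located on each read at ``region.breakpoint - position``
    and measured by periodicity.  Reads that do not span both flanks are
    dropped; an empty result raises (the region is not short-class).
    """
    lengths = []
    for pos, seq in spanning_reads:
        off = region.breakpoint - pos
        if not seq or off < 1 or off >= len(seq):
            continue
        l = measure_tract_length(seq, off, region.unit)
        if l is not None:
            lengths.append(l)
    if not lengths:
        raise ValueError(
            f"region {region.chrom}:{region.breakpoint} has no fully spanning reads "
            "(not short-class)"
        )
    return LengthObservations(region=region, lengths=np.array(lengths, dtype=float))


def fit_normal(lengths: np.ndarray, origin: str = "normal") -> LengthDistribution:
    """Single-component Gaussian MLE (variance divisor N)."""
    x = np.asarray(lengths, dtype=float)
    if x.size < 1:
        raise ValueError("need at least one observation")
    mu = float(x.mean())
    sigma2 = float(x.var())  # MLE: divisor N
    flagged = False
    if sigma2 < SIGMA_FLOOR**2:
        sigma2, flagged = SIGMA_FLOOR**2, True
    return LengthDistribution(mu=mu, sigma2=sigma2, n_obs=x.size, origin=origin, flagged=flagged)


def mixture_loglik(
    x: np.ndarray, p: float, mu1: float, sigma1: float, mu2: float, sigma2: float
) -> float:
    """Log of the fixed-proportion two-component mixture likelihood."""
    f1 = norm.pdf(x, mu1, sigma1)
    f2 = norm.pdf(x, mu2, sigma2)
    return float(np.log((1.0 - p) * f1 + p * f2 + 1e-300).sum())


def mle_deconvolve(
    obs: LengthObservations,
    p: float,
    prior: LengthDistribution,
    tol: float = 1e-8,
    max_iter: int = 300,
) -> LengthDistribution:
    """Tumor component (mu2, sigma2) maximizing the mixture likelihood.

    EM with the mixing weight fixed at p and component 1 frozen at the
    normal-sample fit.  Because the direction of an MSI length shift is
    unknown, the fit is started from both the upper and the lower
    ``ceil(p N)`` order statistics and the higher-likelihood solution is
    kept.  At p = 1 this reduces to the single-sample MLE.
    """
    if not 0.0 < p <= 1.0:
        raise ValueError("tumor component unidentifiable at p = 0")
    if prior.sigma2 <= 0:
        raise ValueError("normal prior needs positive variance")
    x = obs.lengths
    if x.size < 30:
        logger.warning("only %d length observations (>= 30 recommended)", x.size)

    mu1, s1 = prior.mu, prior.sigma
    if p >= 1.0:
        fit = fit_normal(x, origin="tumor")
        return fit

    xs = np.sort(x)
    k = max(1, math.ceil(p * x.size))
    inits = [(float(xs[-k:].mean()), float(max(x.std(), SIGMA_FLOOR))),
             (float(xs[:k].mean()), float(max(x.std(), SIGMA_FLOOR)))]
    best = None
    for mu2, s2 in inits:
        ll_prev = -np.inf
        for _ in range(max_iter):
            f1 = (1.0 - p) * norm.pdf(x, mu1, s1)
            f2 = p * norm.pdf(x, mu2, s2)
            tot = f1 + f2 + 1e-300
            w = f2 / tot
            ll = float(np.log(tot).sum())
            wsum = w.sum()
            if wsum <= 0:
                break
            mu2 = float((w * x).sum() / wsum)
            s2 = float(math.sqrt(max((w * (x - mu2) ** 2).sum() / wsum, SIGMA_FLOOR**2)))
            if ll - ll_prev < tol and np.isfinite(ll_prev):
                break
            ll_prev = ll
        ll = mixture_loglik(x, p, mu1, s1, mu2, s2)
        if best is None or ll > best[0]:
            best = (ll, mu2, s2)
    _, mu2, s2 = best
    flagged = s2 <= SIGMA_FLOOR
    return LengthDistribution(
        mu=mu2, sigma2=max(s2, SIGMA_FLOOR) ** 2, n_obs=max(p * x.size, 1.0),
        origin="tumor", flagged=flagged,
    )


def z_test_state(
    tumor: LengthDistribution,
    normal: LengthDistribution,
    region: MicrosatelliteRegion | None = None,
    alpha: float = 0.05,
) -> MSCall:
    """Two-sided z-test of mu_tumor - mu_normal; MSI iff p-value < alpha.

        z = (mu2 - mu1) / sqrt(sigma1^2 / n1 + sigma2^2 / n2)
    """
    if tumor.sigma2 <= 0 or normal.sigma2 <= 0 or tumor.n_obs < 1 or normal.n_obs < 1:
        raise ValueError("z-test needs positive variances and n_obs >= 1")
    se2 = normal.sigma2 / normal.n_obs + tumor.sigma2 / tumor.n_obs
    if se2 <= 0:
        raise ValueError("zero pooled variance")
    z = (tumor.mu - normal.mu) / math.sqrt(se2)
    pvalue = float(2.0 * norm.sf(abs(z)))
    state = "MSI" if pvalue < alpha else "MSS"
    return MSCall(
        chrom=region.chrom if region else "ref",
        breakpoint=region.breakpoint if region else -1,
        unit=region.unit if region else "",
        mu_normal=normal.mu,
        sigma2_normal=normal.sigma2,
        mu_tumor=tumor.mu,
        sigma2_tumor=tumor.sigma2,
        n_obs=tumor.n_obs,
        z=z,
        pvalue=pvalue,
        state=state,
    )
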