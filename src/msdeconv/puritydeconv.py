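"""Tumor-purity estimation from paired SNV read counts.

The sequenced tumor sample is a mixture of tumor cells (fraction p, the
*purity*) and normal cells (1 - p).  At a candidate somatic SNV site the
observed alt-read fraction in the mixed sample carries information about
p: a site that is reference-homozygous in the normal genome and
heterozygous in the tumor genome has expected mixed alt fraction p / 2.

The model: each site carries a latent joint genotype (G_N, G_T) over
G = {AA, AB, BB} with multinomial prior mu_G (9 cells).  Alt read counts
are binomial in both samples; the normal-sample success probability
depends on G_N alone, while the mixed-sample probability is the
purity-weighted blend

    q(G_N, G_T; p) = (1 - p) * v(G_N) + p * v(G_T),

with canonical per-genotype alt fractions v(AA) = eps, v(AB) = 1/2,
v(BB) = 1 - eps (eps = sequencing noise).  An EM over the latent
genotypes maximizes the observed-data likelihood in (mu_G, mu_p), where
mu_p is the shared purity; the M-step for mu_p is an exact 1-D bounded
maximization, so the log-likelihood is non-decreasing by construction
(asserted at every iteration).  The spread of per-site purity estimates
across somatic-responsibility weights is reported as ``lambda_p_inv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp

logger = logging.getLogger(__name__)

GENOTYPES = ("AA", "AB", "BB")
#: the 9 joint genotypes (G_N, G_T), row-major over GENOTYPES x GENOTYPES
JOINT_GENOTYPES = tuple((gn, gt) for gn in GENOTYPES for gt in GENOTYPES)

#: joint genotypes given non-zero prior mass by default: the germline
#: diagonal plus the heterozygous-somatic state the site filter selects
#: for.  A het-somatic site at purity p and a hom-somatic site at purity
#: p/2 produce identical mixed-sample alt-count distributions, so
#: admitting (AA, BB) would make the purity unidentifiable; the filter's
#: heterozygous-somatic contract resolves the ambiguity.
DEFAULT_SUPPORT = (("AA", "AA"), ("AB", "AB"), ("BB", "BB"), ("AA", "AB"))

SITE_COLUMNS = ["site", "n_N_ref", "n_N_alt", "n_N_d", "n_TM_ref", "n_TM_alt", "n_TM_d"]


@dataclass
class PurityParams:
    """Fitted parameters of the purity model."""

    mu_p: float = 0.5
    mu_G: np.ndarray = field(default_factory=lambda: np.full(9, 1.0 / 9.0))
    mu_N: float = 0.01  # canonical alt fraction of an AA genotype (noise)
    mu_T: float = 0.5  # canonical alt fraction of an AB genotype
    lambda_p_inv: float = 1.0
    loglik: float = -np.inf
    n_iter: int = 0
    converged: bool = False

    @property
    def p_hat(self) -> float:
        return self.mu_p


def _genotype_vaf(eps: float) -> np.ndarray:
    return np.array([eps, 0.5, 1.0 - eps])


def _log_binom(k: np.ndarray, n: np.ndarray, q: np.ndarray) -> np.ndarray:
    """log Binomial(k | n, q), broadcasting, safe at q in {0, 1}."""
    q = np.clip(q, 1e-12, 1.0 - 1e-12)
    return (
        gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        + k * np.log(q) + (n - k) * np.log1p(-q)
    )


def _mixture_logpmf(sites: pd.DataFrame, mu_G: np.ndarray, p: float, eps: float):
    """Per-site, per-joint-genotype complete log density (I x 9)."""
    vaf = _genotype_vaf(eps)
    n_alt = sites["n_N_alt"].to_numpy()[:, None]
    n_d = sites["n_N_d"].to_numpy()[:, None]
    tm_alt = sites["n_TM_alt"].to_numpy()[:, None]
    tm_d = sites["n_TM_d"].to_numpy()[:, None]
    v_n = np.repeat(vaf, 3)[None, :]  # G_N varies slowly (row-major)
    v_t = np.tile(vaf, 3)[None, :]
    q_tm = (1.0 - p) * v_n + p * v_t
    ll = _log_binom(n_alt, n_d, v_n) + _log_binom(tm_alt, tm_d, q_tm)
    with np.errstate(divide="ignore"):
        ll = ll + np.log(mu_G)[None, :]
    return ll


def purity_from_depth(n_T_d: float, n_TM_d: float) -> float:
    """Purity as the virtual pure-tumor to mixed-sample depth ratio.

    Only computable when the pure-tumor depth is known (simulation
    truth); on real data purity comes from :func:`em_fit`.
    """
    if n_TM_d <= 0:
        raise ValueError("mixed-sample depth must be positive")
    if not 0 <= n_T_d <= n_TM_d:
        raise ValueError("need 0 <= n_T_d <= n_TM_d")
    return n_T_d / n_TM_d


def filter_sites(
    records: pd.DataFrame,
    germline_max: float = 0.02,
    signal_min: float = 0.05,
) -> pd.DataFrame:
    """Keep heterozygous-somatic candidate sites.

    A site passes when the normal-sample alt fraction is at most
    *germline_max* (excludes germline heterozygotes) and the mixed-sample
    alt fraction is at least *signal_min* (excludes no-signal sites).
    Malformed records (zero depth, counts exceeding depth) are skipped
    with a logged warning.
    """
    rows = []
    for _, rec in records.iterrows():
        try:
            n_d, tm_d = float(rec["n_N_d"]), float(rec["n_TM_d"])
            n_alt, tm_alt = float(rec["n_N_alt"]), float(rec["n_TM_alt"])
            if n_d <= 0 or tm_d <= 0 or n_alt > n_d or tm_alt > tm_d:
                raise ValueError("inconsistent counts")
        except (KeyError, TypeError, ValueError) as exc:
            logger.warning("skipping malformed SNV record %s: %s", dict(rec), exc)
            continue
        if n_alt / n_d <= germline_max and tm_alt / tm_d >= signal_min:
            rows.append(rec)
    if not rows:
        return records.iloc[0:0]
    return pd.DataFrame(rows).reset_index(drop=True)


def support_mask(support=DEFAULT_SUPPORT) -> np.ndarray:
    mask = np.zeros(9, dtype=bool)
    for gn, gt in support:
        mask[GENOTYPES.index(gn) * 3 + GENOTYPES.index(gt)] = True
    return mask


def em_fit(
    sites: pd.DataFrame,
    init: PurityParams | None = None,
    tol: float = 1e-6,
    max_iter: int = 500,
    eps: float = 0.01,
    support=DEFAULT_SUPPORT,
) -> PurityParams:
    """Fit (mu_G, mu_p) by EM over latent joint genotypes.

    The E-step computes joint-genotype responsibilities; the M-step sets
    mu_G to the mean responsibility and maximizes the expected
    mixed-sample binomial log-likelihood over the shared purity.
    Iterates until the log-likelihood gain drops below *tol*.
    """
    if len(sites) == 0:
        raise ValueError("em_fit requires at least one site")
    if (sites["n_N_d"].to_numpy() == 0).all() or (sites["n_TM_d"].to_numpy() == 0).all():
        raise ValueError("all-zero depths: likelihood undefined")

    mask = support_mask(support)
    params = init if init is not None else PurityParams()
    mu_G = np.asarray(params.mu_G, dtype=float).copy()
    mu_G = np.where(mask, mu_G, 0.0)
    if mu_G.sum() <= 0:
        raise ValueError("initial mu_G has no mass on the supported genotypes")
    mu_G /= mu_G.sum()
    p = float(params.mu_p)
    tm_alt = sites["n_TM_alt"].to_numpy()
    tm_d = sites["n_TM_d"].to_numpy()

    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ll_mat = _mixture_logpmf(sites, mu_G, p, eps)
        site_ll = logsumexp(ll_mat, axis=1)
        loglik = float(site_ll.sum())
        if not np.isfinite(loglik):
            raise ValueError("non-finite likelihood")
        # EM guarantee: each exact E/M pair cannot decrease the objective
        assert loglik >= prev_ll - 1e-8 * max(1.0, abs(prev_ll)), (
            f"log-likelihood decreased: {prev_ll} -> {loglik}"
        )
        if loglik - prev_ll < tol and it > 1:
            prev_ll = loglik
            converged = True
            break
        prev_ll = loglik

        resp = np.exp(ll_mat - site_ll[:, None])
        assert np.allclose(resp.sum(axis=1), 1.0, atol=1e-9)
        mu_G = np.where(mask, resp.mean(axis=0), 0.0)
        mu_G /= mu_G.sum()
        p = _maximize_purity(resp, tm_alt, tm_d, eps, current=p)

    if not converged:
        logger.warning("purity EM did not converge in %d iterations", max_iter)

    if _somatic_mass(resp) < 1e-6 * len(sites):
        # no somatic signal anywhere: the mixed sample shows no tumor reads
        logger.info("no somatic responsibility mass; reporting purity 0")
        p = 0.0
    # descriptive spread of per-site purity over somatic (AA, AB) weight
    somatic = resp[:, GENOTYPES.index("AA") * 3 + GENOTYPES.index("AB")]
    p_site = np.clip(2.0 * tm_alt / np.maximum(tm_d, 1), 0.0, 1.0)
    w = somatic.sum()
    if w > 0:
        var = float(np.sum(somatic * (p_site - p) ** 2) / w)
    else:
        var = 1.0
    return PurityParams(
        mu_p=float(p), mu_G=mu_G, mu_N=eps, mu_T=0.5,
        lambda_p_inv=max(var, 1e-12), loglik=prev_ll, n_iter=it, converged=converged,
    )


def _somatic_mass(resp: np.ndarray) -> float:
    """Total responsibility on purity-dependent states (G_N != G_T)."""
    off_diag = [i for i, (gn, gt) in enumerate(JOINT_GENOTYPES) if gn != gt]
    return float(resp[:, off_diag].sum())


def _maximize_purity(
    resp: np.ndarray, tm_alt: np.ndarray, tm_d: np.ndarray, eps: float,
    current: float = 0.5,
) -> float:
    """Exact M-step for the shared purity: 1-D bounded maximization.

    Only genotype states with G_N != G_T inform the purity; when their
    responsibility mass vanishes the objective is flat and the current
    value is kept (the purity is unidentified without somatic signal).
    """
    if _somatic_mass(resp) < 1e-9 * resp.shape[0]:
        return current
    vaf = _genotype_vaf(eps)
    v_n = np.repeat(vaf, 3)[None, :]
    v_t = np.tile(vaf, 3)[None, :]

    def neg_q(p: float) -> float:
        q_tm = (1.0 - p) * v_n + p * v_t
        ll = _log_binom(tm_alt[:, None], tm_d[:, None], q_tm)
        return -float(np.sum(resp * ll))

    res = minimize_scalar(neg_q, bounds=(1e-9, 1.0 - 1e-9), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x)
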