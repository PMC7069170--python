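"""Short-tract length extraction, mixture MLE and the z-test."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import ks_2samp, norm

from msdeconv import shortms
from msdeconv.refscan import MicrosatelliteRegion
from msdeconv.shortms import (
    LengthDistribution,
    LengthObservations,
    extract_lengths,
    fit_normal,
    measure_tract_length,
    mixture_loglik,
    mle_deconvolve,
    z_test_state,
)

REGION = MicrosatelliteRegion("sim", 1000, "AC")


def _obs(x):
    return LengthObservations(region=REGION, lengths=np.asarray(x, float))


def _mix_sample(rng, n, p, mu1, s1, mu2, s2):
    tumor = rng.random(n) < p
    return np.where(tumor, rng.normal(mu2, s2, n), rng.normal(mu1, s1, n))


# ---------------------------------------------------------------------------
# extraction


def test_extract_constructed_read():
    # 5 bp flank + (AC x 7) + 5 bp flank: measured length 14
    read = "GGTTG" + "AC" * 7 + "GTTGG"
    assert measure_tract_length(read, 5, "AC") == 14
    obs = extract_lengths([(995, read)], REGION)
    assert obs.lengths.tolist() == [14.0]


def test_extract_drops_read_missing_right_flank():
    read = "GGTTG" + "AC" * 10  # tract runs off the read end
    assert measure_tract_length(read, 5, "AC") is None
    with pytest.raises(ValueError, match="short-class"):
        extract_lengths([(995, read)], REGION)


def test_extract_simulated_spanning_reads(rng):
    # error-free reads over a planted 20 bp tract: every length is 20
    from msdeconv import simdata
    from msdeconv.experiments import region_pairs, spanning_mates

    locus = simdata.TruthLocus(breakpoint=30_000, unit="AC", mu_n=20.0,
                               sigma_n=0.0, mu_t=20.0, sigma_t=0.0)
    cfg = simdata.SimConfig(coverage=100, read_length=200, flank_bp=1_000)
    ref = simdata.reference_for_loci([locus], cfg.effective_flank, rng)
    haps, _ = simdata.plant_microsatellites(ref, [locus], cfg, origins=("normal",))
    reads = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    region = MicrosatelliteRegion("sim", 30_000, "AC")
    pos, seqs = spanning_mates(region_pairs(reads, region, 2_000))
    obs = extract_lengths(list(zip(pos, seqs)), region)
    assert obs.n >= 50
    assert set(obs.lengths) == {20.0}


# ---------------------------------------------------------------------------
# mixture MLE


def test_mle_pure_tumor_reduces_to_sample_moments(rng):
    x = rng.normal(25, 3, 400)
    prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=100, origin="normal")
    fit = mle_deconvolve(_obs(x), 1.0, prior)
    assert fit.mu == pytest.approx(x.mean())
    assert fit.sigma2 == pytest.approx(x.var())  # MLE divisor N


def test_mle_null_case_recovers_normal_mean(rng):
    x = rng.normal(20, 2, 2000)
    prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=1000, origin="normal")
    fit = mle_deconvolve(_obs(x), 0.5, prior)
    assert abs(fit.mu - 20.0) <= 2 * 2.0 / math.sqrt(0.5 * 2000) * 3


def test_mle_matches_grid_search_oracle(rng):
    x = _mix_sample(rng, 1000, 0.5, 20, 2, 28, 3)
    prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=500, origin="normal")
    fit = mle_deconvolve(_obs(x), 0.5, prior)
    assert abs(fit.mu - 28.0) <= 0.3
    assert abs(fit.sigma - 3.0) <= 0.5
    # dense grid over (mu2, sigma2), step 0.01: the EM solution must sit
    # within one grid step of the exhaustive maximizer
    grid_mu = np.arange(fit.mu - 0.5, fit.mu + 0.5001, 0.01)
    grid_s = np.arange(max(fit.sigma - 0.5, 0.5), fit.sigma + 0.5001, 0.01)
    lls = np.array([
        [mixture_loglik(x, 0.5, 20.0, 2.0, m, s) for s in grid_s] for m in grid_mu
    ])
    i, j = np.unravel_index(np.argmax(lls), lls.shape)
    assert abs(fit.mu - grid_mu[i]) <= 0.011
    assert abs(fit.sigma - grid_s[j]) <= 0.011
    assert mixture_loglik(x, 0.5, 20.0, 2.0, fit.mu, fit.sigma) >= lls[i, j] - 1e-6


def test_mle_downshifted_component_found(rng):
    # the tumor component may sit below the normal one
    x = _mix_sample(rng, 1000, 0.4, 30, 2, 22, 2)
    prior = LengthDistribution(mu=30.0, sigma2=4.0, n_obs=500, origin="normal")
    fit = mle_deconvolve(_obs(x), 0.4, prior)
    assert abs(fit.mu - 22.0) <= 0.5


def test_mle_dominates_truth_likelihood(rng):
    x = _mix_sample(rng, 500, 0.5, 20, 2, 26, 3)
    prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=500, origin="normal")
    fit = mle_deconvolve(_obs(x), 0.5, prior)
    ll_hat = mixture_loglik(x, 0.5, 20, 2, fit.mu, fit.sigma)
    ll_truth = mixture_loglik(x, 0.5, 20, 2, 26, 3)
    assert ll_hat >= ll_truth - 1e-9


def test_mle_rejects_p_zero(rng):
    prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=10, origin="normal")
    with pytest.raises(ValueError):
        mle_deconvolve(_obs([20.0] * 40), 0.0, prior)


def test_mixture_density_integrates_to_one():
    f = lambda x: 0.5 * norm.pdf(x, 20, 2) + 0.5 * norm.pdf(x, 28, 3)
    val, _ = quad(f, -50, 120)
    assert abs(val - 1.0) < 1e-6


def test_roundtrip_resimulation_ks(rng):
    truth = _mix_sample(rng, 5000, 0.5, 20, 2, 28, 3)
    prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=2500, origin="normal")
    fit = mle_deconvolve(_obs(truth), 0.5, prior)
    resim = _mix_sample(rng, 5000, 0.5, 20, 2, fit.mu, fit.sigma)
    assert ks_2samp(truth, resim).statistic < 0.05


# ---------------------------------------------------------------------------
# z-test


def test_z_test_closed_form_example():
    tumor = LengthDistribution(mu=28.0, sigma2=9.0, n_obs=30, origin="tumor")
    normal = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=70, origin="normal")
    call = z_test_state(tumor, normal)
    assert call.z == pytest.approx(8 / math.sqrt(4 / 70 + 9 / 30))
    assert call.z == pytest.approx(13.4, abs=0.05)
    assert call.state == "MSI"


def test_z_test_null_and_boundary():
    same = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=50, origin="tumor")
    normal = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=50, origin="normal")
    call = z_test_state(same, normal)
    assert call.z == 0.0 and call.pvalue == pytest.approx(1.0) and call.state == "MSS"

    # |z| just below the two-sided 5% boundary: strict < keeps MSS
    se = math.sqrt(4 / 50 + 4 / 50)
    shifted = LengthDistribution(mu=20.0 + 1.959963 * se, sigma2=4.0, n_obs=50,
                                 origin="tumor")
    call = z_test_state(shifted, normal)
    assert call.pvalue == pytest.approx(0.05, abs=1e-4)
    assert call.state == "MSS"
    above = LengthDistribution(mu=20.0 + 1.97 * se, sigma2=4.0, n_obs=50,
                               origin="tumor")
    assert z_test_state(above, normal).state == "MSI"


def test_z_test_requires_positive_variance():
    bad = LengthDistribution(mu=20.0, sigma2=0.0, n_obs=50, origin="tumor")
    ok = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=50, origin="normal")
    with pytest.raises(ValueError):
        z_test_state(bad, ok)


def test_power_monotone_in_shift_and_purity(rng):
    """Detection power grows with both the length shift and the purity."""
    def power(shift, p, reps=60):
        hits = 0
        for _ in range(reps):
            x = _mix_sample(rng, 200, p, 20, 2, 20 + shift, 2)
            prior = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=200, origin="normal")
            fit = mle_deconvolve(_obs(x), p, prior)
            t = LengthDistribution(mu=fit.mu, sigma2=fit.sigma2,
                                   n_obs=max(p * 200, 1), origin="tumor")
            n = LengthDistribution(mu=20.0, sigma2=4.0, n_obs=(1 - p) * 200,
                                   origin="normal")
            hits += z_test_state(t, n).state == "MSI"
        return hits / reps

    grid = {(s, p): power(s, p) for s in (1.0, 4.0) for p in (0.3, 0.8)}
    assert grid[(4.0, 0.8)] >= grid[(1.0, 0.8)]
    assert grid[(4.0, 0.8)] >= grid[(4.0, 0.3)] - 0.05
    assert grid[(4.0, 0.8)] > 0.9


def test_fit_normal_floors_degenerate_variance():
    fit = fit_normal(np.full(50, 31.0))
    assert fit.flagged and fit.sigma2 == pytest.approx(0.25)
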