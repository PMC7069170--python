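"""End-to-end pipelines and the simulation study protocols.

This module wires the pieces together: candidate-region detection from
breakpoint-spanning reads, short/long dispatch, per-region calling, and
the three study designs used to characterize the caller —

* fixed-purity state classification of 30 short MSI loci
  (:func:`run_short_experiment`),
* fixed-locus long-tract state classification across purities
  (:func:`run_long_state_experiment`),
* purity-free length recovery across a coverage x locus-count grid
  (:func:`run_coverage_grid`) and across planted lengths
  (:func:`run_long_recovery`).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import longms, mscall, puritydeconv, refscan, shortms, simdata

logger = logging.getLogger(__name__)

#: matching tolerance (bp) when pairing detected regions back to truth
#: loci for per-locus state scoring
LOCUS_MATCH_TOL = 100
#: a region is short-class when at least this many reads fully span it
MIN_SPANNING_SHORT = 10


# ---------------------------------------------------------------------------
# region detection from spanning reads


def spanning_mates(reads: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """(position, sequence) of every breakpoint-spanning mate with sequence."""
    pos_list = []
    seq_list = []
    for kind_col, ref_col, seq_col in (("kind1", "ref1", "seq1"), ("kind2", "ref2", "seq2")):
        mask = (reads[kind_col].to_numpy() == 2) & (reads[seq_col].to_numpy() != "")
        pos_list.append(reads[ref_col].to_numpy()[mask])
        seq_list.extend(reads[seq_col].to_numpy()[mask])
    return np.concatenate(pos_list) if pos_list else np.array([], int), seq_list


def detect_regions(
    reads: pd.DataFrame,
    chrom: str = "sim",
    k: int = refscan.DEFAULT_K,
    l_max: int = refscan.L_MAX,
    max_reads_per_cluster: int = 60,
    min_cluster_size: int = 2,
) -> list[refscan.MicrosatelliteRegion]:
    """Candidate regions from clustered SB-reads plus consensus voting."""
    positions, seqs = spanning_mates(reads)
    if positions.size == 0:
        return []
    clusters = refscan.cluster_sb_reads(positions.tolist(), l_max=l_max)
    regions = []
    for idx in clusters:
        if len(idx) < min_cluster_size:
            continue
        # spread the vote evenly across the cluster: cluster indices are
        # position-sorted, so a head slice would over-sample the left edge
        if len(idx) > max_reads_per_cluster:
            stride = max(1, len(idx) // max_reads_per_cluster)
            idx = idx[::stride][:max_reads_per_cluster]
        candidates = []
        for i in idx:
            hit = refscan.detect_unit_breakpoint(seqs[i], k=k)
            if hit is not None:
                off, unit = hit
                candidates.append((int(positions[i]) + off, unit))
        if candidates:
            regions.append(refscan.consensus_region(candidates, chrom=chrom))
    regions.sort(key=lambda r: r.breakpoint)
    return regions


def region_pairs(
    reads: pd.DataFrame, region: refscan.MicrosatelliteRegion, radius: int
) -> pd.DataFrame:
    """Read pairs with either mate anchored within *radius* of the region."""
    b = region.breakpoint
    r1 = reads["ref1"].to_numpy()
    r2 = reads["ref2"].to_numpy()
    mask = (np.abs(r1 - b) <= radius) | (np.abs(r2 - b) <= radius)
    return reads[mask]


def count_full_spanners(reads: pd.DataFrame, region: refscan.MicrosatelliteRegion) -> int:
    """Reads that span the whole tract (both flanks measurable)."""
    n = 0
    positions, seqs = spanning_mates(region_pairs(reads, region, radius=2_000))
    for pos, seq in zip(positions, seqs):
        off = region.breakpoint - int(pos)
        if off >= 1 and shortms.measure_tract_length(seq, off, region.unit) is not None:
            n += 1
    return n


def is_short_region(
    reads: pd.DataFrame,
    region: refscan.MicrosatelliteRegion,
    min_spanning: int = MIN_SPANNING_SHORT,
) -> bool:
    """Dispatch rule: short-class iff >= *min_spanning* full spanners."""
    return count_full_spanners(reads, region) >= min_spanning


# ---------------------------------------------------------------------------
# per-region calling


def call_short_region(
    region: refscan.MicrosatelliteRegion,
    mixed: pd.DataFrame,
    control: pd.DataFrame,
    purity: float,
    alpha: float = 0.05,
) -> mscall.MSCall:
    """Short-tract path: exact lengths, mixture MLE, z-test."""
    radius = 2_000
    try:
        m_pos, m_seq = spanning_mates(region_pairs(mixed, region, radius))
        obs = shortms.extract_lengths(list(zip(m_pos, m_seq)), region)
        c_pos, c_seq = spanning_mates(region_pairs(control, region, radius))
        ctrl = shortms.extract_lengths(list(zip(c_pos, c_seq)), region)
    except ValueError:
        return mscall.MSCall(chrom=region.chrom, breakpoint=region.breakpoint,
                             unit=region.unit, state="NA")
    prior = shortms.fit_normal(ctrl.lengths, origin="normal")
    if purity <= 0:
        return mscall.MSCall(chrom=region.chrom, breakpoint=region.breakpoint,
                             unit=region.unit, state="NA")
    tumor = shortms.mle_deconvolve(obs, purity, prior)
    if tumor.flagged or tumor.sigma2 < prior.sigma2 / 4.0:
        # the tumor component collapsed onto one or two discrete length
        # values (per-molecule lengths are integers, so the fixed-weight
        # EM can lock onto support points at low purity); instability
        # broadens dispersion if anything, so a component much narrower
        # than the germline one is not credible -- fall back to the
        # normal-sample dispersion as the reported scale
        tumor = replace(tumor, sigma2=max(prior.sigma2, tumor.sigma2), flagged=True)
    # expected component occupancies of the mixed-length set
    normal_for_test = replace(prior, n_obs=max((1.0 - purity) * obs.n, 1.0))
    tumor = replace(tumor, n_obs=max(purity * obs.n, 1.0))
    return shortms.z_test_state(tumor, normal_for_test, region=region, alpha=alpha)


def call_long_region(
    region: refscan.MicrosatelliteRegion,
    mixed: pd.DataFrame,
    control: pd.DataFrame | None,
    purity: float,
    wcfg: longms.WindowConfig,
    alpha: float = 0.05,
) -> mscall.MSCall:
    """Long-tract path: window sweep, moment deconvolution, z-test.

    With ``control=None`` the sample is treated as pure (purity-free
    length recovery): the call carries the sweep estimate and an MSS
    state, with no test performed.
    """
    radius = wcfg.max_window // 2 + wcfg.l_read + 2_000
    sub = region_pairs(mixed, region, radius)
    sweep = longms.window_sweep(sub, region, wcfg)
    if len(sweep.l_set) < wcfg.min_sweeps:
        return mscall.MSCall(chrom=region.chrom, breakpoint=region.breakpoint,
                             unit=region.unit, state="NA", n_sweeps=len(sweep.l_set))
    if len(sweep.l_set) < wcfg.s_max:
        logger.warning("region %s:%d: only %d usable sweeps",
                       region.chrom, region.breakpoint, len(sweep.l_set))
    mixed_dist, sw_p = longms.fit_and_check_normal(sweep.l_set, origin="mixed")
    if mixed_dist.mu <= 0:
        return mscall.MSCall(chrom=region.chrom, breakpoint=region.breakpoint,
                             unit=region.unit, state="NA", shapiro_p=sw_p,
                             n_sweeps=len(sweep.l_set))
    if control is None:
        return mscall.MSCall(
            chrom=region.chrom, breakpoint=region.breakpoint, unit=region.unit,
            mu_tumor=mixed_dist.mu, sigma2_tumor=mixed_dist.sigma2,
            n_obs=mixed_dist.n_obs, state="MSS", shapiro_p=sw_p,
            n_sweeps=len(sweep.l_set),
        )
    csub = region_pairs(control, region, radius)
    csweep = longms.window_sweep(csub, region, wcfg)
    if len(csweep.l_set) < wcfg.min_sweeps:
        return mscall.MSCall(chrom=region.chrom, breakpoint=region.breakpoint,
                             unit=region.unit, state="NA", n_sweeps=len(sweep.l_set))
    normal_dist, _ = longms.fit_and_check_normal(csweep.l_set, origin="normal")
    if purity <= 0:
        return mscall.MSCall(chrom=region.chrom, breakpoint=region.breakpoint,
                             unit=region.unit, state="NA")
    tumor_dist = longms.deconvolve_moments(mixed_dist, purity, normal_dist)
    return longms.call_state_long(
        tumor_dist, normal_dist, region, alpha=alpha,
        shapiro_p=sw_p, n_sweeps=len(sweep.l_set),
    )


# ---------------------------------------------------------------------------
# purity estimation helper


def estimate_purity(p_true: float, rng: np.random.Generator,
                    depth: int = 100, n_sites: int = 200) -> float:
    """Purity recovered end-to-end from simulated SNV read counts."""
    snv = simdata.simulate_snv_counts(p_true, depth, n_sites, rng)
    kept = puritydeconv.filter_sites(snv)
    if len(kept) < 10:
        kept = snv
    return puritydeconv.em_fit(kept).p_hat


def match_regions_to_loci(loci, regions, tol: int = LOCUS_MATCH_TOL):
    """Nearest detected region per truth locus (within tol), else None."""
    out = []
    for locus in loci:
        best = None
        for r in regions:
            d = abs(r.breakpoint - locus.breakpoint)
            if d <= tol and (best is None or d < abs(best.breakpoint - locus.breakpoint)):
                best = r
        out.append(best)
    return out


# ---------------------------------------------------------------------------
# study protocols


def run_short_experiment(
    purity: float,
    n_loci: int = 30,
    coverage: float = 100.0,
    read_length: int = 200,
    seed: int = 0,
    use_em_purity: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Short-tract MSI classification at one purity.

    Simulates *n_loci* short MSI loci, builds tumor/normal pools and an
    independent normal control, mixes at the requested purity, recovers
    the purity from SNV counts, detects regions, calls each by the
    short-tract path and scores with the correct-call criterion.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    cfg = simdata.SimConfig(coverage=coverage, read_length=read_length, purity=purity,
                            n_loci=n_loci, flank_bp=1_500)
    loci = simdata.random_short_loci(n_loci, rng, read_length=read_length)
    ref = simdata.reference_for_loci(loci, cfg.effective_flank, rng)
    haps, _ = simdata.plant_microsatellites(ref, loci, cfg)
    tumor = simdata.simulate_reads(haps, cfg, rng, origin="tumor")
    normal_pool = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    control = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    mixed = simdata.mix_samples(tumor, normal_pool, purity, rng)
    p_hat = estimate_purity(purity, rng) if use_em_purity else purity
    regions = detect_regions(mixed)
    calls = [call_short_region(r, mixed, control, p_hat, alpha=alpha) for r in regions]
    counts = mscall.match_calls(loci, calls, mscall.EvaluationConfig(mode="full"))
    return {
        "loci": loci, "regions": regions, "calls": calls, "purity_hat": p_hat,
        "counts": counts, "metrics": mscall.compute_metrics(counts),
    }


def run_long_state_experiment(
    purities=(0.5, 0.3, 0.1),
    coverage: float = 100.0,
    read_length: int = 200,
    seed: int = 0,
    use_em_purity: bool = True,
    alpha: float = 0.05,
) -> dict:
    """Long-tract state classification of the 30 fixed truth loci.

    One tumor and two normal pools are simulated once; each requested
    purity re-mixes the pools, recovers the purity from SNV counts and
    scores the per-locus MSI flags (state accuracy, unresolved = 0).
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    loci = simdata.long_panel_fixture()
    cfg = simdata.SimConfig(coverage=coverage, read_length=read_length,
                            n_loci=len(loci))
    wcfg = longms.WindowConfig(l_read=read_length)
    ref = simdata.reference_for_loci(loci, cfg.effective_flank, rng)
    haps, _ = simdata.plant_microsatellites(ref, loci, cfg)
    tumor = simdata.simulate_reads(haps, cfg, rng, origin="tumor")
    normal_pool = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    control = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    results = {}
    for p in purities:
        mixed = simdata.mix_samples(tumor, normal_pool, p, rng)
        p_hat = estimate_purity(p, rng) if use_em_purity else p
        regions = detect_regions(mixed)
        by_locus = match_regions_to_loci(loci, regions)
        calls = [
            call_long_region(r, mixed, control, p_hat, wcfg, alpha=alpha)
            if r is not None else None
            for r in by_locus
        ]
        results[p] = {
            "accuracy": mscall.state_accuracy(loci, calls),
            "calls": calls,
            "purity_hat": p_hat,
        }
    return {"loci": loci, "per_purity": results}


def run_long_recovery(
    lengths,
    coverage: float = 100.0,
    read_length: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Pure-sample recovery of planted tract lengths (relative error)."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    loci = []
    for i, mu in enumerate(lengths):
        unit = simdata._random_unit(rng)
        loci.append(simdata.TruthLocus(
            breakpoint=simdata.FIRST_BREAKPOINT + i * simdata.LOCUS_SPACING,
            unit=unit, mu_n=float(mu), sigma_n=simdata.default_sigma(mu),
            mu_t=float(mu), sigma_t=simdata.default_sigma(mu),
        ))
    cfg = simdata.SimConfig(coverage=coverage, read_length=read_length, n_loci=len(loci))
    wcfg = longms.WindowConfig(l_read=read_length)
    ref = simdata.reference_for_loci(loci, cfg.effective_flank, rng)
    haps, _ = simdata.plant_microsatellites(ref, loci, cfg, origins=("tumor",))
    reads = simdata.simulate_reads(haps, cfg, rng, origin="tumor")
    regions = detect_regions(reads)
    by_locus = match_regions_to_loci(loci, regions)
    rows = []
    for locus, region in zip(loci, by_locus):
        mu_hat = math.nan
        if region is not None:
            call = call_long_region(region, reads, None, 1.0, wcfg)
            mu_hat = call.mu_tumor
        rows.append(dict(truth=locus.mu_t, estimate=mu_hat,
                         rel_error=abs(mu_hat - locus.mu_t) / locus.mu_t))
    return pd.DataFrame(rows)


def run_coverage_cell(
    coverage: float,
    n_loci: int,
    read_length: int = 100,
    seed: int = 0,
    min_len: int = 500,
    max_len: int = 5_000,
) -> dict:
    """One cell of the purity-free coverage grid.

    Pure tumor reads; detection plus window-sweep length estimation;
    scored with the correct-call criterion in detection mode.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    loci = simdata.random_long_loci(n_loci, rng, min_len=min_len, max_len=max_len)
    cfg = simdata.SimConfig(coverage=coverage, read_length=read_length, n_loci=n_loci)
    wcfg = longms.WindowConfig(l_read=read_length)
    ref = simdata.reference_for_loci(loci, cfg.effective_flank, rng)
    haps, _ = simdata.plant_microsatellites(ref, loci, cfg, origins=("tumor",))
    reads = simdata.simulate_reads(haps, cfg, rng, origin="tumor")
    regions = detect_regions(reads)
    calls = [call_long_region(r, reads, None, 1.0, wcfg) for r in regions]
    counts = mscall.match_calls(loci, calls, mscall.EvaluationConfig(mode="detection"))
    metrics = mscall.compute_metrics(counts)
    return {"coverage": coverage, "n_loci": n_loci, "counts": counts, "metrics": metrics}


def run_coverage_grid(
    coverages=tuple(range(10, 101, 10)),
    n_loci_list=(20, 40, 60),
    read_length: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """The full coverage x locus-count grid; one row per cell."""
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(coverages) * len(n_loci_list))]
    i = 0
    for m in n_loci_list:
        for c in coverages:
            cell = run_coverage_cell(c, m, read_length=read_length, seed=seeds[i])
            i += 1
            rows.append(dict(coverage=c, n_loci=m,
                             TP=cell["counts"].TP, FP=cell["counts"].FP,
                             TN=cell["counts"].TN, FN=cell["counts"].FN,
                             **cell["metrics"]))
    return pd.DataFrame(rows)
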