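"""On-disk formats, configuration and the command-line interface.

Internal coordinates are 0-based half-open everywhere; every
human-facing TSV is written 1-based inclusive with a header comment
stating the convention.  Alignments are consumed either from BAM/SAM
(via pysam) or from the simulator's internal read-set TSV; references
from FASTA (via pyfaidx); SNV read counts from a TSV table or a paired
tumor-normal VCF.
"""

from __future__ import annotations

import argparse
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import experiments, longms, mscall, puritydeconv, refscan, simdata

logger = logging.getLogger(__name__)

COORD_HEADER = "# coordinates: 1-based inclusive\n"

READS_TSV_COLUMNS = [
    "qname", "sample_origin", "chrom", "pos1", "pos2", "seq1", "seq2",
    "spans_breakpoint", "kind1", "kind2", "tb1", "tb2", "locus_id",
]


@dataclass
class PipelineConfig:
    """Run-wide defaults; every value matches the method's stated default."""

    k: int = 6
    l_max: int = 50_000
    win_bk: int = 5_000
    win_step: int = 1_000
    sweeps: int = 30
    alpha: float = 0.05
    purity: float | None = None  # user override; None -> estimate from SNVs
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        if self.purity is not None and not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")


# ---------------------------------------------------------------------------
# writers / readers (round-trip safe)


def write_fasta(path, records: dict[str, str], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from pyfaidx import Fasta

    return {name: str(rec[:]) for name, rec in Fasta(str(path)).items()}


def write_reads_tsv(path, reads: pd.DataFrame, chrom: str = "sim") -> None:
    """Serialize a simulator read-pair table (positions become 1-based)."""
    out = pd.DataFrame(
        {
            "qname": reads["qname"],
            "sample_origin": reads["origin"],
            "chrom": chrom,
            "pos1": reads["ref1"] + 1,
            "pos2": reads["ref2"] + 1,
            "seq1": reads["seq1"].replace("", "."),
            "seq2": reads["seq2"].replace("", "."),
            "spans_breakpoint": ((reads["kind1"] == 2) | (reads["kind2"] == 2)).astype(int),
            "kind1": reads["kind1"],
            "kind2": reads["kind2"],
            "tb1": reads["tb1"],
            "tb2": reads["tb2"],
            "locus_id": reads["locus_id"],
        }
    )
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        out.to_csv(fh, sep="\t", index=False)


def read_reads_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False,
                     dtype={"seq1": str, "seq2": str})
    return pd.DataFrame(
        {
            "qname": df["qname"],
            "locus_id": df["locus_id"].astype(np.int32),
            "origin": df["sample_origin"],
            "kind1": df["kind1"].astype(np.int8),
            "ref1": df["pos1"].astype(np.int64) - 1,
            "tb1": df["tb1"].astype(np.int32),
            "seq1": df["seq1"].replace(".", ""),
            "kind2": df["kind2"].astype(np.int8),
            "ref2": df["pos2"].astype(np.int64) - 1,
            "tb2": df["tb2"].astype(np.int32),
            "seq2": df["seq2"].replace(".", ""),
        }
    )[simdata.READ_COLUMNS]


def write_truth_tsv(path, loci) -> None:
    rows = [
        dict(locus_id=i, breakpoint=l.breakpoint + 1, unit=l.unit,
             mu_N=l.mu_n, sigma_N=l.sigma_n, mu_T=l.mu_t, sigma_T=l.sigma_t,
             is_msi=int(l.is_msi))
        for i, l in enumerate(loci)
    ]
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        pd.DataFrame(rows).to_csv(fh, sep="\t", index=False)


def read_truth_tsv(path) -> list[simdata.TruthLocus]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        simdata.TruthLocus(
            breakpoint=int(r.breakpoint) - 1, unit=str(r.unit),
            mu_n=float(r.mu_N), sigma_n=float(r.sigma_N),
            mu_t=float(r.mu_T), sigma_t=float(r.sigma_T),
        )
        for r in df.itertuples()
    ]


def write_regions_tsv(path, regions) -> None:
    rows = [
        dict(chrom=r.chrom, start=r.breakpoint + 1, end=r.breakpoint + len(r.unit),
             unit=r.unit, source=r.source)
        for r in regions
    ]
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        pd.DataFrame(rows, columns=["chrom", "start", "end", "unit", "source"]).to_csv(
            fh, sep="\t", index=False
        )


def read_regions_tsv(path) -> list[refscan.MicrosatelliteRegion]:
    df = pd.read_csv(path, sep="\t", comment="#")
    return [
        refscan.MicrosatelliteRegion(chrom=str(r.chrom), breakpoint=int(r.start) - 1,
                                     unit=str(r.unit), source=str(r.source))
        for r in df.itertuples()
    ]


def calls_to_frame(calls) -> pd.DataFrame:
    rows = []
    for c in calls:
        if c is None:
            continue
        rows.append(
            dict(chrom=c.chrom, breakpoint=c.breakpoint + 1, unit=c.unit,
                 n_obs=c.n_obs, mu1=c.mu_normal, sigma2_1=c.sigma2_normal,
                 mu2_hat=c.mu_tumor, sigma2_2_hat=c.sigma2_tumor,
                 z=c.z, pvalue=c.pvalue, shapiro_p=c.shapiro_p,
                 n_sweeps=c.n_sweeps, state=c.state)
        )
    return pd.DataFrame(rows)


def write_calls_tsv(path, calls) -> None:
    with open(path, "w") as fh:
        fh.write(COORD_HEADER)
        calls_to_frame(calls).to_csv(fh, sep="\t", index=False)


def read_calls_tsv(path) -> list[mscall.MSCall]:
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for r in df.itertuples():
        out.append(mscall.MSCall(
            chrom=str(r.chrom), breakpoint=int(r.breakpoint) - 1, unit=str(r.unit),
            mu_normal=float(r.mu1), sigma2_normal=float(r.sigma2_1),
            mu_tumor=float(r.mu2_hat), sigma2_tumor=float(r.sigma2_2_hat),
            n_obs=float(r.n_obs), z=float(r.z), pvalue=float(r.pvalue),
            state=str(r.state), shapiro_p=float(r.shapiro_p), n_sweeps=int(r.n_sweeps),
        ))
    return out


def read_snv_table(path) -> pd.DataFrame:
    """SNV read counts from TSV, or from a paired tumor-normal VCF.

    The VCF must carry AD (allelic depths) per sample; the first sample
    column is taken as the normal, the second as the mixed tumor.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz", ".bcf")):
        import pysam

        rows = []
        with pysam.VariantFile(path) as vf:
            samples = list(vf.header.samples)
            if len(samples) < 2:
                raise ValueError("VCF needs a normal and a tumor sample column")
            for i, rec in enumerate(vf):
                try:
                    ad_n = rec.samples[samples[0]]["AD"]
                    ad_t = rec.samples[samples[1]]["AD"]
                    rows.append(dict(
                        site=i, n_N_ref=ad_n[0], n_N_alt=sum(ad_n[1:]),
                        n_N_d=sum(ad_n),
                        n_TM_ref=ad_t[0], n_TM_alt=sum(ad_t[1:]), n_TM_d=sum(ad_t),
                    ))
                except (KeyError, TypeError) as exc:
                    logger.warning("skipping VCF record %s:%s: %s", rec.chrom, rec.pos, exc)
        return pd.DataFrame(rows, columns=puritydeconv.SITE_COLUMNS)
    return pd.read_csv(path, sep="\t", comment="#")


def read_alignments(path) -> pd.DataFrame:
    """Read pairs from BAM/SAM or the internal read-set TSV.

    For BAM/SAM, unmapped, secondary, supplementary and duplicate records
    are dropped (counts logged); a mate is marked breakpoint-spanning
    when its alignment is soft-clipped by >= 10 bases on either end, with
    the clipped length recorded as tract bases.
    """
    path = str(path)
    if path.endswith(".tsv") or path.endswith(".txt"):
        return read_reads_tsv(path)
    import pysam

    mode = "rb" if path.endswith(".bam") else "r"
    pairs: dict[str, list] = {}
    dropped = 0
    with pysam.AlignmentFile(path, mode) as af:
        for rec in af:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary or rec.is_duplicate:
                dropped += 1
                continue
            clip = 0
            if rec.cigartuples:
                for op, ln in (rec.cigartuples[0], rec.cigartuples[-1]):
                    if op == 4:  # soft clip
                        clip = max(clip, ln)
            pairs.setdefault(rec.query_name, []).append(
                (rec.reference_start, rec.query_sequence or "", clip)
            )
    if dropped:
        logger.info("dropped %d unusable alignment records", dropped)
    rows = []
    for qname, mates in pairs.items():
        if len(mates) != 2:
            continue
        (p1, s1, c1), (p2, s2, c2) = mates
        rows.append(dict(
            qname=qname, locus_id=-1, origin="unknown",
            kind1=2 if c1 >= 10 else 0, ref1=p1, tb1=c1, seq1=s1,
            kind2=2 if c2 >= 10 else 0, ref2=p2, tb2=c2, seq2=s2,
        ))
    if not rows:
        logger.warning("no usable read pairs in %s", path)
        return pd.DataFrame(columns=simdata.READ_COLUMNS)
    return pd.DataFrame(rows)[simdata.READ_COLUMNS]


def write_metrics_tsv(path, rows: pd.DataFrame) -> None:
    rows.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CLI


def _add_common(sp):
    sp.add_argument("--seed", type=int, default=0)
    sp.add_argument("--alpha", type=float, default=0.05)


def build_parser() -> argparse.ArgumentParser:
    ap = argparse.ArgumentParser(
        prog="msdeconv",
        description="Microsatellite length distributions and MSI state from "
                    "mixed tumor-normal sequencing, with tumor-purity deconvolution.",
    )
    sub = ap.add_subparsers(dest="command", required=True)

    sp = sub.add_parser("simulate", help="generate a synthetic mixed-sample dataset")
    sp.add_argument("--purity", type=float, default=0.5)
    sp.add_argument("--coverage", type=float, default=100.0)
    sp.add_argument("--read-length", type=int, default=200)
    sp.add_argument("--loci", default="short30",
                    help="'short30', 'panel30', or an integer count of short loci")
    sp.add_argument("--out-prefix", required=True)
    _add_common(sp)

    sp = sub.add_parser("scan", help="scan a reference FASTA for microsatellites")
    sp.add_argument("fasta")
    sp.add_argument("--out", required=True)
    sp.add_argument("--max-unit", type=int, default=6)

    sp = sub.add_parser("purity", help="estimate tumor purity from SNV read counts")
    sp.add_argument("snv", help="TSV or VCF of paired read counts")
    sp.add_argument("--out", default="-")

    sp = sub.add_parser("call", help="purity -> detection -> short/long dispatch")
    sp.add_argument("--mixed", required=True, help="mixed-sample reads (TSV/BAM/SAM)")
    sp.add_argument("--normal", required=True, help="paired normal reads (TSV/BAM/SAM)")
    sp.add_argument("--snv", help="SNV counts for purity estimation")
    sp.add_argument("--purity", type=float, help="skip estimation, use this purity")
    sp.add_argument("--out", required=True)
    _add_common(sp)

    sp = sub.add_parser("evaluate", help="score calls against a truth table")
    sp.add_argument("truth")
    sp.add_argument("calls")
    sp.add_argument("--mode", choices=["full", "detection"], default="full")
    sp.add_argument("--out", default="-")
    return ap


def _cmd_simulate(args) -> int:
    rng = np.random.default_rng(args.seed)
    if args.loci == "panel30":
        loci = simdata.long_panel_fixture()
        flank = None
    else:
        n = 30 if args.loci == "short30" else int(args.loci)
        loci = simdata.random_short_loci(n, rng, read_length=args.read_length)
        flank = 1_500
    cfg = simdata.SimConfig(coverage=args.coverage, read_length=args.read_length,
                            purity=args.purity, n_loci=len(loci), flank_bp=flank,
                            rng_seed=args.seed)
    ref = simdata.reference_for_loci(loci, cfg.effective_flank, rng)
    haps, _ = simdata.plant_microsatellites(ref, loci, cfg)
    tumor = simdata.simulate_reads(haps, cfg, rng, origin="tumor")
    normal_pool = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    control = simdata.simulate_reads(haps, cfg, rng, origin="normal")
    mixed = simdata.mix_samples(tumor, normal_pool, args.purity, rng)
    snv = simdata.simulate_snv_counts(args.purity, 100, 200, rng)
    prefix = args.out_prefix
    write_truth_tsv(prefix + ".truth.tsv", loci)
    write_reads_tsv(prefix + ".mixed.tsv", mixed)
    write_reads_tsv(prefix + ".normal.tsv", control)
    snv.to_csv(prefix + ".snv.tsv", sep="\t", index=False)
    print(f"wrote {prefix}.{{truth,mixed,normal,snv}}.tsv "
          f"({len(mixed)} mixed pairs, {len(loci)} loci)")
    return 0


def _cmd_scan(args) -> int:
    records = read_fasta(args.fasta)
    regions = []
    for chrom, seq in records.items():
        regions.extend(refscan.scan_reference(seq, chrom=chrom, max_unit=args.max_unit))
    write_regions_tsv(args.out, regions)
    print(f"{len(regions)} candidate regions")
    return 0


def _cmd_purity(args) -> int:
    snv = read_snv_table(args.snv)
    kept = puritydeconv.filter_sites(snv)
    if len(kept) == 0:
        print("no sites pass the somatic filter", file=sys.stderr)
        return 1
    fit = puritydeconv.em_fit(kept)
    line = (f"p_hat={fit.p_hat:.4f}\tn_sites={len(kept)}\t"
            f"loglik={fit.loglik:.2f}\tconverged={fit.converged}")
    if args.out == "-":
        print(line)
    else:
        Path(args.out).write_text(line + "\n")
    return 0


def _cmd_call(args) -> int:
    mixed = read_alignments(args.mixed)
    control = read_alignments(args.normal)
    if args.purity is not None:
        p_hat = args.purity
    elif args.snv:
        snv = read_snv_table(args.snv)
        kept = puritydeconv.filter_sites(snv)
        p_hat = puritydeconv.em_fit(kept if len(kept) else snv).p_hat
    else:
        print("either --purity or --snv is required", file=sys.stderr)
        return 2
    regions = experiments.detect_regions(mixed)
    read_len = max(len(s) for s in mixed["seq1"] if s) if (mixed["seq1"] != "").any() else 100
    wcfg = longms.WindowConfig(l_read=read_len)
    calls = []
    for region in regions:
        if experiments.is_short_region(mixed, region):
            calls.append(experiments.call_short_region(region, mixed, control,
                                                       p_hat, alpha=args.alpha))
        else:
            calls.append(experiments.call_long_region(region, mixed, control,
                                                      p_hat, wcfg, alpha=args.alpha))
    write_calls_tsv(args.out, calls)
    n_msi = sum(c.state == "MSI" for c in calls)
    print(f"purity={p_hat:.3f}  regions={len(regions)}  MSI={n_msi}")
    return 0


def _cmd_evaluate(args) -> int:
    loci = read_truth_tsv(args.truth)
    calls = read_calls_tsv(args.calls)
    counts = mscall.match_calls(loci, calls, mscall.EvaluationConfig(mode=args.mode))
    metrics = mscall.compute_metrics(counts)
    row = dict(n_loci=len(loci), TP=counts.TP, FP=counts.FP, TN=counts.TN,
               FN=counts.FN, **metrics)
    out = pd.DataFrame([row])
    if args.out == "-":
        print(out.to_csv(sep="\t", index=False), end="")
    else:
        write_metrics_tsv(args.out, out)
    return 0


def main(argv=None) -> int:
    logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")
    args = build_parser().parse_args(argv)
    handlers = {
        "simulate": _cmd_simulate,
        "scan": _cmd_scan,
        "purity": _cmd_purity,
        "call": _cmd_call,
        "evaluate": _cmd_evaluate,
    }
    try:
        return handlers[args.command](args)
    except (ValueError, FileNotFoundError) as exc:
        print(f"error: {exc}", file=sys.stderr)
        return 1


if __name__ == "__main__":
    sys.exit(main())
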