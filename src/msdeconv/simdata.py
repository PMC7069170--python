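"""Synthetic tumor-normal microsatellite sequencing data.

The generator reproduces the evaluation protocol for a mixed-sample MSI
caller.  Per-cell microsatellite tract lengths follow a normal
distribution N(mu, sigma^2) that is discretized into seven sigma-bins
(mu - 3 sigma .. mu + 3 sigma) with probabilities 1/6/24/38/24/6/1 %;
each bin is planted as haplotype copies, with copy counts equal to
``round(coverage * bin_probability)``.  Tumor and normal read pools are
simulated as error-free paired-end reads with truth alignments and then
mixed at the tumor purity p, so no external aligner is required.
Binomial SNV read-count tables provide the input for purity recovery.

Truth alignments are emitted per mate as a *kind* code relative to the
donor tract:

====  =====================================================
kind  meaning
====  =====================================================
0     read entirely in the left flank
1     read entirely inside the repeat tract
2     read spans a tract boundary (breakpoint-spanning)
3     read entirely in the right flank
====  =====================================================

Reference coordinates treat the tract as an insertion at the breakpoint
``b``: left-flank reads keep their positions, right-flank reads map to
``b + offset``, and tract/spanning reads anchor at ``b``.  This mirrors
what a clipped alignment against the tract-free reference would report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .refscan import minimal_period

#: default seven-bin discretization of N(mu, sigma^2)
BIN_OFFSETS = (-3, -2, -1, 0, 1, 2, 3)
BIN_PROBS = (0.01, 0.06, 0.24, 0.38, 0.24, 0.06, 0.01)

#: spacing between planted loci on the virtual reference (bp).  Chosen so
#: that the largest analysis window (34 kb) of one locus never reaches a
#: neighbour and so that SB-read clusters of adjacent loci stay more than
#: L_max = 50 kb apart for tracts up to 10 kb.
LOCUS_SPACING = 65_000
FIRST_BREAKPOINT = 30_000

#: weights for repeat-unit lengths 1..6 bp; mono- and di-nucleotide
#: repeats dominate real microsatellite catalogs
UNIT_LEN_WEIGHTS = (0.35, 0.30, 0.15, 0.10, 0.05, 0.05)

READ_COLUMNS = [
    "qname", "locus_id", "origin",
    "kind1", "ref1", "tb1", "seq1",
    "kind2", "ref2", "tb2", "seq2",
]


def default_sigma(mu: float) -> float:
    """Default tract-length SD: max(2, 0.1 mu) bp.

    Gives overlapping but separable normal/tumor distributions at the
    effect sizes used throughout the simulation experiments.
    """
    return max(2.0, 0.1 * float(mu))


@dataclass
class SimConfig:
    """Study conditions for one simulated experiment."""

    region_length: int = 10_000_000
    coverage: float = 100.0
    read_length: int = 200
    insert_mean: float = 400.0
    insert_sd: float = 40.0
    purity: float = 0.5
    n_loci: int = 30
    bin_offsets: tuple = BIN_OFFSETS
    bin_probs: tuple = BIN_PROBS
    rng_seed: int = 0
    #: uniform substitution error rate (reads are error-free by default)
    error_rate: float = 0.0
    #: flank simulated on each side of a tract; None derives the size
    #: needed for the largest 34 kb analysis window
    flank_bp: int | None = None
    #: "spanning" keeps sequences only for breakpoint-spanning mates,
    #: True keeps all, False none
    with_sequences: object = "spanning"

    def __post_init__(self) -> None:
        if abs(sum(self.bin_probs) - 1.0) > 1e-12:
            raise ValueError("bin_probs must sum to 1")
        if len(self.bin_probs) != len(self.bin_offsets):
            raise ValueError("bin_probs and bin_offsets must have equal length")
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if self.read_length <= 0 or self.region_length < self.read_length:
            raise ValueError("need read_length >= 1 and region_length >= read_length")
        if self.insert_mean <= self.read_length:
            raise ValueError("insert_mean must exceed read_length")

    @property
    def effective_flank(self) -> int:
        if self.flank_bp is not None:
            return int(self.flank_bp)
        # half of the largest sweep window plus fragment-length margin
        return int(34_000 // 2 + self.insert_mean + 6 * self.insert_sd + self.read_length)


@dataclass(frozen=True)
class TruthLocus:
    """A planted microsatellite with its normal and tumor length models."""

    breakpoint: int
    unit: str
    mu_n: float
    sigma_n: float
    mu_t: float
    sigma_t: float

    def __post_init__(self) -> None:
        if not 1 <= len(self.unit) <= 6:
            raise ValueError("unit must be 1-6 bp")
        if self.sigma_n < 0 or self.sigma_t < 0:
            raise ValueError("sigmas must be non-negative")

    @property
    def is_msi(self) -> bool:
        return (self.mu_t, self.sigma_t) != (self.mu_n, self.sigma_n)


@dataclass(frozen=True)
class LocusContext:
    """Reference neighbourhood of one planted locus."""

    locus_id: int
    breakpoint: int
    unit: str
    left_flank: str
    right_flank: str


@dataclass(frozen=True)
class PlantedHaplotype:
    """One sigma-bin of one locus in one population.

    ``copies`` haplotype copies carry a tract of exactly ``tract_len`` bp;
    each copy is sequenced to ~1x, so a bin contributes ``copies`` fold
    coverage.
    """

    ctx: LocusContext
    origin: str  # "normal" | "tumor"
    bin_index: int
    tract_len: int
    copies: int

    def tract_sequence(self) -> str:
        u = self.ctx.unit
        reps = self.tract_len // len(u) + 2
        return (u * reps)[: self.tract_len]

    def local_sequence(self) -> str:
        return self.ctx.left_flank + self.tract_sequence() + self.ctx.right_flank


def make_reference(length: int, rng: np.random.Generator) -> str:
    """Uniform random A/C/G/T sequence of the given length."""
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def _patch_boundary_bases(ref: np.ndarray, loci: Sequence[TruthLocus], rng) -> None:
    """Make the bases flanking each insertion point foreign to the unit.

    Prevents a planted tract from extending ambiguously into the flank,
    so the planted length is the measurable truth.  When a unit uses all
    four bases the patch falls back to an arbitrary base.
    """
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for locus in loci:
        unit_bytes = set(locus.unit.encode())
        choices = [b for b in bases if b not in unit_bytes]
        if not choices:
            continue
        for pos in (locus.breakpoint - 1, locus.breakpoint):
            if 0 <= pos < len(ref):
                ref[pos] = choices[int(rng.integers(0, len(choices)))]


def reference_for_loci(loci: Sequence[TruthLocus], flank: int, rng: np.random.Generator) -> str:
    """Random reference long enough to hold every locus neighbourhood."""
    length = max(l.breakpoint for l in loci) + flank + 1
    ref = rng.integers(0, 4, size=length).astype(np.uint8)
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref = lut[ref]
    _patch_boundary_bases(ref, loci, rng)
    return ref.tobytes().decode("ascii")


def _random_unit(rng: np.random.Generator) -> str:
    """Random repeat unit, 1-6 bp, whose minimal period equals its length.

    Units are drawn from at most three distinct bases so that the
    boundary patch in :func:`_patch_boundary_bases` can always terminate
    the tract unambiguously.
    """
    while True:
        ulen = int(rng.choice(6, p=UNIT_LEN_WEIGHTS)) + 1
        alphabet = list("ACGT")
        rng.shuffle(alphabet)
        alphabet = alphabet[: min(3, ulen)] if ulen > 1 else alphabet[:1]
        unit = "".join(alphabet[int(i)] for i in rng.integers(0, len(alphabet), size=ulen))
        if minimal_period(unit) == ulen:
            return unit


def random_short_loci(
    n_loci: int,
    rng: np.random.Generator,
    read_length: int = 200,
    spacing: int = LOCUS_SPACING,
) -> list[TruthLocus]:
    """MSI truth loci shorter than one read length.

    The tumor length differs from the normal length by exactly one
    repeat unit (insertion or deletion with equal probability), the
    canonical minimal slippage event.
    """
    loci = []
    for i in range(n_loci):
        unit = _random_unit(rng)
        mu_n = float(rng.integers(15, min(81, int(0.4 * read_length))))
        shift = len(unit) * (1 if rng.random() < 0.5 else -1)
        mu_t = float(max(12, mu_n + shift))
        if mu_t == mu_n:
            mu_t = mu_n + len(unit)
        loci.append(
            TruthLocus(
                breakpoint=FIRST_BREAKPOINT + i * spacing,
                unit=unit,
                mu_n=mu_n,
                sigma_n=default_sigma(mu_n),
                mu_t=mu_t,
                sigma_t=default_sigma(mu_t),
            )
        )
    return loci


def random_long_loci(
    n_loci: int,
    rng: np.random.Generator,
    min_len: int = 500,
    max_len: int = 5_000,
    tumor_only: bool = True,
    spacing: int = LOCUS_SPACING,
) -> list[TruthLocus]:
    """Long-tract loci (longer than one read length).

    With ``tumor_only`` the normal model equals the tumor model: these
    loci parameterize pure-sample length-recovery experiments where
    purity is ignored.
    """
    loci = []
    for i in range(n_loci):
        unit = _random_unit(rng)
        mu_t = float(rng.integers(min_len, max_len + 1))
        if tumor_only:
            mu_n = mu_t
        else:
            mu_n = float(rng.integers(min_len, max_len + 1))
        loci.append(
            TruthLocus(
                breakpoint=FIRST_BREAKPOINT + i * spacing,
                unit=unit,
                mu_n=mu_n,
                sigma_n=default_sigma(mu_n),
                mu_t=mu_t,
                sigma_t=default_sigma(mu_t),
            )
        )
    return loci


def bin_copy_counts(coverage: float, bin_probs: Sequence[float]) -> list[int]:
    """Copy count per sigma-bin: round(coverage * probability).

    Rounds half away from zero so that 50x keeps its +-3 sigma bins
    (banker's rounding would drop round(0.5) to 0).
    """
    return [int(np.floor(coverage * p + 0.5)) for p in bin_probs]


def plant_microsatellites(
    reference: str,
    loci: Sequence[TruthLocus],
    config: SimConfig,
    origins: Iterable[str] = ("normal", "tumor"),
) -> tuple[list[PlantedHaplotype], pd.DataFrame]:
    """Build the haplotype copies implied by the seven-bin discretization.

    For each locus and population, bin k (offset in -3..3 sigma) carries
    ``round(coverage * prob_k)`` haplotype copies with tract length
    ``round(mu + offset_k * sigma)``.  Returns the haplotypes and a truth
    table of planted lengths.  Loci must not overlap: each neighbourhood
    ``[b - flank, b + flank)`` has to be disjoint from its successors.
    """
    flank = config.effective_flank
    order = sorted(range(len(loci)), key=lambda i: loci[i].breakpoint)
    for a, b in zip(order, order[1:]):
        if loci[b].breakpoint - loci[a].breakpoint < 2 * flank:
            raise ValueError(f"loci {a} and {b} overlap (breakpoints closer than {2 * flank} bp)")
    for i, locus in enumerate(loci):
        if len(locus.unit) > 6:
            raise ValueError(f"locus {i}: unit longer than 6 bp")
        if locus.breakpoint - flank < 0 or locus.breakpoint + flank > len(reference):
            raise ValueError(f"locus {i}: neighbourhood extends beyond the reference")

    counts = bin_copy_counts(config.coverage, config.bin_probs)
    haplotypes: list[PlantedHaplotype] = []
    truth_rows = []
    for locus_id, locus in enumerate(loci):
        ctx = LocusContext(
            locus_id=locus_id,
            breakpoint=locus.breakpoint,
            unit=locus.unit,
            left_flank=reference[locus.breakpoint - flank : locus.breakpoint],
            right_flank=reference[locus.breakpoint : locus.breakpoint + flank],
        )
        for origin in origins:
            mu, sigma = (
                (locus.mu_n, locus.sigma_n) if origin == "normal" else (locus.mu_t, locus.sigma_t)
            )
            for k, (off, c) in enumerate(zip(config.bin_offsets, counts)):
                if c <= 0:
                    continue
                tract_len = max(len(locus.unit), int(round(mu + off * sigma)))
                haplotypes.append(
                    PlantedHaplotype(ctx=ctx, origin=origin, bin_index=k,
                                     tract_len=tract_len, copies=c)
                )
                truth_rows.append(
                    dict(locus_id=locus_id, origin=origin, bin_index=k,
                         bin_offset=off, tract_len=tract_len, copies=c)
                )
    return haplotypes, pd.DataFrame(truth_rows)


def _emit_kinds(s: np.ndarray, read_len: int, flank: int, tract_len: int, breakpoint: int):
    """Vectorized truth emission for reads starting at donor-local s."""
    e = s + read_len
    t0, t1 = flank, flank + tract_len
    in_left = e <= t0
    in_right = s >= t1
    in_tract = (s >= t0) & (e <= t1)
    spans = ~(in_left | in_right | in_tract)
    kind = np.where(in_left, 0, np.where(in_tract, 1, np.where(spans, 2, 3)))
    ref = np.where(
        in_left, breakpoint - flank + s,
        np.where(in_right, breakpoint + (s - t1),
                 np.where(s < t0, breakpoint - flank + s, breakpoint)),
    )
    tb = np.clip(np.minimum(e, t1) - np.maximum(s, t0), 0, None)
    return kind.astype(np.int8), ref.astype(np.int64), tb.astype(np.int32)


def simulate_reads(
    haplotypes: Sequence[PlantedHaplotype],
    config: SimConfig,
    rng: np.random.Generator,
    origin: str | None = None,
) -> pd.DataFrame:
    """Error-free paired-end reads with truth alignments.

    Each haplotype copy is sequenced to ~1x over its local neighbourhood
    (Poisson pair counts, normal fragment lengths), so a locus receives
    ~``coverage``-fold coverage in total.  Returns a read-pair table with
    the columns of :data:`READ_COLUMNS`.
    """
    L = config.read_length
    frames = []
    qbase = 0
    for h in haplotypes:
        if origin is not None and h.origin != origin:
            continue
        flank = len(h.ctx.left_flank)
        G = 2 * flank + h.tract_len
        n_exp = h.copies * G / (2.0 * L)
        n = int(rng.poisson(n_exp))
        if n == 0:
            continue
        frag = rng.normal(config.insert_mean, config.insert_sd, size=n)
        frag = np.clip(np.round(frag), 2 * L, G).astype(np.int64)
        s1 = rng.integers(0, G - frag + 1)
        s2 = s1 + frag - L
        k1, r1, tb1 = _emit_kinds(s1, L, flank, h.tract_len, h.ctx.breakpoint)
        k2, r2, tb2 = _emit_kinds(s2, L, flank, h.tract_len, h.ctx.breakpoint)
        df = pd.DataFrame(
            {
                "qname": np.arange(qbase, qbase + n),
                "locus_id": np.int32(h.ctx.locus_id),
                "origin": h.origin,
                "kind1": k1, "ref1": r1, "tb1": tb1,
                "kind2": k2, "ref2": r2, "tb2": tb2,
            }
        )
        qbase += n
        if config.with_sequences:
            donor = h.local_sequence()
            want_all = config.with_sequences is True
            df["seq1"] = _slice_seqs(donor, s1, k1, L, want_all, config, rng)
            df["seq2"] = _slice_seqs(donor, s2, k2, L, want_all, config, rng)
        else:
            df["seq1"] = ""
            df["seq2"] = ""
        frames.append(df)
    if not frames:
        import warnings

        warnings.warn("coverage too low: no read pairs drawn")
        return pd.DataFrame(columns=READ_COLUMNS)
    return pd.concat(frames, ignore_index=True)[READ_COLUMNS]


def _slice_seqs(donor, starts, kinds, read_len, want_all, config, rng):
    """Sequences for the requested mates ('' elsewhere)."""
    n = len(starts)
    out = np.full(n, "", dtype=object)
    idx = np.arange(n) if want_all else np.flatnonzero(kinds == 2)
    for j in idx:
        s = int(starts[j])
        seq = donor[s : s + read_len]
        if config.error_rate > 0:
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
            hit = rng.random(len(arr)) < config.error_rate
            if hit.any():
                lut = np.frombuffer(b"ACGT", dtype=np.uint8)
                arr[hit] = lut[rng.integers(0, 4, size=int(hit.sum()))]
                seq = arr.tobytes().decode("ascii")
        out[j] = seq
    return out


def mix_samples(
    tumor_reads: pd.DataFrame,
    normal_reads: pd.DataFrame,
    p: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Mix two read pools at tumor purity p.

    Each tumor pair is kept with probability p and each normal pair with
    probability 1 - p, so pools simulated at equal coverage yield a mixed
    sample at the same total coverage with a binomial tumor fraction.
    Origin labels are retained for evaluation only.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if p > 0 and len(tumor_reads) == 0:
        raise ValueError("p > 0 requires a non-empty tumor pool")
    if p < 1 and len(normal_reads) == 0:
        raise ValueError("p < 1 requires a non-empty normal pool")
    keep_t = tumor_reads[rng.random(len(tumor_reads)) < p] if p > 0 else tumor_reads.iloc[:0]
    keep_n = normal_reads[rng.random(len(normal_reads)) < (1 - p)] if p < 1 else normal_reads.iloc[:0]
    mixed = pd.concat([keep_t, keep_n], ignore_index=True)
    mixed["qname"] = np.arange(len(mixed))
    return mixed


def simulate_snv_counts(
    p: float,
    depth: int,
    n_sites: int,
    rng: np.random.Generator,
    error_rate: float = 0.01,
) -> pd.DataFrame:
    """Read-count table for heterozygous-somatic SNV sites.

    The normal sample carries only sequencing noise at these sites
    (alt ~ Binomial(depth, error_rate)); in the mixed tumor sample the
    expected alt fraction of a heterozygous somatic SNV is p/2.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if depth < 1 or n_sites < 1:
        raise ValueError("depth and n_sites must be >= 1")
    vaf = (1 - p) * error_rate + p * 0.5
    n_alt = rng.binomial(depth, error_rate, size=n_sites)
    tm_alt = rng.binomial(depth, vaf, size=n_sites)
    return pd.DataFrame(
        {
            "site": np.arange(n_sites),
            "n_N_ref": depth - n_alt,
            "n_N_alt": n_alt,
            "n_N_d": depth,
            "n_TM_ref": depth - tm_alt,
            "n_TM_alt": tm_alt,
            "n_TM_d": depth,
        }
    )


# breakpoint, unit, mu_N, mu_T of the 30 printed long-microsatellite truth
# loci used by the fixed-purity state-classification experiment
_LONG_PANEL_ROWS = [
    (34489, "TCATT", 86, 125),
    (122387, "GGCC", 425, 525),
    (189108, "GCTAC", 46, 120),
    (190653, "CATC", 43, 136),
    (194236, "AAC", 89, 166),
    (251655, "GCT", 71, 111),
    (311313, "ACCA", 56, 236),
    (356789, "GCT", 76, 256),
    (398971, "TTCG", 45, 225),
    (412340, "G", 100, 280),
    (432344, "TGA", 78, 258),
    (473174, "AAGG", 221, 354),
    (501994, "CGCCG", 78, 161),
    (505733, "ACAGGG", 40, 111),
    (526358, "GTCC", 58, 144),
    (612344, "TGC", 90, 270),
    (622735, "GGTTC", 77, 142),
    (677621, "TCA", 70, 200),
    (712345, "GACT", 89, 269),
    (731506, "GA", 146, 203),
    (776166, "TAA", 213, 324),
    (842735, "CTC", 134, 211),
    (866450, "TG", 185, 220),
    (891334, "TCAGC", 105, 285),
    (908385, "AGAAT", 167, 229),
    (910124, "C", 205, 301),
    (929056, "CCG", 120, 210),
    (944729, "GGACT", 90, 190),
    (964608, "AGGGGG", 56, 156),
    (973099, "GGGCAC", 355, 460),
]


def long_panel_fixture(spacing: int | None = LOCUS_SPACING) -> list[TruthLocus]:
    """The 30 printed truth loci (breakpoint, unit, mu_N, mu_T).

    Sigmas are not printed and default to max(2, 0.1 mu).  With
    ``spacing`` set (the default) the printed breakpoints are re-spaced
    onto the simulator's virtual reference so that neighbourhood windows
    stay disjoint; pass ``spacing=None`` to keep the printed positions.
    """
    loci = []
    for i, (bp, unit, mu_n, mu_t) in enumerate(_LONG_PANEL_ROWS):
        b = bp if spacing is None else FIRST_BREAKPOINT + i * spacing
        loci.append(
            TruthLocus(
                breakpoint=b,
                unit=unit,
                mu_n=float(mu_n),
                sigma_n=default_sigma(mu_n),
                mu_t=float(mu_t),
                sigma_t=default_sigma(mu_t),
            )
        )
    return loci
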