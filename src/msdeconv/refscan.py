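"""Discovery of candidate microsatellite regions.

A microsatellite is a tandem repeat of a short motif (the *unit*, at most
6 bp here).  Candidate regions come from two complementary sources:

* a direct scan of the reference for maximal tandem tracts
  (:func:`scan_reference`), and
* clustering of breakpoint-spanning reads (*SB-reads*) by mapping
  position (:func:`cluster_sb_reads`), followed by per-read repeat-unit
  and breakpoint detection (:func:`detect_unit_breakpoint`) and a
  consensus vote (:func:`consensus_region`).

Breakpoints are 0-based positions of the first repeat base; repeat units
are canonicalized to the lexicographically smallest rotation of their
minimal period so that reads entering a tract mid-unit vote for the same
unit as reads entering at a unit boundary.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

DEFAULT_K = 6
MAX_UNIT_LEN = 6
#: longest microsatellite considered (bp); tracts are generally < 50 kb
L_MAX = 50_000

_BASES = "ACGT"


def minimal_period(s: str) -> int:
    """Smallest p such that ``s[i] == s[i + p]`` for every valid i.

    A partial trailing copy is allowed (the period need not divide
    ``len(s)``), which is the right notion for tandem-repeat tracts.
    """
    n = len(s)
    for p in range(1, n + 1):
        if all(s[i] == s[i + p] for i in range(n - p)):
            return p
    return n


def canonical_unit(unit: str) -> str:
    """Lexicographically smallest rotation of the primitive core of *unit*.

    The unit folds to a smaller core only when it is an exact integer
    repetition of it ("AGCAGC" -> "AGC"); a partial trailing match does
    not fold ("TCATT" stays 5 bp even though its string period is 4).
    """
    n = len(unit)
    core = unit
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            core = unit[:p]
            break
    return min(core[i:] + core[:i] for i in range(len(core)))


@dataclass(frozen=True)
class MicrosatelliteRegion:
    """A candidate repeat locus.

    ``breakpoint`` is the 0-based reference position of the first repeat
    base; ``unit`` is stored in canonical rotation.
    """

    chrom: str
    breakpoint: int
    unit: str
    source: str = "scan"  # "scan" | "cluster"

    def __post_init__(self) -> None:
        if not 1 <= len(self.unit) <= MAX_UNIT_LEN:
            raise ValueError(f"repeat unit must be 1-{MAX_UNIT_LEN} bp, got {self.unit!r}")
        if self.breakpoint < 0:
            raise ValueError("breakpoint must be non-negative")


@dataclass
class SBReadSet:
    """Breakpoint-spanning reads: (initial mapping position, sequence) pairs."""

    positions: list[int] = field(default_factory=list)
    sequences: list[str] = field(default_factory=list)

    def add(self, pos: int, seq: str) -> None:
        if pos < 0:
            raise ValueError("position must be non-negative")
        if not seq:
            raise ValueError("sequence must be non-empty")
        self.positions.append(pos)
        self.sequences.append(seq)

    def __len__(self) -> int:
        return len(self.positions)


def scan_reference(
    sequence: str,
    chrom: str = "ref",
    max_unit: int = MAX_UNIT_LEN,
    min_length: int = 2 * DEFAULT_K,
    min_copies: int = 2,
) -> list[MicrosatelliteRegion]:
    """Report every maximal tandem tract with minimal period <= *max_unit*.

    A tract is reported when it is at least *min_length* bp long and holds
    at least *min_copies* copies of its unit.  The default *min_length* of
    2k = 12 bp matches the shortest tract on which the read-level k-mer
    rule can fire, keeping the scan and the read-level detector
    consistent.  Tracts containing ``N`` are skipped.
    """
    if not 1 <= max_unit <= MAX_UNIT_LEN:
        raise ValueError("max_unit must be in [1, 6]")
    n = len(sequence)
    if n == 0:
        return []
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    valid = np.isin(arr, np.frombuffer(b"ACGT", dtype=np.uint8))
    regions: list[MicrosatelliteRegion] = []
    seen: set[tuple[int, int]] = set()  # (start, end) spans already reported
    for p in range(1, max_unit + 1):
        if n <= p:
            continue
        match = (arr[:-p] == arr[p:]) & valid[:-p] & valid[p:]
        # maximal runs of True in `match`
        padded = np.concatenate(([False], match, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for s, e in zip(edges[::2], edges[1::2]):
            tract_len = (e - s) + p  # run of matches plus one period
            if tract_len < min_length or tract_len < min_copies * p:
                continue
            tract = sequence[s : s + tract_len]
            if minimal_period(tract) != p:
                continue  # reported at its true (smaller) period
            span = (int(s), int(s) + tract_len)
            if span in seen:
                continue
            seen.add(span)
            regions.append(
                MicrosatelliteRegion(
                    chrom=chrom,
                    breakpoint=int(s),
                    unit=canonical_unit(tract[:p]),
                    source="scan",
                )
            )
    regions.sort(key=lambda r: (r.breakpoint, r.unit))
    return regions


def cluster_sb_reads(
    positions: Sequence[int] | SBReadSet, l_max: int = L_MAX
) -> list[list[int]]:
    """Single-linkage clustering of SB-read positions.

    Two reads share a cluster iff they are connected by a chain of
    pairwise position distances strictly less than *l_max*.  On the line
    this reduces to splitting the sorted positions at gaps >= *l_max*.
    Returns clusters as lists of indices into the input.
    """
    pos = positions.positions if isinstance(positions, SBReadSet) else list(positions)
    if not pos:
        return []
    order = sorted(range(len(pos)), key=lambda i: pos[i])
    clusters: list[list[int]] = [[order[0]]]
    for prev, cur in zip(order, order[1:]):
        if pos[cur] - pos[prev] < l_max:
            clusters[-1].append(cur)
        else:
            clusters.append([cur])
    return clusters


def detect_unit_breakpoint(
    read_seq: str, k: int = DEFAULT_K, min_run: int | None = None
) -> tuple[int, str] | None:
    """Locate a repeat tract inside a read by the k-mer replicate rule.

    Scanning from the first base, the detector fires at the first offset
    ``i`` where the k-mer ``read_seq[i:i+k]`` reappears at a shift
    ``d <= k`` (``read_seq[i+d:i+d+k]``); the smallest such shift is the
    repeat period, and ``i`` is the candidate breakpoint within the read.
    The periodic run starting at ``i`` must extend at least *min_run*
    (default 2k) bases — the shortest tract the reference scan records —
    which suppresses chance shifted matches in flanking sequence.
    Returns ``(offset, canonical_unit)`` or ``None`` when no replicated
    k-mer exists.
    """
    n = len(read_seq)
    if min_run is None:
        min_run = 2 * k
    if n < 2 * k:
        return None
    for i in range(n - k):
        kmer = read_seq[i : i + k]
        if "N" in kmer:
            continue
        dmax = min(k, n - k - i)
        for d in range(1, dmax + 1):
            if kmer == read_seq[i + d : i + d + k]:
                end = i + d + k
                while end < n and read_seq[end] == read_seq[end - d]:
                    end += 1
                if end - i >= min_run:
                    return i, canonical_unit(read_seq[i : i + d])
                # short chance repeat: keep scanning
    return None


def consensus_region(
    candidates: Iterable[tuple[int, str]], chrom: str = "ref"
) -> MicrosatelliteRegion:
    """Vote per-read (absolute breakpoint, unit) candidates into a region.

    The modal unit (after canonicalization) and the modal absolute
    breakpoint are taken separately; ties break toward the smallest
    breakpoint, then the lexicographically smallest unit.
    """
    cands = [(int(b), canonical_unit(u)) for b, u in candidates]
    if not cands:
        raise ValueError("consensus_region requires at least one candidate")
    bp_counts = Counter(b for b, _ in cands)
    unit_counts = Counter(u for _, u in cands)
    best_bp = min(bp_counts, key=lambda b: (-bp_counts[b], b))
    best_unit = min(unit_counts, key=lambda u: (-unit_counts[u], u))
    return MicrosatelliteRegion(
        chrom=chrom, breakpoint=best_bp, unit=best_unit, source="cluster"
    )
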