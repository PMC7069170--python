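"""Truth-vs-call evaluation: the correct-call criterion and metrics.

A call is *correct* when its canonical repeat unit matches the truth
unit, its breakpoint lies within +-10 bp of the planted breakpoint, and
the true tumor tract length lies inside the reported 3-sigma band
(mu_hat - 3 sigma_hat, mu_hat + 3 sigma_hat).  Confusion counts feed the
five metrics: accuracy, recall, precision, Gain = (TP - FP)/(TP + FN),
and the Matthews correlation coefficient.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


from .refscan import canonical_unit


@dataclass
class MSCall:
    """One called microsatellite with its estimated distributions."""

    chrom: str
    breakpoint: int
    unit: str
    mu_normal: float = math.nan
    sigma2_normal: float = math.nan
    mu_tumor: float = math.nan
    sigma2_tumor: float = math.nan
    n_obs: float = 0.0
    z: float = math.nan
    pvalue: float = math.nan
    state: str = "NA"  # "MSI" | "MSS" | "NA"
    shapiro_p: float = math.nan
    n_sweeps: int = 0


@dataclass
class ConfusionCounts:
    TP: int = 0
    FP: int = 0
    TN: int = 0
    FN: int = 0

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.TN, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class EvaluationConfig:
    """Matching rules for the correct-call criterion.

    ``mode`` selects what counts as a positive call:

    * ``"full"``      -- calls with state MSI (state classification and
                         correct-call criterion both required for a TP);
    * ``"detection"`` -- every call with a converged length estimate
                         (purity-free length-recovery experiments);
    * ``"state"``     -- handled by :func:`state_accuracy`.
    """

    breakpoint_tol: int = 10
    require_unit_match: bool = True
    mode: str = "full"

    def __post_init__(self) -> None:
        if self.breakpoint_tol < 0:
            raise ValueError("breakpoint_tol must be >= 0")


def _is_positive(call: MSCall, mode: str) -> bool:
    if mode == "detection":
        return call.state != "NA" and math.isfinite(call.mu_tumor)
    return call.state == "MSI"


def _matches(truth, call: MSCall, cfg: EvaluationConfig) -> bool:
    if abs(call.breakpoint - truth.breakpoint) > cfg.breakpoint_tol:
        return False
    if cfg.require_unit_match and canonical_unit(call.unit) != canonical_unit(truth.unit):
        return False
    sigma = math.sqrt(call.sigma2_tumor) if call.sigma2_tumor > 0 else 0.0
    lo, hi = call.mu_tumor - 3 * sigma, call.mu_tumor + 3 * sigma
    return lo <= truth.mu_t <= hi


def match_calls(
    truth: Sequence, calls: Sequence[MSCall], cfg: EvaluationConfig | None = None
) -> ConfusionCounts:
    """Score calls against truth loci by the correct-call criterion.

    Positive calls (per ``cfg.mode``) match at most one truth locus; when
    several positives hit one locus the closest breakpoint is scored and
    the rest are false positives.  MSI truth loci without a matching
    positive are false negatives; MSS truth loci are true negatives when
    no positive call lands on them, false positives otherwise.
    """
    cfg = cfg or EvaluationConfig()
    positives = [c for c in calls if _is_positive(c, cfg.mode)]
    claimed: dict[int, MSCall] = {}
    fp = 0
    for call in sorted(positives, key=lambda c: c.breakpoint):
        best = None
        for t_idx, t in enumerate(truth):
            if t_idx in claimed or not _matches(t, call, cfg):
                continue
            d = abs(call.breakpoint - t.breakpoint)
            if best is None or d < best[0]:
                best = (d, t_idx)
        if best is None:
            fp += 1
        else:
            claimed[best[1]] = call
    tp = fn = tn = 0
    for t_idx, t in enumerate(truth):
        # in detection mode every planted locus is a target to recover
        if t.is_msi or cfg.mode == "detection":
            if t_idx in claimed:
                tp += 1
            else:
                fn += 1
        else:
            if t_idx in claimed:
                fp += 1  # a positive call landing on an MSS locus is a miscall
            else:
                tn += 1
    return ConfusionCounts(TP=tp, FP=fp, TN=tn, FN=fn)


def state_accuracy(truth: Sequence, calls_by_locus: Sequence[MSCall | None]) -> float:
    """State-only accuracy: the fraction of loci whose MSI/MSS flag is right.

    Mirrors the per-purity binary-flag scoring of the fixed-locus
    classification experiment: an unresolved locus (no call, or state NA)
    scores 0.
    """
    if len(truth) == 0:
        raise ValueError("no truth loci")
    good = 0
    for t, c in zip(truth, calls_by_locus):
        if c is None or c.state == "NA":
            continue
        want = "MSI" if t.is_msi else "MSS"
        good += int(c.state == want)
    return good / len(truth)


def compute_metrics(c: ConfusionCounts) -> dict[str, float]:
    """The five printed metrics; zero-denominator entries are NaN.

    MCC is the only exception: a zero denominator reports 0 (the
    conventional value for a degenerate contingency table).
    """
    tp, fp, tn, fn = float(c.TP), float(c.FP), float(c.TN), float(c.FN)

    def ratio(num: float, den: float) -> float:
        return num / den if den > 0 else math.nan

    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    return {
        "accuracy": ratio(tp + tn, tp + tn + fn + fp),
        "recall": ratio(tp, tp + fn),
        "precision": ratio(tp, tp + fp),
        "gain": ratio(tp - fp, tp + fn),
        "mcc": (tp * tn - fp * fn) / mcc_den if mcc_den > 0 else 0.0,
    }
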