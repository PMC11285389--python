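"""Benchmarking of TD call sets against truth, and cross-caller concordance.

A truth duplication counts as recalled (TP) when the union of calls
overlapping it covers more than half of its length; calls touching no
recalled truth are false positives. Sensitivity, precision and F1 follow
from the counts; boundary bias is the mean absolute deviation of matched
call edges from the true breakpoints. The overlap density score (ODS)
compares call sets from different methods without truth: the mean number of
events shared with each other method, weighted by the sharing ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Interval",
    "MatchResult",
    "OdsResult",
    "match_calls",
    "prf",
    "boundary_bias",
    "ods",
]

Interval = tuple[str, int, int]  # chrom, start, end (0-based half-open)


def _overlap(a: Interval, b: Interval) -> int:
    if a[0] != b[0]:
        return 0
    return max(0, min(a[2], b[2]) - max(a[1], b[1]))


@dataclass
class MatchResult:
    """Counts and matched (call, truth) pairs for one sample."""

    tp: int
    fp: int
    fn: int
    p: int
    pairs: list[tuple[Interval, Interval]] = field(default_factory=list)


def match_calls(calls: list[Interval], truth: list[Interval]) -> MatchResult:
    """Match calls to truth with the >50%-coverage true-positive rule.

    Coverage of a truth interval pools every overlapping call, so a
    fragmented detection still recalls its truth. For boundary statistics
    each recalled truth is paired with its single largest-overlap call
    (ties: leftmost call).
    """
    truth = sorted(truth, key=lambda t: (t[0], t[1], t[2]))
    calls = sorted(calls, key=lambda c: (c[0], c[1], c[2]))
    recalled: list[bool] = []
    pairs: list[tuple[Interval, Interval]] = []
    for t in truth:
        overlapping = [c for c in calls if _overlap(c, t) > 0]
        covered = 0
        lo = t[1]
        # calls are sorted; accumulate union coverage of the truth interval
        for c in overlapping:
            covered += max(0, min(c[2], t[2]) - max(c[1], lo))
            lo = max(lo, c[2])
        ok = covered * 2 > (t[2] - t[1])
        recalled.append(ok)
        if ok:
            best = max(overlapping, key=lambda c: (_overlap(c, t), -c[1]))
            pairs.append((best, t))
    recalled_truth = [t for t, ok in zip(truth, recalled) if ok]
    fp = sum(
        1
        for c in calls
        if not any(_overlap(c, t) > 0 for t in recalled_truth)
    )
    tp = len(recalled_truth)
    return MatchResult(tp=tp, fp=fp, fn=len(truth) - tp, p=len(truth), pairs=pairs)


def prf(match: MatchResult) -> tuple[float, float, float]:
    """(sensitivity, precision, F1); 0/0 ratios evaluate to 0."""
    sens = match.tp / match.p if match.p else 0.0
    denom = match.tp + match.fp
    prec = match.tp / denom if denom else 0.0
    f1 = 2 * prec * sens / (prec + sens) if (prec + sens) else 0.0
    return sens, prec, f1


def boundary_bias(match: MatchResult) -> float:
    """Mean bp deviation of recalled TD boundaries; NaN when no TP.

    For each recalled truth and its matched call, the deviation is the mean
    of the absolute start and end offsets.
    """
    if not match.pairs:
        return float("nan")
    devs = [
        (abs(c[1] - t[1]) + abs(c[2] - t[2])) / 2.0 for c, t in match.pairs
    ]
    return float(np.mean(devs))


def per_call_biases(match: MatchResult) -> list[float]:
    """Boundary deviation of each recalled TD (for pooled averaging)."""
    return [(abs(c[1] - t[1]) + abs(c[2] - t[2])) / 2.0 for c, t in match.pairs]


@dataclass
class OdsResult:
    """Overlap density score of one call set against the other methods."""

    aver_olap: float
    ratio_olap: float

    @property
    def ods(self) -> float:
        return self.aver_olap * self.ratio_olap


def ods(callsets: dict[str, list[Interval]]) -> dict[str, OdsResult]:
    """Overlap density score for every method in ``callsets``.

    For method M, ``aver_olap`` is the number of M's predictions that
    intersect at least one prediction of another method, averaged over the
    other methods; ``ratio_olap`` divides that by M's prediction count; the
    score is their product.
    """
    if len(callsets) < 2:
        raise ValueError("ODS needs at least two call sets")
    out: dict[str, OdsResult] = {}
    for name, calls in callsets.items():
        others = [v for k, v in callsets.items() if k != name]
        if not calls:
            out[name] = OdsResult(aver_olap=0.0, ratio_olap=0.0)
            continue
        counts = []
        for other in others:
            counts.append(
                sum(1 for c in calls if any(_overlap(c, o) > 0 for o in other))
            )
        aver = float(np.mean(counts))
        out[name] = OdsResult(aver_olap=aver, ratio_olap=aver / len(calls))
    return out
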