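"""Candidate tandem-duplication detection by KNN anomaly scoring.

Each unmasked bin contributes one object to a 2-D feature space of
standardized (RD, MQ); the outlier score of an object is the mean Euclidean
distance to its k nearest neighbours (k defaults to 20% of the number of
scored objects). Duplicated regions raise RD and depress MQ, pushing their
bins away from the bulk of the cloud, so high scores flag duplication-like
anomalies without assuming any distribution for the signals.

Scores are summarised per CBS segment (mean over member bins) and a segment
becomes part of a candidate region when its score exceeds the upper boxplot
fence UQ + theta * IQR of the per-object scores; genomically adjacent
above-threshold segments are merged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .config import PipelineConfig
from .profile import ProfileResult, SegmentTable

logger = logging.getLogger(__name__)

__all__ = [
    "OutlierScores",
    "BoxplotCutoff",
    "CandidateRegion",
    "knn_outlier_scores",
    "boxplot_cutoff",
    "segment_scores",
    "select_candidates",
    "detect_candidates",
]


@dataclass
class OutlierScores:
    """Per-object KNN average-distance outlier scores."""

    scores: np.ndarray
    k: int


@dataclass
class BoxplotCutoff:
    """Upper boxplot fence for outlier scores: threshold = UQ + theta * IQR."""

    lq: float
    uq: float
    theta: float

    @property
    def iqr(self) -> float:
        return self.uq - self.lq

    @property
    def threshold(self) -> float:
        return self.uq + self.theta * self.iqr


@dataclass
class CandidateRegion:
    """Rough candidate boundaries [start, end) in base coordinates."""

    chromosome: str
    start: int
    end: int
    score: float
    segment_indices: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


def knn_outlier_scores(features: np.ndarray, k: int) -> OutlierScores:
    """Mean Euclidean distance from each object to its k nearest neighbours.

    Self-distances are excluded; neighbours are found with a KD-tree. ``k`` is
    clamped to ``n_objects - 1`` (with a warning) when too large.
    """
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 2:
        raise ValueError("features must be a 2-D array (objects x features)")
    n = features.shape[0]
    if n < 2:
        raise ValueError("need at least 2 objects to score")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite (drop masked bins first)")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        warnings.warn(f"k={k} >= n_objects={n}; clamping to {n - 1}", stacklevel=2)
        k = n - 1
    nn = NearestNeighbors(n_neighbors=k + 1, algorithm="kd_tree")
    nn.fit(features)
    dist, _ = nn.kneighbors(features)
    # first column is the self-distance (0); with exact duplicates any of the
    # zero-distance columns may come first, which changes nothing
    scores = dist[:, 1:].mean(axis=1)
    return OutlierScores(scores=scores, k=k)


def default_k(n_objects: int, k_fraction: float = 0.2) -> int:
    """Default neighbour count: 20% of the scored objects, at least 1."""
    return max(1, int(round(k_fraction * n_objects)))


def boxplot_cutoff(scores: np.ndarray, theta: float = 0.6) -> BoxplotCutoff:
    """Upper fence of the score boxplot with linear-interpolation quartiles."""
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 4:
        raise ValueError("need at least 4 scores for quartiles")
    lq, uq = np.percentile(scores, [25.0, 75.0])  # linear interpolation
    return BoxplotCutoff(lq=float(lq), uq=float(uq), theta=theta)


def segment_scores(bin_scores: np.ndarray, segments: SegmentTable) -> np.ndarray:
    """Median per-bin outlier score over each segment's member bins.

    ``bin_scores`` is aligned with the unmasked bins in genomic order, which
    is exactly the order in which segments partition them. The median makes
    a segment's score reflect its typical bin: a background segment is not
    promoted by a handful of contaminated bins spilling over from an
    adjacent duplication when a segment boundary lands a few bins off.
    """
    out = np.empty(len(segments), dtype=float)
    offset = 0
    for i, seg in enumerate(segments):
        n = seg.n_bins
        out[i] = float(np.median(bin_scores[offset : offset + n]))
        offset += n
    if offset != bin_scores.size:
        raise ValueError("segment table does not partition the scored bins")
    return out


def select_candidates(
    segment_table: SegmentTable,
    scores: np.ndarray,
    cutoff: BoxplotCutoff,
    lb: int,
    chromosome: str,
    chrom_length: int | None = None,
) -> list[CandidateRegion]:
    """Declare candidate regions from above-threshold segments.

    Segments with score strictly above the threshold *and* positive mean
    standardized RD are candidates (a tandem duplication raises read depth,
    so depth-deficit anomalies are not TD candidates even when their outlier
    score clears the fence); genomically adjacent qualifying segments (no
    masked gap between them) merge into a single region. Boundaries snap to
    bin edges.
    """
    if len(segment_table) != len(scores):
        raise ValueError("scores are not aligned to segments")
    thr = cutoff.threshold
    regions: list[CandidateRegion] = []
    current: CandidateRegion | None = None
    for i, seg in enumerate(segment_table):
        if not (scores[i] > thr and seg.mean_std_rd > 0):
            current = None
            continue
        start = seg.start_bin * lb
        end = seg.end_bin * lb
        if chrom_length is not None:
            end = min(end, chrom_length)
        if current is not None and current.end == start:
            current.end = end
            current.score = max(current.score, float(scores[i]))
            current.segment_indices.append(i)
        else:
            current = CandidateRegion(
                chromosome=chromosome,
                start=start,
                end=end,
                score=float(scores[i]),
                segment_indices=[i],
            )
            regions.append(current)
    return regions


def detect_candidates(
    profile: ProfileResult, config: PipelineConfig | None = None
) -> list[CandidateRegion]:
    """Full candidate stage: score bins, set the fence, merge segments."""
    config = config or PipelineConfig()
    ok = ~profile.grid.n_mask
    feats = np.column_stack([profile.z_rd[ok], profile.z_mq[ok]])
    if feats.shape[0] < 4:
        return []
    k = default_k(feats.shape[0], config.k_fraction)
    scores = knn_outlier_scores(feats, k)
    cutoff = boxplot_cutoff(scores.scores, config.theta)
    seg_scores = segment_scores(scores.scores, profile.segments)
    regions = select_candidates(
        profile.segments,
        seg_scores,
        cutoff,
        lb=config.lb,
        chromosome=profile.grid.chromosome,
        chrom_length=profile.grid.chrom_length,
    )
    logger.info(
        "%s: %d/%d segments above fence %.4f -> %d candidate regions",
        profile.grid.chromosome,
        sum(len(r.segment_indices) for r in regions),
        len(profile.segments),
        cutoff.threshold,
        len(regions),
    )
    return regions
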