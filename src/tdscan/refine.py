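"""Breakpoint classification and refinement from SR and PEM evidence.

A candidate region [a, b) from the read-depth stage has bin-resolution
boundaries. This module sharpens them to base-pair resolution:

* split reads (soft-clipped alignments, CIGAR ``xMyS`` pre-alignment or
  ``ySxM`` post-alignment) pin the duplication junction exactly: a
  post-aligned clip near the start gives the start breakpoint A = POS, a
  pre-aligned clip near the end gives the end breakpoint from POS plus its
  matched length;
* the multiple mapping loci of those split reads (SA tag partners)
  distinguish a tandem duplication (partners confined to the region's own
  start/end) from an interspersed duplication (partners at a third locus
  showing both clip patterns), which is dropped from TD output;
* discordant read pairs (everted pairs spanning the junction) refine any
  edge split reads could not, via the outermost qualifying pair positions.

Search windows extend S = m * Lb on each side of the rough boundaries; an
edge never moves more than 2S. Unrefined edges keep the bin-level boundary
and are flagged as such. Coordinates are 0-based half-open internally.
"""

from __future__ import annotations

import logging
import re
from collections import Counter
from dataclasses import dataclass, field

import pysam

from .config import PipelineConfig
from .detect import CandidateRegion

logger = logging.getLogger(__name__)

__all__ = [
    "SplitReadEvidence",
    "PartnerAlignment",
    "DiscordantPairEvidence",
    "RefinementConfig",
    "TDCall",
    "harvest_split_reads",
    "classify_duplication",
    "refine_with_sr",
    "harvest_discordant_pairs",
    "refine_with_pem",
    "call_tds",
]

_CLIP_OPS = {4, 5}  # S, H
_MATCH_OPS = {0, 7, 8}  # M, =, X
_SA_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass
class RefinementConfig:
    """Breakpoint search parameters.

    ``s`` is the search radius in bases (``m * lb``); split reads are
    harvested in [a-S, a+S] and [b-S, b+S], and a refined edge may move at
    most 2S from its bin-level position. ``min_clip`` is the shortest
    soft-clip trusted as breakpoint evidence.
    """

    m: int = 2
    lb: int = 1000
    r_l: int = 100
    min_clip: int = 20

    @property
    def s(self) -> int:
        return self.m * self.lb

    @classmethod
    def from_pipeline(cls, config: PipelineConfig) -> "RefinementConfig":
        return cls(m=config.m, lb=config.lb, r_l=config.r_l, min_clip=config.min_clip)


@dataclass
class PartnerAlignment:
    """Another mapping locus of a split read, parsed from its SA tag."""

    pos: int
    orientation: str  # 'pre' | 'post'
    matched_len: int
    clipped_len: int

    @property
    def breakpoint(self) -> int:
        # post clips point at their POS; pre clips at the end of the match
        return self.pos if self.orientation == "post" else self.pos + self.matched_len


@dataclass
class SplitReadEvidence:
    """One soft-clipped alignment matching the xMyS / ySxM patterns."""

    qname: str
    pos: int  # leftmost mapped reference coordinate (0-based)
    matched_len: int  # x
    clipped_len: int  # y
    orientation: str  # 'pre' (xMyS) | 'post' (ySxM)
    partners: list[PartnerAlignment] = field(default_factory=list)

    @property
    def breakpoint(self) -> int:
        return self.pos if self.orientation == "post" else self.pos + self.matched_len


@dataclass
class DiscordantPairEvidence:
    """A discordant pair anchored near the candidate start."""

    qname: str
    read_pos: int
    mate_pos: int
    insert_size: int


@dataclass
class TDCall:
    """A called tandem duplication with refined boundaries [start, end)."""

    chromosome: str
    start: int
    end: int
    classification: str  # 'tandem' | 'unresolved'
    source_start: str  # 'SR' | 'PEM' | 'bin'
    source_end: str
    score: float

    @property
    def length(self) -> int:
        return self.end - self.start


def _clip_pattern(cigartuples) -> tuple[str, int, int] | None:
    """Classify a CIGAR as ('pre'|'post', matched_len, clipped_len) or None.

    Only the two single-clip patterns carry junction information: match then
    clip (pre-alignment) or clip then match (post-alignment). Hard clips are
    treated like soft clips, as supplementary alignments often use them.
    """
    if cigartuples is None or len(cigartuples) != 2:
        return None
    (op1, n1), (op2, n2) = cigartuples
    if op1 in _MATCH_OPS and op2 in _CLIP_OPS:
        return "pre", n1, n2
    if op1 in _CLIP_OPS and op2 in _MATCH_OPS:
        return "post", n2, n1
    return None


def _parse_sa_tag(sa: str) -> list[PartnerAlignment]:
    partners = []
    for entry in sa.rstrip(";").split(";"):
        if not entry:
            continue
        fields = entry.split(",")
        if len(fields) < 4:
            continue
        pos = int(fields[1]) - 1  # SA tag positions are 1-based
        tuples = [
            ({"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}[op], int(n))
            for n, op in _SA_CIGAR_RE.findall(fields[3])
        ]
        pat = _clip_pattern(tuples)
        if pat is None:
            continue
        orientation, x, y = pat
        partners.append(
            PartnerAlignment(pos=pos, orientation=orientation, matched_len=x, clipped_len=y)
        )
    return partners


def harvest_split_reads(
    bam: pysam.AlignmentFile,
    candidate: CandidateRegion,
    config: RefinementConfig,
) -> list[SplitReadEvidence]:
    """Collect qualifying split reads around both candidate edges.

    Searches [a-S, a+S] and [b-S, b+S]; keeps alignments whose CIGAR is
    exactly one match run plus one clip of at least ``min_clip`` bases.
    Supplementary alignments are included (they carry the partner locus of a
    junction-spanning read); secondary alignments and duplicates are not.
    """
    s = config.s
    windows = [
        (max(0, candidate.start - s), candidate.start + s),
        (max(0, candidate.end - s), candidate.end + s),
    ]
    seen: set[tuple[str, int, int]] = set()
    out: list[SplitReadEvidence] = []
    for lo, hi in windows:
        for read in bam.fetch(candidate.chromosome, lo, hi):
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            pat = _clip_pattern(read.cigartuples)
            if pat is None:
                continue
            orientation, x, y = pat
            if y < config.min_clip or x < 1:
                continue
            key = (read.query_name, read.reference_start, read.flag)
            if key in seen:
                continue
            seen.add(key)
            partners = (
                _parse_sa_tag(read.get_tag("SA")) if read.has_tag("SA") else []
            )
            out.append(
                SplitReadEvidence(
                    qname=read.query_name,
                    pos=read.reference_start,
                    matched_len=x,
                    clipped_len=y,
                    orientation=orientation,
                    partners=partners,
                )
            )
    return out


def _edge_split_reads(
    candidate: CandidateRegion,
    split_reads: list[SplitReadEvidence],
    s: int,
) -> tuple[list[SplitReadEvidence], list[SplitReadEvidence]]:
    """Post-aligned SRs near the start and pre-aligned SRs near the end."""
    posts = [
        sr
        for sr in split_reads
        if sr.orientation == "post" and abs(sr.breakpoint - candidate.start) <= s
    ]
    pres = [
        sr
        for sr in split_reads
        if sr.orientation == "pre" and abs(sr.breakpoint - candidate.end) <= s
    ]
    return posts, pres


def classify_duplication(
    candidate: CandidateRegion,
    split_reads: list[SplitReadEvidence],
    config: RefinementConfig,
) -> str:
    """Tandem vs interspersed vs unresolved, from split-read partner loci.

    Tandem (Fig-2A-like signature): junction reads map to exactly two loci -
    post-aligned at the start breakpoint and pre-aligned at the end
    breakpoint - so every partner locus falls inside the candidate region
    (allowing for the bin-level boundary uncertainty of the depth stage) and
    each locus shows a single clip pattern. An interspersed duplication
    instead routes partners to its insertion site, a third locus that is far
    from the candidate and exhibits *both* clip patterns. No informative SRs
    leaves the candidate unresolved.
    """
    s = config.s
    posts, pres = _edge_split_reads(candidate, split_reads, s)
    informative = [sr for sr in posts + pres if sr.partners]
    if not informative:
        return "unresolved"
    # tolerance for partner loci: candidate boundaries are only bin-accurate,
    # and at low signal-to-noise the depth stage can clip a few kb off an
    # edge, so allow partners within half a candidate length (at least 2S)
    tol = max(2 * s, candidate.length // 2)
    lo, hi = candidate.start - tol, candidate.end + tol
    loci: list[tuple[int, str]] = []
    for sr in posts:
        for p in sr.partners:
            if p.orientation != "pre" or not lo <= p.breakpoint <= hi:
                return "interspersed"
            loci.append((p.breakpoint, "pre"))
    for sr in pres:
        for p in sr.partners:
            if p.orientation != "post" or not lo <= p.breakpoint <= hi:
                return "interspersed"
            loci.append((p.breakpoint, "post"))
    loci.extend((sr.breakpoint, sr.orientation) for sr in posts + pres)
    # both clip patterns at one locus = an insertion site
    loci.sort()
    for (pos1, o1), (pos2, o2) in zip(loci[:-1], loci[1:]):
        if pos2 - pos1 <= config.r_l and o1 != o2:
            return "interspersed"
    return "tandem"


def _majority_breakpoint(
    breakpoints: list[int], anchor: int, max_shift: int | None
) -> int | None:
    """Most-supported breakpoint; ties resolved by proximity to the anchor."""
    if max_shift is None:
        eligible = list(breakpoints)
    else:
        eligible = [bp for bp in breakpoints if abs(bp - anchor) <= max_shift]
    if not eligible:
        return None
    counts = Counter(eligible)
    best = max(counts.items(), key=lambda kv: (kv[1], -abs(kv[0] - anchor), -kv[0]))
    return best[0]


def _overlap_len(a1: int, b1: int, a2: int, b2: int) -> int:
    return max(0, min(b1, b2) - max(a1, a2))


def refine_with_sr(
    candidate: CandidateRegion,
    split_reads: list[SplitReadEvidence],
    config: RefinementConfig,
) -> tuple[int | None, int | None]:
    """SR boundary refinement: A from post clips, B from pre clips.

    Each edge is refined independently. Directly observed clips must lie
    within 2S of the rough boundary. When one edge has no direct split-read
    observation, the partner loci (SA-linked supplementary mappings) of the
    junction reads found at the *other* edge supply the missing breakpoint:
    they are alignments of the same junction-spanning reads, so they may
    move the edge beyond 2S, but only if at least half of the implied
    duplication lies inside the depth-stage candidate (the candidate may be
    larger - a boundary can slop outward, and two nearby duplications can
    merge into one depth anomaly - but junction evidence pointing mostly
    outside it is distrusted). Edges with no evidence at all are reported
    as None and fall through to PEM refinement.
    """
    posts, pres = _edge_split_reads(candidate, split_reads, config.s)
    max_shift = 2 * config.s
    a = _majority_breakpoint([sr.breakpoint for sr in posts], candidate.start, max_shift)
    b = _majority_breakpoint([sr.breakpoint for sr in pres], candidate.end, max_shift)
    a_partner = b_partner = False
    if a is None and pres:
        loci = [
            p.breakpoint
            for sr in pres
            for p in sr.partners
            if p.orientation == "post"
        ]
        a = _majority_breakpoint(loci, candidate.start, None)
        a_partner = a is not None
    if b is None and posts:
        loci = [
            p.breakpoint
            for sr in posts
            for p in sr.partners
            if p.orientation == "pre"
        ]
        b = _majority_breakpoint(loci, candidate.end, None)
        b_partner = b is not None
    if a_partner or b_partner:
        lo = a if a is not None else candidate.start
        hi = b if b is not None else candidate.end
        implied_len = hi - lo
        ov = _overlap_len(lo, hi, candidate.start, candidate.end)
        if implied_len <= 0 or 2 * ov < implied_len:
            if a_partner:
                a = None
            if b_partner:
                b = None
    return a, b


def harvest_discordant_pairs(
    bam: pysam.AlignmentFile,
    candidate: CandidateRegion,
    config: RefinementConfig,
    exclude_qnames: set[str] | None = None,
    start_anchor: int | None = None,
) -> list[DiscordantPairEvidence]:
    """Discordant pairs anchored within S of the candidate start.

    Two filters apply: the read must map within [start-S, start+S], and the
    pair's absolute insert size must lie within 2S of the candidate length.
    Reads that already served as split-read evidence are excluded.
    """
    exclude_qnames = exclude_qnames or set()
    anchor = candidate.start if start_anchor is None else start_anchor
    s = config.s
    lo, hi = max(0, anchor - s), anchor + s
    td_len = candidate.length
    out = []
    for read in bam.fetch(candidate.chromosome, lo, hi):
        if (
            read.is_unmapped
            or read.is_secondary
            or read.is_supplementary
            or read.is_duplicate
            or not read.is_paired
            or read.mate_is_unmapped
        ):
            continue
        if read.is_proper_pair:
            continue
        if read.next_reference_id != read.reference_id:
            continue
        if read.query_name in exclude_qnames:
            continue
        if not lo <= read.reference_start <= hi:
            continue
        tlen = read.template_length
        if tlen == 0:
            continue
        if abs(abs(tlen) - td_len) > 2 * s:
            continue
        out.append(
            DiscordantPairEvidence(
                qname=read.query_name,
                read_pos=read.reference_start,
                mate_pos=read.next_reference_start,
                insert_size=abs(tlen),
            )
        )
    return out


def refine_with_pem(
    candidate: CandidateRegion,
    pairs: list[DiscordantPairEvidence],
    config: RefinementConfig,
) -> tuple[int | None, int | None]:
    """PEM boundary refinement from the outermost qualifying pair positions.

    A is the smallest read position among qualifying discordant reads; B is
    the mate position of the largest-position read plus the read length.
    Only edges split reads left unrefined should take these values.
    """
    if not pairs:
        return None, None
    first = min(pairs, key=lambda p: p.read_pos)
    last = max(pairs, key=lambda p: p.read_pos)
    a = first.read_pos
    b = last.mate_pos + config.r_l
    max_shift = 2 * config.s
    a_ok = abs(a - candidate.start) <= max_shift
    b_ok = abs(b - candidate.end) <= max_shift and b > a
    return (a if a_ok else None), (b if b_ok else None)


def _merge_overlapping(calls: list[TDCall]) -> list[TDCall]:
    """Merge overlapping calls into the widest extent."""
    if not calls:
        return calls
    calls = sorted(calls, key=lambda c: (c.chromosome, c.start, c.end))
    merged = [calls[0]]
    for call in calls[1:]:
        prev = merged[-1]
        if call.chromosome == prev.chromosome and call.start < prev.end:
            prev.end = max(prev.end, call.end)
            prev.score = max(prev.score, call.score)
            prev.source_end = call.source_end
            if call.classification == "tandem":
                prev.classification = "tandem"
        else:
            merged.append(call)
    return merged


def call_tds(
    bam: pysam.AlignmentFile | str,
    candidates: list[CandidateRegion],
    config: RefinementConfig | PipelineConfig,
) -> list[TDCall]:
    """Classify, filter and refine every candidate region into TD calls.

    Interspersed duplications are logged and dropped. Candidates without
    any junction evidence are retained with bin-level boundaries (flagged
    ``bin``): at low coverage and purity the depth signal is frequently the
    only signal present (junction-informative fragments per event are
    Poisson with mean of order one), and dropping such candidates would
    cost most of the sensitivity exactly where the method is meant to work.
    An edge that could not be refined keeps its bin-level boundary.
    Overlapping final calls merge into the widest extent.
    """
    if isinstance(config, PipelineConfig):
        config = RefinementConfig.from_pipeline(config)
    own_handle = isinstance(bam, str)
    handle = pysam.AlignmentFile(bam) if own_handle else bam
    calls: list[TDCall] = []
    try:
        for cand in candidates:
            srs = harvest_split_reads(handle, cand, config)
            classification = classify_duplication(cand, srs, config)
            if classification == "interspersed":
                logger.info(
                    "dropping interspersed duplication candidate %s:%d-%d",
                    cand.chromosome,
                    cand.start,
                    cand.end,
                )
                continue
            a_sr, b_sr = refine_with_sr(cand, srs, config)
            a, b = a_sr, b_sr
            src_a = "SR" if a is not None else "bin"
            src_b = "SR" if b is not None else "bin"
            if a is None or b is None:
                anchor = a if a is not None else cand.start
                pairs = harvest_discordant_pairs(
                    handle,
                    cand,
                    config,
                    exclude_qnames={sr.qname for sr in srs},
                    start_anchor=anchor,
                )
                a_pem, b_pem = refine_with_pem(cand, pairs, config)
                if a is None and a_pem is not None:
                    a, src_a = a_pem, "PEM"
                if b is None and b_pem is not None:
                    b, src_b = b_pem, "PEM"
            if a is None:
                a = cand.start
            if b is None:
                b = cand.end
            if b <= a:  # conflicting evidence; keep the depth-stage extent
                a, b, src_a, src_b = cand.start, cand.end, "bin", "bin"
            calls.append(
                TDCall(
                    chromosome=cand.chromosome,
                    start=a,
                    end=b,
                    classification=classification,
                    source_start=src_a,
                    source_end=src_b,
                    score=cand.score,
                )
            )
    finally:
        if own_handle:
            handle.close()
    return _merge_overlapping(calls)
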