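"""Paired-end read simulator for tandem-duplication benchmarking.

The simulator replaces the usual FASTA -> read generator -> aligner chain
with direct BAM synthesis: a random reference with drifting GC content is
generated, duplications are implanted into a variant ("donor") haplotype,
and paired-end alignments are written straight in reference coordinates.
Junction signals are constructed to be exactly what an ideal aligner would
report:

* reads spanning the copy1->copy2 junction of a tandem duplication become
  soft-clipped records (post-aligned ``ySxM`` at the start breakpoint,
  pre-aligned ``xMyS`` at the end breakpoint) with SA-tagged partner loci
  and a supplementary record for the clipped part;
* pairs straddling the junction without either read crossing it map as
  discordant (everted) pairs whose apparent insert size is close to the
  duplication length;
* reads originating from duplicated sequence get their MAPQ degraded
  (uniform 0-30) with probability 0.5 as an explicit stand-in for the
  multi-mapping ambiguity that depresses MQ over real duplications.

Tumor purity follows the mutant/normal FASTQ mixing protocol: a fraction
``purity`` of read pairs is drawn from the variant genome and the rest from
the reference, holding total depth fixed, so the expected in-duplication
read-depth multiplier is ``1 + purity``.

Everything is deterministic given (config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pysam

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "TruthRecord",
    "DonorGenome",
    "SimResult",
    "generate_reference",
    "implant_tds",
    "simulate_reads",
    "simulate_sample",
]

_GC_BLOCK = 10_000
_MIN_SUPPL_MATCH = 20  # shortest clipped part re-reported as supplementary


@dataclass
class SimConfig:
    """Study conditions for one simulated sample.

    Defaults follow the simulation protocol this package benchmarks against:
    10-50 kbp duplications, 100 bp paired-end reads with a 300 +/- 30 bp
    insert, coverage in {4, 6, 8}, purity in {0.2, 0.4, 0.6}. ``n_tds``
    tandem duplications are implanted; ``interspersed_fraction`` adds that
    fraction again as interspersed duplications (insertion at a distant
    site) for classification testing.
    """

    ref_length: int = 5_000_000
    n_tds: int = 12
    td_size_range: tuple[int, int] = (10_000, 50_000)
    coverage: float = 8.0
    purity: float = 0.6
    r_l: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    seed: int = 0
    interspersed_fraction: float = 0.0
    min_separation: int = 20_000
    chromosome: str = "chr1"
    n_gaps: int = 0
    gap_length: int = 5_000
    mapq_degrade_prob: float = 0.5
    mapq_degrade_max: int = 30
    substitution_rate: float = 0.0
    write_sequences: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError(f"purity must be in [0, 1], got {self.purity}")
        if self.coverage <= 0:
            raise ValueError(f"coverage must be positive, got {self.coverage}")
        if self.ref_length < 10 * self.td_size_range[1]:
            raise ValueError(
                "reference too short: need ref_length >= 10 * max TD size "
                f"({self.ref_length} < {10 * self.td_size_range[1]})"
            )
        if self.td_size_range[0] > self.td_size_range[1]:
            raise ValueError("invalid td_size_range")
        if self.r_l < 20:
            raise ValueError("read length too short")


@dataclass
class TruthRecord:
    """One implanted event, in reference coordinates (0-based half-open)."""

    chromosome: str
    start: int
    end: int
    kind: str  # 'tandem' | 'interspersed'
    insert_site: int | None = None  # interspersed events only

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DonorGenome:
    """Variant haplotype: sequence plus its piecewise mapping to reference.

    ``pieces`` is a colinear decomposition: (donor_start, length, ref_start)
    triples sorted by donor_start. Reference-coordinate discontinuities
    between adjacent pieces are duplication junctions.
    """

    sequence: str
    pieces: list[tuple[int, int, int]]

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimResult:
    """File paths and in-memory truth for one simulated sample."""

    fasta: Path
    bam: Path
    truth_bed: Path
    config_json: Path
    truth: list[TruthRecord]


def _rngs(config: SimConfig) -> tuple[np.random.Generator, ...]:
    seqs = np.random.SeedSequence(config.seed).spawn(3)
    return tuple(np.random.default_rng(s) for s in seqs)


def generate_reference(
    config: SimConfig, rng: np.random.Generator | None = None
) -> str:
    """Random A/C/G/T reference with GC drifting across 10 kb blocks.

    The per-block GC target performs a reflected random walk in
    [0.35, 0.65], giving the GC-correction stage realistic heterogeneity.
    With ``n_gaps > 0``, runs of 'N' are inserted so bin masking is
    exercised.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)[0]
    length = config.ref_length
    n_blocks = -(-length // _GC_BLOCK)
    steps = rng.normal(0.0, 0.04, n_blocks)
    gc_blocks = np.empty(n_blocks)
    g = 0.5
    for i in range(n_blocks):
        g = g + steps[i]
        # reflect into [0.35, 0.65]
        if g > 0.65:
            g = 1.30 - g
        if g < 0.35:
            g = 0.70 - g
        gc_blocks[i] = min(max(g, 0.35), 0.65)
    gc_t = np.repeat(gc_blocks, _GC_BLOCK)[:length]
    u_class = rng.random(length)
    u_base = rng.random(length)
    is_gc = u_class < gc_t
    arr = np.where(
        is_gc,
        np.where(u_base < 0.5, ord("G"), ord("C")),
        np.where(u_base < 0.5, ord("A"), ord("T")),
    ).astype(np.uint8)
    if config.n_gaps > 0:
        margin = config.gap_length + 50_000
        for _ in range(config.n_gaps):
            start = int(rng.integers(margin, length - margin))
            arr[start : start + config.gap_length] = ord("N")
    return arr.tobytes().decode("ascii")


def _place_events(
    config: SimConfig, rng: np.random.Generator, gap_free: np.ndarray | None
) -> tuple[list[tuple[int, int]], list[int]]:
    """Non-overlapping event placements and interspersed insertion sites."""
    n_inter = int(round(config.n_tds * config.interspersed_fraction))
    n_events = config.n_tds + n_inter
    lo, hi = config.td_size_range
    # events on a full chromosome are sparse; keep them resolvable at bin
    # resolution on a desk-scale reference (never below 2 * insert_mean)
    min_gap = max(int(config.min_separation), int(2 * config.insert_mean))
    margin = 25_000  # keep events and their search windows off chromosome ends
    for _attempt in range(1000):
        sizes = rng.integers(lo, hi + 1, n_events)
        total = int(sizes.sum())
        if total >= config.ref_length // 3:
            continue
        free = config.ref_length - 2 * margin - total - (n_events - 1) * min_gap
        if free <= 0:
            raise ValueError("reference too short for the requested events")
        offsets = np.sort(rng.uniform(0, free, n_events))
        starts = (
            margin
            + offsets
            + np.concatenate([[0], np.cumsum(sizes[:-1])])
            + np.arange(n_events) * min_gap
        ).astype(np.int64)
        regions = [(int(s), int(s + sz)) for s, sz in zip(starts, sizes)]
        sites: list[int] = []
        ok = True
        if gap_free is not None:
            for s, e in regions:
                if not gap_free[max(0, s - min_gap) : e + min_gap].all():
                    ok = False
                    break
        if ok and n_inter > 0:
            # insertion sites for the interspersed events, away from everything
            occupied = sorted(regions)
            for _ in range(n_inter):
                for _try in range(1000):
                    c = int(rng.integers(margin, config.ref_length - margin))
                    near = any(
                        s - min_gap <= c <= e + min_gap for s, e in occupied
                    ) or any(abs(c - c2) < min_gap for c2 in sites)
                    bad_gap = gap_free is not None and not gap_free[
                        max(0, c - min_gap) : c + min_gap
                    ].all()
                    if not near and not bad_gap:
                        sites.append(c)
                        break
                else:
                    ok = False
                    break
        if ok:
            return regions, sites
    raise RuntimeError("could not place events after 1000 attempts")


def implant_tds(
    reference: str, config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[DonorGenome, list[TruthRecord]]:
    """Implant duplications into a donor haplotype.

    A tandem event duplicates its segment immediately after itself; an
    interspersed event copies the segment to a distant insertion site. Truth
    records are in reference coordinates.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)[1]
    gap_free = None
    if "N" in reference:
        arr = np.frombuffer(reference.encode("ascii"), dtype=np.uint8)
        gap_free = arr != ord("N")
    regions, sites = _place_events(config, rng, gap_free)
    n_inter = len(sites)
    n_events = len(regions)
    # which of the placed regions are the interspersed sources
    which_inter = sorted(
        rng.choice(n_events, size=n_inter, replace=False).tolist()
    )
    kind_of = ["tandem"] * n_events
    site_of: list[int | None] = [None] * n_events
    for j, idx in enumerate(which_inter):
        kind_of[idx] = "interspersed"
        site_of[idx] = sites[j]
    truth = [
        TruthRecord(
            chromosome=config.chromosome,
            start=s,
            end=e,
            kind=kind_of[i],
            insert_site=site_of[i],
        )
        for i, (s, e) in enumerate(regions)
    ]
    # donor assembly: insertion points in reference coordinates
    insertions = []  # (ref_insert_point, src_start, src_end)
    for rec in truth:
        if rec.kind == "tandem":
            insertions.append((rec.end, rec.start, rec.end))
        else:
            insertions.append((rec.insert_site, rec.start, rec.end))
    insertions.sort()
    parts: list[str] = []
    pieces: list[tuple[int, int, int]] = []
    ref_cursor = 0
    donor_cursor = 0
    for point, src_s, src_e in insertions:
        if point > ref_cursor:
            parts.append(reference[ref_cursor:point])
            pieces.append((donor_cursor, point - ref_cursor, ref_cursor))
            donor_cursor += point - ref_cursor
            ref_cursor = point
        parts.append(reference[src_s:src_e])
        pieces.append((donor_cursor, src_e - src_s, src_s))
        donor_cursor += src_e - src_s
    if ref_cursor < len(reference):
        parts.append(reference[ref_cursor:])
        pieces.append((donor_cursor, len(reference) - ref_cursor, ref_cursor))
    donor = DonorGenome(sequence="".join(parts), pieces=pieces)
    assert donor.length == len(reference) + sum(e - s for _, s, e in insertions)
    return donor, truth


# ---------------------------------------------------------------------------
# read synthesis


@dataclass
class _MappedRead:
    pos: int
    ref_span: int  # reference bases consumed by the primary alignment
    cigar: str
    crosses: bool
    # junction fields (crossing reads only)
    p: int = 0  # bases before the junction (map ending at left_end)
    q: int = 0  # bases after the junction (map starting at right_start)
    left_end: int = 0
    right_start: int = 0

    @property
    def primary_is_pre(self) -> bool:
        return self.p >= self.q


def _map_interval(u: int, r_l: int, dstarts, dlens, drefs) -> _MappedRead:
    """Map one read interval [u, u+r_l) from donor to reference."""
    i = int(np.searchsorted(dstarts, u, side="right")) - 1
    boundary = dstarts[i] + dlens[i]
    if u + r_l <= boundary:
        return _MappedRead(
            pos=int(drefs[i] + (u - dstarts[i])),
            ref_span=r_l,
            cigar=f"{r_l}M",
            crosses=False,
        )
    left_end = int(drefs[i] + dlens[i])
    right_start = int(drefs[i + 1])
    if left_end == right_start:  # colinear pieces: no junction here
        return _MappedRead(
            pos=int(drefs[i] + (u - dstarts[i])),
            ref_span=r_l,
            cigar=f"{r_l}M",
            crosses=False,
        )
    p = int(boundary - u)
    q = r_l - p
    if p >= q:
        pos = left_end - p
        cigar = f"{p}M{q}S"
        span = p
    else:
        pos = right_start
        cigar = f"{p}S{q}M"
        span = q
    return _MappedRead(
        pos=pos,
        ref_span=span,
        cigar=cigar,
        crosses=True,
        p=p,
        q=q,
        left_end=left_end,
        right_start=right_start,
    )


_COMP = bytes.maketrans(b"ACGTN", b"TGCAN")


def _revcomp(s: str) -> str:
    return s.encode("ascii").translate(_COMP)[::-1].decode("ascii")


def simulate_reads(
    reference: str,
    donor: DonorGenome,
    config: SimConfig,
    bam_path: str | Path,
    rng: np.random.Generator | None = None,
) -> Path:
    """Synthesize a coordinate-sorted, indexed BAM for the mixed sample.

    A fraction ``purity`` of pairs is drawn from the donor haplotype and the
    rest from the reference, at a combined depth of ``coverage``. Alignments
    are emitted directly in reference coordinates; see the module docstring
    for the junction signal model.
    """
    config.validate()
    if rng is None:
        rng = _rngs(config)[2]
    bam_path = Path(bam_path)
    r_l = config.r_l
    chrom = config.chromosome
    ref_len = len(reference)
    pair_rate = config.coverage / (2.0 * r_l)  # pairs per sampled-genome base
    dstarts = np.array([p[0] for p in donor.pieces], dtype=np.int64)
    dlens = np.array([p[1] for p in donor.pieces], dtype=np.int64)
    drefs = np.array([p[2] for p in donor.pieces], dtype=np.int64)
    # duplicated source intervals, for the MAPQ degradation model
    dup_intervals = _duplicated_ref_intervals(donor)
    dup_starts = np.array([iv[0] for iv in dup_intervals], dtype=np.int64)
    dup_ends = np.array([iv[1] for iv in dup_intervals], dtype=np.int64)

    lines: list[str] = []
    positions: list[int] = []

    def in_duplicated(pos: int, span: int) -> bool:
        if dup_starts.size == 0:
            return False
        i = int(np.searchsorted(dup_ends, pos, side="right"))
        return i < dup_starts.size and dup_starts[i] < pos + span

    def emit(pieces_mode: bool, n_pairs: int, prefix: str) -> None:
        if n_pairs <= 0:
            return
        glen = donor.length if pieces_mode else ref_len
        ins = np.rint(
            rng.normal(config.insert_mean, config.insert_sd, n_pairs)
        ).astype(np.int64)
        np.clip(ins, r_l, None, out=ins)
        frag = (rng.random(n_pairs) * (glen - ins + 1)).astype(np.int64)
        u_err = rng.random(n_pairs)  # degradation coin flip per pair's reads
        u_err2 = rng.random(n_pairs)
        degraded_q = rng.integers(0, config.mapq_degrade_max + 1, 2 * n_pairs)
        for j in range(n_pairs):
            u1 = int(frag[j])
            u2 = int(frag[j] + ins[j] - r_l)
            if pieces_mode:
                m1 = _map_interval(u1, r_l, dstarts, dlens, drefs)
                m2 = _map_interval(u2, r_l, dstarts, dlens, drefs)
            else:
                m1 = _MappedRead(pos=u1, ref_span=r_l, cigar=f"{r_l}M", crosses=False)
                m2 = _MappedRead(pos=u2, ref_span=r_l, cigar=f"{r_l}M", crosses=False)
            proper = (
                not m1.crosses
                and not m2.crosses
                and m2.pos - m1.pos == u2 - u1
                and m2.pos >= m1.pos
            )
            qname = f"{prefix}{j}"
            mapq1 = mapq2 = 60
            if pieces_mode and config.mapq_degrade_prob > 0:
                if in_duplicated(m1.pos, m1.ref_span) and u_err[j] < config.mapq_degrade_prob:
                    mapq1 = int(degraded_q[2 * j])
                if in_duplicated(m2.pos, m2.ref_span) and u_err2[j] < config.mapq_degrade_prob:
                    mapq2 = int(degraded_q[2 * j + 1])
            left = min(m1.pos, m2.pos)
            right = max(m1.pos + m1.ref_span, m2.pos + m2.ref_span)
            span = right - left
            tlen1 = span if m1.pos <= m2.pos else -span
            tlen2 = -tlen1
            seq1 = seq2 = "*"
            qual = "*"
            if config.write_sequences:
                src = donor.sequence if pieces_mode else reference
                seq1 = src[u1 : u1 + r_l]
                seq2 = _revcomp(src[u2 : u2 + r_l])
                if config.substitution_rate > 0:
                    seq1 = _mutate(seq1, config.substitution_rate, rng)
                    seq2 = _mutate(seq2, config.substitution_rate, rng)
                qual = "I" * r_l
            for read_idx, (m, mate, mapq, tlen, seq) in enumerate(
                ((m1, m2, mapq1, tlen1, seq1), (m2, m1, mapq2, tlen2, seq2))
            ):
                flag = 0x1 | (0x40 if read_idx == 0 else 0x80)
                flag |= 0x20 if read_idx == 0 else 0x10
                if proper:
                    flag |= 0x2
                tags = ""
                if m.crosses and min(m.p, m.q) >= _MIN_SUPPL_MATCH:
                    # primary + supplementary pair with mutual SA tags
                    if m.primary_is_pre:
                        sup_pos, sup_cigar = m.right_start, f"{m.p}S{m.q}M"
                    else:
                        sup_pos, sup_cigar = m.left_end - m.p, f"{m.p}M{m.q}S"
                    tags = f"\tSA:Z:{chrom},{sup_pos + 1},+,{sup_cigar},60,0;"
                    sup_flag = flag | 0x800
                    sup_tags = f"\tSA:Z:{chrom},{m.pos + 1},+,{m.cigar},60,0;"
                    positions.append(sup_pos)
                    lines.append(
                        f"{qname}\t{sup_flag}\t{chrom}\t{sup_pos + 1}\t{mapq}\t"
                        f"{sup_cigar}\t=\t{mate.pos + 1}\t0\t{seq}\t{qual}{sup_tags}"
                    )
                positions.append(m.pos)
                lines.append(
                    f"{qname}\t{flag}\t{chrom}\t{m.pos + 1}\t{mapq}\t{m.cigar}"
                    f"\t=\t{mate.pos + 1}\t{tlen}\t{seq}\t{qual}{tags}"
                )

    n_norm = int(rng.poisson((1.0 - config.purity) * ref_len * pair_rate))
    n_var = int(rng.poisson(config.purity * donor.length * pair_rate))
    emit(False, n_norm, "n")
    emit(True, n_var, "v")
    logger.info(
        "simulated %d normal + %d variant pairs (%d records)",
        n_norm,
        n_var,
        len(lines),
    )
    order = np.argsort(np.asarray(positions, dtype=np.int64), kind="stable")
    sam_path = bam_path.with_suffix(".tmp.sam")
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{ref_len}\n")
        for i in order:
            fh.write(lines[i])
            fh.write("\n")
    pysam.view("--no-PG", "-b", "-o", str(bam_path), str(sam_path), catch_stdout=False)
    sam_path.unlink()
    pysam.index(str(bam_path))
    return bam_path


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(arr.size) < rate)
    if hits.size:
        bases = np.frombuffer(b"ACGT", dtype=np.uint8)
        arr[hits] = bases[rng.integers(0, 4, hits.size)]
    return arr.tobytes().decode("ascii")


def _duplicated_ref_intervals(donor: DonorGenome) -> list[tuple[int, int]]:
    """Reference intervals whose sequence occurs more than once in the donor."""
    counts: dict[tuple[int, int], int] = {}
    for _, length, ref_start in donor.pieces:
        counts[(ref_start, ref_start + length)] = (
            counts.get((ref_start, ref_start + length), 0) + 1
        )
    # pieces repeated verbatim (the inserted copies) plus the originals they
    # shadow: an inserted piece (s, e) duplicates reference [s, e)
    intervals: list[tuple[int, int]] = []
    seen_ref: list[tuple[int, int]] = []
    for _, length, ref_start in donor.pieces:
        iv = (ref_start, ref_start + length)
        for s2, e2 in seen_ref:
            if iv[0] < e2 and s2 < iv[1]:
                intervals.append((max(iv[0], s2), min(iv[1], e2)))
        seen_ref.append(iv)
    if not intervals:
        return []
    intervals.sort()
    merged = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def write_fasta(sequence: str, path: str | Path, chromosome: str) -> Path:
    """Write a single-record FASTA (60-column lines) and index it."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f">{chromosome}\n")
        for i in range(0, len(sequence), 60):
            fh.write(sequence[i : i + 60])
            fh.write("\n")
    pysam.faidx(str(path))
    return path


def simulate_sample(config: SimConfig, outdir: str | Path) -> SimResult:
    """Generate one complete sample: FASTA+fai, BAM+bai, truth BED, config echo."""
    from .io import write_truth_bed

    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng_ref, rng_implant, rng_reads = _rngs(config)
    reference = generate_reference(config, rng_ref)
    donor, truth = implant_tds(reference, config, rng_implant)
    fasta = write_fasta(reference, outdir / "reference.fa", config.chromosome)
    bam = simulate_reads(reference, donor, config, outdir / "sample.bam", rng_reads)
    truth_bed = outdir / "truth.bed"
    write_truth_bed(truth, truth_bed)
    config_json = outdir / "sim_config.json"
    with open(config_json, "w") as fh:
        json.dump(dataclasses.asdict(config), fh, indent=2, default=list)
        fh.write("\n")
    return SimResult(
        fasta=fasta, bam=bam, truth_bed=truth_bed, config_json=config_json, truth=truth
    )
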