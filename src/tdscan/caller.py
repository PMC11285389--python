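"""End-to-end TD calling: BAM + FASTA -> refined calls (BED/VCF)."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from . import io as tdio
from .config import PipelineConfig
from .detect import detect_candidates
from .profile import ProfileResult, build_profile
from .refine import TDCall, call_tds

logger = logging.getLogger(__name__)

__all__ = ["CallResult", "run_call", "profile_table"]


@dataclass
class CallResult:
    """Calls plus per-stage bookkeeping for one run."""

    calls: list[TDCall]
    profiles: dict[str, ProfileResult] = field(default_factory=dict)
    candidates: dict[str, list] = field(default_factory=dict)
    timings: dict[str, float] = field(default_factory=dict)


def run_call(
    bam_path: str | Path,
    fasta_path: str | Path,
    config: PipelineConfig | None = None,
    chromosomes: list[str] | None = None,
    out_prefix: str | Path | None = None,
) -> CallResult:
    """Run the full caller over every chromosome shared by BAM and FASTA.

    With ``out_prefix`` set, writes ``<prefix>.calls.bed`` (BED6),
    ``<prefix>.calls.vcf`` and ``<prefix>.candidates.bed``. The pipeline is
    deterministic for a fixed config (the segmentation permutation RNG is
    seeded per chromosome from ``config.seed``).
    """
    config = config or PipelineConfig()
    config.validate()
    bam_path, fasta_path = str(bam_path), str(fasta_path)
    with pysam.FastaFile(fasta_path) as fa:
        fa_chroms = {name: length for name, length in zip(fa.references, fa.lengths)}
    with pysam.AlignmentFile(bam_path) as bam:
        bam_chroms = set(bam.references)
    if chromosomes is None:
        chromosomes = [c for c in fa_chroms if c in bam_chroms]
    if not chromosomes:
        raise ValueError("no chromosome shared between BAM and FASTA")
    result = CallResult(calls=[])
    for idx, chrom in enumerate(chromosomes):
        rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, idx], pool_size=4)
        )
        t0 = time.perf_counter()
        profile = build_profile(bam_path, fasta_path, chrom, config, rng=rng)
        t1 = time.perf_counter()
        candidates = detect_candidates(profile, config)
        t2 = time.perf_counter()
        calls = call_tds(bam_path, candidates, config)
        t3 = time.perf_counter()
        result.profiles[chrom] = profile
        result.candidates[chrom] = candidates
        result.calls.extend(calls)
        result.timings[chrom] = t3 - t0
        logger.info(
            "%s: profile %.1fs, detect %.1fs, refine %.1fs -> "
            "%d candidates, %d calls",
            chrom,
            t1 - t0,
            t2 - t1,
            t3 - t2,
            len(candidates),
            len(calls),
        )
    if out_prefix is not None:
        prefix = Path(out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        tdio.write_calls_bed(result.calls, f"{prefix}.calls.bed")
        tdio.write_calls_vcf(
            result.calls,
            f"{prefix}.calls.vcf",
            {c: fa_chroms[c] for c in chromosomes},
        )
        all_candidates = [c for chrom in chromosomes for c in result.candidates[chrom]]
        tdio.write_candidates_bed(all_candidates, f"{prefix}.candidates.bed")
    return result


def profile_table(profile: ProfileResult) -> pd.DataFrame:
    """Debug dump of the per-bin profile as a tidy table."""
    grid = profile.grid
    return pd.DataFrame(
        {
            "chrom": grid.chromosome,
            "bin_start": grid.bin_starts(),
            "bin_end": grid.bin_ends(),
            "rd_raw": profile.rd_raw,
            "rd_gc": profile.rd_gc,
            "rd_smooth": profile.rd_smooth,
            "mq": profile.mq_raw,
            "gc": profile.gc,
            "masked": grid.n_mask,
        }
    )
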