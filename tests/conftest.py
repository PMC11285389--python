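"""Shared fixtures: tiny hand-built FASTA/BAM files and small simulations."""

from __future__ import annotations

from pathlib import Path

import pysam
import pytest


def write_fasta(path: Path, sequences: dict[str, str]) -> Path:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")
    pysam.faidx(str(path))
    return path


def write_bam(
    path: Path,
    records: list[str],
    chrom: str = "chr1",
    length: int = 10_000,
) -> Path:
    """Write SAM record lines (without header) to a sorted, indexed BAM."""
    sam = path.with_suffix(".sam")
    with open(sam, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for line in records:
            fh.write(line + "\n")
    pysam.sort("--no-PG", "-o", str(path), str(sam))
    pysam.index(str(path))
    return path


def simple_record(
    qname: str,
    pos: int,
    cigar: str,
    chrom: str = "chr1",
    flag: int = 0,
    mapq: int = 60,
    rnext: str = "*",
    pnext: int = 0,
    tlen: int = 0,
    tags: str = "",
) -> str:
    """One SAM line; ``pos`` is 0-based (converted to SAM's 1-based)."""
    line = (
        f"{qname}\t{flag}\t{chrom}\t{pos + 1}\t{mapq}\t{cigar}\t{rnext}"
        f"\t{pnext + 1}\t{tlen}\t*\t*"
    )
    return line + (f"\t{tags}" if tags else "")


@pytest.fixture(scope="session")
def tiny_sim(tmp_path_factory):
    """One small simulated sample shared by read-backed tests: 1.5 Mb, 3 TDs,
    8X, purity 0.6."""
    from tdscan import SimConfig, simulate_sample

    outdir = tmp_path_factory.mktemp("tiny_sim")
    cfg = SimConfig(ref_length=1_500_000, n_tds=3, coverage=8.0, purity=0.6, seed=202)
    return cfg, simulate_sample(cfg, outdir)
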