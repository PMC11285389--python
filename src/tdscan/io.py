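"""Reading and writing call sets, truth sets and profile dumps.

Coordinate convention: everything in memory is 0-based half-open; all
emitted BED/VCF text is 1-based with inclusive ends (so a region [s, e) is
printed as ``s+1`` .. ``e``), and the readers here invert that mapping. The
BED writers/readers in this package therefore round-trip each other; files
produced by 0-based tools should be shifted before comparison.
"""

from __future__ import annotations

from pathlib import Path
from typing import TYPE_CHECKING, Iterable

import pysam

if TYPE_CHECKING:  # pragma: no cover
    from .detect import CandidateRegion
    from .refine import TDCall
    from .simulate import TruthRecord

__all__ = [
    "write_calls_bed",
    "write_calls_vcf",
    "write_candidates_bed",
    "write_truth_bed",
    "read_bed",
    "read_vcf",
    "read_intervals",
]


def write_candidates_bed(candidates: "Iterable[CandidateRegion]", path: str | Path) -> None:
    """Candidate dump: BED4 (chrom, start, end, outlier score)."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.chromosome}\t{c.start + 1}\t{c.end}\t{c.score:.6g}\n")


def write_calls_bed(calls: "Iterable[TDCall]", path: str | Path) -> None:
    """Final calls: BED6 (chrom, start, end, name=TD id, score, strand='.')."""
    with open(path, "w") as fh:
        for i, c in enumerate(calls, start=1):
            fh.write(
                f"{c.chromosome}\t{c.start + 1}\t{c.end}\tTD{i}"
                f"\t{c.score:.6g}\t.\n"
            )


def write_truth_bed(truth: "Iterable[TruthRecord]", path: str | Path) -> None:
    """Truth BED4; the name column is the event type.

    Interspersed events append their insertion site as ``interspersed@<pos>``
    (1-based), which is enough to reconstruct the donor layout.
    """
    with open(path, "w") as fh:
        for rec in truth:
            name = rec.kind
            if rec.kind == "interspersed" and rec.insert_site is not None:
                name = f"interspersed@{rec.insert_site + 1}"
            fh.write(f"{rec.chromosome}\t{rec.start + 1}\t{rec.end}\t{name}\n")


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=tdscan
##ALT=<ID=DUP,Description="Duplication">
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">
##INFO=<ID=BKPT,Number=2,Type=String,Description="Refinement source of start,end (SR/PEM/bin)">
"""


def write_calls_vcf(
    calls: "Iterable[TDCall]", path: str | Path, contigs: dict[str, int]
) -> None:
    """Minimal VCF 4.2 with SVTYPE=DUP records for the TD calls.

    Uses the structural-variant anchor convention: POS is the base before
    the first duplicated base, END the last duplicated base (both 1-based),
    SVLEN the duplicated length, so ``END - POS == SVLEN``.
    """
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contigs.items():
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, c in enumerate(calls, start=1):
            pos = max(1, c.start)  # anchor base, 1-based
            info = (
                f"SVTYPE=DUP;END={c.end};SVLEN={c.length};"
                f"BKPT={c.source_start},{c.source_end}"
            )
            fh.write(
                f"{c.chromosome}\t{pos}\tTD{i}\tN\t<DUP>\t"
                f"{c.score:.6g}\tPASS\t{info}\n"
            )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read an emitted BED back to 0-based half-open (chrom, start, end, name)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            chrom, start, end = fields[0], int(fields[1]) - 1, int(fields[2])
            name = fields[3] if len(fields) > 3 else ""
            out.append((chrom, start, end, name))
    return out


def read_vcf(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Read DUP records from a VCF into 0-based half-open intervals.

    Inverts the anchor convention of :func:`write_calls_vcf`: the event
    starts one base after POS and ``rec.stop`` is already its half-open end.
    """
    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            out.append((rec.chrom, rec.start + 1, rec.stop, rec.id or ""))
    return out


def read_intervals(path: str | Path) -> list[tuple[str, int, int, str]]:
    """Dispatch on file extension: .vcf/.vcf.gz via pysam, else BED."""
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz")):
        return read_vcf(path)
    return read_bed(path)
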