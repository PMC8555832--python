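"""Splice-junction extraction from spliced alignments and junction filtering.

Candidate introns are the distinct gaps (CIGAR ``N`` operations) in a set of
spliced alignments. For each candidate, ``n_support`` counts reads carrying
exactly that gap and ``n_spanning`` counts reads whose alignment covers the
last exonic base on both sides of the intron (positions donor-1 and
acceptor), whether spliced or contiguous — the denominator for the
"fraction of reads spanning the intron ends".

Two filter presets mirror common use: nanopore mode (>= 2 supporting reads,
>= 1% of spanning reads, GU-AG motif) and short-read mode (>= 5 supporting
reads, no fraction test, GU-AG motif).

Intron intervals are 0-based half-open internally; the TSV output reports
1-based inclusive coordinates for genome-browser compatibility.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Mapping, Optional, Sequence

import pandas as pd
import pysam
from Bio.Seq import reverse_complement

logger = logging.getLogger(__name__)

_REF_CONSUMING_ALIGNED = {0, 2, 7, 8}  # M, D, =, X cover the reference
_N_OP = 3


@dataclass(frozen=True)
class JunctionCall:
    """One candidate intron: [donor, acceptor) on chrom, with read support."""

    chrom: str
    strand: str
    donor: int
    acceptor: int
    motif: str = ""
    n_support: int = 0
    n_spanning: int = 0
    passes: bool = False

    @property
    def fraction(self) -> float:
        return self.n_support / self.n_spanning if self.n_spanning else 0.0


@dataclass(frozen=True)
class JunctionFilterParams:
    """Thresholds of the junction filter.

    min_fraction None disables the spanning-fraction test (short-read mode).
    """

    min_support: int = 2
    min_fraction: Optional[float] = 0.01
    require_gu_ag: bool = True

    def __post_init__(self) -> None:
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        if self.min_fraction is not None and not 0 <= self.min_fraction <= 1:
            raise ValueError("min_fraction must be in [0, 1]")

    @classmethod
    def nanopore(cls) -> "JunctionFilterParams":
        return cls(min_support=2, min_fraction=0.01, require_gu_ag=True)

    @classmethod
    def short_read(cls) -> "JunctionFilterParams":
        return cls(min_support=5, min_fraction=None, require_gu_ag=True)


def _walk_alignment(rec) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """(covered reference intervals, intron gaps) from one alignment's CIGAR."""
    pos = rec.reference_start
    covered: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    for op, length in rec.cigartuples or []:
        if op in _REF_CONSUMING_ALIGNED:
            if covered and covered[-1][1] == pos:
                covered[-1] = (covered[-1][0], pos + length)
            else:
                covered.append((pos, pos + length))
            pos += length
        elif op == _N_OP:
            gaps.append((pos, pos + length))
            pos += length
        # I, S, H, P consume no reference
    return covered, gaps


def extract_introns(sam_path: str) -> list[JunctionCall]:
    """Candidate introns (no filters applied) from a SAM file of spliced alignments.

    One candidate per distinct (chrom, donor, acceptor); the reported strand
    is the majority read orientation. Records whose CIGAR cannot be walked
    are skipped with a warning and counted.
    """
    reads: list[tuple[str, str, list, list]] = []
    n_skipped = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped or rec.cigartuples is None:
                n_skipped += 1
                continue
            try:
                covered, gaps = _walk_alignment(rec)
            except (ValueError, TypeError):
                n_skipped += 1
                logger.warning("skipping unparseable alignment %s", rec.query_name)
                continue
            strand = "-" if rec.is_reverse else "+"
            reads.append((rec.reference_name, strand, covered, gaps))
    if n_skipped:
        logger.info("extract_introns: %d records skipped", n_skipped)

    support: dict[tuple[str, int, int], list[str]] = {}
    for chrom, strand, _, gaps in reads:
        for donor, acceptor in gaps:
            support.setdefault((chrom, donor, acceptor), []).append(strand)

    calls = []
    for (chrom, donor, acceptor), strands in sorted(support.items()):
        spanning = 0
        for r_chrom, _, covered, _ in reads:
            if r_chrom != chrom:
                continue
            if _covers(covered, donor - 1) and _covers(covered, acceptor):
                spanning += 1
        strand = "+" if strands.count("+") >= strands.count("-") else "-"
        calls.append(
            JunctionCall(chrom=chrom, strand=strand, donor=donor, acceptor=acceptor,
                         n_support=len(strands), n_spanning=spanning)
        )
    return calls


def _covers(intervals: Sequence[tuple[int, int]], pos: int) -> bool:
    return any(s <= pos < e for s, e in intervals)


def motif_check(genome: Mapping[str, str], call: JunctionCall) -> tuple[str, bool]:
    """Sense-strand splice-site dinucleotides and whether they are GU-AG.

    ``genome`` maps chrom to sequence (a dict or a ``pyfaidx.Fasta``). On
    the minus strand the genomic intron is reverse-complemented before
    reading the boundary dinucleotides. Returns (motif like "GU-AG", ok).
    """
    if call.acceptor - call.donor < 4:
        return ("", False)
    seq = str(genome[call.chrom][call.donor : call.acceptor]).upper().replace("U", "T")
    if call.strand == "-":
        seq = reverse_complement(seq)
    motif = f"{seq[:2]}-{seq[-2:]}".replace("T", "U")
    return motif, motif == "GU-AG"


def filter_junctions(
    candidates: Sequence[JunctionCall],
    params: JunctionFilterParams = JunctionFilterParams.nanopore(),
    genome: Optional[Mapping[str, str]] = None,
) -> list[JunctionCall]:
    """Apply support, spanning-fraction and motif filters; set ``passes``.

    A genome is required when ``require_gu_ag`` is set and candidates carry
    no motif yet.
    """
    out = []
    for call in candidates:
        motif, motif_ok = call.motif, call.motif == "GU-AG"
        if params.require_gu_ag and not call.motif:
            if genome is None:
                raise ValueError("require_gu_ag needs a genome to read motifs")
            motif, motif_ok = motif_check(genome, call)
        ok = call.n_support >= params.min_support
        if params.min_fraction is not None:
            ok = ok and call.fraction >= params.min_fraction
        if params.require_gu_ag:
            ok = ok and motif_ok
        out.append(replace(call, motif=motif, passes=ok))
    return out


def junctions_to_frame(calls: Sequence[JunctionCall]) -> pd.DataFrame:
    """BED-like table; start/end are 1-based inclusive intron coordinates."""
    return pd.DataFrame(
        [
            {
                "chrom": c.chrom,
                "start": c.donor + 1,
                "end": c.acceptor,
                "strand": c.strand,
                "motif": c.motif,
                "n_support": c.n_support,
                "n_spanning": c.n_spanning,
                "fraction": c.fraction,
                "passes": c.passes,
            }
            for c in calls
        ]
    )
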