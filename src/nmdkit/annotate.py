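"""Transcript models and NMD-relevant classification.

Parses GTF transcript annotations into spliced-coordinate transcript models
and computes the classifications that matter for nonsense-mediated decay
(NMD): the exon-junction-complex (EJC) "50-nt rule" (a 3'UTR exon-exon
junction more than ``d_ejc`` nt downstream of the stop codon), the presence
of an out-of-frame upstream AUG in the 5'UTR (a broad uORF proxy), and the
selection of one representative isoform per shared stop codon (longest CDS,
then longest transcript, then lexicographically smallest id).

Conventions
-----------
All internal coordinates are 0-based half-open genomic intervals and 0-based
transcript offsets; GTF input is 1-based inclusive and converted on parse.
The stop codon is counted as part of the CDS internally (``cds_end_t`` is
the transcript offset of the *last* nucleotide of the stop codon) because
junction distances are measured downstream of the stop codon.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import gffutils

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")


class GTFParseError(ValueError):
    """Raised for structurally malformed GTF input, naming the line."""


class CoordinateError(ValueError):
    """Raised when a genomic position does not map into a transcript."""


@dataclass(frozen=True)
class ClassifierParams:
    """Thresholds of the NMD classifiers.

    d_ejc
        Junction distance (nt downstream of the last stop-codon nucleotide)
        beyond which a 3'UTR junction marks the transcript EJC-dependent.
        The rule is strict (> d_ejc). Literature quotes 50-55 nt; default 50.
    uorf_frame_rule
        Only ``out_of_frame_only`` is implemented: an upstream AUG counts
        only if it is out of frame with the main start codon.
    """

    d_ejc: int = 50
    uorf_frame_rule: str = "out_of_frame_only"

    def __post_init__(self) -> None:
        if self.d_ejc < 0:
            raise ValueError("d_ejc must be >= 0")
        if self.uorf_frame_rule != "out_of_frame_only":
            raise ValueError(f"unknown uorf_frame_rule: {self.uorf_frame_rule}")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript isoform: exon structure plus CDS, both coordinate systems.

    exons are genomic half-open intervals ordered 5'->3' in *transcript*
    orientation (descending genomic coordinate on the minus strand).
    ``cds_start_t``/``cds_end_t`` are transcript offsets of the first
    nucleotide of the start codon and the last nucleotide of the stop codon.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds_start_t: int
    cds_end_t: int
    _cumlen: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")
        if not self.exons:
            raise ValueError("transcript must have at least one exon")
        for start, end in self.exons:
            if end <= start:
                raise ValueError(f"empty exon interval [{start},{end})")
        genomic_order = sorted(self.exons)
        if sorted(self.exons, reverse=(self.strand == "-")) != list(self.exons):
            raise ValueError("exons not ordered 5'->3' in transcript orientation")
        for (_, e1), (s2, _) in zip(genomic_order, genomic_order[1:]):
            if s2 < e1:
                raise ValueError("exons overlap")
        cum, total = [], 0
        for start, end in self.exons:
            total += end - start
            cum.append(total)
        object.__setattr__(self, "_cumlen", tuple(cum))
        if not (0 <= self.cds_start_t < self.cds_end_t < self.length_t):
            raise ValueError("CDS coordinates out of transcript bounds")
        if self.cds_len % 3 != 0 or self.cds_len < 6:
            raise ValueError("CDS length (stop included) must be >=6 and divisible by 3")

    @property
    def length_t(self) -> int:
        """Spliced transcript length in nt."""
        return self._cumlen[-1]

    @property
    def cds_len(self) -> int:
        """CDS length in nt, stop codon included."""
        return self.cds_end_t - self.cds_start_t + 1

    def to_transcript_coord(self, gpos: int) -> int:
        """Map an exonic genomic position to its 0-based transcript offset."""
        offset = 0
        for (start, end), cum in zip(self.exons, self._cumlen):
            if start <= gpos < end:
                within = (gpos - start) if self.strand == "+" else (end - 1 - gpos)
                return offset + within
            offset = cum
        raise CoordinateError(
            f"{self.transcript_id}: genomic position {gpos} is not exonic"
        )

    def to_genomic_coord(self, tpos: int) -> int:
        """Map a transcript offset back to its genomic position (inverse map)."""
        if not 0 <= tpos < self.length_t:
            raise CoordinateError(
                f"{self.transcript_id}: transcript position {tpos} out of range"
            )
        prev = 0
        for (start, end), cum in zip(self.exons, self._cumlen):
            if tpos < cum:
                within = tpos - prev
                return start + within if self.strand == "+" else end - 1 - within
            prev = cum
        raise AssertionError("unreachable")

    def genomic_intervals(self, t_start: int, t_end: int) -> list[tuple[int, int]]:
        """Genomic half-open intervals covering transcript range [t_start, t_end]."""
        if not 0 <= t_start <= t_end < self.length_t:
            raise CoordinateError("transcript range out of bounds")
        intervals: list[tuple[int, int]] = []
        prev = 0
        for (start, end), cum in zip(self.exons, self._cumlen):
            lo, hi = max(t_start, prev), min(t_end, cum - 1)
            if lo <= hi:
                if self.strand == "+":
                    intervals.append((start + lo - prev, start + hi - prev + 1))
                else:
                    intervals.append((end - 1 - (hi - prev), end - (lo - prev)))
            prev = cum
        return intervals

    def exon_end_positions_t(self) -> list[int]:
        """Transcript offset of the last nt of each exon except the final one."""
        return [cum - 1 for cum in self._cumlen[:-1]]

    def stop_codon_last_genomic(self) -> int:
        """Genomic position of the last nucleotide of the stop codon."""
        return self.to_genomic_coord(self.cds_end_t)


@dataclass(frozen=True)
class NMDClassification:
    """Per-transcript NMD-relevant flags."""

    transcript_id: str
    gene_id: str
    is_representative: bool
    ejc_dependent: bool
    has_uorf: bool
    is_nmd_target: bool
    min_downstream_junction_distance: Optional[int] = None


def _prescan_gtf(path: str) -> None:
    # gffutils reports no line numbers; a light structural pass supplies them.
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise GTFParseError(
                    f"line {lineno}: expected 9 tab-separated fields, got {len(fields)}"
                )
            try:
                start, end = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise GTFParseError(f"line {lineno}: non-integer coordinates") from exc
            if start < 1 or end < start:
                raise GTFParseError(f"line {lineno}: bad coordinate range {start}-{end}")
            if fields[6] not in ("+", "-", "."):
                raise GTFParseError(f"line {lineno}: bad strand {fields[6]!r}")


def _normalize_seq(seq: str) -> str:
    return seq.upper().replace("U", "T")


def parse_gtf(
    path: str,
    seqs: Optional[Mapping[str, str]] = None,
) -> list[TranscriptModel]:
    """Parse a GTF file into transcript models.

    One model is produced per transcript with at least one CDS feature and an
    annotated stop codon: either an explicit ``stop_codon`` feature, or --
    when ``seqs`` supplies transcript sequences keyed by transcript id -- a
    CDS whose sense-strand terminal codon is a stop. Transcripts failing
    these requirements, or whose CDS (stop included) is not a multiple of 3,
    are dropped with a warning.
    """
    _prescan_gtf(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    per_tx: dict[str, dict] = {}
    for feat in db.all_features():
        if feat.featuretype not in ("exon", "CDS", "stop_codon"):
            continue
        tid = feat.attributes.get("transcript_id", [None])[0]
        gid = feat.attributes.get("gene_id", [None])[0]
        if tid is None:
            raise GTFParseError(f"{feat.featuretype} feature lacks transcript_id")
        rec = per_tx.setdefault(
            tid,
            {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
             "exon": [], "CDS": [], "stop_codon": []},
        )
        # GTF is 1-based inclusive; store 0-based half-open
        rec[feat.featuretype].append((feat.start - 1, feat.end))

    models: list[TranscriptModel] = []
    n_no_cds = n_no_stop = n_bad_frame = 0
    for tid, rec in per_tx.items():
        if not rec["CDS"]:
            n_no_cds += 1
            continue
        strand = rec["strand"]
        exons = sorted(rec["exon"]) if strand == "+" else sorted(rec["exon"], reverse=True)
        try:
            model = _build_model(tid, rec, tuple(exons), strand, seqs)
        except _NoStopCodon:
            n_no_stop += 1
            logger.warning("transcript %s dropped: no annotated stop codon", tid)
            continue
        except ValueError as exc:
            n_bad_frame += 1
            logger.warning("transcript %s dropped: %s", tid, exc)
            continue
        models.append(model)
    logger.info(
        "parse_gtf: %d models kept; dropped %d without CDS, %d without stop codon, "
        "%d invalid", len(models), n_no_cds, n_no_stop, n_bad_frame,
    )
    return models


class _NoStopCodon(Exception):
    pass


def _build_model(tid, rec, exons, strand, seqs) -> TranscriptModel:
    probe = TranscriptModel.__new__(TranscriptModel)  # coordinate map shell
    object.__setattr__(probe, "transcript_id", tid)
    object.__setattr__(probe, "gene_id", rec["gene_id"])
    object.__setattr__(probe, "chrom", rec["chrom"])
    object.__setattr__(probe, "strand", strand)
    object.__setattr__(probe, "exons", exons)
    cum, total = [], 0
    for s, e in exons:
        total += e - s
        cum.append(total)
    object.__setattr__(probe, "_cumlen", tuple(cum))

    cds_t: list[int] = []
    for s, e in rec["CDS"] + rec["stop_codon"]:
        for g in range(s, e):
            cds_t.append(probe.to_transcript_coord(g))
    cds_start_t, cds_end_t = min(cds_t), max(cds_t)

    if not rec["stop_codon"]:
        if seqs is None or tid not in seqs:
            raise _NoStopCodon(tid)
        seq = _normalize_seq(seqs[tid])
        terminal = seq[cds_end_t - 2 : cds_end_t + 1]
        if terminal not in STOP_CODONS:
            raise _NoStopCodon(tid)

    return TranscriptModel(
        transcript_id=tid, gene_id=rec["gene_id"], chrom=rec["chrom"],
        strand=strand, exons=exons, cds_start_t=cds_start_t, cds_end_t=cds_end_t,
    )


def select_representatives(models: Sequence[TranscriptModel]) -> set[str]:
    """One transcript id per stop-codon key (chrom, strand, last stop-codon nt).

    Within each group the isoform with the longest CDS wins; ties go to the
    longest transcript overall, then to the lexicographically smallest id.
    """
    groups: dict[tuple, list[TranscriptModel]] = {}
    for m in models:
        key = (m.chrom, m.strand, m.stop_codon_last_genomic())
        groups.setdefault(key, []).append(m)
    chosen: set[str] = set()
    for group in groups.values():
        best = min(group, key=lambda m: (-m.cds_len, -m.length_t, m.transcript_id))
        chosen.add(best.transcript_id)
    return chosen


def downstream_junction_distances(model: TranscriptModel) -> list[int]:
    """Spliced distances (nt) from the last stop-codon nt to each 3'UTR junction.

    For each exon-exon junction 3' of the stop codon, the distance from the
    last nucleotide of the stop codon to the last nucleotide of the exon
    preceding the junction. Empty if the 3'UTR lies in the final exon.
    """
    return [
        b - model.cds_end_t
        for b in model.exon_end_positions_t()
        if b >= model.cds_end_t
    ]


def classify_ejc_dependence(
    model: TranscriptModel, params: ClassifierParams = ClassifierParams()
) -> bool:
    """True iff any 3'UTR junction lies strictly more than d_ejc nt downstream."""
    return any(d > params.d_ejc for d in downstream_junction_distances(model))


def detect_uorf(model: TranscriptModel, seq: str) -> bool:
    """True iff the 5'UTR contains an AUG out of frame with the main start.

    Any position i < cds_start_t with seq[i:i+3] == AUG and
    (cds_start_t - i) % 3 != 0 counts, even if the codon extends into the
    CDS. In-frame upstream AUGs never count. T and U are equivalent.
    """
    if len(seq) != model.length_t:
        raise ValueError(
            f"{model.transcript_id}: sequence length {len(seq)} != "
            f"transcript length {model.length_t}"
        )
    s = _normalize_seq(seq)
    cds_start = model.cds_start_t
    for i in range(cds_start):
        if s[i : i + 3] == "ATG" and (cds_start - i) % 3 != 0:
            return True
    return False


def classify_transcriptome(
    models: Sequence[TranscriptModel],
    seqs: Mapping[str, str],
    nmd_target_ids: Iterable[str],
    params: ClassifierParams = ClassifierParams(),
) -> list[NMDClassification]:
    """Combine all flags into one record per representative transcript."""
    reps = select_representatives(models)
    targets = set(nmd_target_ids)
    stray = targets - reps
    if stray:
        logger.warning(
            "%d NMD-target ids are not representative transcripts and are "
            "ignored: %s", len(stray), sorted(stray)[:10],
        )
        targets -= stray

    out: list[NMDClassification] = []
    for m in models:
        if m.transcript_id not in reps:
            continue
        dists = downstream_junction_distances(m)
        out.append(
            NMDClassification(
                transcript_id=m.transcript_id,
                gene_id=m.gene_id,
                is_representative=True,
                ejc_dependent=any(d > params.d_ejc for d in dists),
                has_uorf=detect_uorf(m, seqs[m.transcript_id]),
                is_nmd_target=m.transcript_id in targets,
                min_downstream_junction_distance=min(dists) if dists else None,
            )
        )
    n_ejc = sum(c.ejc_dependent for c in out)
    n_uorf = sum(c.has_uorf for c in out)
    n_tgt = sum(c.is_nmd_target for c in out)
    logger.info(
        "classified %d representatives: %d EJC-dependent, %d with uORF, "
        "%d NMD targets", len(out), n_ejc, n_uorf, n_tgt,
    )
    return out


def classifications_to_frame(records: Sequence[NMDClassification]):
    """Tabulate classification records (column order matches the TSV contract)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "transcript_id": r.transcript_id,
                "gene_id": r.gene_id,
                "is_representative": r.is_representative,
                "ejc_dependent": r.ejc_dependent,
                "has_uorf": r.has_uorf,
                "is_nmd_target": r.is_nmd_target,
                "min_downstream_junction_distance": r.min_downstream_junction_distance,
            }
            for r in records
        ]
    )
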