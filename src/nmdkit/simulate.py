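"""Synthetic data with ground truth for every stage of the analysis.

Generators emit the statistical structure the pipeline assumes — nothing
more: multi-isoform transcript models with controlled 3'UTR-intron
distances straddling the 50-nt rule, shared stop codons and planted in/out-
of-frame upstream AUGs; negative-binomial RNA-seq and footprint counts with
planted mRNA-level and occupancy-level effects; spliced alignments with
planted true and noise junctions; footprint 5' ends from ribosomes queued
at a stop codon; and screen reads with planted guide enrichment. Every
generator records machine-readable truth and is deterministic for a fixed
seed (all randomness flows through one ``numpy`` Generator).

Sequences are uniform random nucleotides apart from the planted motifs
(AUG, GT/AG splice sites, stop codons); no codon-usage or error-model
realism is attempted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

from .annotate import TranscriptModel
from .quant import CountMatrix
from .screen import NONTARGETING, SPACER_LEN, GuideLibrary

NUCS = np.array(list("ACGT"))
STOPS = ("TAA", "TAG", "TGA")


@dataclass
class SimulationConfig:
    """Study conditions for all generators (one seed governs everything)."""

    seed: int = 0
    # transcriptome
    n_genes: int = 200
    isoforms_per_gene: int = 2
    fraction_ejc_dependent: float = 0.2
    junction_distance_range: tuple[int, int] = (20, 120)  # straddles 50 nt
    fraction_short_junction: float = 0.25  # non-EJC genes given a <=50 nt junction
    fraction_uorf: float = 0.3
    fraction_uorf_out_of_frame: float = 0.5
    # counts
    nb_dispersion: float = 0.05
    mean_count_range: tuple[float, float] = (100.0, 1000.0)
    replicates: int = 3
    mrna_effect: float = 1.0       # on NMD targets, both assays
    occupancy_effect: float = 2.0  # on EJC-dependent targets, footprints only
    rpf_rate: float = 0.75         # baseline footprint/mRNA mean ratio
    # NMD-caller evidence
    n_contrasts: int = 4
    evidence_effect: float = 2.5
    fraction_nmd_planted: float = 0.1
    # footprints
    footprint_length: int = 30
    footprint_offset: int = 18
    footprint_background_rate: float = 2.0
    queue_depths: tuple[int, ...] = (1, 2, 3, 4)
    # screen
    n_screen_genes: int = 40
    guides_per_gene: int = 4
    n_nontargeting: int = 40
    screen_anchor: str = "CACCG"
    screen_enrichment_lfc: float = 1.5
    fraction_enriched: float = 0.1
    screen_reads: int = 20000

    def __post_init__(self) -> None:
        for name in ("fraction_ejc_dependent", "fraction_short_junction",
                     "fraction_uorf", "fraction_uorf_out_of_frame",
                     "fraction_nmd_planted", "fraction_enriched"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mrna_effect <= 0 or self.occupancy_effect <= 0:
            raise ValueError("effect factors must be positive")
        if self.junction_distance_range[0] < 1:
            raise ValueError("junction distances must be >= 1 nt")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class TranscriptomeBundle:
    """Models, transcript sequences and the planted truth table."""

    models: list[TranscriptModel]
    seqs: dict[str, str]
    truth: pd.DataFrame


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(NUCS, size=n))

def _scrub(seq: str, motif: str, rng: np.random.Generator) -> str:
    """Remove every occurrence of motif by flipping its last base."""
    s = list(seq)
    i = "".join(s).find(motif)
    while i >= 0:
        repl = [c for c in "ACGT" if c != motif[-1]]
        s[i + len(motif) - 1] = repl[int(rng.integers(len(repl)))]
        i = "".join(s).find(motif)
    return "".join(s)


def _layout(exon_lens: Sequence[int], intron_lens: Sequence[int],
            strand: str, offset: int) -> list[tuple[int, int]]:
    """Genomic exon intervals (transcript order) for an exon/intron chain."""
    cum = []
    pos = 0
    for i, el in enumerate(exon_lens):
        cum.append((pos, pos + el))
        pos += el
        if i < len(intron_lens):
            pos += intron_lens[i]
    total = pos
    if strand == "+":
        return [(offset + s, offset + e) for s, e in cum]
    return [(offset + total - e, offset + total - s) for s, e in cum]


def make_transcriptome(config: SimulationConfig) -> TranscriptomeBundle:
    """Generate a multi-isoform transcriptome with planted NMD class labels.

    Each gene gets one representative isoform (the longest CDS) and, when
    ``isoforms_per_gene`` > 1, a second isoform sharing the stop codon with
    a 30-nt-shorter annotated CDS. Exactly ``fraction_ejc_dependent`` of the
    genes carry a 3'UTR intron more than 50 nt downstream of the stop; a
    further ``fraction_short_junction`` carry one at <= 50 nt; uORF AUGs are
    planted in or out of frame per the configured fractions. Planted NMD
    targets are the EJC-dependent or out-of-frame-uORF representatives.
    """
    rng = config.rng()
    n = config.n_genes
    n_ejc = round(config.fraction_ejc_dependent * n)
    n_short = round(config.fraction_short_junction * (n - n_ejc))
    jclass = np.array(["none"] * n, dtype=object)
    order = rng.permutation(n)
    jclass[order[:n_ejc]] = "ejc"
    jclass[order[n_ejc:n_ejc + n_short]] = "short"

    n_uorf = round(config.fraction_uorf * n)
    n_out = round(config.fraction_uorf_out_of_frame * n_uorf)
    uclass = np.array(["none"] * n, dtype=object)
    uorder = rng.permutation(n)
    uclass[uorder[:n_out]] = "out_of_frame"
    uclass[uorder[n_out:n_uorf]] = "in_frame"

    lo_j, hi_j = config.junction_distance_range
    models: list[TranscriptModel] = []
    seqs: dict[str, str] = {}
    rows = []
    for g in range(n):
        chrom = f"chr{g + 1}"
        strand = "+" if g % 2 == 0 else "-"
        gene_id = f"G{g + 1:04d}"

        utr5_len = int(rng.integers(90, 151))
        n_codons = int(rng.integers(100, 201))
        cds_nostop = 3 * n_codons

        utr5 = _scrub(_rand_seq(rng, utr5_len), "ATG", rng)
        if uclass[g] != "none":
            if uclass[g] == "in_frame":
                k = int(rng.integers(1, utr5_len // 3))
                i = utr5_len - 3 * k
            else:
                while True:
                    i = int(rng.integers(0, utr5_len - 3))
                    if (utr5_len - i) % 3 != 0:
                        break
            utr5 = utr5[:i] + "ATG" + utr5[i + 3:]
        # first 27 nt after the start codon kept AUG-free so the shorter
        # isoform's extended 5'UTR gains no unplanned uORF
        body_head = _scrub(_rand_seq(rng, 27), "ATG", rng)
        body = body_head + _rand_seq(rng, cds_nostop - 3 - 27)
        stop = STOPS[int(rng.integers(3))]

        if jclass[g] == "ejc":
            d = int(rng.integers(max(51, lo_j), hi_j + 1))
        elif jclass[g] == "short":
            d = int(rng.integers(lo_j, 51))
        else:
            d = None
        tail_len = int(rng.integers(80, 151))
        if d is not None and d < 1:
            raise ValueError("infeasible junction geometry")

        # exon chain: [utr5+cds5'] -intron- [cds3'+stop+utr3a] (-intron- [utr3b])
        split = 3 * int(rng.integers(30, n_codons - 30))
        tx_seq = utr5 + "ATG" + body + stop + (
            _rand_seq(rng, d) + _rand_seq(rng, tail_len) if d is not None
            else _rand_seq(rng, tail_len)
        )
        exon_lens = [utr5_len + split, cds_nostop + 3 - split + (d if d is not None else tail_len)]
        intron_lens = [int(rng.integers(80, 201))]
        if d is not None:
            exon_lens.append(tail_len)
            intron_lens.append(int(rng.integers(80, 201)))
        offset = 1000
        exons = _layout(exon_lens, intron_lens, strand, offset)

        cds_start_t = utr5_len
        cds_end_t = utr5_len + cds_nostop + 2
        tid_a = f"{gene_id}.1"
        model_a = TranscriptModel(
            transcript_id=tid_a, gene_id=gene_id, chrom=chrom, strand=strand,
            exons=tuple(exons), cds_start_t=cds_start_t, cds_end_t=cds_end_t,
        )
        models.append(model_a)
        seqs[tid_a] = tx_seq

        is_ejc = jclass[g] == "ejc"
        has_uorf = uclass[g] == "out_of_frame"
        rows.append(
            {"transcript_id": tid_a, "gene_id": gene_id, "strand": strand,
             "length": model_a.length_t, "cds_len": model_a.cds_len,
             "is_representative": True, "ejc_dependent": is_ejc,
             "junction_distance": d, "uorf_planted": uclass[g],
             "has_uorf": has_uorf, "is_nmd_target": is_ejc or has_uorf}
        )

        if config.isoforms_per_gene > 1:
            # same exons and stop codon, CDS annotated 30 nt (10 codons) shorter
            tid_b = f"{gene_id}.2"
            model_b = TranscriptModel(
                transcript_id=tid_b, gene_id=gene_id, chrom=chrom, strand=strand,
                exons=tuple(exons), cds_start_t=cds_start_t + 30, cds_end_t=cds_end_t,
            )
            models.append(model_b)
            seqs[tid_b] = tx_seq
            rows.append(
                {"transcript_id": tid_b, "gene_id": gene_id, "strand": strand,
                 "length": model_b.length_t, "cds_len": model_b.cds_len,
                 "is_representative": False, "ejc_dependent": is_ejc,
                 "junction_distance": d, "uorf_planted": uclass[g],
                 "has_uorf": has_uorf, "is_nmd_target": False}
            )

    truth = pd.DataFrame(rows)
    return TranscriptomeBundle(models=models, seqs=seqs, truth=truth)


def write_fasta(seqs: Mapping[str, str], path: str) -> None:
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    records = [SeqRecord(Seq(s), id=tid, description="") for tid, s in seqs.items()]
    SeqIO.write(records, path, "fasta")


def write_gtf(models: Sequence[TranscriptModel], path: str) -> None:
    """Emit exon, CDS (stop excluded) and stop_codon features, 1-based inclusive."""
    lines = []
    for m in models:
        attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
        def feature(ftype, gstart, gend, frame="."):
            lines.append("\t".join(
                [m.chrom, "nmdkit_sim", ftype, str(gstart + 1), str(gend),
                 ".", m.strand, str(frame), attrs]
            ))
        for s, e in sorted(m.exons):
            feature("exon", s, e)
        cds_t_end = m.cds_end_t - 3  # exclude stop codon from CDS features
        for s, e in m.genomic_intervals(m.cds_start_t, cds_t_end):
            t0 = m.to_transcript_coord(s if m.strand == "+" else e - 1)
            frame = (3 - (t0 - m.cds_start_t) % 3) % 3
            feature("CDS", s, e, frame)
        for s, e in m.genomic_intervals(m.cds_end_t - 2, m.cds_end_t):
            feature("stop_codon", s, e, 0)
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, alpha: float) -> np.ndarray:
    mean = np.asarray(mean, float)
    if alpha <= 1e-9:
        return rng.poisson(mean)
    r = 1.0 / alpha
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def simulate_counts(
    config: SimulationConfig,
    truth: pd.DataFrame,
    conditions: tuple[str, str] = ("ctrl", "treat"),
    rng: Optional[np.random.Generator] = None,
) -> tuple[CountMatrix, CountMatrix]:
    """Paired RNA and footprint count matrices with planted class effects.

    Counts are NB(mu, alpha) with variance mu + alpha*mu^2. In the second
    condition, ``mrna_effect`` multiplies both assays' means for planted NMD
    targets and ``occupancy_effect`` multiplies footprint means only for
    EJC-dependent transcripts. Only representative transcripts are simulated.
    """
    if rng is None:
        rng = config.rng()
    rep = truth[truth["is_representative"]].reset_index(drop=True)
    t = len(rep)
    base = np.exp(rng.uniform(np.log(config.mean_count_range[0]),
                              np.log(config.mean_count_range[1]), size=t))
    mrna_fac = np.where(rep["is_nmd_target"], config.mrna_effect, 1.0)
    occ_fac = np.where(rep["ejc_dependent"], config.occupancy_effect, 1.0)

    cols, conds = [], {}
    rna_cols, rpf_cols = {}, {}
    for ci, cond in enumerate(conditions):
        for r in range(config.replicates):
            rna_mu = base * (mrna_fac if ci == 1 else 1.0)
            rpf_mu = base * config.rpf_rate * (mrna_fac * occ_fac if ci == 1 else 1.0)
            s = f"{cond}_rna_{r + 1}"
            rna_cols[s] = _nb_draw(rng, rna_mu, config.nb_dispersion)
            conds[s] = cond
            s = f"{cond}_rpf_{r + 1}"
            rpf_cols[s] = _nb_draw(rng, rpf_mu, config.nb_dispersion)
            conds[s] = cond

    idx = pd.Index(rep["transcript_id"], name="transcript_id")
    rna = CountMatrix(
        assay="rna",
        counts=pd.DataFrame(rna_cols, index=idx),
        effective_length=pd.Series(rep["length"].to_numpy(float), index=idx),
        conditions={s: c for s, c in conds.items() if "_rna_" in s},
    )
    rpf = CountMatrix(
        assay="rpf",
        counts=pd.DataFrame(rpf_cols, index=idx),
        effective_length=pd.Series(rep["cds_len"].to_numpy(float), index=idx),
        conditions={s: c for s, c in conds.items() if "_rpf_" in s},
    )
    return rna, rpf


def simulate_evidence(
    config: SimulationConfig,
    truth: pd.DataFrame,
    rng: Optional[np.random.Generator] = None,
):
    """Per-contrast knockdown/rescue evidence for the NMD meta-caller.

    A random ``fraction_nmd_planted`` of representative transcripts are the
    planted targets; each of ``n_contrasts`` contrasts perturbs their mRNA
    by ``evidence_effect`` (up in knockdowns, down in rescues — contrasts
    alternate), simulates NB counts, and is analyzed with the package's own
    two-group test plus BH. Returns (list of ContrastEvidence, planted ids).
    """
    from .difftest import bh_adjust, nb_two_group
    from .nmd_caller import ContrastEvidence

    if rng is None:
        rng = config.rng()
    rep = truth[truth["is_representative"]].reset_index(drop=True)
    t = len(rep)
    ids = rep["transcript_id"].to_numpy()
    n_planted = round(config.fraction_nmd_planted * t)
    planted = set(ids[rng.permutation(t)[:n_planted]])
    is_planted = np.isin(ids, list(planted))
    base = np.exp(rng.uniform(np.log(config.mean_count_range[0]),
                              np.log(config.mean_count_range[1]), size=t))
    evidence = []
    for c in range(config.n_contrasts):
        direction = "up" if c % 2 == 0 else "down"
        fac = config.evidence_effect if direction == "up" else 1.0 / config.evidence_effect
        mu_b = base * np.where(is_planted, fac, 1.0)
        a = np.column_stack([_nb_draw(rng, base, config.nb_dispersion)
                             for _ in range(config.replicates)])
        b = np.column_stack([_nb_draw(rng, mu_b, config.nb_dispersion)
                             for _ in range(config.replicates)])
        res = nb_two_group(a, b)
        table = pd.DataFrame(
            {"transcript_id": ids, "lfc": res["lfc"],
             "p": res["p"], "q": bh_adjust(res["p"].to_numpy())}
        )
        evidence.append(ContrastEvidence(contrast_id=f"contrast_{c + 1}",
                                         expected_direction=direction, table=table))
    return evidence, planted


def simulate_transcript_alignments(
    lengths: Mapping[str, int],
    unique_counts: Mapping[str, int],
    out_sam: str,
    rng: np.random.Generator,
    n_multimapped: int = 0,
    n_unmapped: int = 0,
    read_len: int = 50,
) -> None:
    """SAM of reads aligned to transcripts with known unique totals.

    Each transcript receives exactly ``unique_counts[tid]`` uniquely mapping
    reads; ``n_multimapped`` reads are emitted twice (primary + secondary to
    a different transcript) and ``n_unmapped`` reads are unmapped.
    """
    tids = list(lengths)
    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": t, "LN": int(lengths[t])} for t in tids]}
    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        i = 0
        def new_read(name, ref_id, pos, flag=0):
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            if ref_id is not None:
                a.reference_id = ref_id
                a.reference_start = pos
                L = min(read_len, lengths[tids[ref_id]] - pos)
                a.cigarstring = f"{L}M"
                a.mapping_quality = 60
            return a

        for ref_id, tid in enumerate(tids):
            for _ in range(unique_counts.get(tid, 0)):
                pos = int(rng.integers(0, max(1, lengths[tid] - read_len)))
                out.write(new_read(f"u{i}", ref_id, pos))
                i += 1
        for _ in range(n_multimapped):
            r1, r2 = rng.choice(len(tids), size=2, replace=False)
            pos1 = int(rng.integers(0, max(1, lengths[tids[r1]] - read_len)))
            pos2 = int(rng.integers(0, max(1, lengths[tids[r2]] - read_len)))
            out.write(new_read(f"m{i}", int(r1), pos1))
            out.write(new_read(f"m{i}", int(r2), pos2, flag=256))
            i += 1
        for _ in range(n_unmapped):
            out.write(new_read(f"n{i}", None, 0, flag=4))
            i += 1


def simulate_spliced_alignments(
    config: SimulationConfig,
    out_sam: str,
    rng: Optional[np.random.Generator] = None,
) -> tuple[dict[str, str], pd.DataFrame]:
    """Spliced alignments with planted true introns plus noise junctions.

    Plants GU-AG true introns (including one on the minus strand and one
    with nanopore-only support), a 1-read gap, a non-GU-AG gap and sub-1%
    gaps. Returns (genome, truth) where truth lists every planted junction
    with its expected ``passes_nanopore``/``passes_shortread`` flags.
    """
    if rng is None:
        rng = config.rng()
    chrom = "chrJ"
    spacing = 3000
    # (kind, strand, n_support, n_contiguous)
    plan = [
        ("true", "+", int(rng.integers(6, 15)), int(rng.integers(60, 120))),
        ("true", "+", int(rng.integers(6, 15)), int(rng.integers(60, 120))),
        ("true", "-", int(rng.integers(6, 15)), int(rng.integers(60, 120))),
        ("true_lowsupport", "+", 3, 80),          # nanopore-only (support < 5)
        ("one_read", "+", 1, 60),                 # fails both modes
        ("bad_motif", "+", 8, 60),                # GC..AG: fails both modes
        ("sub_fraction", "+", 2, 400),            # 0.5%: fails both modes
        ("sub_fraction_supported", "+", 6, 700),  # <1% but support >= 5
    ]
    genome_len = spacing * (len(plan) + 1)
    genome = list(_rand_seq(rng, genome_len))
    rows = []
    reads = []  # (qname, flag, pos, cigar)
    ridx = 0
    for li, (kind, strand, n_sup, n_cont) in enumerate(plan):
        donor = spacing * (li + 1)
        ilen = int(rng.integers(100, 301))
        acceptor = donor + ilen
        if kind == "bad_motif":
            d5, d3 = "GC", "AG"
        elif strand == "-":
            d5, d3 = "CT", "AC"  # sense-strand GU-AG on the minus strand
        else:
            d5, d3 = "GT", "AG"
        genome[donor:donor + 2] = list(d5)
        genome[acceptor - 2:acceptor] = list(d3)
        flag = 16 if strand == "-" else 0

        for _ in range(n_sup):
            u = int(rng.integers(20, 41))
            v = int(rng.integers(20, 41))
            reads.append((f"s{ridx}", flag, donor - u, f"{u}M{ilen}N{v}M"))
            ridx += 1
        for _ in range(n_cont):
            u = int(rng.integers(1, 21))
            v = int(rng.integers(1, 21))
            start = donor - 1 - u
            length = (acceptor - start) + 1 + v
            reads.append((f"c{ridx}", flag, start, f"{length}M"))
            ridx += 1

        n_span = n_sup + n_cont
        frac = n_sup / n_span
        motif_ok = kind != "bad_motif"
        rows.append(
            {"chrom": chrom, "strand": strand, "donor": donor, "acceptor": acceptor,
             "kind": kind, "n_support": n_sup, "n_spanning": n_span,
             "motif_ok": motif_ok,
             "passes_nanopore": motif_ok and n_sup >= 2 and frac >= 0.01,
             "passes_shortread": motif_ok and n_sup >= 5}
        )

    header = {"HD": {"VN": "1.6", "SO": "unsorted"},
              "SQ": [{"SN": chrom, "LN": genome_len}]}
    with pysam.AlignmentFile(out_sam, "wh", header=header) as out:
        for qname, flag, pos, cigar in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = qname
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.mapping_quality = 60
            out.write(a)
    return {chrom: "".join(genome)}, pd.DataFrame(rows)


def simulate_footprints(
    config: SimulationConfig,
    anchor: int,
    n_events: int = 200,
    rng: Optional[np.random.Generator] = None,
    window: tuple[int, int] = (-120, 30),
) -> np.ndarray:
    """Footprint 5'-end positions from ribosomes queued at a stop codon.

    Each termination event places the leading ribosome's 5' end at
    ``anchor - footprint_offset`` and every additional queued ribosome one
    protected length (``footprint_length``) further upstream; uniform
    Poisson background (``footprint_background_rate`` expected counts per
    position) is added across the window.
    """
    if rng is None:
        rng = config.rng()
    off, L = config.footprint_offset, config.footprint_length
    positions: list[int] = []
    depths = rng.choice(config.queue_depths, size=n_events)
    for d in depths:
        for k in range(int(d)):
            positions.append(anchor - off - k * L)
    lo, hi = window
    for relpos in range(lo, hi + 1):
        positions.extend([anchor + relpos] * int(rng.poisson(config.footprint_background_rate)))
    return np.array(sorted(positions), dtype=int)


def make_guide_library(config: SimulationConfig,
                       rng: Optional[np.random.Generator] = None) -> GuideLibrary:
    """Random guide library: targeting genes plus non-targeting controls."""
    if rng is None:
        rng = config.rng()
    anchor = config.screen_anchor.upper()
    rows, seen = [], set()

    def fresh_spacer() -> str:
        while True:
            s = _rand_seq(rng, SPACER_LEN)
            if s not in seen and anchor not in s:
                seen.add(s)
                return s

    for g in range(config.n_screen_genes):
        gene = f"SG{g + 1:03d}"
        for j in range(config.guides_per_gene):
            rows.append({"guide_id": f"{gene}_g{j + 1}", "gene": gene,
                         "spacer": fresh_spacer()})
    for j in range(config.n_nontargeting):
        rows.append({"guide_id": f"NT_g{j + 1}", "gene": NONTARGETING,
                     "spacer": fresh_spacer()})
    return GuideLibrary(pd.DataFrame(rows))


def simulate_screen_reads(
    config: SimulationConfig,
    library: GuideLibrary,
    fastq_input: str,
    fastq_sorted: str,
    rng: Optional[np.random.Generator] = None,
    n_no_anchor: int = 25,
    n_bad_spacer: int = 25,
) -> tuple[pd.DataFrame, set[str]]:
    """FASTQ pair (input, sorted) with planted per-gene enrichment.

    Guide frequencies in the sorted sample are tilted by 2**lfc for guides
    of the enriched genes. Returns (per-guide draw tallies, enriched genes).
    Each file also receives ``n_no_anchor`` anchor-free reads and
    ``n_bad_spacer`` reads whose spacer matches no guide.
    """
    if rng is None:
        rng = config.rng()
    anchor = config.screen_anchor.upper()
    tab = library.table
    genes = sorted(set(tab["gene"]) - {NONTARGETING})
    n_enr = round(config.fraction_enriched * len(genes))
    enriched = {str(g) for g in np.array(genes)[rng.permutation(len(genes))[:n_enr]]}

    base = rng.dirichlet(np.full(len(tab), 5.0))
    tilt = np.where(tab["gene"].isin(enriched), 2.0 ** config.screen_enrichment_lfc, 1.0)
    sorted_p = base * tilt
    sorted_p /= sorted_p.sum()

    n_input = rng.multinomial(config.screen_reads, base)
    n_sorted = rng.multinomial(config.screen_reads, sorted_p)

    def write(path: str, tallies: np.ndarray, tag: str) -> None:
        known = set(tab["spacer"])
        with open(path, "w") as fh:
            i = 0
            def emit(seq: str) -> None:
                nonlocal i
                fh.write(f"@{tag}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
                i += 1

            def read_around(spacer: str) -> str:
                while True:
                    prefix = _rand_seq(rng, 10)
                    suffix = _rand_seq(rng, 10)
                    seq = prefix + anchor + spacer + suffix
                    if seq.find(anchor) == len(prefix):
                        return seq

            for spacer, cnt in zip(tab["spacer"], tallies):
                for _ in range(int(cnt)):
                    emit(read_around(spacer))
            for _ in range(n_bad_spacer):
                while True:
                    sp = _rand_seq(rng, SPACER_LEN)
                    if sp not in known and anchor not in sp:
                        break
                emit(read_around(sp))
            for _ in range(n_no_anchor):
                emit(_scrub(_rand_seq(rng, 10 + len(anchor) + SPACER_LEN + 10),
                            anchor, rng))

    write(fastq_input, n_input, "in")
    write(fastq_sorted, n_sorted, "so")
    truth = pd.DataFrame({"guide_id": tab["guide_id"], "gene": tab["gene"],
                          "n_input": n_input, "n_sorted": n_sorted})
    return truth, enriched


def config_to_dict(config: SimulationConfig) -> dict:
    return dataclasses.asdict(config)
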