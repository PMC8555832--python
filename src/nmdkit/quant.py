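"""Abundance quantification: unique-read counting, TPM, ribosome occupancy.

Counts are kept per assay (``rna``: RNA-seq over whole transcripts; ``rpf``:
ribosome footprints over coding regions), normalized to transcripts per
million (TPM) with the assay-appropriate effective length (full transcript
length for RNA, CDS length including the stop codon for footprints), and
combined into per-condition ribosome occupancy, the ratio of footprint TPM
to mRNA TPM — the standard proxy for translation per mRNA molecule.

Unique-assignment counting deliberately replaces EM-based multi-mapping
resolution: a read aligning to more than one transcript contributes nothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CountMatrix:
    """Integer counts, transcripts x samples, for one assay.

    ``conditions`` maps each sample id to its condition label;
    ``effective_length`` is per-transcript (transcript length for rna,
    CDS length for rpf).
    """

    assay: str
    counts: pd.DataFrame
    effective_length: pd.Series
    conditions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.assay not in ("rna", "rpf"):
            raise ValueError(f"assay must be rna or rpf, got {self.assay!r}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if self.counts.index.has_duplicates or self.counts.columns.has_duplicates:
            raise ValueError("duplicate transcript or sample ids")
        self.effective_length = self.effective_length.reindex(self.counts.index)
        if self.effective_length.isna().any() or (self.effective_length <= 0).any():
            raise ValueError("effective_length must be positive for every transcript")

    @property
    def transcript_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.sample_ids if self.conditions.get(s) == condition]


@dataclass
class TPMMatrix:
    """Length-normalized abundances; each nonzero sample column sums to 1e6."""

    assay: str
    values: pd.DataFrame
    conditions: Mapping[str, str] = field(default_factory=dict)
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def samples_for(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.conditions.get(s) == condition]


def count_unique(
    sam_path: str,
    models_or_lengths: Mapping[str, int] | Sequence,
    assay: str = "rna",
    sample_id: str = "sample",
    conditions: Optional[Mapping[str, str]] = None,
) -> CountMatrix:
    """Count uniquely mapping reads per transcript from a SAM file.

    Every read whose alignments (primary plus secondary) all point to a
    single transcript increments that transcript once; multi-mapped and
    unmapped reads are tallied and logged but excluded. ``models_or_lengths``
    is either a mapping transcript_id -> effective length or a sequence of
    ``annotate.TranscriptModel`` (effective length = transcript length for
    rna, CDS length for rpf).
    """
    if isinstance(models_or_lengths, Mapping):
        eff_len = dict(models_or_lengths)
    else:
        eff_len = {
            m.transcript_id: (m.length_t if assay == "rna" else m.cds_len)
            for m in models_or_lengths
        }

    hits: dict[str, set[str]] = {}
    n_unmapped = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as sam:
        for rec in sam.fetch(until_eof=True):
            if rec.is_unmapped:
                n_unmapped += 1
                continue
            ref = rec.reference_name
            if ref not in eff_len:
                raise KeyError(f"alignment references unknown transcript {ref!r}")
            hits.setdefault(rec.query_name, set()).add(ref)

    counts = dict.fromkeys(eff_len, 0)
    n_multi = 0
    for refs in hits.values():
        if len(refs) == 1:
            counts[next(iter(refs))] += 1
        else:
            n_multi += 1
    logger.info(
        "count_unique(%s): %d unique reads counted, %d multi-mapped and "
        "%d unmapped excluded", sample_id, sum(counts.values()), n_multi, n_unmapped,
    )
    df = pd.DataFrame({sample_id: pd.Series(counts, dtype=int)})
    return CountMatrix(
        assay=assay,
        counts=df,
        effective_length=pd.Series(eff_len, dtype=float),
        conditions=dict(conditions or {sample_id: "default"}),
    )


def tpm(cm: CountMatrix) -> TPMMatrix:
    """Transcripts per million: length-normalized rates scaled to 1e6 per sample."""
    rates = cm.counts.div(cm.effective_length, axis=0)
    totals = rates.sum(axis=0)
    zero = totals == 0
    if zero.any():
        logger.warning("all-zero sample(s): %s", list(totals.index[zero]))
        totals = totals.replace(0, np.nan)
    values = rates.div(totals, axis=1).fillna(0.0) * 1e6
    return TPMMatrix(assay=cm.assay, values=values, conditions=dict(cm.conditions),
                     pseudocount=0.0)


def occupancy_matrix(
    rpf: TPMMatrix,
    rna: TPMMatrix,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-(transcript, condition) ribosome occupancy.

    Replicate TPMs are averaged within each condition before the ratio
    (mean RPF TPM + pseudocount) / (mean RNA TPM + pseudocount). Conditions
    must be present in both assays. Transcripts with zero mean RNA TPM are
    reported (the pseudocount keeps the ratio finite) and logged as
    low-confidence.
    """
    conds_rpf = set(rpf.conditions.values())
    conds_rna = set(rna.conditions.values())
    if conds_rpf != conds_rna:
        raise ValueError(
            f"condition sets differ between assays: {conds_rpf ^ conds_rna}"
        )
    shared = rpf.values.index.intersection(rna.values.index)
    out = {}
    for cond in sorted(conds_rpf):
        mean_rpf = rpf.values.loc[shared, rpf.samples_for(cond)].mean(axis=1)
        mean_rna = rna.values.loc[shared, rna.samples_for(cond)].mean(axis=1)
        n_zero = int((mean_rna == 0).sum())
        if n_zero and pseudocount > 0:
            logger.warning(
                "condition %s: %d transcripts with zero RNA TPM; occupancy is "
                "pseudocount-dominated (low confidence)", cond, n_zero,
            )
        out[cond] = (mean_rpf + pseudocount) / (mean_rna + pseudocount)
    return pd.DataFrame(out)


def write_matrix_tsv(df: pd.DataFrame, path: str) -> None:
    df.to_csv(path, sep="\t", index_label="transcript_id", float_format="%.6g")


def read_count_matrix_tsv(
    path: str,
    assay: str,
    effective_length: pd.Series,
    conditions: Mapping[str, str],
) -> CountMatrix:
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    return CountMatrix(assay=assay, counts=df.astype(int),
                       effective_length=effective_length, conditions=dict(conditions))
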