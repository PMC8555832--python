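"""CRISPR screen guide counting and guide-level enrichment.

Spacers are counted from screen reads by locating the first exact occurrence
of a constant vector anchor sequence and exact-matching the following 20 nt
against the guide library (no mismatch tolerance by default, matching the
behavior of standard spacer-counting scripts; an optional one-mismatch
rescue is off by default). Sorted-versus-input enrichment is summarized per
guide as a depth-normalized log2 fold change, and per gene by the median
guide fold change with a rank-sum test against the non-targeting guides —
deliberately a simple statistic, not an RRA-style aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO

from .difftest import bh_adjust, group_shift_test

logger = logging.getLogger(__name__)

NONTARGETING = "NONTARGETING"
SPACER_LEN = 20
LFC_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class GuideLibrary:
    """Guide table with columns guide_id, gene, spacer (unique 20-nt ACGT)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = {"guide_id", "gene", "spacer"} - set(self.table.columns)
        if missing:
            raise ValueError(f"library lacks columns: {sorted(missing)}")
        if len(self.table) == 0:
            raise ValueError("empty guide library")
        spacers = self.table["spacer"]
        if spacers.duplicated().any():
            raise ValueError("duplicate spacers in library")
        bad = ~spacers.str.fullmatch(f"[ACGT]{{{SPACER_LEN}}}")
        if bad.any():
            raise ValueError(
                f"{int(bad.sum())} spacers are not {SPACER_LEN}-nt ACGT strings"
            )

    @property
    def guide_ids(self) -> list[str]:
        return list(self.table["guide_id"])

    def nontargeting_ids(self) -> list[str]:
        return list(self.table.loc[self.table["gene"] == NONTARGETING, "guide_id"])

    @classmethod
    def from_tsv(cls, path: str) -> "GuideLibrary":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def count_spacers(
    fastq_path: str,
    library: GuideLibrary,
    anchor: str,
    allow_one_mismatch: bool = False,
) -> tuple[pd.Series, dict]:
    """Count reads per guide by exact anchor + spacer matching.

    Returns (per-guide counts indexed by guide_id, stats) where stats tallies
    matched, unmatched_spacer, no_anchor and total reads; the three classes
    always sum to the total.
    """
    if not anchor:
        raise ValueError("anchor sequence is required")
    anchor = anchor.upper()
    spacer_to_guide = dict(zip(library.table["spacer"], library.table["guide_id"]))
    counts = dict.fromkeys(library.guide_ids, 0)
    stats = {"matched": 0, "unmatched_spacer": 0, "no_anchor": 0, "total": 0}
    for rec in SeqIO.parse(fastq_path, "fastq"):
        stats["total"] += 1
        seq = str(rec.seq).upper()
        idx = seq.find(anchor)
        if idx < 0 or idx + len(anchor) + SPACER_LEN > len(seq):
            stats["no_anchor"] += 1
            continue
        spacer = seq[idx + len(anchor) : idx + len(anchor) + SPACER_LEN]
        guide = spacer_to_guide.get(spacer)
        if guide is None and allow_one_mismatch:
            guide = _one_mismatch_rescue(spacer, spacer_to_guide)
        if guide is None:
            stats["unmatched_spacer"] += 1
        else:
            counts[guide] += 1
            stats["matched"] += 1
    logger.info(
        "count_spacers(%s): %d matched, %d unmatched, %d without anchor",
        fastq_path, stats["matched"], stats["unmatched_spacer"], stats["no_anchor"],
    )
    return pd.Series(counts, name="count"), stats


def _one_mismatch_rescue(spacer: str, spacer_to_guide: dict) -> Optional[str]:
    hits = set()
    for known, guide in spacer_to_guide.items():
        if sum(a != b for a, b in zip(spacer, known)) == 1:
            hits.add(guide)
            if len(hits) > 1:
                return None  # ambiguous
    return hits.pop() if len(hits) == 1 else None


def guide_lfc(
    counts_input: pd.Series,
    counts_sorted: pd.Series,
    pseudocount: float = LFC_PSEUDOCOUNT,
) -> pd.Series:
    """Depth-normalized log2((sorted + c)/(input + c)) per guide.

    Counts are scaled to reads-per-million within each sample first, so the
    fold change is invariant to sequencing depth.
    """
    counts_sorted = counts_sorted.reindex(counts_input.index).fillna(0)
    norm_in = counts_input / counts_input.sum() * 1e6
    norm_so = counts_sorted / counts_sorted.sum() * 1e6
    return np.log2((norm_so + pseudocount) / (norm_in + pseudocount)).rename("lfc")


def guide_enrichment(
    counts_input: pd.Series,
    counts_sorted: pd.Series,
    library: GuideLibrary,
    pseudocount: float = LFC_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene enrichment summary of sorted vs input counts.

    For each gene: its guides' median lfc and a two-sided Mann-Whitney test
    of the guides' lfcs against the non-targeting guides' lfcs, BH-adjusted
    across genes. Requires at least one non-targeting guide.
    """
    nt_ids = library.nontargeting_ids()
    if not nt_ids:
        raise ValueError("library has no non-targeting guides")
    lfc = guide_lfc(counts_input, counts_sorted, pseudocount)
    nt_lfc = lfc.loc[nt_ids].to_numpy()

    rows = []
    for gene, sub in library.table.groupby("gene"):
        if gene == NONTARGETING:
            continue
        gids = [g for g in sub["guide_id"] if g in lfc.index]
        if not gids:
            logger.warning("gene %s has no counted guides; skipped", gene)
            continue
        g_lfc = lfc.loc[gids].to_numpy()
        res = group_shift_test(
            np.concatenate([g_lfc, nt_lfc]),
            np.concatenate([np.ones(len(g_lfc), bool), np.zeros(len(nt_lfc), bool)]),
            class_label=str(gene),
        )
        rows.append(
            {"gene": gene, "n_guides": len(gids), "median_lfc": res.median_class,
             "U": res.U, "p": res.p}
        )
    out = pd.DataFrame(rows).sort_values("gene").reset_index(drop=True)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values(["q", "median_lfc"], ascending=[True, False]).reset_index(drop=True)
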