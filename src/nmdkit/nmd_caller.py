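"""Empirical NMD-target calling by meta-analysis across perturbation contrasts.

Evidence comes from per-contrast differential-expression tables for
knockdown (targets expected up) and rescue (targets expected down) of NMD
factors. Per transcript, contrasts whose fold-change direction contradicts
the expectation contribute p = 1 (a directionality gate); the remaining
BH-adjusted p-values are combined by both Fisher's method (chi-square of
-2*sum(ln p)) and the sum of p-values (Edgington's method, Irwin-Hall CDF
of the sum of k uniforms), and the final meta p-value is the maximum of the
two — the conservative combination. Transcripts with meta p below the
cutoff (default 0.05) are called NMD targets.

Combining adjusted rather than raw p-values is statistically non-standard
but is the procedure reproduced here; ``use_raw_p`` switches to raw
p-values when the evidence tables carry them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_NMD = 0.05
_P_MIN = 1e-300


@dataclass(frozen=True)
class ContrastEvidence:
    """One contrast's per-transcript evidence.

    ``table`` needs columns transcript_id, lfc, q (and optionally p);
    ``expected_direction`` is "up" for knockdown of an NMD factor and
    "down" for a rescue.
    """

    contrast_id: str
    expected_direction: str
    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expected_direction not in ("up", "down"):
            raise ValueError("expected_direction must be 'up' or 'down'")
        missing = {"transcript_id", "lfc", "q"} - set(self.table.columns)
        if missing:
            raise ValueError(f"evidence table lacks columns: {sorted(missing)}")
        q = self.table["q"].to_numpy(float)
        if np.isnan(q).any() or (q < 0).any() or (q > 1).any():
            raise ValueError("q-values must lie in [0, 1]")


def combine_fisher(pvals: Sequence[float]) -> float:
    """Fisher's method: upper chi-square tail of -2*sum(ln p) with 2k df."""
    p = _validated(pvals)
    x = -2.0 * np.sum(np.log(np.maximum(p, _P_MIN)))
    return float(stats.chi2.sf(x, 2 * p.size))


def combine_sum(pvals: Sequence[float]) -> float:
    """Edgington's method: Irwin-Hall CDF of the sum of k p-values."""
    p = _validated(pvals)
    return float(np.clip(stats.irwinhall(p.size).cdf(p.sum()), 0.0, 1.0))


def combine_meta(pvals: Sequence[float]) -> tuple[float, float, float]:
    """(p_fisher, p_sum, p_meta) with p_meta = max of the two combinations."""
    pf, ps = combine_fisher(pvals), combine_sum(pvals)
    return pf, ps, max(pf, ps)


def _validated(pvals: Sequence[float]) -> np.ndarray:
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ValueError("need at least one p-value to combine")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return p


def call_targets(
    evidence: Sequence[ContrastEvidence],
    alpha_nmd: float = DEFAULT_ALPHA_NMD,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Combine per-contrast evidence into per-transcript NMD-target calls.

    The transcript universe is the union over contrasts; a contrast missing
    a transcript, or showing a fold change whose sign contradicts its
    expected direction, contributes p = 1 for that transcript. Returns a
    frame with transcript_id, p_fisher, p_sum, p_meta and is_nmd_target
    (p_meta < alpha_nmd), invariant to the order of contrasts.
    """
    if not evidence:
        raise ValueError("need at least one contrast")
    evidence = sorted(evidence, key=lambda e: e.contrast_id)
    universe = sorted(set().union(*(e.table["transcript_id"] for e in evidence)))
    index = pd.Index(universe, name="transcript_id")
    k = len(evidence)
    pmat = np.ones((len(universe), k))
    pcol = "p" if use_raw_p else "q"
    for j, ev in enumerate(evidence):
        if pcol not in ev.table.columns:
            raise ValueError(f"contrast {ev.contrast_id}: no column {pcol!r}")
        tab = ev.table.set_index("transcript_id").reindex(index)
        n_missing = int(tab["lfc"].isna().sum())
        if n_missing:
            logger.warning(
                "contrast %s: %d transcripts absent; they contribute p=1",
                ev.contrast_id, n_missing,
            )
        sign_ok = (tab["lfc"] > 0) if ev.expected_direction == "up" else (tab["lfc"] < 0)
        p = tab[pcol].to_numpy(float)
        pmat[:, j] = np.where(sign_ok.fillna(False).to_numpy() & ~np.isnan(p), p, 1.0)

    x = -2.0 * np.sum(np.log(np.maximum(pmat, _P_MIN)), axis=1)
    p_fisher = stats.chi2.sf(x, 2 * k)
    p_sum = np.clip(stats.irwinhall(k).cdf(pmat.sum(axis=1)), 0.0, 1.0)
    p_meta = np.maximum(p_fisher, p_sum)
    out = pd.DataFrame(
        {
            "transcript_id": universe,
            "p_fisher": p_fisher,
            "p_sum": p_sum,
            "p_meta": p_meta,
            "is_nmd_target": p_meta < alpha_nmd,
        }
    )
    logger.info("call_targets: %d/%d transcripts called NMD targets at %.3g",
                int(out["is_nmd_target"].sum()), len(out), alpha_nmd)
    return out


def read_evidence_tsv(path: str) -> list[ContrastEvidence]:
    """Load long-format evidence (transcript_id, contrast_id, lfc, q, expected_direction)."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for cid, sub in df.groupby("contrast_id"):
        directions = sub["expected_direction"].unique()
        if len(directions) != 1:
            raise ValueError(f"contrast {cid}: inconsistent expected_direction")
        out.append(
            ContrastEvidence(
                contrast_id=str(cid),
                expected_direction=str(directions[0]),
                table=sub[["transcript_id", "lfc", "q"]].reset_index(drop=True),
            )
        )
    return out
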