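"""Differential tests for mRNA, footprint and ribosome-occupancy changes.

The per-transcript engine is a negative-binomial (NB) delta-method test:
counts are normalized by median-of-ratios size factors, per-transcript
dispersions are estimated by the method of moments (variance = mu +
alpha*mu^2) and shrunk halfway toward the trimmed mean dispersion of
transcripts of similar abundance, and the log2 fold change is tested
against a normal with its delta-method standard error. The occupancy
(translational-efficiency) change is the difference of the footprint and
mRNA log2 fold changes, with standard errors combined in quadrature under
the assumption that the two libraries are independent preparations.

This is intentionally a simple, fully specified test — not a
re-implementation of DESeq2 or Xtail; its validity surface is calibration
and parameter recovery on negative-binomial simulations.

Class-level statistics (rank-sum shift of a transcript class against the
background, and hypergeometric set-overlap tests) live here too.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

ALPHA_FLOOR = 0.01
LFC_PSEUDOCOUNT = 0.5
DEFAULT_FDR = 0.1  # significance threshold for occupancy calls


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample column)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2:
        raise ValueError("counts must be transcripts x samples")
    if (counts.sum(axis=0) == 0).any():
        raise ValueError("degenerate size factors: a sample has all-zero counts")
    positive = (counts > 0).all(axis=1)
    if positive.sum() < 2:
        raise ValueError("too few all-positive transcripts for median-of-ratios")
    log_ref = np.log(counts[positive]).mean(axis=1, keepdims=True)
    sf = np.exp(np.median(np.log(counts[positive]) - log_ref, axis=0))
    return sf


def estimate_dispersion(counts: Sequence[float], alpha_floor: float = ALPHA_FLOOR) -> float:
    """Method-of-moments NB dispersion from replicate counts of one group.

    alpha = max((s^2 - m) / m^2, alpha_floor). Requires >= 2 replicates;
    with fewer, supply a dispersion explicitly.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("need >= 2 replicates to estimate dispersion; supply alpha")
    m = x.mean()
    if m == 0:
        logger.warning("all replicates zero; dispersion set to floor %g", alpha_floor)
        return alpha_floor
    s2 = x.var(ddof=1)
    return max((s2 - m) / m**2, alpha_floor)


def shrink_dispersions(
    alphas: np.ndarray,
    means: np.ndarray,
    weight: float = 0.5,
    n_bins: int = 20,
    trim: float = 0.1,
) -> np.ndarray:
    """Shrink raw dispersions 50/50 toward the trimmed mean of similar-abundance transcripts.

    Transcripts are binned by mean abundance into ``n_bins`` quantile bins;
    each raw alpha is averaged with the trimmed mean alpha of its bin.
    """
    alphas = np.asarray(alphas, float)
    means = np.asarray(means, float)
    if len(alphas) < n_bins * 2:
        target = stats.trim_mean(alphas, trim) if len(alphas) > 2 else alphas.mean()
        return weight * alphas + (1 - weight) * target
    order = np.argsort(means, kind="stable")
    bins = np.array_split(order, n_bins)
    out = alphas.copy()
    for idx in bins:
        out[idx] = weight * alphas[idx] + (1 - weight) * stats.trim_mean(alphas[idx], trim)
    return out


def nb_two_group(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    sf: Optional[np.ndarray] = None,
    alpha: Optional[np.ndarray] = None,
) -> pd.DataFrame:
    """Per-transcript NB delta-method test of group B against group A.

    Returns a frame with columns lfc (log2((meanB+c)/(meanA+c)) on
    size-factor-normalized counts, c = 0.5), se and two-sided normal p.
    """
    counts_a = np.atleast_2d(np.asarray(counts_a, float))
    counts_b = np.atleast_2d(np.asarray(counts_b, float))
    n_a, n_b = counts_a.shape[1], counts_b.shape[1]
    if n_a < 2 or n_b < 2:
        raise ValueError("need >= 2 replicates per group")
    if sf is None:
        sf = size_factors(np.hstack([counts_a, counts_b]))
    sf = np.asarray(sf, float)
    norm_a = counts_a / sf[:n_a]
    norm_b = counts_b / sf[n_a:]

    mean_a = norm_a.mean(axis=1)
    mean_b = norm_b.mean(axis=1)
    c = LFC_PSEUDOCOUNT
    lfc = np.log2((mean_b + c) / (mean_a + c))

    if alpha is None:
        raw_a = _raw_alpha(norm_a)
        raw_b = _raw_alpha(norm_b)
        w_a, w_b = n_a - 1, n_b - 1
        raw = (w_a * raw_a + w_b * raw_b) / (w_a + w_b)
        alpha = shrink_dispersions(raw, (mean_a + mean_b) / 2)
    alpha = np.broadcast_to(np.asarray(alpha, float), lfc.shape)

    # delta method: var(log2 mean) ~= var(mean) / ((mean + c) ln 2)^2
    var_a = (mean_a + alpha * mean_a**2) / n_a
    var_b = (mean_b + alpha * mean_b**2) / n_b
    ln2 = np.log(2.0)
    se = np.sqrt(var_a / (mean_a + c) ** 2 + var_b / (mean_b + c) ** 2) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), 0.0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return pd.DataFrame({"lfc": lfc, "se": se, "p": np.clip(p, 0.0, 1.0)})


def _raw_alpha(norm: np.ndarray) -> np.ndarray:
    m = norm.mean(axis=1)
    s2 = norm.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        a = np.where(m > 0, (s2 - m) / np.where(m > 0, m, 1.0) ** 2, ALPHA_FLOOR)
    return np.maximum(a, ALPHA_FLOOR)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, clipped at 1."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def occupancy_diff(rna, rpf, cond_a: str, cond_b: str,
                   fdr: float = DEFAULT_FDR) -> pd.DataFrame:
    """Per-transcript occupancy change between two conditions.

    ``rna`` and ``rpf`` are :class:`nmdkit.quant.CountMatrix` objects for the
    two assays. mRNA and footprint log2 fold changes come from
    :func:`nb_two_group` per assay; the occupancy change is their difference
    with standard errors added in quadrature, two-sided normal p, and BH q.
    ``significant`` marks q below the FDR threshold (default 0.1).
    """
    shared = rna.counts.index.intersection(rpf.counts.index)
    dropped = len(rna.counts.index.union(rpf.counts.index)) - len(shared)
    if dropped:
        logger.warning("%d transcripts present in only one assay excluded", dropped)

    parts = {}
    for label, cm in (("mrna", rna), ("rpf", rpf)):
        sa, sb = cm.samples_for(cond_a), cm.samples_for(cond_b)
        if len(sa) < 2 or len(sb) < 2:
            raise ValueError(
                f"{label}: conditions {cond_a!r}/{cond_b!r} need >= 2 replicates each"
            )
        a = cm.counts.loc[shared, sa].to_numpy(float)
        b = cm.counts.loc[shared, sb].to_numpy(float)
        parts[label] = nb_two_group(a, b)

    lfc_occ = parts["rpf"]["lfc"].to_numpy() - parts["mrna"]["lfc"].to_numpy()
    se_occ = np.sqrt(parts["rpf"]["se"].to_numpy() ** 2 + parts["mrna"]["se"].to_numpy() ** 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se_occ > 0, lfc_occ / np.where(se_occ > 0, se_occ, 1.0), 0.0)
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 0.0, 1.0)
    q = bh_adjust(p)
    out = pd.DataFrame(
        {
            "transcript_id": shared,
            "lfc_mrna": parts["mrna"]["lfc"].to_numpy(),
            "lfc_rpf": parts["rpf"]["lfc"].to_numpy(),
            "lfc_occ": lfc_occ,
            "se_occ": se_occ,
            "p": p,
            "q": q,
        }
    )
    out["significant"] = out["q"] < fdr
    return out


@dataclass(frozen=True)
class ClassShiftResult:
    """Rank-sum comparison of a transcript class against the background."""

    class_label: str
    n_class: int
    n_background: int
    median_class: float
    median_background: float
    U: float
    p: float


def group_shift_test(
    values: Sequence[float],
    in_class: Sequence[bool],
    class_label: str = "class",
    exact_max_n: int = 20,
) -> ClassShiftResult:
    """Two-sided Mann-Whitney U test of class values against background values.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and no ties; normal approximation with tie correction (and continuity
    correction) otherwise.
    """
    values = np.asarray(values, float)
    in_class = np.asarray(in_class, bool)
    cls, bg = values[in_class], values[~in_class]
    if cls.size == 0 or bg.size == 0:
        raise ValueError("both the class and the background must be non-empty")
    has_ties = len(np.unique(values)) < values.size
    method = "exact" if (max(cls.size, bg.size) <= exact_max_n and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(cls, bg, alternative="two-sided", method=method)
    return ClassShiftResult(
        class_label=class_label,
        n_class=int(cls.size),
        n_background=int(bg.size),
        median_class=float(np.median(cls)),
        median_background=float(np.median(bg)),
        U=float(res.statistic),
        p=float(min(res.pvalue, 1.0)),
    )


def overlap_test(set_a: set, set_b: set, background_size: int) -> float:
    """Upper-tail hypergeometric probability of >= |A ∩ B| shared members."""
    n_a, n_b = len(set_a), len(set_b)
    if n_a > background_size or n_b > background_size:
        raise ValueError("set larger than the background")
    k = len(set_a & set_b)
    if k > min(n_a, n_b):
        raise ValueError("overlap exceeds the smaller set")
    return float(stats.hypergeom.sf(k - 1, background_size, n_a, n_b))
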