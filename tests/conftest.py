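import numpy as np
import pandas as pd
import pytest

from nmdkit.annotate import TranscriptModel
from nmdkit.quant import CountMatrix
from nmdkit.simulate import SimulationConfig, make_transcriptome


@pytest.fixture(scope="session")
def small_bundle():
    """60-gene synthetic transcriptome shared by read-only tests."""
    return make_transcriptome(SimulationConfig(seed=1, n_genes=60))


@pytest.fixture(scope="session")
def big_bundle():
    """500-gene transcriptome (1000 isoforms) for the oracle-equivalence checks."""
    return make_transcriptome(SimulationConfig(seed=7, n_genes=500))


@pytest.fixture
def two_exon_plus():
    """Plus-strand model on exons [100,200)+[300,400), CDS t50..151."""
    return TranscriptModel(
        transcript_id="TX1", gene_id="G1", chrom="chr1", strand="+",
        exons=((100, 200), (300, 400)), cds_start_t=50, cds_end_t=151,
    )


@pytest.fixture
def two_exon_minus():
    """Minus-strand model on the same exons (transcript order reversed)."""
    return TranscriptModel(
        transcript_id="TX2", gene_id="G2", chrom="chr1", strand="-",
        exons=((300, 400), (100, 200)), cds_start_t=50, cds_end_t=151,
    )


def nb_draw(rng, mean, alpha, size=None):
    r = 1.0 / alpha
    return rng.negative_binomial(r, r / (r + np.asarray(mean, float)), size=size)


def make_count_matrix(assay, cols, eff_len, conditions):
    idx = pd.Index([f"T{i:04d}" for i in range(len(eff_len))], name="transcript_id")
    return CountMatrix(
        assay=assay,
        counts=pd.DataFrame(cols, index=idx),
        effective_length=pd.Series(np.asarray(eff_len, float), index=idx),
        conditions=conditions,
    )


def null_occupancy_inputs(rng, n_transcripts=2000, n_rep=3, mean_range=(100, 1000),
                          alpha=0.05, planted=None, occ_effect=1.0, mrna_effect=1.0):
    """Paired rna/rpf CountMatrix with optional planted effects in condition B."""
    if np.isscalar(mean_range):
        mu = np.full(n_transcripts, float(mean_range))
    else:
        mu = np.exp(rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]),
                                n_transcripts))
    if planted is None:
        planted = np.zeros(n_transcripts, bool)
    rna_cols, rpf_cols, conds = {}, {}, {}
    for cond in ("A", "B"):
        m_fac = np.where(planted, mrna_effect, 1.0) if cond == "B" else 1.0
        o_fac = np.where(planted, occ_effect, 1.0) if cond == "B" else 1.0
        for r in range(n_rep):
            s = f"rna_{cond}{r}"
            rna_cols[s] = nb_draw(rng, mu * m_fac, alpha)
            conds[s] = cond
            s = f"rpf_{cond}{r}"
            rpf_cols[s] = nb_draw(rng, mu * m_fac * o_fac, alpha)
            conds[s] = cond
    rna = make_count_matrix("rna", rna_cols, np.full(n_transcripts, 1000.0),
                            {k: v for k, v in conds.items() if k.startswith("rna")})
    rpf = make_count_matrix("rpf", rpf_cols, np.full(n_transcripts, 500.0),
                            {k: v for k, v in conds.items() if k.startswith("rpf")})
    return rna, rpf, planted
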