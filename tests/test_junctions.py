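"""Intron extraction from spliced alignments and the junction filters."""

import numpy as np
import pysam
import pytest

from nmdkit.junctions import (
    JunctionCall,
    JunctionFilterParams,
    extract_introns,
    filter_junctions,
    junctions_to_frame,
    motif_check,
)
from nmdkit.simulate import SimulationConfig, simulate_spliced_alignments


def write_sam(path, reads, chrom="chr1", length=10000):
    header = {"HD": {"VN": "1.6"}, "SQ": [{"SN": chrom, "LN": length}]}
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, flag, pos, cigar in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.flag = flag
            a.reference_id = 0
            a.reference_start = pos
            a.cigarstring = cigar
            a.mapping_quality = 60
            out.write(a)


def test_extract_introns_support_and_spanning(tmp_path):
    """3 spliced + 97 contiguous reads across a 100-nt gap -> 3/100."""
    reads = [(f"s{i}", 0, 950, "50M100N30M") for i in range(3)]
    reads += [(f"c{i}", 0, 940, "300M") for i in range(97)]
    sam = tmp_path / "a.sam"
    write_sam(sam, reads)
    calls = extract_introns(str(sam))
    assert len(calls) == 1
    c = calls[0]
    assert (c.donor, c.acceptor) == (1000, 1100)
    assert (c.n_support, c.n_spanning) == (3, 100)
    assert c.fraction == pytest.approx(0.03)


def test_read_with_two_gaps_contributes_to_two_candidates(tmp_path):
    sam = tmp_path / "b.sam"
    write_sam(sam, [("r1", 0, 100, "20M50N20M80N20M")])
    calls = extract_introns(str(sam))
    assert [(c.donor, c.acceptor) for c in calls] == [(120, 170), (190, 270)]


def test_non_spanning_read_not_in_denominator(tmp_path):
    reads = [("s1", 0, 950, "50M100N30M"), ("short", 0, 900, "50M")]
    sam = tmp_path / "c.sam"
    write_sam(sam, reads)
    c = extract_introns(str(sam))[0]
    assert c.n_spanning == 1  # the 50M read stops before the donor


def test_motif_check_strands():
    plus = "N" * 100 + "GT" + "A" * 96 + "AG" + "N" * 100
    minus = "N" * 100 + "CT" + "A" * 96 + "AC" + "N" * 100
    call = JunctionCall("chr1", "+", 100, 200)
    motif, ok = motif_check({"chr1": plus}, call)
    assert (motif, ok) == ("GU-AG", True)
    motif, ok = motif_check({"chr1": plus.replace("GT", "GC", 1)}, call)
    assert (motif, ok) == ("GC-AG", False)
    mcall = JunctionCall("chr1", "-", 100, 200)
    motif, ok = motif_check({"chr1": minus}, mcall)
    assert (motif, ok) == ("GU-AG", True)  # reverse complement of CT..AC
    tiny = JunctionCall("chr1", "+", 100, 102)
    assert motif_check({"chr1": plus}, tiny) == ("", False)


def test_filter_thresholds_nanopore():
    genome = {"chr1": "N" * 100 + "GT" + "A" * 96 + "AG" + "N" * 100}
    mk = lambda sup, span: JunctionCall("chr1", "+", 100, 200,
                                        n_support=sup, n_spanning=span)
    params = JunctionFilterParams.nanopore()
    assert filter_junctions([mk(3, 100)], params, genome)[0].passes
    assert not filter_junctions([mk(1, 10)], params, genome)[0].passes
    assert not filter_junctions([mk(2, 400)], params, genome)[0].passes  # 0.5%
    # short-read mode: no fraction test, but >= 5 reads
    sr = JunctionFilterParams.short_read()
    assert filter_junctions([mk(5, 2000)], sr, genome)[0].passes
    assert not filter_junctions([mk(4, 10)], sr, genome)[0].passes


def test_planted_junction_recovery_both_modes(tmp_path):
    cfg = SimulationConfig(seed=3)
    sam = tmp_path / "spliced.sam"
    genome, truth = simulate_spliced_alignments(cfg, str(sam))
    candidates = extract_introns(str(sam))
    assert {(c.donor, c.acceptor) for c in candidates} == set(
        zip(truth["donor"], truth["acceptor"])
    )
    for mode, col in (
        (JunctionFilterParams.nanopore(), "passes_nanopore"),
        (JunctionFilterParams.short_read(), "passes_shortread"),
    ):
        passed = {(c.donor, c.acceptor)
                  for c in filter_junctions(candidates, mode, genome) if c.passes}
        planted = set(zip(truth.loc[truth[col], "donor"], truth.loc[truth[col], "acceptor"]))
        assert passed == planted


def test_filters_monotone_in_min_support(tmp_path):
    cfg = SimulationConfig(seed=4)
    sam = tmp_path / "s.sam"
    genome, _ = simulate_spliced_alignments(cfg, str(sam))
    candidates = extract_introns(str(sam))
    previous = None
    for min_support in (1, 2, 5, 10, 20):
        params = JunctionFilterParams(min_support=min_support, min_fraction=None,
                                      require_gu_ag=True)
        passing = {(c.donor, c.acceptor)
                   for c in filter_junctions(candidates, params, genome) if c.passes}
        if previous is not None:
            assert passing <= previous
        previous = passing


def test_junction_frame_one_based_output(tmp_path):
    sam = tmp_path / "d.sam"
    write_sam(sam, [("s1", 0, 950, "50M100N30M"), ("c1", 0, 940, "300M")])
    genome = {"chr1": "N" * 1000 + "GT" + "N" * 96 + "AG" + "N" * 9000}
    df = junctions_to_frame(filter_junctions(extract_introns(str(sam)),
                                             JunctionFilterParams(min_support=1), genome))
    row = df.iloc[0]
    assert (row["start"], row["end"]) == (1001, 1100)  # 1-based inclusive intron
    assert row["motif"] == "GU-AG"


def test_filter_params_validation():
    with pytest.raises(ValueError):
        JunctionFilterParams(min_support=0)
    with pytest.raises(ValueError):
        JunctionFilterParams(min_fraction=1.5)
    with pytest.raises(ValueError):
        filter_junctions([JunctionCall("c", "+", 0, 100, n_support=5, n_spanning=5)],
                         JunctionFilterParams(), genome=None)
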