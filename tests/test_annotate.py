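"""Transcript-model coordinates, GTF parsing and the NMD classifiers."""

import numpy as np
import pytest

from nmdkit.annotate import (
    ClassifierParams,
    CoordinateError,
    GTFParseError,
    TranscriptModel,
    classify_ejc_dependence,
    classify_transcriptome,
    detect_uorf,
    downstream_junction_distances,
    parse_gtf,
    select_representatives,
)

# ---------------------------------------------------------------- coordinates


def test_transcript_coordinates_plus(two_exon_plus):
    m = two_exon_plus
    assert m.to_transcript_coord(100) == 0
    assert m.to_transcript_coord(150) == 50
    assert m.to_transcript_coord(300) == 100
    assert m.to_transcript_coord(352) == 152
    assert m.length_t == 200


def test_transcript_coordinates_minus(two_exon_minus):
    m = two_exon_minus
    assert m.to_transcript_coord(399) == 0
    assert m.to_transcript_coord(300) == 99
    assert m.to_transcript_coord(199) == 100


def test_intronic_position_rejected(two_exon_plus):
    with pytest.raises(CoordinateError):
        two_exon_plus.to_transcript_coord(250)


def test_coordinate_round_trip_on_random_models(small_bundle):
    """to_transcript_coord and to_genomic_coord are mutual inverses, both strands."""
    for m in small_bundle.models:
        for t in range(0, m.length_t, 7):
            assert m.to_transcript_coord(m.to_genomic_coord(t)) == t
        assert m.to_transcript_coord(m.to_genomic_coord(m.length_t - 1)) == m.length_t - 1


def test_minus_strand_map_matches_per_base_oracle():
    """Brute-force per-base enumeration of the minus-strand spliced map."""
    m = TranscriptModel("T", "G", "c", "-", ((300, 400), (100, 200)), 50, 151)
    expected = [g for g in range(399, 299, -1)] + [g for g in range(199, 99, -1)]
    for t, g in enumerate(expected):
        assert m.to_genomic_coord(t) == g
        assert m.to_transcript_coord(g) == t


def test_model_invariants_enforced():
    with pytest.raises(ValueError):  # CDS not divisible by 3
        TranscriptModel("T", "G", "c", "+", ((0, 100),), 10, 50)
    with pytest.raises(ValueError):  # overlapping exons
        TranscriptModel("T", "G", "c", "+", ((0, 100), (50, 150)), 10, 51)
    with pytest.raises(ValueError):  # CDS beyond transcript
        TranscriptModel("T", "G", "c", "+", ((0, 100),), 10, 120)


# ----------------------------------------------------------------- GTF parse

TOY_GTF = """\
chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t151\t200\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tCDS\t301\t349\t.\t+\t2\tgene_id "G1"; transcript_id "T1";
chr1\ttest\tstop_codon\t350\t352\t.\t+\t0\tgene_id "G1"; transcript_id "T1";
chr1\ttest\texon\t501\t600\t.\t+\t.\tgene_id "G2"; transcript_id "T2";
chr1\ttest\texon\t701\t800\t.\t+\t.\tgene_id "G3"; transcript_id "T3";
chr1\ttest\tCDS\t711\t782\t.\t+\t0\tgene_id "G3"; transcript_id "T3";
"""


def test_parse_gtf_two_exon_toy(tmp_path):
    """Hand-computed coordinate map: CDS (stop included) spans t50..151."""
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    models = parse_gtf(str(path))
    by_id = {m.transcript_id: m for m in models}
    # T2 has no CDS; T3 has CDS but no stop_codon feature nor sequence
    assert set(by_id) == {"T1"}
    m = by_id["T1"]
    assert m.exons == ((100, 200), (300, 400))
    assert (m.cds_start_t, m.cds_end_t) == (50, 151)
    assert m.cds_len == 102


def test_parse_gtf_stop_from_sequence(tmp_path):
    """Without a stop_codon feature, a CDS ending in a stop in the sequence counts."""
    gtf = (
        'chr1\tt\texon\t1\t90\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        'chr1\tt\tCDS\t11\t40\t.\t+\t0\tgene_id "G"; transcript_id "T";\n'
    )
    path = tmp_path / "s.gtf"
    path.write_text(gtf)
    seq = "A" * 10 + "ATG" + "C" * 24 + "TAA" + "G" * 50
    assert len(parse_gtf(str(path), seqs={"T": seq})) == 1
    bad = "A" * 10 + "ATG" + "C" * 27 + "G" * 50  # terminal codon not a stop
    assert parse_gtf(str(path), seqs={"T": bad}) == []


def test_parse_gtf_is_deterministic(tmp_path):
    path = tmp_path / "toy.gtf"
    path.write_text(TOY_GTF)
    assert parse_gtf(str(path)) == parse_gtf(str(path))


def test_parse_gtf_malformed_line_names_line_number(tmp_path):
    path = tmp_path / "bad.gtf"
    path.write_text('chr1\ttest\texon\t101\n')
    with pytest.raises(GTFParseError, match="line 1"):
        parse_gtf(str(path))


def test_parse_gtf_drops_out_of_frame_cds(tmp_path):
    gtf = (
        'chr1\tt\texon\t1\t100\t.\t+\t.\tgene_id "G"; transcript_id "T";\n'
        'chr1\tt\tCDS\t11\t41\t.\t+\t0\tgene_id "G"; transcript_id "T";\n'
        'chr1\tt\tstop_codon\t42\t44\t.\t+\t0\tgene_id "G"; transcript_id "T";\n'
    )
    path = tmp_path / "frame.gtf"
    path.write_text(gtf)
    assert parse_gtf(str(path)) == []


# ------------------------------------------------------- representative rule


def _model(tid, exons, cds_start, cds_end, strand="+"):
    return TranscriptModel(tid, "G", "chr1", strand, exons, cds_start, cds_end)


def test_select_representatives_longest_cds():
    a = _model("A", ((0, 1000),), 100, 399)   # CDS 300
    b = _model("B", ((0, 1000),), 100, 549)   # CDS 450, same stop? no — same stop needed
    # share the stop-codon end (genomic 549) but different CDS length
    a = _model("A", ((0, 1000),), 250, 549)   # CDS 300
    assert select_representatives([a, b]) == {"B"}


def test_select_representatives_tie_breaks():
    # CDS tie 300/300: longer transcript wins
    a = _model("A", ((0, 1200),), 250, 549)
    b = _model("B", ((0, 1500),), 250, 549)
    assert select_representatives([a, b]) == {"B"}
    # full tie: lexicographically smaller id
    c = _model("C", ((0, 1200),), 250, 549)
    assert select_representatives([a, c]) == {"A"}
    assert select_representatives([]) == set()


def test_one_representative_per_stop_key(big_bundle):
    reps = select_representatives(big_bundle.models)
    keys = {}
    for m in big_bundle.models:
        keys.setdefault((m.chrom, m.strand, m.stop_codon_last_genomic()), []).append(m)
    assert len(reps) == len(keys)
    for group in keys.values():
        winner = [m for m in group if m.transcript_id in reps]
        assert len(winner) == 1
        assert winner[0].cds_len == max(m.cds_len for m in group)


# -------------------------------------------------- junction distances / EJC


def test_downstream_junction_distances():
    single = _model("S", ((0, 1000),), 100, 399)
    assert downstream_junction_distances(single) == []
    # stop ends at t=500; junction after t=551 -> [51]
    m = _model("M", ((0, 552), (700, 900)), 201, 500)
    assert downstream_junction_distances(m) == [51]
    # two 3'UTR junctions at 30 and 120
    m2 = _model("M2", ((0, 531), (600, 690), (800, 1000)), 201, 500)
    assert downstream_junction_distances(m2) == [30, 120]


def test_classify_ejc_dependence_strict_threshold():
    m51 = _model("A", ((0, 552), (700, 900)), 201, 500)
    m50 = _model("B", ((0, 551), (700, 900)), 201, 500)
    single = _model("C", ((0, 1000),), 100, 399)
    assert classify_ejc_dependence(m51)
    assert not classify_ejc_dependence(m50)  # "more than 50 nt" read strictly
    assert not classify_ejc_dependence(single)
    assert classify_ejc_dependence(m50, ClassifierParams(d_ejc=49))


# --------------------------------------------------------------------- uORFs


def test_detect_uorf_frame_rule():
    m = _model("U", ((0, 300),), 90, 191)
    no_aug = "C" * 300
    assert not detect_uorf(m, no_aug)
    in_frame = "C" * 30 + "ATG" + "C" * 267   # (90-30) % 3 == 0
    assert not detect_uorf(m, in_frame)
    out_frame = "C" * 31 + "ATG" + "C" * 266  # (90-31) % 3 != 0
    assert detect_uorf(m, out_frame)
    assert detect_uorf(m, out_frame.replace("T", "U"))  # RNA alphabet
    with pytest.raises(ValueError):
        detect_uorf(m, "C" * 299)


def test_detect_uorf_codon_may_extend_into_cds():
    m = _model("U", ((0, 300),), 90, 191)
    seq = "C" * 89 + "ATG" + "C" * 208  # AUG first nt at i=89, extends into CDS
    assert (90 - 89) % 3 != 0
    assert detect_uorf(m, seq)


# ------------------------------------------------------ brute-force oracles


def ejc_oracle(model, d_ejc=50):
    """Scan every junction via the per-base transcript->genomic map."""
    gmap = [model.to_genomic_coord(t) for t in range(model.length_t)]
    step = 1 if model.strand == "+" else -1
    flags = []
    for t in range(model.length_t - 1):
        if gmap[t + 1] != gmap[t] + step:  # junction between t and t+1
            if t >= model.cds_end_t:
                flags.append(t - model.cds_end_t)
    return any(d > d_ejc for d in flags), flags


def uorf_oracle(model, seq):
    s = seq.upper().replace("U", "T")
    return any(
        s[i : i + 3] == "ATG" and (model.cds_start_t - i) % 3 != 0
        for i in range(model.cds_start_t)
    )


def test_classifiers_agree_with_oracles(big_bundle):
    """50-nt rule and uORF classifier match per-base brute force on 1000 models."""
    assert len(big_bundle.models) == 1000
    for m in big_bundle.models:
        oracle_flag, oracle_dists = ejc_oracle(m)
        assert classify_ejc_dependence(m) == oracle_flag
        assert downstream_junction_distances(m) == oracle_dists
        assert detect_uorf(m, big_bundle.seqs[m.transcript_id]) == uorf_oracle(
            m, big_bundle.seqs[m.transcript_id]
        )


# ------------------------------------------------------------- whole-set API


def test_classify_transcriptome_flags_and_targets(small_bundle):
    truth = small_bundle.truth.set_index("transcript_id")
    targets = set(truth.index[truth["is_nmd_target"]])
    records = classify_transcriptome(small_bundle.models, small_bundle.seqs, targets)
    assert len(records) == int(truth["is_representative"].sum())
    for r in records:
        row = truth.loc[r.transcript_id]
        assert r.ejc_dependent == row["ejc_dependent"]
        assert r.has_uorf == row["has_uorf"]
        assert r.is_nmd_target == row["is_nmd_target"]
        if r.ejc_dependent:
            assert r.min_downstream_junction_distance is not None


def test_classify_transcriptome_empty_targets_and_stray_ids(small_bundle):
    records = classify_transcriptome(small_bundle.models, small_bundle.seqs, set())
    assert not any(r.is_nmd_target for r in records)
    stray = classify_transcriptome(
        small_bundle.models, small_bundle.seqs, {"NOT_A_TRANSCRIPT"}
    )
    assert not any(r.is_nmd_target for r in stray)
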