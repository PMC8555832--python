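"""End-to-end orchestration: simulate -> annotate -> quant -> diff -> call -> class stats.

``run_pipeline`` executes the stages in dependency order on a synthetic
bundle (or user-supplied inputs), writing deterministic TSVs plus a run
manifest (package version, config hash, seed, per-file SHA-256). Rerunning
with an identical configuration reproduces identical bytes. The optional
junction, footprint and screen stages demonstrate the remaining modules.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from . import __version__
from .annotate import ClassifierParams, classifications_to_frame, classify_transcriptome, parse_gtf
from .difftest import DEFAULT_FDR, group_shift_test, occupancy_diff
from .footprints import fiveprime_profile, footprint_geometry, profile_to_frame
from .junctions import JunctionFilterParams, extract_introns, filter_junctions, junctions_to_frame
from .nmd_caller import DEFAULT_ALPHA_NMD, call_targets
from .quant import occupancy_matrix, tpm, write_matrix_tsv
from .screen import count_spacers, guide_enrichment
from .simulate import (
    SimulationConfig,
    make_guide_library,
    make_transcriptome,
    simulate_counts,
    simulate_evidence,
    simulate_footprints,
    simulate_screen_reads,
    simulate_spliced_alignments,
    write_fasta,
    write_gtf,
)

logger = logging.getLogger(__name__)

ANALYSIS_KEYS = {
    "d_ejc": 50,
    "alpha_nmd": DEFAULT_ALPHA_NMD,
    "fdr": DEFAULT_FDR,
    "junction_mode": "nanopore",
    "lag_range": (20, 40),
    "run_junctions": True,
    "run_footprints": True,
    "run_screen": True,
}
_SIM_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}


class PipelineConfigError(ValueError):
    pass


def validate_config(config: Mapping) -> tuple[SimulationConfig, dict]:
    """Split a flat config mapping into simulation and analysis settings.

    Unknown keys are rejected before any stage runs.
    """
    unknown = set(config) - _SIM_KEYS - set(ANALYSIS_KEYS)
    if unknown:
        raise PipelineConfigError(f"unknown config keys: {sorted(unknown)}")
    sim = SimulationConfig(**{k: _coerce(k, v) for k, v in config.items() if k in _SIM_KEYS})
    analysis = dict(ANALYSIS_KEYS)
    analysis.update({k: v for k, v in config.items() if k in ANALYSIS_KEYS})
    if not 0 < analysis["alpha_nmd"] < 1 or not 0 < analysis["fdr"] < 1:
        raise PipelineConfigError("alpha_nmd and fdr must lie in (0, 1)")
    if analysis["d_ejc"] < 0:
        raise PipelineConfigError("d_ejc must be >= 0")
    if analysis["junction_mode"] not in ("nanopore", "short_read"):
        raise PipelineConfigError("junction_mode must be nanopore or short_read")
    return sim, analysis


def _coerce(key: str, value):
    # YAML gives lists where the dataclass wants tuples
    field_types = {f.name: f.type for f in dataclasses.fields(SimulationConfig)}
    if isinstance(value, list) and "tuple" in str(field_types.get(key, "")):
        return tuple(value)
    return value


def load_config(path: str) -> dict:
    import yaml

    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, Mapping):
        raise PipelineConfigError("config must be a mapping of key: value pairs")
    return dict(data)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: Mapping,
    outdir: str,
    seed: Optional[int] = None,
) -> dict:
    """Run every stage on a synthetic bundle; return the manifest.

    ``seed`` overrides the config seed. Outputs land under ``outdir``:
    inputs/ (GTF, FASTA, truth), then one TSV per stage and a
    ``manifest.json`` hashing every output.
    """
    sim_cfg, analysis = validate_config(config)
    if seed is not None:
        sim_cfg = dataclasses.replace(sim_cfg, seed=int(seed))
    out = Path(outdir)
    (out / "inputs").mkdir(parents=True, exist_ok=True)
    params = ClassifierParams(d_ejc=int(analysis["d_ejc"]))

    # --- simulate ---------------------------------------------------------
    bundle = make_transcriptome(sim_cfg)
    gtf_path = out / "inputs" / "transcripts.gtf"
    fasta_path = out / "inputs" / "transcripts.fa"
    write_gtf(bundle.models, str(gtf_path))
    write_fasta(bundle.seqs, str(fasta_path))
    _write_tsv(bundle.truth, out / "inputs" / "truth.tsv")
    rng = sim_cfg.rng()
    rna, rpf = simulate_counts(sim_cfg, bundle.truth, rng=rng)
    write_matrix_tsv(rna.counts, str(out / "counts_rna.tsv"))
    write_matrix_tsv(rpf.counts, str(out / "counts_rpf.tsv"))

    # --- annotate ---------------------------------------------------------
    models = parse_gtf(str(gtf_path), seqs=bundle.seqs)
    logger.info("annotate: %d transcript models", len(models))

    # --- quant ------------------------------------------------------------
    rna_tpm, rpf_tpm = tpm(rna), tpm(rpf)
    write_matrix_tsv(rna_tpm.values, str(out / "tpm_rna.tsv"))
    write_matrix_tsv(rpf_tpm.values, str(out / "tpm_rpf.tsv"))
    occ = occupancy_matrix(rpf_tpm, rna_tpm)
    write_matrix_tsv(occ, str(out / "occupancy_by_condition.tsv"))

    # --- difftest ---------------------------------------------------------
    diff = occupancy_diff(rna, rpf, "ctrl", "treat", fdr=float(analysis["fdr"]))
    _write_tsv(diff, out / "occupancy_diff.tsv")

    # --- nmd_caller -------------------------------------------------------
    evidence, _planted = simulate_evidence(sim_cfg, bundle.truth, rng=rng)
    calls = call_targets(evidence, alpha_nmd=float(analysis["alpha_nmd"]))
    _write_tsv(calls, out / "nmd_calls.tsv")
    target_ids = set(calls.loc[calls["is_nmd_target"], "transcript_id"])

    # --- classification + class-level stats -------------------------------
    records = classify_transcriptome(models, bundle.seqs, target_ids, params)
    cls_df = classifications_to_frame(records)
    _write_tsv(cls_df, out / "classification.tsv")

    merged = cls_df.merge(diff, on="transcript_id")
    shift_rows = []
    for label, mask in (
        ("ejc_dependent", merged["ejc_dependent"]),
        ("nmd_target", merged["is_nmd_target"]),
    ):
        if 0 < mask.sum() < len(merged):
            for metric in ("lfc_occ", "lfc_mrna", "lfc_rpf"):
                res = group_shift_test(merged[metric].to_numpy(), mask.to_numpy(),
                                       class_label=label)
                shift_rows.append(
                    {"class_label": label, "metric": metric,
                     "n_class": res.n_class, "n_background": res.n_background,
                     "median_class": res.median_class,
                     "median_background": res.median_background,
                     "U": res.U, "p": res.p}
                )
    _write_tsv(pd.DataFrame(shift_rows), out / "class_shift.tsv")

    # --- optional stages --------------------------------------------------
    if analysis["run_junctions"]:
        sam_path = out / "inputs" / "spliced.sam"
        genome, jtruth = simulate_spliced_alignments(sim_cfg, str(sam_path), rng=rng)
        _write_tsv(jtruth, out / "inputs" / "junction_truth.tsv")
        mode = analysis["junction_mode"]
        jparams = (JunctionFilterParams.nanopore() if mode == "nanopore"
                   else JunctionFilterParams.short_read())
        calls_j = filter_junctions(extract_introns(str(sam_path)), jparams, genome)
        _write_tsv(junctions_to_frame(calls_j), out / "junctions.tsv")

    if analysis["run_footprints"]:
        anchor = 600
        positions = simulate_footprints(sim_cfg, anchor=anchor, rng=rng)
        profile = fiveprime_profile(positions, anchor=anchor)
        _write_tsv(profile_to_frame(profile), out / "footprint_profile.tsv")
        lag_lo, lag_hi = analysis["lag_range"]
        geom = footprint_geometry(profile, lag_range=(int(lag_lo), int(lag_hi)),
                                  seed=sim_cfg.seed)
        (out / "footprint_geometry.json").write_text(
            json.dumps({"offset": geom.offset, "period": geom.period,
                        "period_score": geom.period_score}, sort_keys=True) + "\n"
        )

    if analysis["run_screen"]:
        library = make_guide_library(sim_cfg, rng=rng)
        fq_in = out / "inputs" / "screen_input.fastq"
        fq_so = out / "inputs" / "screen_sorted.fastq"
        struth, _enriched = simulate_screen_reads(sim_cfg, library, str(fq_in),
                                                  str(fq_so), rng=rng)
        _write_tsv(struth, out / "inputs" / "screen_truth.tsv")
        counts_in, _ = count_spacers(str(fq_in), library, sim_cfg.screen_anchor)
        counts_so, _ = count_spacers(str(fq_so), library, sim_cfg.screen_anchor)
        genes = guide_enrichment(counts_in, counts_so, library)
        _write_tsv(genes, out / "screen_genes.tsv")

    # --- manifest ---------------------------------------------------------
    full_cfg = {**dataclasses.asdict(sim_cfg), **analysis}
    cfg_json = json.dumps(full_cfg, sort_keys=True, default=list)
    files = sorted(p for p in out.rglob("*") if p.is_file() and p.name != "manifest.json")
    manifest = {
        "version": __version__,
        "seed": sim_cfg.seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "files": {str(p.relative_to(out)): _sha256(p) for p in files},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("pipeline complete: %d output files in %s", len(files), out)
    return manifest
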