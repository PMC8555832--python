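"""Detect translational repression of EJC-dependent transcripts.

Simulates paired RNA-seq and ribosome-footprint counts in which the
footprints (but not the mRNA) of EJC-dependent transcripts double in the
treated condition, runs the per-transcript occupancy test, and compares
the occupancy log2 fold changes of the EJC-dependent class against the
background with a Mann-Whitney test — the class-level analysis that shows
reduced/increased translation per mRNA for a transcript class.
"""

from nmdkit.difftest import group_shift_test, occupancy_diff
from nmdkit.simulate import SimulationConfig, make_transcriptome, simulate_counts

cfg = SimulationConfig(seed=21, n_genes=400, occupancy_effect=2.0, mrna_effect=1.0)
bundle = make_transcriptome(cfg)
rna, rpf = simulate_counts(cfg, bundle.truth)

diff = occupancy_diff(rna, rpf, "ctrl", "treat")
rep = bundle.truth[bundle.truth["is_representative"]].set_index("transcript_id")
merged = diff.set_index("transcript_id").join(rep[["ejc_dependent"]])

for metric in ("lfc_occ", "lfc_mrna"):
    res = group_shift_test(merged[metric].to_numpy(),
                           merged["ejc_dependent"].to_numpy(),
                           class_label="EJC-dependent")
    print(f"{metric}: median(class)={res.median_class:+.3f} "
          f"median(background)={res.median_background:+.3f}  "
          f"U={res.U:.0f}  p={res.p:.3g}")

print("\nThe occupancy shift is large and significant (planted 2x on footprints"
      "\nonly), while the mRNA fold changes show no class difference.")
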