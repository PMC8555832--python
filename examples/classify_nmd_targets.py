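"""Classify a synthetic transcriptome with the 50-nt rule and uORF detector.

Builds a small annotated transcriptome, then flags each representative
isoform as EJC-dependent (a 3'UTR exon-exon junction more than 50 nt
downstream of the stop codon) and/or uORF-bearing (an out-of-frame AUG in
the 5'UTR), and checks the flags against the generator's ground truth.
"""

from nmdkit.annotate import classifications_to_frame, classify_transcriptome
from nmdkit.simulate import SimulationConfig, make_transcriptome

cfg = SimulationConfig(seed=1, n_genes=100)
bundle = make_transcriptome(cfg)
truth = bundle.truth.set_index("transcript_id")
targets = set(truth.index[truth["is_nmd_target"]])

records = classify_transcriptome(bundle.models, bundle.seqs, targets)
df = classifications_to_frame(records)

print(df.head(8).to_string(index=False))
print(f"\n{df['ejc_dependent'].sum()} / {len(df)} representatives are EJC-dependent "
      f"(3'UTR junction > 50 nt past the stop codon)")
print(f"{df['has_uorf'].sum()} / {len(df)} carry an out-of-frame upstream AUG")

rep_truth = truth[truth["is_representative"]]
agree = (df.set_index("transcript_id")["ejc_dependent"] == rep_truth["ejc_dependent"]).mean()
print(f"agreement with planted truth: {agree:.0%}")
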