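"""Call empirical NMD targets by meta-analysis across perturbation contrasts.

Simulates four knockdown/rescue contrasts with 10% planted targets, runs
the package's NB two-group test per contrast, combines the BH-adjusted
p-values per transcript by Fisher's method and the sum of p-values
(taking the conservative maximum), and calls targets at meta-p < 0.05.
"""

from nmdkit.nmd_caller import call_targets
from nmdkit.simulate import SimulationConfig, make_transcriptome, simulate_evidence

cfg = SimulationConfig(seed=5, n_genes=300)
bundle = make_transcriptome(cfg)
evidence, planted = simulate_evidence(cfg, bundle.truth)

calls = call_targets(evidence, alpha_nmd=0.05)
called = set(calls.loc[calls["is_nmd_target"], "transcript_id"])

print(calls.sort_values("p_meta").head(6).to_string(index=False))
print(f"\ncalled {len(called)} targets; planted {len(planted)}")
print(f"sensitivity = {len(called & planted) / len(planted):.2f}, "
      f"false-call rate = {len(called - planted) / max(1, len(called)):.2f}")
print("Direction-inconsistent contrasts contribute p=1, so transcripts moving"
      "\nthe wrong way in any knockdown/rescue are penalized.")
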