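"""Extract and filter splice junctions from spliced alignments.

Simulates a SAM file with planted true GU-AG introns plus noise (1-read
gaps, non-GU-AG gaps, gaps below 1% of spanning reads), extracts candidate
introns from CIGAR N gaps, and applies the nanopore filter (>= 2 supporting
reads, >= 1% of reads spanning the intron ends, GU-AG motif).
"""

import tempfile

from nmdkit.junctions import JunctionFilterParams, extract_introns, filter_junctions, junctions_to_frame
from nmdkit.simulate import SimulationConfig, simulate_spliced_alignments

cfg = SimulationConfig(seed=3)
sam = tempfile.NamedTemporaryFile(suffix=".sam", delete=False).name
genome, truth = simulate_spliced_alignments(cfg, sam)

calls = filter_junctions(extract_introns(sam), JunctionFilterParams.nanopore(), genome)
df = junctions_to_frame(calls)
print(df.to_string(index=False))

planted = set(zip(truth.loc[truth["passes_nanopore"], "donor"],
                  truth.loc[truth["passes_nanopore"], "acceptor"]))
passed = {(c.donor, c.acceptor) for c in calls if c.passes}
print(f"\npassing set equals planted true set: {passed == planted}")
print("Noise junctions fail on support (<2 reads), motif (not GU-AG) or the"
      "\nspanning-read fraction (<1%).")
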