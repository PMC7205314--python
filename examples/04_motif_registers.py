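"""Find the enriched 7-mer in a miRNA's targets and map its register.

Forty target fragments carrying a planted seed match are tested against
background sequences from other miRNAs; the winning 7-mer is slid along the
reverse-complemented miRNA to reveal which miRNA positions drive pairing.
"""

import numpy as np

from clearclip._seq import revcomp
from clearclip.motifs import enrich_kmers, map_motif_register, sample_background

rng = np.random.Generator(np.random.PCG64(8))
mir = "TGAGGTAGTAGGTTGTATAGTT"  # DNA alphabet, as mapped reads are
seed_match = revcomp(mir[1:7])  # RC of miRNA nt 2-7

targets = []
for _ in range(40):
    s = "".join(rng.choice(list("ACGT"), size=50))
    targets.append(s[:20] + seed_match + s[26:])
background = ["".join(rng.choice(list("ACGT"), size=50)) for _ in range(200)]

motifs = enrich_kmers(targets, background, "let-7", mir)
top = motifs[0]
print(f"top 7-mer: {top.kmer}  present in {top.n_targets_with_motif}/{top.n_targets}"
      f" targets, corrected p = {top.corrected_pvalue:.1e}")
for start, matches in map_motif_register(top.kmer, mir)[:2]:
    print(f"  register: miRNA positions {start}-{start + 6} ({matches}/7 matches)")
# The register starting at position 1-2 is the canonical seed footprint;
# 3'-register motifs would start around position 13 instead.
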