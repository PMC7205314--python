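"""Simulate a small CLEAR-CLIP library and classify its reads.

Generates a toy transcriptome with planted miRNA binding sites, one FASTQ
library, runs preprocessing (adapter/barcode/collapse) and the chimera
caller, then scores the calls against the planted truth.
"""

import clearclip as cc

cfg = cc.SimulationConfig(n_reads=10_000, rng_seed=42)
ref = cc.generate_reference(cfg)
truth = cc.plant_interactions(ref, cfg)
records, labels = cc.simulate_library(ref, truth, cfg, "24hPBM")

reads = [cc.ReadRecord(rid, seq, [37] * len(seq)) for rid, seq, _ in records]
kept, stats = cc.prepare_reads(reads)
print(f"prep: kept {stats.n_kept_unique} unique reads of {stats.n_input}")

clf = cc.Classifier(ref.mirnas, ref.transcripts, ref.annotation)
chim, clip_df, counts, weighted = clf.classify_reads(kept)
total = sum(weighted.values())
for cls in ("chimera", "clip", "mirna_only", "ncRNA"):
    print(f"  {cls:<11} {100 * weighted[cls] / total:5.2f}% of reads")

lab = labels.set_index("read_id")
correct = sum(
    lab.loc[r.read_id].mirna_id == r.mirna_id
    and lab.loc[r.read_id].transcript_id == r.transcript_id
    for r in chim.itertuples()
)
print(f"chimeras called: {len(chim)}, correct (miRNA, transcript): {correct}")
# The class percentages mirror a deep CLEAR-CLIP library (~1.7% chimeras,
# ~77% CLIP single reads); the last line shows planted-truth recovery.
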