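"""Perturbation-validation statistics: KS fold-change shift and TE.

Simulates a miRNA knockdown in which 200 targets are derepressed by +0.5
log2 fold change, compares their CDF against 2000 non-targets, and recovers
a planted 2x translational-efficiency shift from count tables.
"""

from clearclip.validation import (
    cdf_compare,
    simulate_foldchange_table,
    simulate_te_tables,
    translational_efficiency,
)

tbl = simulate_foldchange_table(200, 2000, shift=0.5, rng_seed=1)
res = cdf_compare(tbl, "target", "nontarget")
print(f"KS D = {res.statistic:.3f}, p = {res.pvalue:.2e}  "
      "(targets shifted right: derepression after knockdown)")

ribo, mrna, targets = simulate_te_tables(n_transcripts=300, te_shift_targets=2.0,
                                         rng_seed=4)
te = translational_efficiency(ribo, mrna)
ratio = (te.loc[te.index.intersection(targets), "te"].median()
         / te.loc[te.index.difference(targets), "te"].median())
print(f"median TE ratio targets/non-targets = {ratio:.2f} (planted 2.0)")
# A significant KS shift plus the recovered TE ratio are the two readouts
# used to validate chimera-defined targets after miRNA perturbation.
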