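"""Perturbation-validation statistics.

Two computations support target validation after miRNA perturbation
(e.g. an antagomir knockdown): a two-sample Kolmogorov-Smirnov comparison of
log2 fold-change distributions between chimera-defined targets and
non-targets, and translational efficiency (TE) - ribosome occupancy divided
by mRNA abundance after median-of-ratios library-size normalization.
Differential modeling (DESeq2/RiboDiff style) is upstream tooling; this
module consumes count and fold-change tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp


@dataclass
class CdfComparison:
    statistic: float  # KS D
    pvalue: float
    curve_a: pd.DataFrame  # columns: value, cdf
    curve_b: pd.DataFrame


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    v = np.sort(values)
    return pd.DataFrame(dict(value=v, cdf=np.arange(1, v.size + 1) / v.size))


def cdf_compare(
    table: pd.DataFrame, set_a: str, set_b: str, value_col: str = "log2fc",
    label_col: str = "set_label",
) -> CdfComparison:
    """Two-sample KS test on fold changes of two disjoint transcript sets.

    `table` must have a transcript_id column, the value column and a label
    column; a transcript appearing in both sets is an error.
    """
    a = table[table[label_col] == set_a]
    b = table[table[label_col] == set_b]
    if not len(a) or not len(b):
        raise ValueError("both sets must be nonempty")
    if set(a.transcript_id) & set(b.transcript_id):
        raise ValueError("sets overlap")
    va = a[value_col].to_numpy(float)
    vb = b[value_col].to_numpy(float)
    res = ks_2samp(va, vb, method="auto")
    return CdfComparison(float(res.statistic), float(res.pvalue), _ecdf(va), _ecdf(vb))


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (columns = libraries)."""
    logs = np.log(counts.replace(0, np.nan))
    ref = logs.mean(axis=1)
    ok = np.isfinite(ref)
    sf = np.exp((logs[ok].sub(ref[ok], axis=0)).median(axis=0))
    return sf


def translational_efficiency(
    ribo_counts: pd.DataFrame,
    mrna_counts: pd.DataFrame,
    count_floor: int = 10,
) -> pd.DataFrame:
    """TE per transcript: normalized ribosome counts / normalized mRNA counts.

    Inputs are transcript x library raw-count tables (indexes = transcript
    ids). Both assays are normalized by median-of-ratios independently, then
    averaged over libraries. Transcripts with mean raw counts below
    `count_floor` in either assay, or zero mRNA signal after normalization,
    are dropped; dropped ids are reported in the 'dropped' attribute column.
    """
    common = ribo_counts.index.intersection(mrna_counts.index)
    ribo = ribo_counts.loc[common]
    mrna = mrna_counts.loc[common]
    # one joint size-factor fit across both assays, so a global rescaling of
    # either assay's libraries cancels out of the TE ratio
    joint = pd.concat(
        [ribo.add_suffix("_ribo"), mrna.add_suffix("_mrna")], axis=1
    )
    sf = size_factors(joint)
    ribo_n = ribo / sf[[f"{c}_ribo" for c in ribo.columns]].to_numpy()
    mrna_n = mrna / sf[[f"{c}_mrna" for c in mrna.columns]].to_numpy()
    ribo_mean = ribo_n.mean(axis=1)
    mrna_mean = mrna_n.mean(axis=1)
    keep = (ribo.mean(axis=1) >= count_floor) & (mrna.mean(axis=1) >= count_floor)
    keep &= mrna_mean > 0
    out = pd.DataFrame(
        dict(
            ribo=ribo_mean[keep],
            mrna=mrna_mean[keep],
            te=ribo_mean[keep] / mrna_mean[keep],
        )
    )
    out.index.name = "transcript_id"
    out.attrs["dropped"] = sorted(common[~keep])
    return out


# ---------------------------------------------------------------------------
# synthetic inputs for power checks


def simulate_foldchange_table(
    n_targets: int, n_nontargets: int, shift: float, sd: float = 1.0,
    rng_seed: int = 0,
) -> pd.DataFrame:
    """Fold-change table with a planted derepression shift in targets."""
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    rows = []
    for i in range(n_targets):
        rows.append((f"t{i:05d}", rng.normal(shift, sd), "target"))
    for i in range(n_nontargets):
        rows.append((f"n{i:05d}", rng.normal(0.0, sd), "nontarget"))
    return pd.DataFrame(rows, columns=["transcript_id", "log2fc", "set_label"])


def simulate_te_tables(
    n_transcripts: int = 300,
    n_libs: int = 2,
    te_shift_targets: float = 2.0,
    target_frac: float = 0.5,
    mean_count: float = 200.0,
    rng_seed: int = 0,
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.Index]:
    """Ribo/mRNA count tables with a planted TE multiplier in a target set.

    Returns (ribo_counts, mrna_counts, target transcript ids).
    """
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    ids = pd.Index([f"tx{i:05d}" for i in range(n_transcripts)], name="transcript_id")
    base = rng.lognormal(np.log(mean_count), 0.6, size=n_transcripts)
    is_target = np.zeros(n_transcripts, dtype=bool)
    is_target[: int(target_frac * n_transcripts)] = True
    te = np.where(is_target, te_shift_targets, 1.0)
    mrna = np.column_stack([
        rng.poisson(base * rng.uniform(0.9, 1.1)) for _ in range(n_libs)
    ])
    ribo = np.column_stack([
        rng.poisson(base * te * rng.uniform(0.9, 1.1)) for _ in range(n_libs)
    ])
    cols = [f"lib{j}" for j in range(n_libs)]
    return (
        pd.DataFrame(ribo, index=ids, columns=cols),
        pd.DataFrame(mrna, index=ids, columns=cols),
        ids[is_target],
    )
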