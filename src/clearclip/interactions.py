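"""Collapse chimera records into miRNA-target interactions with peak support.

Chimeras sharing a miRNA and transitively overlapping target sites on the
same transcript merge into one interaction; ``unique_reads`` counts collapsed
chimera records (PCR-duplicate multiplicity is deliberately not re-counted).
"""

from __future__ import annotations

from typing import Dict, Iterable, Optional

import pandas as pd

INTERACTION_COLS = [
    "interaction_id", "mirna_id", "transcript_id", "site_start", "site_end",
    "unique_reads", "region", "timepoint", "peak_supported", "member_read_ids",
]


def build_interactions(chimeras: pd.DataFrame, timepoint: str = "") -> pd.DataFrame:
    """Merge same-miRNA chimeras with overlapping target intervals.

    Expects the chimera table from the classifier, already restricted to
    uniquely mapped records. The merge is order-independent: members are
    sorted by interval before clustering.
    """
    rows = []
    if len(chimeras) and "multimapped" in chimeras:
        chimeras = chimeras[~chimeras.multimapped.astype(bool)]
    if len(chimeras):
        for (mid, tid), grp in sorted(
            chimeras.groupby(["mirna_id", "transcript_id"], sort=True),
            key=lambda kv: kv[0],
        ):
            members = sorted(
                zip(grp.target_start, grp.target_end, grp.read_id, grp.region)
            )
            cur = [members[0]]
            cur_end = members[0][1]
            flush = []
            for m in members[1:]:
                if m[0] < cur_end:
                    cur.append(m)
                    cur_end = max(cur_end, m[1])
                else:
                    flush.append(cur)
                    cur = [m]
                    cur_end = m[1]
            flush.append(cur)
            for mem in flush:
                regions = [m[3] for m in mem]
                rows.append(
                    dict(
                        interaction_id="",
                        mirna_id=mid,
                        transcript_id=tid,
                        site_start=min(m[0] for m in mem),
                        site_end=max(m[1] for m in mem),
                        unique_reads=len(mem),
                        region=max(sorted(set(regions)), key=regions.count),
                        timepoint=timepoint,
                        peak_supported=False,
                        member_read_ids=",".join(sorted(m[2] for m in mem)),
                    )
                )
    df = pd.DataFrame(rows, columns=INTERACTION_COLS)
    df["interaction_id"] = [
        f"{r.mirna_id}|{r.transcript_id}|{r.site_start}" for r in df.itertuples()
    ]
    return df


def attach_peak_support(interactions: pd.DataFrame, peaks: pd.DataFrame) -> pd.DataFrame:
    """Set peak_supported where the site overlaps a significant peak >= 1 nt."""
    out = interactions.copy()
    if not len(out):
        return out
    sig = peaks[peaks.significant] if len(peaks) else peaks
    by_tx: Dict[str, list] = {}
    if len(sig):
        for p in sig.itertuples():
            by_tx.setdefault(p.transcript_id, []).append((int(p.start), int(p.end)))
    supported = []
    for r in out.itertuples():
        hits = by_tx.get(r.transcript_id, ())
        supported.append(any(r.site_start < e and s < r.site_end for s, e in hits))
    out["peak_supported"] = supported
    return out


def composition_summary(
    class_counts: Dict[str, int],
    chimeras: Optional[pd.DataFrame] = None,
    clip_reads: Optional[pd.DataFrame] = None,
    annotate_region=None,
    dup_weight: bool = True,
) -> Dict[str, Dict[str, float]]:
    """Class fractions plus 5UTR/CDS/3UTR fractions for chimera targets and
    CLIP reads.

    Class fractions fold ambiguous/multimapped/unmapped into 'other' and are
    computed over all classified reads. Region fractions need `annotate_region`
    (a callable ``(transcript_id, (start, end)) -> region``) for CLIP reads;
    chimera regions come from the table itself.
    """
    total = sum(class_counts.values())
    keys = ["chimera", "clip", "mirna_only", "ncRNA"]
    class_frac = {k: class_counts.get(k, 0) / total if total else 0.0 for k in keys}
    class_frac["other"] = 1.0 - sum(class_frac.values()) if total else 0.0
    out = {"class_fractions": class_frac}
    if chimeras is not None and len(chimeras):
        w = chimeras.dup_count if dup_weight else pd.Series(1, index=chimeras.index)
        tot = 0.0
        reg = {"5UTR": 0.0, "CDS": 0.0, "3UTR": 0.0}
        for region, wt in zip(chimeras.region, w):
            if region in reg:
                reg[region] += wt
                tot += wt
        out["chimera_region_fractions"] = {k: v / tot if tot else 0.0 for k, v in reg.items()}
    if clip_reads is not None and len(clip_reads) and annotate_region is not None:
        reg = {"5UTR": 0.0, "CDS": 0.0, "3UTR": 0.0}
        tot = 0.0
        w = clip_reads.dup_count if dup_weight else pd.Series(1, index=clip_reads.index)
        for r, wt in zip(clip_reads.itertuples(), w):
            region = annotate_region(r.transcript_id, (int(r.start), int(r.end)))
            if region in reg:
                reg[region] += wt
                tot += wt
        out["clip_region_fractions"] = {k: v / tot if tot else 0.0 for k, v in reg.items()}
    return out


def join_across_timepoints(per_timepoint: Iterable[pd.DataFrame]) -> pd.DataFrame:
    """Join per-time-point interactions on (miRNA, transcript, overlapping site).

    The joined table carries one row per cross-stage interaction with a
    stable id and per-time-point unique-read counts and peak heights left to
    the dynamics module; here we assign each per-time-point interaction a
    cross-stage group id.
    """
    frames = [df for df in per_timepoint if len(df)]
    if not frames:
        return pd.DataFrame(columns=INTERACTION_COLS + ["group_id"])
    allint = pd.concat(frames, ignore_index=True)
    allint = allint.sort_values(
        ["mirna_id", "transcript_id", "site_start"], kind="mergesort"
    ).reset_index(drop=True)
    gids = []
    cur_gid = -1
    cur_key = None
    cur_end = -1
    for r in allint.itertuples():
        key = (r.mirna_id, r.transcript_id)
        if key != cur_key or r.site_start >= cur_end:
            cur_gid += 1
            cur_key = key
            cur_end = r.site_end
        else:
            cur_end = max(cur_end, r.site_end)
        gids.append(cur_gid)
    allint["group_id"] = [f"grp{g:05d}" for g in gids]
    return allint
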