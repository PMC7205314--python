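"""Ago CLIP peak calling in transcript space.

Overlapping mapped reads (CLIP single reads pooled with chimeric target
segments) are grouped into clusters; a cubic smoothing spline over the
per-position coverage locates the summit and its height; cluster
significance is a Poisson upper tail under uniform read placement within the
transcript, retained at p < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import UnivariateSpline
from scipy.stats import poisson

ALPHA_DEFAULT = 0.01


@dataclass
class Cluster:
    transcript_id: str
    interval: Tuple[int, int]
    read_count: int
    coverage: np.ndarray


def cluster_reads(intervals: Sequence[Tuple[int, int]], transcript_id: str = ""
                  ) -> List[Cluster]:
    """Group transitively overlapping intervals (>= 1 nt shared) into clusters.

    Half-open intervals that merely abut ([10,50) and [50,80)) do not overlap.
    Cluster interval is the union span; coverage is per-position read depth.
    """
    if not len(intervals):
        return []
    ivs = sorted(intervals)
    clusters: List[List[Tuple[int, int]]] = [[ivs[0]]]
    cur_end = ivs[0][1]
    for s, e in ivs[1:]:
        if s < cur_end:
            clusters[-1].append((s, e))
            cur_end = max(cur_end, e)
        else:
            clusters.append([(s, e)])
            cur_end = e
    out = []
    for members in clusters:
        lo = members[0][0]
        hi = max(e for _, e in members)
        cov = np.zeros(hi - lo, dtype=float)
        for s, e in members:
            cov[s - lo : e - lo] += 1.0
        out.append(Cluster(transcript_id, (lo, hi), len(members), cov))
    return out


def spline_summit(cluster: Cluster) -> Tuple[float, float]:
    """Summit position and height from a cubic spline over the coverage.

    The spline interpolates for short clusters (< 10 positions) and smooths
    (s = n) otherwise; the summit is the maximum on a 0.1-nt grid, with ties
    resolved to the midpoint of the tied stretch (so constant coverage yields
    the interval midpoint). Height is floored at the observed maximum depth.
    """
    cov = cluster.coverage
    lo = cluster.interval[0]
    n = cov.size
    if n < 4:
        peak = np.flatnonzero(cov == cov.max())
        return lo + float(peak.mean()), float(cov.max())
    x = np.arange(n, dtype=float)
    s = 0.0 if n < 10 else float(n)
    try:
        spl = UnivariateSpline(x, cov, k=3, s=s)
    except Exception:
        spl = UnivariateSpline(x, cov, k=3, s=0.0)
    grid = np.arange(0.0, n - 1 + 1e-9, 0.1)
    vals = spl(grid)
    vmax = vals.max()
    tied = np.flatnonzero(vals >= vmax - 1e-9)
    summit = lo + float(grid[tied[len(tied) // 2]])
    height = max(float(vmax), float(cov.max()))
    return summit, height


def poisson_pvalue(read_count: int, width: int, transcript_read_total: int,
                   transcript_length: int) -> float:
    """P[Poisson(lambda) >= read_count] with
    lambda = transcript_read_total * width / transcript_length."""
    if transcript_length <= 0:
        raise ValueError("transcript_length must be positive")
    lam = transcript_read_total * width / transcript_length
    return float(poisson.sf(read_count - 1, lam))


def call_peaks(
    clip_reads: pd.DataFrame,
    chimera_targets: pd.DataFrame,
    transcript_lengths: Dict[str, int],
    alpha: float = ALPHA_DEFAULT,
    timepoint: str = "",
) -> pd.DataFrame:
    """Pool CLIP reads and chimeric target intervals, cluster and test.

    `clip_reads` needs columns transcript_id/start/end; `chimera_targets`
    transcript_id/target_start/target_end (either may be empty). Returns all
    peaks with a significance flag (one summit per cluster).
    """
    pooled: Dict[str, List[Tuple[int, int]]] = {}
    if len(clip_reads):
        for r in clip_reads.itertuples():
            pooled.setdefault(r.transcript_id, []).append((int(r.start), int(r.end)))
    if len(chimera_targets):
        for r in chimera_targets.itertuples():
            pooled.setdefault(r.transcript_id, []).append(
                (int(r.target_start), int(r.target_end))
            )
    rows = []
    for tid in sorted(pooled):
        ivs = pooled[tid]
        total = len(ivs)
        tlen = transcript_lengths[tid]
        for cl in cluster_reads(ivs, tid):
            summit, height = spline_summit(cl)
            width = cl.interval[1] - cl.interval[0]
            p = poisson_pvalue(cl.read_count, width, total, tlen)
            rows.append(
                dict(
                    transcript_id=tid, summit=summit, start=cl.interval[0],
                    end=cl.interval[1], read_count=cl.read_count, height=height,
                    pvalue=p, significant=p < alpha, timepoint=timepoint,
                )
            )
    cols = ["transcript_id", "summit", "start", "end", "read_count", "height",
            "pvalue", "significant", "timepoint"]
    return pd.DataFrame(rows, columns=cols)


def peaks_to_bed(peaks: pd.DataFrame) -> pd.DataFrame:
    """BED6 (transcript-space) export; score = peak height."""
    if not len(peaks):
        return pd.DataFrame(columns=["chrom", "start", "end", "name", "score", "strand"])
    return pd.DataFrame(
        dict(
            chrom=peaks.transcript_id,
            start=peaks.start.astype(int),
            end=peaks.end.astype(int),
            name=[f"peak_{i}" for i in range(len(peaks))],
            score=peaks.height,
            strand="+",
        )
    )
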