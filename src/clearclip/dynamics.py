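"""Temporal dynamics of miRNA-target interactions.

The interaction x time-point matrix holds peak heights normalized to mRNA
abundance (ratio with a small floor; log-ratio optional). Rows are
z-normalized, gridded with a batch self-organizing map into tiles of similar
temporal profile, and summarized by stage-stage Pearson correlations and
hierarchical clustering of annotated subsets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import cdist

ABUNDANCE_FLOOR = 0.1


def normalize_matrix(
    heights: pd.DataFrame,
    expression: pd.DataFrame,
    timepoints: Sequence[str],
    floor: float = ABUNDANCE_FLOOR,
    log_ratio: bool = False,
) -> Tuple[pd.DataFrame, List[str]]:
    """Build the interaction x time-point matrix of mRNA-normalized heights.

    `heights`: long table (interaction_id, transcript_id, timepoint, height).
    `expression`: long table (transcript_id, timepoint, abundance).
    cell = height / max(abundance, floor); missing heights are 0.
    Interactions on transcripts absent from the expression table are dropped
    and returned in the second element.
    """
    expr = expression.pivot_table(
        index="transcript_id", columns="timepoint", values="abundance"
    )
    dropped: List[str] = []
    rows: Dict[str, np.ndarray] = {}
    tx_of: Dict[str, str] = {}
    for r in heights.itertuples():
        tx_of[r.interaction_id] = r.transcript_id
    for iid in sorted(tx_of):
        tid = tx_of[iid]
        if tid not in expr.index or expr.loc[tid].isna().all():
            dropped.append(iid)
            continue
        rows[iid] = np.zeros(len(timepoints))
    for r in heights.itertuples():
        if r.interaction_id not in rows:
            continue
        j = list(timepoints).index(r.timepoint)
        ab = expr.loc[r.transcript_id].get(r.timepoint, np.nan)
        ab = floor if pd.isna(ab) else max(float(ab), floor)
        val = float(r.height) / ab
        rows[r.interaction_id][j] = np.log2(val + 1.0) if log_ratio else val
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=list(timepoints))
    mat.index.name = "interaction_id"
    return mat, dropped


def zscore_rows(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-normalization; constant rows become all-zero."""
    vals = matrix.to_numpy(float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    out = np.where(sd > 1e-12, (vals - mu) / np.where(sd > 1e-12, sd, 1.0), 0.0)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


# ---------------------------------------------------------------------------
# batch self-organizing map


@dataclass
class SOMResult:
    grid_shape: Tuple[int, int]
    tile_of: pd.Series  # interaction id -> flat tile index (row-major)
    tile_mean: np.ndarray  # (n_tiles, n_timepoints)
    rng_seed: int

    def tile_coords(self, flat: int) -> Tuple[int, int]:
        return divmod(flat, self.grid_shape[1])


def som_fit(
    matrix: pd.DataFrame,
    grid: Tuple[int, int] = (26, 25),
    epochs: int = 50,
    rng_seed: int = 0,
) -> SOMResult:
    """Batch Kohonen SOM over row profiles.

    Gaussian neighborhood whose radius decays linearly from max(grid)/2 to 1
    over the epochs; codebook initialized from randomly drawn data rows;
    tile assignment is the best-matching unit. Deterministic under the seed.
    """
    if not len(matrix):
        raise ValueError("empty matrix")
    gr, gc = grid
    n_tiles = gr * gc
    if n_tiles < 4:
        raise ValueError("grid must have >= 4 cells")
    X = matrix.to_numpy(float)
    n = X.shape[0]
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    W = X[rng.integers(0, n, size=n_tiles)] + rng.normal(0, 1e-6, (n_tiles, X.shape[1]))
    coords = np.array([(i, j) for i in range(gr) for j in range(gc)], float)
    grid_d2 = cdist(coords, coords, "sqeuclidean")
    r0 = max(gr, gc) / 2.0
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = r0 + (1.0 - r0) * frac  # linear decay r0 -> 1
        bmu = cdist(X, W).argmin(axis=1)
        Hn = np.exp(-grid_d2[:, bmu] / (2.0 * radius ** 2))  # tiles x samples
        denom = Hn.sum(axis=1, keepdims=True)
        ok = denom[:, 0] > 1e-12
        W[ok] = (Hn @ X)[ok] / denom[ok]
    bmu = cdist(X, W).argmin(axis=1)
    tile_mean = np.full((n_tiles, X.shape[1]), np.nan)
    for t in range(n_tiles):
        members = X[bmu == t]
        tile_mean[t] = members.mean(axis=0) if len(members) else W[t]
    return SOMResult(
        grid_shape=grid,
        tile_of=pd.Series(bmu, index=matrix.index, name="tile"),
        tile_mean=tile_mean,
        rng_seed=rng_seed,
    )


def topographic_ok(som: SOMResult, rng_seed: int = 0) -> Tuple[float, float]:
    """(mean adjacent-tile distance, mean random-pair distance) of tile means.

    The SOM preserves topology when the first is below the second.
    """
    gr, gc = som.grid_shape
    tm = som.tile_mean
    adj = []
    for i in range(gr):
        for j in range(gc):
            f = i * gc + j
            if j + 1 < gc:
                adj.append(np.linalg.norm(tm[f] - tm[f + 1]))
            if i + 1 < gr:
                adj.append(np.linalg.norm(tm[f] - tm[f + gc]))
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    n = gr * gc
    pairs = rng.integers(0, n, size=(max(1000, 4 * n), 2))
    pairs = pairs[pairs[:, 0] != pairs[:, 1]]
    rand = np.linalg.norm(tm[pairs[:, 0]] - tm[pairs[:, 1]], axis=1)
    return float(np.mean(adj)), float(np.mean(rand))


# ---------------------------------------------------------------------------
# stage correlation & hierarchical clustering


def stage_correlation(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation between time-point columns (NaN for zero variance)."""
    if len(matrix) < 2:
        raise ValueError("need >= 2 rows")
    return matrix.corr(method="pearson")


def hcluster(
    matrix: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> Tuple[List[str], np.ndarray, str]:
    """Agglomerative clustering of z-normalized rows.

    Rows are sorted by id before linkage, so the result is invariant to
    input permutation. Returns (leaf ids in dendrogram order, linkage matrix,
    newick string with merge heights as branch lengths).
    """
    sub = matrix.sort_index()
    Z = None
    if len(sub) == 1:
        return [str(sub.index[0])], np.empty((0, 4)), f"({sub.index[0]});"
    zrows = zscore_rows(sub)
    Z = hierarchy.linkage(zrows.to_numpy(float), method=method, metric=metric)
    order = hierarchy.leaves_list(Z)
    ids = [str(sub.index[i]) for i in order]
    newick = _to_newick(Z, [str(i) for i in sub.index])
    return ids, Z, newick


def _to_newick(Z: np.ndarray, labels: List[str]) -> str:
    """Newick string from a scipy linkage matrix; branch length = parent
    merge height minus own merge height (leaves sit at height 0)."""
    n = len(labels)

    def rec(node: int, parent_h: float) -> str:
        if node < n:
            return f"{labels[node]}:{parent_h:.6g}"
        row = Z[node - n]
        h = float(row[2])
        inner = f"({rec(int(row[0]), h)},{rec(int(row[1]), h)})"
        return f"{inner}:{max(parent_h - h, 0.0):.6g}"

    h_root = float(Z[-1][2])
    return f"({rec(int(Z[-1][0]), h_root)},{rec(int(Z[-1][1]), h_root)});"
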