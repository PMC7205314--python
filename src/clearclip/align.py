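"""Seed-and-extend local alignment with Karlin-Altschul E-values.

A bespoke Smith-Waterman (blastn-like scoring: match +2, mismatch -3, gap
open -5, gap extend -2) locates mature miRNAs inside reads and maps residual
target segments onto the transcriptome. Candidate subjects are found by exact
k-mer seeding (word size 11 for the short miRNA queries, 12 for transcript
mapping); the dynamic program then runs only against seeded candidates.

E-values use the ungapped Karlin-Altschul statistics computed for the score
matrix at import time: lambda solves sum_ij p_i p_j exp(lambda s_ij) = 1 and
K comes from the lattice-case series (validated against the published
ungapped blastn values, e.g. K = 0.621 for +1/-2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
from numba import njit
from scipy.optimize import brentq
from scipy.stats import binom

from ._seq import encode

MATCH = 2
MISMATCH = -3
GAP_OPEN = -5  # first gapped base costs GAP_OPEN + GAP_EXTEND
GAP_EXTEND = -2

DEFAULT_EVALUE_MAX = 0.4
WORD_MIRNA = 11
WORD_TRANSCRIPT = 12


def karlin_altschul(match: int = MATCH, mismatch: int = MISMATCH, p_match: float = 0.25
                    ) -> Tuple[float, float, float]:
    """(lambda, K, H) for an i.i.d. match/mismatch score under uniform bases.

    Lattice-case K via the Karlin-Altschul series
    K = d*lambda*exp(-2*sigma) / (H*(1 - exp(-lambda*d))), with
    sigma = sum_j (1/j)[P(S_j >= 0) + E(exp(lambda*S_j); S_j < 0)].
    """
    pm, pq = p_match, 1.0 - p_match
    lam = brentq(
        lambda la: pm * math.exp(la * match) + pq * math.exp(la * mismatch) - 1.0,
        1e-6, 10.0,
    )
    H = lam * (pm * match * math.exp(lam * match) + pq * mismatch * math.exp(lam * mismatch))
    d = math.gcd(match, -mismatch)
    sigma = 0.0
    for j in range(1, 400):
        k = np.arange(j + 1)
        S = k * match + (j - k) * mismatch
        pr = binom.pmf(k, j, pm)
        term = pr[S >= 0].sum() + (pr[S < 0] * np.exp(lam * S[S < 0])).sum()
        sigma += term / j
        if term / j < 1e-14:
            break
    K = d * lam * math.exp(-2.0 * sigma) / (H * (1.0 - math.exp(-lam * d)))
    return lam, K, H


LAMBDA, KA_K, KA_H = karlin_altschul()


def evalue(score: float, query_len: int, db_len: int,
           lam: float = LAMBDA, K: float = KA_K) -> float:
    return K * query_len * db_len * math.exp(-lam * score)


@dataclass
class AlignmentHit:
    query_id: str
    subject_id: str
    query_interval: Tuple[int, int]  # 0-based half-open on the query
    subject_interval: Tuple[int, int]
    matches: int
    mismatches: int
    gaps: int
    score: float
    evalue: float

    @property
    def identity(self) -> float:
        denom = self.matches + self.mismatches + self.gaps
        return self.matches / denom if denom else 0.0

    @property
    def aln_len(self) -> int:
        return self.matches + self.mismatches + self.gaps


@njit(cache=True)
def _sw_fill(q, s, match, mismatch, gap_open_ext, gap_ext):  # pragma: no cover
    n, m = q.shape[0], s.shape[0]
    H = np.zeros((n + 1, m + 1), dtype=np.float64)
    E = np.full((n + 1, m + 1), -1e18)
    F = np.full((n + 1, m + 1), -1e18)
    ptr = np.zeros((n + 1, m + 1), dtype=np.uint8)  # 0 stop, 1 diag, 2 up(E), 3 left(F)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = match if (q[i - 1] == s[j - 1] and q[i - 1] < 4) else mismatch
            e = max(H[i - 1, j] + gap_open_ext, E[i - 1, j] + gap_ext)
            f = max(H[i, j - 1] + gap_open_ext, F[i, j - 1] + gap_ext)
            E[i, j] = e
            F[i, j] = f
            h = H[i - 1, j - 1] + sub
            val = h
            p = 1
            if e > val:
                val = e
                p = 2
            if f > val:
                val = f
                p = 3
            if val <= 0.0:
                val = 0.0
                p = 0
            H[i, j] = val
            ptr[i, j] = p
            if val > best:
                best = val
                bi = i
                bj = j
    return H, ptr, best, bi, bj


def smith_waterman(query: str, subject: str) -> Optional[AlignmentHit]:
    """Best local alignment; None if no positive-scoring alignment exists."""
    q = encode(query)
    s = encode(subject)
    if q.size == 0 or s.size == 0:
        return None
    H, ptr, best, bi, bj = _sw_fill(
        q, s, float(MATCH), float(MISMATCH), float(GAP_OPEN + GAP_EXTEND), float(GAP_EXTEND)
    )
    if best <= 0.0:
        return None
    i, j = bi, bj
    matches = mismatches = gaps = 0
    while ptr[i, j] != 0:
        p = ptr[i, j]
        if p == 1:
            if q[i - 1] == s[j - 1] and q[i - 1] < 4:
                matches += 1
            else:
                mismatches += 1
            i -= 1
            j -= 1
        elif p == 2:
            gaps += 1
            i -= 1
        else:
            gaps += 1
            j -= 1
    return AlignmentHit(
        query_id="", subject_id="", query_interval=(i, bi), subject_interval=(j, bj),
        matches=matches, mismatches=mismatches, gaps=gaps, score=best,
        evalue=float("nan"),
    )


class KmerIndex:
    """Exact k-mer index over a set of named sequences."""

    def __init__(self, seqs: Dict[str, str], word: int):
        if not seqs:
            raise ValueError("empty sequence set")
        self.word = word
        self.seqs = dict(seqs)
        self.total_len = sum(len(s) for s in seqs.values())
        self.index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in seqs.items():
            for p in range(len(seq) - word + 1):
                self.index.setdefault(seq[p : p + word], []).append((name, p))

    def candidates(self, query: str) -> Dict[str, List[int]]:
        """Subject -> sorted unique seed diagonals (query_pos - subject_pos)."""
        w = self.word
        out: Dict[str, set] = {}
        for p in range(len(query) - w + 1):
            for name, sp in self.index.get(query[p : p + w], ()):
                out.setdefault(name, set()).add(p - sp)
        return {k: sorted(v) for k, v in out.items()}


def _window(subject: str, diag: int, qlen: int, pad: int = 30) -> Tuple[int, str]:
    lo = max(0, -diag - pad)
    hi = min(len(subject), -diag + qlen + pad)
    return lo, subject[lo:hi]


def best_hit(
    query: str,
    query_id: str,
    index: KmerIndex,
    evalue_max: float = DEFAULT_EVALUE_MAX,
    windowed: bool = False,
) -> Tuple[Optional[AlignmentHit], bool]:
    """Best seeded local alignment of `query` against the indexed set.

    Returns (hit, multimapped); multimapped is True when a second subject ties
    the best score. Ties for best are broken by higher identity, longer
    alignment, then lexicographic subject id. With ``windowed=True`` the DP
    runs on a window around each seed diagonal instead of the full subject
    (used for transcript-scale subjects).
    """
    cands = index.candidates(query)
    if not cands:
        return None, False
    hits: List[AlignmentHit] = []
    for name in sorted(cands):
        subject = index.seqs[name]
        if windowed:
            diags = cands[name]
            groups = [[diags[0]]]
            for d in diags[1:]:
                if d - groups[-1][-1] <= 20:
                    groups[-1].append(d)
                else:
                    groups.append([d])
            best_local = None
            for grp in groups:
                off, win = _window(subject, grp[len(grp) // 2], len(query))
                h = smith_waterman(query, win)
                if h is None:
                    continue
                h.subject_interval = (h.subject_interval[0] + off, h.subject_interval[1] + off)
                if best_local is None or h.score > best_local.score:
                    best_local = h
            h = best_local
        else:
            h = smith_waterman(query, subject)
        if h is None:
            continue
        h.query_id = query_id
        h.subject_id = name
        h.evalue = evalue(h.score, len(query), index.total_len)
        if h.evalue < evalue_max:
            hits.append(h)
    if not hits:
        return None, False
    hits.sort(key=lambda h: (-h.score, -h.identity, -h.aln_len, h.subject_id))
    top = hits[0]
    multi = len(hits) > 1 and hits[1].score == top.score and hits[1].subject_id != top.subject_id
    return top, multi
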