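"""Intermolecular miRNA:target duplex free energy by dynamic programming.

A nearest-neighbor model scores every non-crossing set of intermolecular base
pairs (Watson-Crick and G:U wobble): stacking free energies for adjacent
pairs, length-dependent bulge/internal-loop penalties between non-adjacent
pairs (total unpaired span bounded by ``max_loop``), a duplex initiation
penalty and terminal AU/GU penalties. The DP minimizes total free energy over
all such pairings; a duplex that cannot reach negative energy is reported as
unstable (no pairing, mfe = 0).

Intramolecular structure of either strand is not modeled, matching the
hybrid-only view of miRNA targeting used throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from numba import njit

from ._seq import encode, to_rna

RT37 = 0.616  # kcal/mol at 37 C, for Jacobson-Stockmayer extrapolation

# base codes: A=0 C=1 G=2 U=3 (shared with _seq.encode, U->3)
_PAIRS = [(0, 3), (3, 0), (2, 1), (1, 2), (2, 3), (3, 2)]  # AU UA GC CG GU UG
_AU_GU_ENDS = {(0, 3), (3, 0), (2, 3), (3, 2)}

BULGE_INIT = {1: 3.8, 2: 2.8, 3: 3.2, 4: 3.6, 5: 4.0, 6: 4.4}
INTERNAL_INIT = {2: 1.5, 3: 1.6, 4: 1.7, 5: 1.8, 6: 2.0}


def _loop_extrapolate(base6: float, n: int) -> float:
    return base6 + 1.75 * RT37 * math.log(n / 6.0)


@dataclass
class EnergyModel:
    """Parameter set for the duplex DP; defaults load the shipped table."""

    stack_dG: Dict[Tuple[str, str], float]
    init_dG: float = 4.09
    au_end_dG: float = 0.45
    max_loop: int = 15
    _stack4: np.ndarray = field(init=False, repr=False)
    _loop: np.ndarray = field(init=False, repr=False)
    _pairable: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        if self.max_loop < 1:
            raise ValueError("max_loop must be >= 1")
        s4 = np.full((4, 4, 4, 4), 100.0)
        code = {"A": 0, "C": 1, "G": 2, "U": 3}
        for (top, bottom), dg in self.stack_dG.items():
            s4[code[top[0]], code[top[1]], code[bottom[0]], code[bottom[1]]] = dg
        self._stack4 = s4
        pairable = np.zeros((4, 4), dtype=np.bool_)
        for a, b in _PAIRS:
            pairable[a, b] = True
        self._pairable = pairable
        ml = self.max_loop
        loop = np.full((ml + 1, ml + 1), 1e9)
        for g1 in range(ml + 1):
            for g2 in range(ml + 1):
                n = g1 + g2
                if n == 0 or n > ml:
                    continue
                if g1 == 0 or g2 == 0:
                    loop[g1, g2] = (
                        BULGE_INIT[n] if n <= 6 else _loop_extrapolate(BULGE_INIT[6], n)
                    )
                else:
                    loop[g1, g2] = (
                        INTERNAL_INIT[n] if n <= 6 else _loop_extrapolate(INTERNAL_INIT[6], n)
                    )
        self._loop = loop

    @classmethod
    def default(cls, **kwargs) -> "EnergyModel":
        return cls(stack_dG=load_stack_table(), **kwargs)


def load_stack_table() -> Dict[Tuple[str, str], float]:
    with resources.files("clearclip").joinpath("data/rna_stack.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    return {(r.top, r.bottom): float(r.dG) for r in df.itertuples()}


@dataclass
class DuplexResult:
    mfe: float
    pairing: List[Tuple[int, int]]  # (miRNA position, target position), 0-based

    @property
    def stable(self) -> bool:
        return bool(self.pairing)

    def duplex_string(self, mirna_len: int, target_len: int) -> str:
        """Dot-parenthesis-like duplex notation '(((.(&).)))'."""
        mi = {i for i, _ in self.pairing}
        ti = {j for _, j in self.pairing}
        top = "".join("(" if i in mi else "." for i in range(mirna_len))
        bot = "".join(")" if j in ti else "." for j in range(target_len))
        return f"{top}&{bot}"


@njit(cache=True)
def _duplex_fill(x, yr, stack4, loop, pairable, init_dG, au_end, max_loop
                 ):  # pragma: no cover - exercised via duplex_mfe
    n, m = x.shape[0], yr.shape[0]
    INF = 1e18
    E = np.full((n, m), INF)
    NP = np.zeros((n, m), dtype=np.int32)
    FK = np.full((n, m), -1, dtype=np.int32)
    FL = np.full((n, m), -1, dtype=np.int32)
    for i in range(n):
        for j in range(m):
            if x[i] > 3 or yr[j] > 3 or not pairable[x[i], yr[j]]:
                continue
            # open a new duplex at this pair
            e = init_dG
            if (x[i] == 0 and yr[j] == 3) or (x[i] == 3 and yr[j] == 0) \
               or (x[i] == 2 and yr[j] == 3) or (x[i] == 3 and yr[j] == 2):
                e += au_end
            best = e
            bnp = 1
            bk = -1
            bl = -1
            k0 = max(0, i - max_loop - 1)
            l0 = max(0, j - max_loop - 1)
            for k in range(k0, i):
                for l in range(l0, j):
                    if E[k, l] >= INF:
                        continue
                    g1 = i - k - 1
                    g2 = j - l - 1
                    if g1 + g2 > max_loop:
                        continue
                    if g1 == 0 and g2 == 0:
                        cost = stack4[x[k], x[i], yr[l], yr[j]]
                    else:
                        cost = loop[g1, g2]
                    cand = E[k, l] + cost
                    cnp = NP[k, l] + 1
                    if cand < best - 1e-9 or (
                        cand < best + 1e-9
                        and (cnp > bnp or (cnp == bnp and (bk < 0 or k < bk)))
                    ):
                        best = cand
                        bnp = cnp
                        bk = k
                        bl = l
            E[i, j] = best
            NP[i, j] = bnp
            FK[i, j] = bk
            FL[i, j] = bl
    return E, NP, FK, FL


def duplex_mfe(mirna: str, target: str, model: Optional[EnergyModel] = None
               ) -> DuplexResult:
    """Minimum free energy duplex between a miRNA and a target (both 5'->3').

    Sequences must be RNA (A/C/G/U); DNA input should be converted with
    ``to_rna`` first. Ties are broken toward more paired bases, then the
    leftmost start on the miRNA.
    """
    if model is None:
        model = _default_model()
    for name, seq in (("mirna", mirna), ("target", target)):
        if len(seq) < 2:
            raise ValueError(f"{name} shorter than 2 nt")
        if any(c not in "ACGU" for c in seq.upper()):
            raise ValueError(f"{name} contains non-RNA characters")
    x = encode(mirna.upper())
    yr = encode(target.upper()[::-1])
    E, NP, FK, FL = _duplex_fill(
        x, yr, model._stack4, model._loop, model._pairable,
        model.init_dG, model.au_end_dG, model.max_loop,
    )
    m = len(target)
    best = 0.0
    bi = bj = -1
    bnp = 0
    for i in range(len(mirna)):
        for j in range(m):
            if E[i, j] >= 1e17:
                continue
            e = E[i, j]
            if (x[i], yr[j]) in _AU_GU_ENDS:
                e += model.au_end_dG
            if e < best - 1e-9 or (
                e < best + 1e-9 and bi >= 0 and NP[i, j] > bnp
            ):
                best = e
                bi, bj = i, j
                bnp = NP[i, j]
    if bi < 0 or best >= -1e-9:
        return DuplexResult(mfe=0.0, pairing=[])
    pairs = []
    i, j = bi, bj
    while i >= 0:
        pairs.append((i, m - 1 - j))  # map reversed-target index back
        i, j = int(FK[i, j]), int(FL[i, j])
        if i < 0:
            break
    pairs.reverse()
    return DuplexResult(mfe=float(best), pairing=pairs)


_MODEL_CACHE: List[EnergyModel] = []


def _default_model() -> EnergyModel:
    if not _MODEL_CACHE:
        _MODEL_CACHE.append(EnergyModel.default())
    return _MODEL_CACHE[0]


# ---------------------------------------------------------------------------
# real-vs-shuffled energy gap


def extract_target_context(
    transcripts: Dict[str, str], transcript_id: str, start: int, end: int,
    flank: int = 10,
) -> str:
    """Target segment extended +/- flank nt, bounded by transcript ends."""
    seq = transcripts[transcript_id]
    return seq[max(0, start - flank) : min(len(seq), end + flank)]


def shuffled_null(mirna_ids: Sequence[str], rng_seed: int) -> List[int]:
    """Derangement-style reassignment of miRNAs to targets.

    Returns an index permutation ``perm`` such that target t receives the
    miRNA of entry perm[t] and mirna_ids[perm[t]] != mirna_ids[t] for all t.
    Deterministic under the seed; raises on single-miRNA input.
    """
    ids = list(mirna_ids)
    if len(set(ids)) < 2:
        raise ValueError("need >= 2 distinct miRNAs for a shuffled null")
    counts = {}
    for i in ids:
        counts[i] = counts.get(i, 0) + 1
    if max(counts.values()) > len(ids) // 2:
        raise ValueError(
            "derangement impossible: one miRNA owns more than half the targets"
        )
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    n = len(ids)
    perm = rng.permutation(n)
    # repair conflicts by random transpositions; converges quickly whenever a
    # derangement exists (no miRNA owns more than half the targets)
    for _ in range(200 * n + 1000):
        bad = [t for t in range(n) if ids[perm[t]] == ids[t]]
        if not bad:
            return perm.tolist()
        t = bad[int(rng.integers(len(bad)))]
        u = int(rng.integers(n))
        if ids[perm[t]] != ids[u] and ids[perm[u]] != ids[t]:
            perm[t], perm[u] = perm[u], perm[t]
    raise RuntimeError("could not find a derangement (too few distinct miRNAs?)")


def interaction_mfes(
    pairs: Sequence[Tuple[str, str]], model: Optional[EnergyModel] = None
) -> np.ndarray:
    """MFE per (miRNA seq, target seq) pair; sequences may be DNA or RNA."""
    model = model or _default_model()
    return np.array([
        duplex_mfe(to_rna(m.upper()), to_rna(t.upper()), model).mfe for m, t in pairs
    ])


def energy_gap(real_mfes: np.ndarray, null_mfes: np.ndarray,
               n_perm: int = 10_000, rng_seed: int = 0
               ) -> Tuple[float, float, float]:
    """(delta_median, delta_mean, permutation p) for real vs shuffled MFEs.

    delta = statistic(real) - statistic(null); p is the two-sided
    label-permutation probability of a mean difference at least as extreme.
    """
    real = np.asarray(real_mfes, float)
    null = np.asarray(null_mfes, float)
    if real.size == 0 or null.size == 0:
        raise ValueError("both samples must be nonempty")
    d_med = float(np.median(real) - np.median(null))
    d_mean = float(real.mean() - null.mean())
    pooled = np.concatenate([real, null])
    n1 = real.size
    rng = np.random.Generator(np.random.PCG64(rng_seed))
    count = 0
    for _ in range(n_perm):
        rng.shuffle(pooled)
        d = pooled[:n1].mean() - pooled[n1:].mean()
        if abs(d) >= abs(d_mean) - 1e-12:
            count += 1
    return d_med, d_mean, (count + 1) / (n_perm + 1)
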