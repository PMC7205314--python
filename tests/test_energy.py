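"""Duplex MFE dynamic program vs independent oracles; shuffled-null checks."""

import functools
import itertools
import shutil
import subprocess

import numpy as np
import pytest

from clearclip._seq import revcomp, to_rna
from clearclip.energy import (
    _AU_GU_ENDS,
    EnergyModel,
    duplex_mfe,
    energy_gap,
    interaction_mfes,
    shuffled_null,
)

MODEL = EnergyModel.default()
CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


def _pairable(a: int, b: int) -> bool:
    return bool(MODEL._pairable[a, b])


def pairing_energy(x: str, yr: str, pairs) -> float | None:
    """Score one candidate pairing independently of the DP.

    `pairs` are (i, j) indices into x and the reversed target yr, strictly
    increasing in both coordinates. Returns None when the pairing is invalid
    (non-complementary pair or an over-long loop).
    """
    xi = [CODE[c] for c in x]
    yi = [CODE[c] for c in yr]
    e = MODEL.init_dG
    for i, j in pairs:
        if not _pairable(xi[i], yi[j]):
            return None
    for (i1, j1), (i2, j2) in zip(pairs, pairs[1:]):
        g1, g2 = i2 - i1 - 1, j2 - j1 - 1
        if g1 == 0 and g2 == 0:
            e += MODEL._stack4[xi[i1], xi[i2], yi[j1], yi[j2]]
        elif g1 + g2 > MODEL.max_loop:
            return None
        else:
            e += MODEL._loop[g1, g2]
    for i, j in (pairs[0], pairs[-1]):
        if (xi[i], yi[j]) in _AU_GU_ENDS:
            e += MODEL.au_end_dG
    return e


def exhaustive_mfe(x: str, y: str) -> float:
    """Enumerate every non-crossing intermolecular pairing (brute force)."""
    yr = y[::-1]
    n, m = len(x), len(yr)
    best = [0.0]

    def rec(i0, j0, pairs):
        if pairs:
            e = pairing_energy(x, yr, pairs)
            if e is not None and e < best[0]:
                best[0] = e
        for i in range(i0, n):
            for j in range(j0, m):
                pairs.append((i, j))
                rec(i + 1, j + 1, pairs)
                pairs.pop()

    rec(0, 0, [])
    return best[0]


def memo_mfe(x: str, y: str) -> float:
    """Top-down memoized formulation, structurally independent of the
    iterative fill in the implementation."""
    yr = y[::-1]
    xi = tuple(CODE[c] for c in x)
    yi = tuple(CODE[c] for c in yr)
    ml = MODEL.max_loop

    def end_pen(i, j):
        return MODEL.au_end_dG if (xi[i], yi[j]) in _AU_GU_ENDS else 0.0

    @functools.lru_cache(maxsize=None)
    def ext(i, j):
        """Best energy of the duplex part right of pair (i, j), inclusive of
        the closing end penalty but not the pair's own left context."""
        best = end_pen(i, j)
        for k in range(i + 1, min(i + ml + 2, len(xi))):
            for l in range(j + 1, min(j + ml + 2, len(yi))):
                if not _pairable(xi[k], yi[l]):
                    continue
                g1, g2 = k - i - 1, l - j - 1
                if g1 + g2 > ml:
                    continue
                cost = (
                    MODEL._stack4[xi[i], xi[k], yi[j], yi[l]]
                    if g1 == 0 and g2 == 0
                    else MODEL._loop[g1, g2]
                )
                cand = cost + ext(k, l)
                if cand < best:
                    best = cand
        return best

    best = 0.0
    for i in range(len(xi)):
        for j in range(len(yi)):
            if _pairable(xi[i], yi[j]):
                e = MODEL.init_dG + end_pen(i, j) + ext(i, j)
                best = min(best, e)
    return best


def _random_rna(rng, n):
    return "".join(rng.choice(list("ACGU"), size=n))


class TestDuplexDP:
    def test_fully_complementary_hand_sum(self):
        res = duplex_mfe("GGGG", "CCCC", MODEL)
        expect = MODEL.init_dG + 3 * MODEL.stack_dG[("GG", "CC")]
        assert res.mfe == pytest.approx(expect)
        assert res.pairing == [(0, 3), (1, 2), (2, 1), (3, 0)]

    def test_no_complementarity_reports_unstable_sentinel(self):
        res = duplex_mfe("AAAA", "AAAA", MODEL)
        assert res.mfe == 0.0 and res.pairing == []

    def test_terminal_au_penalty_applied(self):
        res = duplex_mfe("AGGA", "UCCU", MODEL)
        expect = (
            MODEL.init_dG
            + MODEL.stack_dG[("AG", "UC")]
            + MODEL.stack_dG[("GG", "CC")]
            + MODEL.stack_dG[("GA", "CU")]
            + 2 * MODEL.au_end_dG
        )
        assert res.mfe == pytest.approx(expect)

    def test_non_rna_characters_rejected(self):
        with pytest.raises(ValueError):
            duplex_mfe("ACGT", "ACGU", MODEL)  # T is DNA
        with pytest.raises(ValueError):
            duplex_mfe("A", "ACGU", MODEL)

    def test_dp_equals_exhaustive_enumeration_short(self, rng):
        for _ in range(12):
            x = _random_rna(rng, int(rng.integers(4, 8)))
            y = _random_rna(rng, int(rng.integers(4, 8)))
            assert duplex_mfe(x, y, MODEL).mfe == pytest.approx(exhaustive_mfe(x, y))

    def test_dp_equals_memoized_recursion_medium(self, rng):
        for _ in range(25):
            x = _random_rna(rng, int(rng.integers(8, 13)))
            y = _random_rna(rng, int(rng.integers(8, 13)))
            assert duplex_mfe(x, y, MODEL).mfe == pytest.approx(memo_mfe(x, y))

    def test_complementary_extension_never_raises_mfe(self, rng):
        comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
        for _ in range(20):
            x = _random_rna(rng, 10)
            y = _random_rna(rng, 12)
            base = duplex_mfe(x, y, MODEL).mfe
            b = str(rng.choice(list("ACGU")))
            ext = duplex_mfe(x + b, comp[b] + y, MODEL).mfe
            assert ext <= base + 1e-9

    def test_pairing_monotone_and_intermolecular(self, rng):
        for _ in range(10):
            mir = _random_rna(rng, 21)
            tgt = to_rna(revcomp(mir))  # perfect duplex in DNA->RNA space
            res = duplex_mfe(mir, tgt, MODEL)
            assert res.mfe < -15
            mis = [i for i, _ in res.pairing]
            tis = [j for _, j in res.pairing]
            assert mis == sorted(mis)
            assert tis == sorted(tis, reverse=True)

    def test_duplex_string_shape(self):
        res = duplex_mfe("GGGG", "CCCC", MODEL)
        s = res.duplex_string(4, 4)
        assert s == "((((&))))"


class TestViennaCrossCheck:
    def test_rank_agreement_with_rnaduplex(self, rng):
        """Independent check against ViennaRNA's RNAduplex: across duplexes
        spanning weak to strong complementarity, the two models' MFEs must
        rank-correlate strongly (parameterizations differ, ranks should not).
        """
        assert shutil.which("RNAduplex"), "ViennaRNA RNAduplex not on PATH"
        pairs = []
        for k in range(0, 22, 3):  # increasing planted complementarity
            mir = _random_rna(rng, 21)
            tgt = list(_random_rna(rng, 40))
            rc = to_rna(revcomp(mir))[:k]
            tgt[10 : 10 + k] = list(rc)
            pairs.append((mir, "".join(tgt)))
        ours = interaction_mfes(pairs, MODEL)
        stdin = "\n".join(f"{m}\n{t}" for m, t in pairs) + "\n"
        out = subprocess.run(
            ["RNAduplex", "--noconv"], input=stdin, capture_output=True, text=True,
            check=True,
        ).stdout
        vienna = [
            float(line.rsplit("(", 1)[1].rstrip(")").strip())
            for line in out.splitlines()
            if "(" in line and line.strip().endswith(")")
        ]
        assert len(vienna) == len(pairs)
        from scipy.stats import spearmanr

        rho, _ = spearmanr(ours, vienna)
        assert rho > 0.8


class TestShuffledNull:
    def test_two_items_forced_swap(self):
        assert shuffled_null(["A", "B"], rng_seed=0) == [1, 0]

    def test_no_self_assignment_large(self):
        ids = [f"m{i % 20}" for i in range(1000)]
        perm = shuffled_null(ids, rng_seed=2)
        assert all(ids[perm[t]] != ids[t] for t in range(1000))
        assert sorted(perm) == list(range(1000))  # a true permutation

    def test_single_mirna_rejected(self):
        with pytest.raises(ValueError):
            shuffled_null(["A", "A", "A"], rng_seed=0)

    def test_seeds_differ_but_marginals_preserved(self):
        ids = [f"m{i % 6}" for i in range(600)]
        p1 = shuffled_null(ids, rng_seed=1)
        p2 = shuffled_null(ids, rng_seed=2)
        assert p1 != p2
        # multiset of assigned miRNAs is exactly the original multiset
        assert sorted(ids[i] for i in p1) == sorted(ids)


class TestEnergyGap:
    def test_identical_samples_zero_delta(self):
        x = np.array([-5.0, -6.0, -7.0, -8.0] * 10)
        d_med, d_mean, p = energy_gap(x, x.copy(), n_perm=500, rng_seed=0)
        assert d_med == 0.0 and d_mean == 0.0
        assert p > 0.5

    def test_constant_shift_recovered(self):
        rng = np.random.Generator(np.random.PCG64(3))
        null = rng.normal(-8, 2, size=300)
        real = null - 2.0
        d_med, d_mean, p = energy_gap(real, null, n_perm=500, rng_seed=0)
        assert d_med == pytest.approx(-2.0, abs=1e-9)
        assert d_mean == pytest.approx(-2.0, abs=1e-9)
        assert p < 0.01
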