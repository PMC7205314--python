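"""Seed-match density, k-mer enrichment, motif registers, usage matrices."""

import numpy as np
import pandas as pd
import pytest

from clearclip._seq import revcomp
from clearclip.motifs import (
    enrich_kmers,
    map_motif_register,
    sample_background,
    seed_match_density,
    seed_sequence,
    usage_by_timepoint,
)

LET7 = "TGAGGTAGTAGGTTGTATAGTT"  # DNA-space let-7-like miRNA


def _random_seqs(rng, n, length=50):
    return ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]


class TestSeedSequence:
    def test_seed_is_revcomp_of_nt2_to_7(self):
        # nt 2-7 of let-7 are GAGGTA -> RC = TACCTC
        assert LET7[1:7] == "GAGGTA"
        assert seed_sequence(LET7) == revcomp("GAGGTA") == "TACCTC"


class TestSeedDensity:
    def _chimeras(self, rng, mirnas, transcripts, dist=20, n=120):
        """miR-first chimeras whose seed match sits `dist` nt 3' of the
        ligation point."""
        rows = []
        tx = transcripts["tx"]
        mids = sorted(mirnas)
        for i in range(n):
            mid = mids[i % len(mids)]
            lig = 150 + i * 150  # spaced beyond the scan window so sites stay independent
            rows.append(
                dict(
                    read_id=f"r{i}", mirna_id=mid, orientation="miR_first",
                    transcript_id="tx", target_start=lig, target_end=lig + 45,
                )
            )
        return pd.DataFrame(rows)

    def test_planted_offset_peak_and_flat_shuffle(self, rng):
        mirnas = {f"m{i}": "".join(rng.choice(list("ACGT"), size=22)) for i in range(6)}
        tx = list("".join(rng.choice(list("ACGT"), size=150 + 120 * 150 + 300)))
        chim = self._chimeras(rng, mirnas, {"tx": "".join(tx)})
        dist = 20
        for r in chim.itertuples():  # plant the seed match at +dist
            seed = seed_sequence(mirnas[r.mirna_id])
            pos = r.target_start + dist
            tx[pos : pos + len(seed)] = list(seed)
        transcripts = {"tx": "".join(tx)}
        dens = seed_match_density(chim, mirnas, transcripts, window_nt=60, shuffle_seed=1)
        peak_off = dens.loc[dens.real_density.idxmax(), "offset"]
        assert peak_off == dist
        at_peak = dens[dens.offset == dist].iloc[0]
        assert at_peak.real_density >= 0.9  # nearly every chimera contributes
        assert at_peak.real_density >= 3 * max(at_peak.shuffled_density, 1e-6)
        # shuffled control stays at background level everywhere
        assert dens.shuffled_density.max() <= 0.1


class TestEnrichment:
    def test_extreme_enrichment_top_ranked(self, rng):
        motif = "GAGGTAC"
        targets = []
        for s in _random_seqs(rng, 40):
            targets.append(s[:20] + motif + s[27:])
        background = [s for s in _random_seqs(rng, 200) if motif not in s]
        res = enrich_kmers(targets, background, "m1", LET7)
        assert res and res[0].kmer == motif
        assert res[0].corrected_pvalue < 1e-6
        assert res[0].n_targets_with_motif == 40

    def test_null_rarely_passes(self, rng):
        hits = 0
        for rep in range(10):
            targets = _random_seqs(rng, 40)
            background = _random_seqs(rng, 200)
            if enrich_kmers(targets, background, "m1", LET7):
                hits += 1
        assert hits <= 1  # Bonferroni keeps family-wise error low

    def test_too_few_targets_skipped(self, rng):
        with pytest.raises(ValueError):
            enrich_kmers(_random_seqs(rng, 29), _random_seqs(rng, 145), "m1", LET7)

    def test_zoops_counts_bounded_by_target_count(self, rng):
        motif = "GAGGTAC"
        targets = [motif + s + motif for s in _random_seqs(rng, 35, 30)]  # twice per seq
        background = _random_seqs(rng, 175)
        res = enrich_kmers(targets, background, "m1", LET7)
        top = [m for m in res if m.kmer == motif][0]
        assert top.n_targets_with_motif == 35  # counted once per target

    def test_background_sampler_is_seeded_and_sized(self, rng):
        own = _random_seqs(rng, 30)
        other = _random_seqs(rng, 400)
        a = sample_background(own, other, rng_seed=5)
        b = sample_background(own, other, rng_seed=5)
        assert a == b and len(a) == 150


class TestRegister:
    def test_exact_rc_of_nt2_to_8_maps_to_register_2(self):
        kmer = revcomp(LET7[1:8])
        regs = map_motif_register(kmer, LET7)
        assert regs[0] == (2, 7)

    def test_rc_of_nt13_to_19_maps_to_register_13(self):
        kmer = revcomp(LET7[12:19])
        regs = map_motif_register(kmer, LET7)
        assert regs[0] == (13, 7)

    def test_one_mismatch_register_still_found(self):
        kmer = list(revcomp(LET7[1:8]))
        kmer[3] = "A" if kmer[3] != "A" else "C"
        regs = map_motif_register("".join(kmer), LET7)
        assert any(start == 2 and m == 6 for start, m in regs)

    def test_random_kmer_rarely_registers(self, rng):
        hits = 0
        trials = 300
        for _ in range(trials):
            kmer = "".join(rng.choice(list("ACGT"), size=7))
            mir = "".join(rng.choice(list("ACGT"), size=22))
            if map_motif_register(kmer, mir):
                hits += 1
        # expected ~= 16 offsets * P(>=6/7 matches) ~ 16 * 22*3/4^7 ~ 0.06
        assert hits / trials < 0.25


class TestUsage:
    def _targets(self, rng, mirna, register_start, n=40, k=7):
        """Targets carrying the RC of miRNA positions [start, start+7)."""
        kmer = revcomp(mirna[register_start - 1 : register_start - 1 + k])
        out = []
        for s in _random_seqs(rng, n):
            out.append(s[:20] + kmer + s[27:])
        return out

    def test_single_shared_motif_covers_its_positions(self, rng):
        targets = self._targets(rng, LET7, 2)
        others = {
            (f"bg{i}", "t1"): _random_seqs(rng, 40) for i in range(4)
        }
        data = {("m1", "t1"): targets, **others}
        mirnas = {"m1": LET7, **{f"bg{i}": "".join(rng.choice(list("ACGT"), 22))
                                 for i in range(4)}}
        usage = usage_by_timepoint(data, mirnas, ["t1"], rng_seed=0)
        m1 = usage[usage.mirna_id == "m1"].set_index("position")
        covered = m1.loc[2:8, "proportion"]
        assert (covered > 0.9).all()
        assert m1.loc[15, "proportion"] <= 0.1

    def test_register_shift_between_timepoints_reproduced(self, rng):
        data = {
            ("m1", "t1"): self._targets(rng, LET7, 1),
            ("m1", "t3"): self._targets(rng, LET7, 2),
            ("bg0", "t1"): _random_seqs(rng, 40),
            ("bg0", "t3"): _random_seqs(rng, 40),
            ("bg1", "t1"): _random_seqs(rng, 40),
            ("bg1", "t3"): _random_seqs(rng, 40),
        }
        mirnas = {"m1": LET7,
                  "bg0": "".join(rng.choice(list("ACGT"), 22)),
                  "bg1": "".join(rng.choice(list("ACGT"), 22))}
        usage = usage_by_timepoint(data, mirnas, ["t1", "t3"], rng_seed=0)
        m1 = usage[usage.mirna_id == "m1"]
        t1 = m1[m1.timepoint == "t1"].set_index("position").proportion
        t3 = m1[m1.timepoint == "t3"].set_index("position").proportion
        assert t1.loc[1] > 0.9 and t3.loc[1] <= 0.5
        assert t3.loc[8] > 0.9 and t1.loc[8] <= 0.5

    def test_absent_timepoint_is_nan(self, rng):
        data = {
            ("m1", "t1"): self._targets(rng, LET7, 2),
            ("bg0", "t1"): _random_seqs(rng, 40),
        }
        mirnas = {"m1": LET7, "bg0": "".join(rng.choice(list("ACGT"), 22))}
        usage = usage_by_timepoint(data, mirnas, ["t1", "t2"], rng_seed=0)
        t2 = usage[(usage.mirna_id == "m1") & (usage.timepoint == "t2")]
        assert t2.proportion.isna().all()
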