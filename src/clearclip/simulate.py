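"""Synthetic CLEAR-CLIP study generator with planted ground truth.

Builds a toy transcriptome (mRNAs with contiguous 5'UTR/CDS/3'UTR blocks plus
high-GC rRNA/tRNA decoys), a mirnome, a planted interactome (canonical-seed,
3'-supplementary, central and seedless sites, each with a known
complementarity register), and per-time-point FASTQ libraries whose reads are
labelled: miRNA-target chimeras in both orientations, CLIP single reads piled
on active sites, miRNA-only reads, ncRNA reads and unmappable junk, with PCR
duplicates under a degenerate 3-nt barcode and per-base substitution errors.

Every labelled read traces back to a planted interaction, so recovery of the
interactome by the downstream pipeline can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._seq import revcomp, random_seq
from .config import (
    ADAPTER_3P,
    BARCODE_LEN,
    SITE_CLASS_REGISTERS,
    ConfigurationError,
    SimulationConfig,
)

PHRED_HIGH = 37
PHRED_LOW = 8


@dataclass
class Reference:
    """Synthetic transcriptome + mirnome."""

    transcripts: Dict[str, str]  # includes ncRNA decoys
    annotation: pd.DataFrame  # transcript_id, feature, start, end (0-based half-open)
    mirnas: Dict[str, str]  # mature miRNA sequences, DNA alphabet

    def transcript_lengths(self) -> Dict[str, int]:
        return {t: len(s) for t, s in self.transcripts.items()}

    def ncrna_ids(self) -> set:
        nc = self.annotation[self.annotation.feature.isin(["rRNA", "tRNA", "miRNA_locus"])]
        return set(nc.transcript_id)


@dataclass
class GroundTruth:
    """Planted interactome and, after library simulation, per-read labels."""

    interactions: pd.DataFrame
    # columns: interaction_id, mirna_id, transcript_id, site_start, site_end,
    #          site_class, register_start, register_end, act_<tp> per time point
    skipped: List[str] = field(default_factory=list)
    read_labels: Dict[str, pd.DataFrame] = field(default_factory=dict)  # per time point


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.Generator(np.random.PCG64(np.random.SeedSequence(seed, spawn_key=key)))


# ---------------------------------------------------------------------------
# reference


def generate_reference(config: SimulationConfig) -> Reference:
    """Generate transcript FASTA-equivalent dict, annotation table and mirnome.

    Each mRNA transcript is partitioned into contiguous 5'UTR/CDS/3'UTR blocks
    whose lengths follow ``config.utr_fractions`` (within 1 nt of the exact
    split). ncRNA decoys get a distinctively high GC content and are flagged
    rRNA/tRNA in the annotation.
    """
    config.validate()
    rng = _spawn(config.rng_seed, 0)
    transcripts: Dict[str, str] = {}
    rows = []
    lo, hi = config.transcript_len_range
    f5, fc, _ = config.utr_fractions
    for i in range(config.n_transcripts):
        tid = f"tx{i:04d}"
        length = int(rng.integers(lo, hi + 1))
        transcripts[tid] = random_seq(rng, length)
        b1 = int(round(f5 * length))
        b2 = b1 + int(round(fc * length))
        rows.append((tid, "5UTR", 0, b1))
        rows.append((tid, "CDS", b1, b2))
        rows.append((tid, "3UTR", b2, length))
    nlo, nhi = config.ncrna_len_range
    for i in range(config.n_ncrna):
        tid = f"nc{i:04d}"
        length = int(rng.integers(nlo, nhi + 1))
        transcripts[tid] = random_seq(rng, length, gc=config.ncrna_gc)
        rows.append((tid, "rRNA" if i % 2 == 0 else "tRNA", 0, length))
    mirnas: Dict[str, str] = {}
    seen = set()
    mlo, mhi = config.mirna_len_range
    while len(mirnas) < config.n_mirnas:
        seq = random_seq(rng, int(rng.integers(mlo, mhi + 1)))
        if seq in seen:
            continue
        seen.add(seq)
        mirnas[f"miR-{len(mirnas) + 1}"] = seq
    annotation = pd.DataFrame(rows, columns=["transcript_id", "feature", "start", "end"])
    return Reference(transcripts, annotation, mirnas)


# ---------------------------------------------------------------------------
# planting


def _activity_profiles(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    """Per-interaction nonnegative weight per time point, from a few archetypes.

    Archetypes are stage-peaked bumps so neighbouring stages share programmes
    (adjacent time points end up more correlated than distant ones).
    """
    T = len(config.timepoints)
    k = min(config.n_activity_archetypes, T)
    centers = np.linspace(0, T - 1, k)
    archetypes = np.exp(-0.5 * ((np.arange(T)[None, :] - centers[:, None]) / 0.8) ** 2)
    archetypes = archetypes / archetypes.sum(axis=1, keepdims=True)
    which = rng.integers(0, k, size=n)
    noise = rng.uniform(0.8, 1.25, size=(n, T))
    prof = archetypes[which] * noise
    return prof / prof.sum(axis=1, keepdims=True)


def _has_forbidden_seed(window: str, mirna: str) -> bool:
    """True if `window` contains a 6-mer complementary to miRNA nt 1-8."""
    for s in range(3):  # nt 1-6, 2-7, 3-8
        if revcomp(mirna[s : s + 6]) in window:
            return True
    return False


def plant_interactions(reference: Reference, config: SimulationConfig) -> GroundTruth:
    """Plant miRNA binding sites into the transcriptome, in place.

    For register-bearing classes the planted window is overwritten with the
    reverse complement of the configured miRNA segment; seedless sites are
    loci verified to lack any 6-mer complementary to miRNA nt 1-8 within
    +/- 20 nt. Sites are non-overlapping with >= 100 nt spacing so planted
    interactions stay separable after clustering.
    """
    config.validate()
    rng = _spawn(config.rng_seed, 1)
    classes = sorted(config.site_class_mix)
    class_p = np.array([config.site_class_mix[c] for c in classes])
    regions = sorted(config.site_region_mix)
    region_p = np.array([config.site_region_mix[r] for r in regions])
    mirna_ids = sorted(reference.mirnas)
    # miRNA expression is heavy-tailed in real small-RNA libraries; a
    # lognormal weight per miRNA makes interaction (and hence chimera)
    # counts per miRNA realistically uneven
    mirna_w = rng.lognormal(0.0, 1.0, size=len(mirna_ids))
    mirna_p = mirna_w / mirna_w.sum()
    ann = reference.annotation
    mrna_feats = ann[ann.feature.isin(["5UTR", "CDS", "3UTR"])]
    used: Dict[str, List[Tuple[int, int]]] = {}
    margin = 60  # keep target fragments inside the transcript
    spacing = 100
    rows = []
    skipped: List[str] = []
    seqs = reference.transcripts
    profiles = _activity_profiles(rng, config.n_interactions, config)
    for idx in range(config.n_interactions):
        cls = classes[rng.choice(len(classes), p=class_p)]
        region = regions[rng.choice(len(regions), p=region_p)]
        mid = mirna_ids[rng.choice(len(mirna_ids), p=mirna_p)]
        mir = reference.mirnas[mid]
        if cls == "seedless":
            reg_start, reg_end = 0, 0
            site_len = 7
        else:
            reg_start, reg_end = SITE_CLASS_REGISTERS[cls]
            site_len = reg_end - reg_start + 1
        placed = False
        for _attempt in range(60):
            feat = mrna_feats[mrna_feats.feature == region]
            row = feat.iloc[int(rng.integers(len(feat)))]
            tid = row.transcript_id
            tlen = len(seqs[tid])
            lo = max(row.start, margin)
            hi = min(row.end, tlen - margin) - site_len
            if hi <= lo:
                continue
            start = int(rng.integers(lo, hi))
            end = start + site_len
            if any(start < e + spacing and s - spacing < end for s, e in used.get(tid, [])):
                continue
            if cls == "seedless":
                win = seqs[tid][max(0, start - 20) : end + 20]
                if _has_forbidden_seed(win, mir):
                    continue
            else:
                planted = revcomp(mir[reg_start - 1 : reg_end])
                seqs[tid] = seqs[tid][:start] + planted + seqs[tid][end:]
            used.setdefault(tid, []).append((start, end))
            rows.append(
                dict(
                    interaction_id=f"int{idx:04d}",
                    mirna_id=mid,
                    transcript_id=tid,
                    site_start=start,
                    site_end=end,
                    site_class=cls,
                    register_start=reg_start,
                    register_end=reg_end,
                    **{f"act_{tp}": profiles[idx, j] for j, tp in enumerate(config.timepoints)},
                )
            )
            placed = True
            break
        if not placed:
            skipped.append(f"int{idx:04d}: no placement for class={cls} region={region}")
    if not rows:
        raise ConfigurationError("no interactions could be planted")
    return GroundTruth(interactions=pd.DataFrame(rows), skipped=skipped)


# ---------------------------------------------------------------------------
# library simulation


def _truncnorm_lengths(rng: np.random.Generator, n: int, config: SimulationConfig) -> np.ndarray:
    a = (config.target_len_min - config.target_len_mean) / config.target_len_sd
    d = stats.truncnorm(a, np.inf, loc=config.target_len_mean, scale=config.target_len_sd)
    return np.rint(d.rvs(size=n, random_state=rng)).astype(int)


def _apply_errors(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    if hits.size == 0:
        return seq
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[int(rng.integers(3))]
    return arr.tobytes().decode("ascii")


def _fragment_around_site(
    rng: np.random.Generator, tlen: int, s0: int, s1: int, frag_len: int
) -> Tuple[int, int]:
    """Interval of length ~frag_len containing [s0, s1), clipped to transcript."""
    frag_len = max(frag_len, s1 - s0 + 4)
    lo = max(0, s1 - frag_len)
    hi = min(s0, tlen - frag_len)
    start = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, min(s0, tlen - frag_len))
    return start, min(start + frag_len, tlen)


def simulate_library(
    reference: Reference,
    truth: GroundTruth,
    config: SimulationConfig,
    timepoint: str,
) -> Tuple[List[Tuple[str, str, str]], pd.DataFrame]:
    """Simulate one FASTQ library for one time point.

    Returns ``(records, labels)`` where records are ``(read_id, sequence,
    quality)`` and labels carry the true class, miRNA, locus, orientation,
    template id and barcode for every read. Reads are 3-nt degenerate barcode
    + insert + 3' adapter, truncated at ``read_len``; PCR duplicates re-emit
    an existing template (same barcode + insert) with independent sequencing
    errors.
    """
    if timepoint not in config.timepoints:
        raise ConfigurationError(f"unknown time point {timepoint!r}")
    tp_idx = config.timepoints.index(timepoint)
    rng = _spawn(config.rng_seed, 2, tp_idx)
    inter = truth.interactions
    act = inter[f"act_{timepoint}"].to_numpy(float)
    w = act / act.sum() if act.sum() > 0 else np.full(len(inter), 1.0 / len(inter))
    # miRNA sampling for miRNA-only reads follows total interaction activity,
    # so miRNA abundance and chimera frequency are correlated by construction.
    mirna_ids = sorted(reference.mirnas)
    mir_w = pd.Series(0.0, index=mirna_ids)
    for mid, aw in zip(inter.mirna_id, act):
        mir_w[mid] += aw
    mir_w += 0.02 * mir_w.sum() / len(mir_w) + 1e-12
    mir_p = (mir_w / mir_w.sum()).to_numpy()

    classes = ["chimera", "clip", "mirna_only", "ncRNA", "junk"]
    class_p = np.array([config.read_class_mix.get(c, 0.0) for c in classes])
    class_p = class_p / class_p.sum()
    n = config.n_reads
    n_dup = rng.binomial(n, config.pcr_dup_rate)
    n_unique = n - n_dup
    cls_draw = rng.choice(len(classes), size=n_unique, p=class_p)
    frag_lens = _truncnorm_lengths(rng, n_unique, config)
    nc_ids = sorted(reference.ncrna_ids())
    seqs = reference.transcripts

    templates: List[dict] = []
    for u in range(n_unique):
        cls = classes[cls_draw[u]]
        bc = random_seq(rng, BARCODE_LEN)
        lab = dict(
            true_class=cls, mirna_id="", transcript_id="", frag_start=-1, frag_end=-1,
            orientation="", interaction_id="",
        )
        if cls == "chimera":
            i = rng.choice(len(inter), p=w)
            row = inter.iloc[int(i)]
            tid = row.transcript_id
            f0, f1 = _fragment_around_site(
                rng, len(seqs[tid]), row.site_start, row.site_end, int(frag_lens[u])
            )
            frag = seqs[tid][f0:f1]
            mir = reference.mirnas[row.mirna_id]
            mir_first = rng.random() < config.chimera_mir_first_frac
            insert = mir + frag if mir_first else frag + mir
            lab.update(
                mirna_id=row.mirna_id, transcript_id=tid, frag_start=f0, frag_end=f1,
                orientation="miR_first" if mir_first else "miR_last",
                interaction_id=row.interaction_id,
            )
        elif cls == "clip":
            i = rng.choice(len(inter), p=w)
            row = inter.iloc[int(i)]
            tid = row.transcript_id
            f0, f1 = _fragment_around_site(
                rng, len(seqs[tid]), row.site_start, row.site_end, int(frag_lens[u])
            )
            insert = seqs[tid][f0:f1]
            lab.update(
                transcript_id=tid, frag_start=f0, frag_end=f1, interaction_id=row.interaction_id
            )
        elif cls == "mirna_only":
            mid = mirna_ids[rng.choice(len(mirna_ids), p=mir_p)]
            insert = reference.mirnas[mid]
            lab.update(mirna_id=mid)
        elif cls == "ncRNA":
            tid = nc_ids[int(rng.integers(len(nc_ids)))]
            tlen = len(seqs[tid])
            flen = min(int(frag_lens[u]), tlen)
            f0 = int(rng.integers(0, tlen - flen + 1))
            insert = seqs[tid][f0 : f0 + flen]
            lab.update(transcript_id=tid, frag_start=f0, frag_end=f0 + flen)
        else:  # junk: unmappable
            insert = random_seq(rng, int(frag_lens[u]) + 20)
        templates.append(dict(barcode=bc, insert=insert, **lab))

    order = list(range(n_unique)) + [int(rng.integers(n_unique)) for _ in range(n_dup)]
    records: List[Tuple[str, str, str]] = []
    label_rows = []
    low_q = rng.random(n) < config.low_quality_frac
    for ridx, t_idx in enumerate(order):
        t = templates[t_idx]
        full = t["barcode"] + t["insert"] + ADAPTER_3P
        seq = _apply_errors(rng, full[: config.read_len], config.error_rate)
        qual = chr((PHRED_LOW if low_q[ridx] else PHRED_HIGH) + 33) * len(seq)
        rid = f"rd_{timepoint}_{ridx:07d}"
        records.append((rid, seq, qual))
        label_rows.append(
            dict(
                read_id=rid, template_id=f"tpl_{timepoint}_{t_idx:07d}",
                is_duplicate=ridx >= n_unique, barcode=t["barcode"], insert=t["insert"],
                **{k: t[k] for k in (
                    "true_class", "mirna_id", "transcript_id", "frag_start",
                    "frag_end", "orientation", "interaction_id",
                )},
            )
        )
    labels = pd.DataFrame(label_rows)
    truth.read_labels[timepoint] = labels
    return records, labels


# ---------------------------------------------------------------------------
# expression table


def simulate_expression(
    reference: Reference, config: SimulationConfig, truth: Optional[GroundTruth] = None
) -> pd.DataFrame:
    """Per-time-point mRNA abundance (arbitrary TPM-like units), long format."""
    rng = _spawn(config.rng_seed, 3)
    tids = sorted(t for t in reference.transcripts if t.startswith("tx"))
    base = rng.lognormal(mean=3.0, sigma=0.8, size=len(tids))
    rows = []
    for j, tp in enumerate(config.timepoints):
        jitter = rng.uniform(0.85, 1.18, size=len(tids))
        for t, b, f in zip(tids, base, jitter):
            rows.append((t, tp, float(b * f)))
    return pd.DataFrame(rows, columns=["transcript_id", "timepoint", "abundance"])


# ---------------------------------------------------------------------------
# on-disk study


def write_fasta(path: Path, seqs: Dict[str, str]) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n{seqs[name]}\n")


def write_fastq(path: Path, records: Sequence[Tuple[str, str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def simulate_study(config: SimulationConfig, outdir: str | Path) -> Tuple[Reference, GroundTruth]:
    """Generate the full study to ``outdir`` and return the in-memory objects.

    Emits transcripts.fa, mirnas.fa, annotation.tsv, interactions.tsv,
    expression.tsv, per-time-point FASTQ + label TSVs, and a manifest JSON
    recording the config and seed.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    truth = plant_interactions(reference, config)
    write_fasta(out / "transcripts.fa", reference.transcripts)
    write_fasta(out / "mirnas.fa", reference.mirnas)
    reference.annotation.to_csv(out / "annotation.tsv", sep="\t", index=False)
    truth.interactions.to_csv(out / "interactions.tsv", sep="\t", index=False)
    simulate_expression(reference, config, truth).to_csv(
        out / "expression.tsv", sep="\t", index=False
    )
    for tp in config.timepoints:
        records, labels = simulate_library(reference, truth, config, tp)
        write_fastq(out / f"reads_{tp}.fastq", records)
        labels.to_csv(out / f"labels_{tp}.tsv", sep="\t", index=False)
    manifest = dict(config=config.to_dict(), seed=config.rng_seed, skipped=truth.skipped)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return reference, truth
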