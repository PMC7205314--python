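"""End-to-end orchestration: simulate -> prep -> chimeras -> peaks ->
interactions -> energetics -> motifs -> dynamics, with per-stage manifests
recording the config hash and seed so runs are resumable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import energy as energy_mod
from . import motifs as motifs_mod
from ._seq import to_rna
from .chimera import Classifier
from .config import ADAPTER_3P, SimulationConfig, ConfigurationError
from .dynamics import normalize_matrix, som_fit, stage_correlation, zscore_rows
from .interactions import (
    attach_peak_support,
    build_interactions,
    composition_summary,
    join_across_timepoints,
)
from .peaks import call_peaks
from .prep import prepare_reads, read_fastq, write_collapsed_fasta
from .simulate import simulate_study

STAGE_VERSION = "1"


class MissingInputError(FileNotFoundError):
    """A stage input file is absent; earlier stages are unaffected."""


@dataclass
class PipelineConfig:
    """Whole-pipeline configuration; unknown keys are rejected on load."""

    outdir: str = "clearclip_out"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    evalue_max: float = 0.4
    min_len: int = 16
    alpha: float = 0.01
    energy_flank: int = 10
    energy_n_perm: int = 2000
    motif_k: int = 7
    motif_min_targets: int = 30
    som_grid: Tuple[int, int] = (8, 8)
    som_epochs: int = 50
    rng_seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        sim_known = set(SimulationConfig.__dataclass_fields__)
        sim_unknown = set(sim) - sim_known
        if sim_unknown:
            raise ConfigurationError(f"unknown simulation keys: {sorted(sim_unknown)}")
        if "site_class_mix" in sim:
            sim["site_class_mix"] = dict(sim["site_class_mix"])
        cfg = cls(**d)
        simcfg = SimulationConfig(**sim)
        # tuples survive JSON round-trips as lists
        for f in ("transcript_len_range", "utr_fractions", "ncrna_len_range",
                  "mirna_len_range", "timepoints"):
            setattr(simcfg, f, tuple(getattr(simcfg, f)))
        cfg.simulation = simcfg
        cfg.som_grid = tuple(cfg.som_grid)
        return cfg

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["simulation"] = self.simulation.to_dict()
        return d

    def manifest_dict(self) -> dict:
        """Config as recorded in manifests: the output location is where the
        manifest lives, so it is stored as '.' to keep runs comparable."""
        d = self.to_dict()
        d["outdir"] = "."
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.manifest_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _write_manifest(out: Path, stage: str, cfg: PipelineConfig, extra: dict | None = None
                    ) -> None:
    manifest = dict(
        stage=stage, stage_version=STAGE_VERSION, config_hash=cfg.content_hash(),
        seed=cfg.rng_seed, **(extra or {}),
    )
    (out / f"manifest_{stage}.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )


def _stage_done(out: Path, stage: str, cfg: PipelineConfig) -> bool:
    p = out / f"manifest_{stage}.json"
    if not p.exists():
        return False
    try:
        m = json.loads(p.read_text())
    except json.JSONDecodeError:
        return False
    return m.get("config_hash") == cfg.content_hash()


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"stage {stage}: missing input {path}")
    return path


def run_all(config: PipelineConfig, resume: bool = False) -> Path:
    """Run every stage in dependency order under ``config.outdir``.

    With ``resume=True`` stages whose manifest matches the current config
    hash are skipped. Returns the output directory.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    tps = list(sim.timepoints)

    if not (resume and _stage_done(out, "simulate", config)):
        simulate_study(sim, out / "sim")
        _write_manifest(out, "simulate", config)

    reference_fa = _require(out / "sim" / "transcripts.fa", "prep")
    mirna_fa = _require(out / "sim" / "mirnas.fa", "prep")
    annotation = pd.read_csv(_require(out / "sim" / "annotation.tsv", "prep"), sep="\t")
    transcripts = {r.id: str(r.seq) for r in SeqIO.parse(str(reference_fa), "fasta")}
    mirnas = {r.id: str(r.seq) for r in SeqIO.parse(str(mirna_fa), "fasta")}

    if not (resume and _stage_done(out, "prep", config)):
        for tp in tps:
            reads = read_fastq(_require(out / "sim" / f"reads_{tp}.fastq", "prep"))
            kept, stats = prepare_reads(reads, ADAPTER_3P, min_len=config.min_len)
            write_collapsed_fasta(out / f"prep_{tp}.fa", kept)
            (out / f"prep_stats_{tp}.json").write_text(
                json.dumps(stats.to_dict(), indent=2, sort_keys=True) + "\n"
            )
        _write_manifest(out, "prep", config)

    clf = Classifier(mirnas, transcripts, annotation, evalue_max=config.evalue_max)
    if not (resume and _stage_done(out, "chimeras", config)):
        from .prep import read_collapsed_fasta

        for tp in tps:
            kept = read_collapsed_fasta(_require(out / f"prep_{tp}.fa", "chimeras"))
            chim, clip_df, counts, weighted = clf.classify_reads(kept)
            chim.to_csv(out / f"chimeras_{tp}.tsv", sep="\t", index=False)
            clip_df.to_csv(out / f"clip_{tp}.tsv", sep="\t", index=False)
            comp = composition_summary(weighted, chim, clip_df, clf.annotate_region)
            (out / f"classes_{tp}.json").write_text(
                json.dumps(dict(counts=counts, **comp), indent=2, sort_keys=True) + "\n"
            )
        _write_manifest(out, "chimeras", config)

    tlen = {t: len(s) for t, s in transcripts.items()}
    if not (resume and _stage_done(out, "peaks", config)):
        for tp in tps:
            chim = pd.read_csv(_require(out / f"chimeras_{tp}.tsv", "peaks"), sep="\t")
            clip_df = pd.read_csv(_require(out / f"clip_{tp}.tsv", "peaks"), sep="\t")
            pk = call_peaks(clip_df, chim, tlen, alpha=config.alpha, timepoint=tp)
            pk.to_csv(out / f"peaks_{tp}.tsv", sep="\t", index=False)
        _write_manifest(out, "peaks", config)

    if not (resume and _stage_done(out, "interactions", config)):
        per_tp = []
        for tp in tps:
            chim = pd.read_csv(_require(out / f"chimeras_{tp}.tsv", "interactions"), sep="\t")
            pk = pd.read_csv(_require(out / f"peaks_{tp}.tsv", "interactions"), sep="\t")
            inter = build_interactions(chim, timepoint=tp)
            inter = attach_peak_support(inter, pk)
            per_tp.append(inter)
        joined = join_across_timepoints(per_tp)
        joined.to_csv(out / "interactions.tsv", sep="\t", index=False)
        _write_manifest(out, "interactions", config)

    if not (resume and _stage_done(out, "energy", config)):
        inter = pd.read_csv(_require(out / "interactions.tsv", "energy"), sep="\t")
        if len(inter) >= 2 and inter.mirna_id.nunique() >= 2:
            pairs = [
                (
                    mirnas[r.mirna_id],
                    energy_mod.extract_target_context(
                        transcripts, r.transcript_id, int(r.site_start),
                        int(r.site_end), config.energy_flank,
                    ),
                )
                for r in inter.itertuples()
            ]
            real = energy_mod.interaction_mfes(pairs)
            df = inter[["interaction_id", "mirna_id", "transcript_id"]].copy()
            df["mfe"] = real
            df.to_csv(out / "energies.tsv", sep="\t", index=False)
            try:
                perm = energy_mod.shuffled_null(list(inter.mirna_id), config.rng_seed)
            except ValueError:
                perm = None  # derangement impossible at this scale; no null
            if perm is not None:
                null_pairs = [
                    (pairs[perm[t]][0], pairs[t][1]) for t in range(len(pairs))
                ]
                null = energy_mod.interaction_mfes(null_pairs)
                d_med, d_mean, p = energy_mod.energy_gap(
                    real, null, n_perm=config.energy_n_perm, rng_seed=config.rng_seed
                )
                (out / "energy_gap.json").write_text(
                    json.dumps(
                        dict(delta_median=d_med, delta_mean=d_mean, pvalue=p),
                        indent=2, sort_keys=True,
                    ) + "\n"
                )
        _write_manifest(out, "energy", config)

    if not (resume and _stage_done(out, "motifs", config)):
        targets_by: Dict[Tuple[str, str], List[str]] = {}
        for tp in tps:
            chim = pd.read_csv(_require(out / f"chimeras_{tp}.tsv", "motifs"), sep="\t")
            for r in chim.itertuples():
                targets_by.setdefault((r.mirna_id, tp), []).append(str(r.target_segment))
        usage = motifs_mod.usage_by_timepoint(
            targets_by, mirnas, tps, k=config.motif_k,
            min_targets=config.motif_min_targets, rng_seed=config.rng_seed,
        )
        usage.to_csv(out / "motif_usage.tsv", sep="\t", index=False)
        all_chim = pd.concat(
            [pd.read_csv(out / f"chimeras_{tp}.tsv", sep="\t") for tp in tps],
            ignore_index=True,
        )
        if len(all_chim) and all_chim.mirna_id.nunique() >= 2:
            try:
                dens = motifs_mod.seed_match_density(
                    all_chim, mirnas, transcripts, shuffle_seed=config.rng_seed
                )
                dens.to_csv(out / "seed_density.tsv", sep="\t", index=False)
            except ValueError:
                pass  # shuffled control impossible (dominant miRNA) at tiny scale
        _write_manifest(out, "motifs", config)

    if not (resume and _stage_done(out, "dynamics", config)):
        expr_path = _require(out / "sim" / "expression.tsv", "dynamics")
        expression = pd.read_csv(expr_path, sep="\t")
        inter = pd.read_csv(_require(out / "interactions.tsv", "dynamics"), sep="\t")
        heights_rows = []
        for tp in tps:
            pk = pd.read_csv(_require(out / f"peaks_{tp}.tsv", "dynamics"), sep="\t")
            sub = inter[(inter.timepoint == tp) & inter.peak_supported]
            by_tx: Dict[str, list] = {}
            for p in pk[pk.significant].itertuples():
                by_tx.setdefault(p.transcript_id, []).append(p)
            for r in sub.itertuples():
                best = None
                for p in by_tx.get(r.transcript_id, ()):
                    if r.site_start < p.end and p.start < r.site_end:
                        if best is None or p.height > best.height:
                            best = p
                if best is not None:
                    heights_rows.append(
                        dict(
                            interaction_id=r.group_id, transcript_id=r.transcript_id,
                            timepoint=tp, height=float(best.height),
                        )
                    )
        heights = pd.DataFrame(
            heights_rows,
            columns=["interaction_id", "transcript_id", "timepoint", "height"],
        )
        if len(heights):
            mat, dropped = normalize_matrix(heights, expression, tps)
            mat.to_csv(out / "interaction_matrix.tsv", sep="\t")
            zscore_rows(mat).to_csv(out / "interaction_matrix_z.tsv", sep="\t")
            if len(mat) >= 4:
                som = som_fit(
                    zscore_rows(mat), grid=config.som_grid,
                    epochs=config.som_epochs, rng_seed=config.rng_seed,
                )
                som.tile_of.to_csv(out / "som_tiles.tsv", sep="\t")
                corr = stage_correlation(mat)
                corr.to_csv(out / "stage_correlation.tsv", sep="\t")
        _write_manifest(out, "dynamics", config, dict(n_heights=len(heights)))

    (out / "manifest.json").write_text(
        json.dumps(
            dict(config=config.manifest_dict(), config_hash=config.content_hash(),
                 stage_version=STAGE_VERSION),
            indent=2, sort_keys=True, default=list,
        ) + "\n"
    )
    return out
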