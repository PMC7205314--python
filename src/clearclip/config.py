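"""Configuration objects for the simulator and the pipeline.

`SimulationConfig` fixes the statistical structure of the synthetic study:
read-class composition, chimera orientations, planted site classes and their
complementarity registers, per-stage activity of each interaction, PCR
duplication under a degenerate 3-nt barcode, and sequencing error rate.
Defaults emulate a CLEAR-CLIP library of an adult female mosquito time course
(five stages, chimeras a small percentage of reads, mRNA single reads the
bulk), so every downstream stage can be tested against planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

ADAPTER_3P = "AGATCGGAAGAGCACACGTCT"
BARCODE_LEN = 3

DEFAULT_TIMEPOINTS = ("3hPE", "30hPE", "120hPE", "24hPBM", "48hPBM")

# read-class composition observed in deep CLEAR-CLIP libraries
# (chimera / CLIP single read / miRNA single read / other ncRNA),
# normalized to sum to 1.
_RAW_CLASS_MIX = {"chimera": 1.70, "clip": 77.07, "mirna_only": 10.30, "ncRNA": 10.96}
_TOT = sum(_RAW_CLASS_MIX.values())
DEFAULT_READ_CLASS_MIX = {k: v / _TOT for k, v in _RAW_CLASS_MIX.items()}
DEFAULT_READ_CLASS_MIX["junk"] = 0.0

# where planted target sites fall on a transcript (5'UTR / CDS / 3'UTR)
_RAW_REGION_MIX = {"5UTR": 10.66, "CDS": 47.01, "3UTR": 42.32}
_RTOT = sum(_RAW_REGION_MIX.values())
DEFAULT_SITE_REGION_MIX = {k: v / _RTOT for k, v in _RAW_REGION_MIX.items()}

# complementarity registers per site class, 1-based inclusive miRNA positions.
# canonical = seed (nt 2-7); 3'-supplementary = nt 13-19; central = nt 9-15;
# seedless sites carry no 6-mer complementary to nt 1-8.
SITE_CLASS_REGISTERS: Dict[str, Tuple[int, int]] = {
    "canonical": (2, 7),
    "supplementary_3p": (13, 19),
    "central": (9, 15),
}


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


def _check_simplex(name: str, probs: Dict[str, float] | Tuple[float, ...]) -> None:
    vals = list(probs.values()) if isinstance(probs, dict) else list(probs)
    if any(v < 0 for v in vals):
        raise ConfigurationError(f"{name}: negative proportion")
    if abs(sum(vals) - 1.0) > 1e-9:
        raise ConfigurationError(f"{name}: proportions sum to {sum(vals)!r}, not 1")


@dataclass
class SimulationConfig:
    n_transcripts: int = 60
    transcript_len_range: Tuple[int, int] = (800, 2000)
    utr_fractions: Tuple[float, float, float] = (0.15, 0.50, 0.35)  # 5'UTR, CDS, 3'UTR
    n_ncrna: int = 6
    ncrna_len_range: Tuple[int, int] = (120, 300)
    ncrna_gc: float = 0.72  # distinctive composition so mis-mapping is detectable
    n_mirnas: int = 30
    mirna_len_range: Tuple[int, int] = (21, 23)
    n_interactions: int = 300
    site_class_mix: Dict[str, float] = field(
        default_factory=lambda: {
            "canonical": 0.60,
            "supplementary_3p": 0.15,
            "central": 0.15,
            "seedless": 0.10,
        }
    )
    site_region_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SITE_REGION_MIX)
    )
    timepoints: Tuple[str, ...] = DEFAULT_TIMEPOINTS
    n_activity_archetypes: int = 5
    n_reads: int = 50_000
    read_class_mix: Dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_READ_CLASS_MIX)
    )
    chimera_mir_first_frac: float = 0.5
    target_len_mean: float = 42.0
    target_len_sd: float = 10.0
    target_len_min: int = 16
    read_len: int = 100
    pcr_dup_rate: float = 0.15
    error_rate: float = 0.005
    low_quality_frac: float = 0.0  # fraction of reads emitted with Phred 8 quality
    rng_seed: int = 0

    def validate(self) -> "SimulationConfig":
        _check_simplex("utr_fractions", self.utr_fractions)
        _check_simplex("site_class_mix", self.site_class_mix)
        _check_simplex("site_region_mix", self.site_region_mix)
        _check_simplex("read_class_mix", self.read_class_mix)
        if not 0.0 <= self.chimera_mir_first_frac <= 1.0:
            raise ConfigurationError("chimera_mir_first_frac outside [0, 1]")
        if self.mirna_len_range[0] < 18:
            raise ConfigurationError("miRNAs shorter than 18 nt are not supported")
        for cls in self.site_class_mix:
            if cls != "seedless" and cls not in SITE_CLASS_REGISTERS:
                raise ConfigurationError(f"unknown site class {cls!r}")
        return self

    def to_dict(self) -> dict:
        return asdict(self)
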