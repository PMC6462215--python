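"""Configuration objects for the simulator and the analysis pipeline.

Two dataclasses carry every tunable: :class:`SimConfig` describes the
synthetic ChIP-nexus experiment (genome, planted sites, hormone-condition
occupancy, read model) and :class:`PipelineConfig` the analysis parameters
(quality filters, peak calling, annotation flank, border widths, the
co-positioning half-width and motif windows).  Both round-trip through YAML
so a single file can drive the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Tuple

import yaml

#: Hormone conditions: vehicle, a 20-min corticosterone pulse, and a pulse
#: followed by washout.
CONDITIONS: Tuple[str, ...] = ("vehicle", "CORT", "washout")

#: The two corticosteroid receptors profiled.
FACTORS: Tuple[str, ...] = ("MR", "GR")


def default_occupancy() -> Dict[str, Dict[str, float]]:
    """Per-condition, per-factor binding probability at a capable site.

    Encodes the affinity asymmetry of the dual-receptor system: both
    receptors are fully liganded during the CORT pulse; after washout the
    high-affinity MR retains roughly a third of its sites while the
    low-affinity GR retains only a few percent; vehicle binding is near
    zero for both.
    """
    return {
        "vehicle": {"MR": 0.005, "GR": 0.005},
        "CORT": {"MR": 1.0, "GR": 1.0},
        "washout": {"MR": 0.33, "GR": 0.023},
    }


class ConfigError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass
class SimConfig:
    """Parameters of the synthetic ChIP-nexus experiment.

    Attributes
    ----------
    genome_length : int
        Length of the synthetic chromosome in bases.
    gc_content : float
        GC fraction of the background sequence (mouse-like 0.41 default).
    n_sites : int
        Number of planted receptor binding sites.
    co_binding_fraction : float
        Fraction of sites capable of binding both factors; the remainder
        are split evenly between MR-only and GR-only sites.
    motif_fraction : float
        Fraction of sites carrying the GRE consensus at their midpoint.
    protected_width : int
        Border-to-border width of the exonuclease-protected region (bp).
    occupancy : dict
        condition -> factor -> probability that a capable site is bound.
    reads_per_bound_site : int
        Unique (pre-duplication) reads emitted per bound site, split
        between strands.
    background_read_rate : float
        Non-specific reads per kilobase in an immunoprecipitated sample.
    input_read_rate : float
        Reads per kilobase in the input (no-IP) control sample.
    duplication_rate : float
        Fraction of the final read stream that are PCR re-emissions of an
        earlier read (identical position, strand and barcode).
    border_jitter : int
        Maximal uniform jitter (bp) of a read 5' stop around its border.
    insert_length : int
        Genomic insert length per read (bp).
    barcode_length : int
        Random-barcode length prepended to each read.
    base_quality : int
        Constant Phred score assigned to simulated bases.
    seed : int
        Master seed; the whole module is deterministic given it.
    """

    genome_length: int = 200_000
    gc_content: float = 0.41
    n_sites: int = 100
    co_binding_fraction: float = 0.66
    motif_fraction: float = 0.58
    protected_width: int = 30
    occupancy: Dict[str, Dict[str, float]] = field(default_factory=default_occupancy)
    reads_per_bound_site: int = 100
    background_read_rate: float = 0.5
    input_read_rate: float = 5.0
    duplication_rate: float = 0.1
    border_jitter: int = 2
    insert_length: int = 50
    barcode_length: int = 9
    base_quality: int = 35
    chrom: str = "chr1"
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.genome_length <= 0:
            raise ConfigError("genome_length must be positive")
        for name in ("gc_content", "co_binding_fraction", "motif_fraction",
                     "duplication_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")
        if self.protected_width < 1:
            raise ConfigError("protected_width must be >= 1")
        if self.n_sites < 0:
            raise ConfigError("n_sites must be non-negative")
        if self.barcode_length < 1:
            raise ConfigError("barcode_length must be >= 1")
        for cond, byfac in self.occupancy.items():
            for fac, p in byfac.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigError(
                        f"occupancy[{cond}][{fac}] must lie in [0, 1], got {p}")


@dataclass
class PipelineConfig:
    """Analysis parameters.

    Defaults follow the published processing scheme: reads are trimmed at
    the first 4-base window with mean Phred < 20, dropped under 29 bp and
    capped at 59 bp (9-bp barcode plus 50-bp insert); alignments with
    MAPQ <= 20 are discarded; peaks are 100 bp wide at FDR < 0.05; gene
    annotation uses a 5 kb flank; border-pair widths span 10-100 bp; the
    co-positioning window extends 155 nt either side of the reference
    midpoint; motifs are scanned in +/-100 and +/-200 bp summit windows.
    """

    qual_window: int = 4
    qual_threshold: int = 20
    min_len: int = 29
    max_len: int = 59
    barcode_length: int = 9
    mapq_min: int = 21            # retain mapq > 20
    peak_fdr: float = 0.05
    peak_width: int = 100
    peak_step: int = 10
    pileup_extension: int = 50    # read extension used for the summit pileup
    lambda_windows: Tuple[int, ...] = (1000, 10000)
    pseudocount: float = 1.0
    flank: int = 5000
    motif_windows: Tuple[int, ...] = (100, 200)
    min_score_fraction: float = 0.8
    border_width_range: Tuple[int, int] = (10, 100)
    border_margin: int = 100
    border_min_count: int = 5
    cobind_halfwidth: int = 155

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ConfigError("min_len must not exceed max_len")
        for name in ("qual_window", "peak_width", "flank", "cobind_halfwidth"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        lo, hi = self.border_width_range
        if not (0 < lo <= hi):
            raise ConfigError("border_width_range must satisfy 0 < min <= max")


def load_config(path) -> Tuple[SimConfig, PipelineConfig]:
    """Read a YAML file with optional ``simulate:`` and ``pipeline:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = SimConfig(**(raw.get("simulate") or {}))
    pipe_raw = dict(raw.get("pipeline") or {})
    for key in ("lambda_windows", "motif_windows", "border_width_range"):
        if key in pipe_raw:
            pipe_raw[key] = tuple(pipe_raw[key])
    pipe = PipelineConfig(**pipe_raw)
    return sim, pipe


def dump_config(sim: SimConfig, pipe: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump({"simulate": asdict(sim), "pipeline": asdict(pipe)},
                       fh, sort_keys=False)
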