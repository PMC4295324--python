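"""Configuration objects for the synthetic methylome generator and the pipeline.

All tunable parameters of the simulation live in :class:`SimulationConfig`;
analysis-stage thresholds live next to the code that applies them and are
surfaced again in :class:`RunConfig` for the end-to-end pipeline.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import yaml

#: Developmental stages, ordered. Pre-implantation blastocyst (E3.5, E4.5)
#: followed by post-implantation epiblast/embryo stages.
DEFAULT_STAGES = ("E3.5", "E4.5", "E5.5", "E6.5", "E7.5", "E8.5")

GENOTYPES = ("WT", "Dnmt3aKO", "Dnmt3bKO")

#: CGI truth classes the simulator can plant.
CGI_CLASSES = ("protected", "fast", "slow", "pm", "gdmr", "sdmr", "xlinked")


def _stage_time(stage: str) -> float:
    """Numeric embryonic day of a stage label like 'E5.5'."""
    return float(stage.lstrip("E"))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic RRBS-like dataset.

    The per-stage kinetic vectors are generative stand-ins for the empirical
    trajectories of early mouse development: a hypomethylated blastocyst,
    a rapid genome-wide gain at implantation (bulk 12% -> 62% between E4.5
    and E5.5), slower gain at a subset of CpG islands, stable ~50% aggregate
    methylation at imprinted germline DMRs, and genotype-dependent losses in
    Dnmt3a/Dnmt3b knockouts.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 400_000
    x_chrom: bool = True  # last chromosome is named chrX and flagged
    n_genes: int = 32
    n_cgis_per_class: Mapping[str, int] = field(
        default_factory=lambda: {
            "protected": 6,
            "fast": 6,
            "slow": 6,
            "pm": 6,
            "gdmr": 4,
            "sdmr": 4,
            "xlinked": 4,
        }
    )
    n_te: int = 30
    stage_list: Sequence[str] = DEFAULT_STAGES
    genotypes: Sequence[str] = GENOTYPES
    ko_stages: Sequence[str] = ("E8.5",)
    mean_depth: float = 30.0
    conversion_error: float = 0.004
    # per-stage methylation probability of non-CGI background CpGs in WT
    bulk_kinetics: Sequence[float] = (0.08, 0.12, 0.62, 0.75, 0.80, 0.82)
    fast_cgi_kinetics: Sequence[float] = (0.05, 0.10, 0.60, 0.70, 0.75, 0.78)
    slow_cgi_kinetics: Sequence[float] = (0.05, 0.08, 0.20, 0.35, 0.55, 0.70)
    protected_level: float = 0.03
    # pmCGI per-allele per-CpG methylation probability at the last stage;
    # earlier stages follow a fixed rising shape scaled by this level
    pm_level: float = 0.35
    pm_shape: Sequence[float] = (0.086, 0.143, 0.286, 0.514, 0.80, 1.0)
    gdmr_allele_meth: float = 0.95
    gdmr_allele_unmeth: float = 0.02
    sdmr_mat_kinetics: Sequence[float] = (0.15, 0.20, 0.35, 0.55, 0.75, 0.90)
    sdmr_pat_level: float = 0.05
    # knockout offsets applied to the background (bulk) probability
    ko_bulk_offset: float = 0.10
    fast_3bko_offset: float = 0.10
    fast_3ako_offset: float = 0.05
    # read-pattern generation (single-molecule analysis)
    reads_per_cgi: int = 60
    read_cpgs_min: int = 3
    read_cpgs_max: int = 6
    # genome layout
    min_cgi_len: int = 320
    max_cgi_len: int = 650
    n_noncpg_sites: int = 2000
    sex: str = "F"

    def __post_init__(self) -> None:
        times = [_stage_time(s) for s in self.stage_list]
        if not all(a < b for a, b in zip(times, times[1:])):
            raise ValueError("stage_list must be strictly ordered")
        if self.mean_depth < 1:
            raise ValueError("mean_depth must be >= 1")
        if self.chrom_length < 10_000:
            raise ValueError("chrom_length must be >= 10000")
        for name in (
            "bulk_kinetics",
            "fast_cgi_kinetics",
            "slow_cgi_kinetics",
            "sdmr_mat_kinetics",
            "pm_shape",
        ):
            vec = getattr(self, name)
            if len(vec) != len(self.stage_list):
                raise ValueError(f"{name} must have one value per stage")
            if not all(0.0 <= v <= 1.0 for v in vec):
                raise ValueError(f"{name} values must be in [0, 1]")
        for name in (
            "conversion_error",
            "protected_level",
            "pm_level",
            "gdmr_allele_meth",
            "gdmr_allele_unmeth",
            "sdmr_pat_level",
            "ko_bulk_offset",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0, 1]")
        unknown = set(self.n_cgis_per_class) - set(CGI_CLASSES)
        if unknown:
            raise ValueError(f"unknown CGI classes: {sorted(unknown)}")

    @property
    def stage_index(self) -> Mapping[str, int]:
        return {s: i for i, s in enumerate(self.stage_list)}

    @property
    def pm_kinetics(self) -> tuple:
        return tuple(f * self.pm_level for f in self.pm_shape)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["n_cgis_per_class"] = dict(self.n_cgis_per_class)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        kwargs = dict(d)
        for k in (
            "stage_list",
            "genotypes",
            "ko_stages",
            "bulk_kinetics",
            "fast_cgi_kinetics",
            "slow_cgi_kinetics",
            "sdmr_mat_kinetics",
            "pm_shape",
        ):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(**kwargs)


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration.

    In synthetic mode (``simulation`` set) the pipeline first writes the
    generated inputs into the run directory; in file mode the sample sheet,
    genome and annotation paths must be provided.
    """

    out_dir: str = "methkin_run"
    seed: int = 0
    simulation: SimulationConfig | None = None
    sample_sheet: str | None = None
    genome_fasta: str | None = None
    genes_bed: str | None = None
    dmr_bed: str | None = None
    x_chroms: Sequence[str] = ("chrX",)
    # analysis thresholds (defaults as in the published procedure)
    min_depth: int = 8
    tile_size: int = 400
    min_cpg_per_tile: int = 3
    transition_delta: float = 0.20
    de_novo_low: float = 0.20
    de_novo_high: float = 0.50
    ko_delta: float = 0.10
    dnmt3b_target_delta: float = 0.60
    pm_band: Sequence[float] = (0.15, 0.60)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.simulation is not None:
            d["simulation"] = self.simulation.to_dict()
        d["pm_band"] = list(self.pm_band)
        d["x_chroms"] = list(self.x_chroms)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        kwargs = dict(d)
        if kwargs.get("simulation") is not None:
            kwargs["simulation"] = SimulationConfig.from_dict(kwargs["simulation"])
        if "pm_band" in kwargs:
            kwargs["pm_band"] = tuple(kwargs["pm_band"])
        if "x_chroms" in kwargs:
            kwargs["x_chroms"] = tuple(kwargs["x_chroms"])
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        """Stable short hash of the configuration, stamped on outputs.

        The output directory is a location, not a parameter, and is
        excluded so identical analyses hash identically wherever they run.
        """
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
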