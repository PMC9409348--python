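"""Configuration objects for the simulator and the end-to-end pipeline.

All numeric thresholds used anywhere in the pipeline live in
:class:`RunConfig`; stage functions receive them explicitly so that every
cut-off (quality 30, depth gate 2, exclusive-coverage 10/3, 10 kb window,
cluster threshold 30, dS range 0.01-2) is auditable in one place.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

WINDOW_BP = 10_000

FEMALE = "female"
MALE = "male"


class ConfigurationError(ValueError):
    """Raised when a simulation or run configuration is internally impossible."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic two-species, two-sex cohort.

    The defaults describe the standard test cohort: 10 diploid-coded samples
    (5 male, 5 female) over 2 contigs of 100 kb, mean depth 20 (the real
    cohort's per-sample depth was ~17-23), three planted 10 kb clusters of
    40 male-homozygous/female-het-or-absent variants, ~200 background
    heterozygous noise records, 50 low-quality decoy records, and one
    sex-exclusive coverage block per sex.
    """

    seed: int = 0
    n_contigs: int = 2
    contig_length_bp: int = 100_000
    n_male: int = 5
    n_female: int = 5
    mean_depth: float = 20.0
    #: probability per bp per sample of a background 0/1 noise record
    background_het_rate: float = 1.0e-4
    #: probability per bp of a species-fixed site (1/1 in every sample)
    fixed_diff_rate: float = 5.0e-4
    #: (contig, window_start_bp, n_variants); window_start_bp is 1-based and
    #: must be a 10 kb window boundary + 1
    planted_clusters: list[tuple[str, int, int]] = field(
        default_factory=lambda: [
            ("contig_1", 20_001, 40),
            ("contig_1", 50_001, 40),
            ("contig_2", 30_001, 40),
        ]
    )
    #: number of low-quality decoy records (QUAL in [0, 30]) planted at
    #: positions disjoint from every other truth category
    n_lowqual_decoys: int = 50
    #: fraction of species-fixed sites emitted as 1 bp indels rather than SNPs
    indel_fraction: float = 0.1
    #: (contig, start_bp, end_bp, zero_sex) 1-based inclusive blocks where
    #: every sample of zero_sex has depth 0
    sex_exclusive_blocks: list[tuple[str, int, int, str]] = field(
        default_factory=lambda: [
            ("contig_2", 70_001, 71_000, "female"),
            ("contig_2", 80_001, 81_000, "male"),
        ]
    )
    n_genes: int = 4
    gene_length_bp: int = 2_001
    n_ortholog_pairs: int = 8

    def __post_init__(self) -> None:
        if self.n_male < 1 or self.n_female < 1:
            raise ConfigurationError("need at least one sample of each sex")
        if self.contig_length_bp < 3 * WINDOW_BP:
            raise ConfigurationError(
                f"contig_length_bp must be >= {3 * WINDOW_BP} (three 10 kb windows), "
                f"got {self.contig_length_bp}"
            )
        contigs = set(self.contig_names)
        for contig, start, n in self.planted_clusters:
            if contig not in contigs:
                raise ConfigurationError(f"planted cluster on unknown contig {contig!r}")
            if (start - 1) % WINDOW_BP != 0:
                raise ConfigurationError(
                    f"cluster start {start} is not a 10 kb window boundary (1, 10001, ...)"
                )
            if start + WINDOW_BP - 1 > self.contig_length_bp:
                raise ConfigurationError(
                    f"cluster window [{start}, {start + WINDOW_BP - 1}] exceeds contig length"
                )
            if n > WINDOW_BP:
                raise ConfigurationError(
                    f"cannot plant {n} variants in a {WINDOW_BP} bp window"
                )
        for contig, start, end, zero_sex in self.sex_exclusive_blocks:
            if contig not in contigs:
                raise ConfigurationError(f"exclusive block on unknown contig {contig!r}")
            if zero_sex not in (MALE, FEMALE):
                raise ConfigurationError(f"zero_sex must be male/female, got {zero_sex!r}")
            if not (1 <= start <= end <= self.contig_length_bp):
                raise ConfigurationError(f"exclusive block [{start}, {end}] out of range")
            for ccontig, cstart, _ in self.planted_clusters:
                if ccontig == contig and start <= cstart + WINDOW_BP - 1 and cstart <= end:
                    raise ConfigurationError(
                        "sex_exclusive_blocks must not overlap planted clusters"
                    )
        if self.n_genes * self.gene_length_bp > self.contig_length_bp:
            raise ConfigurationError(
                f"{self.n_genes} genes of {self.gene_length_bp} bp do not fit in a "
                f"{self.contig_length_bp} bp contig"
            )

    @property
    def contig_names(self) -> list[str]:
        return [f"contig_{i + 1}" for i in range(self.n_contigs)]

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {name: self.contig_length_bp for name in self.contig_names}

    @property
    def sample_names(self) -> list[str]:
        males = [f"male_{i + 1}" for i in range(self.n_male)]
        females = [f"female_{i + 1}" for i in range(self.n_female)]
        return males + females

    @property
    def sex_of(self) -> dict[str, str]:
        return {
            s: (MALE if s.startswith("male") else FEMALE) for s in self.sample_names
        }

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["planted_clusters"] = [list(t) for t in self.planted_clusters]
        d["sex_exclusive_blocks"] = [list(t) for t in self.sex_exclusive_blocks]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        d["planted_clusters"] = [tuple(t) for t in d.get("planted_clusters", [])]
        d["sex_exclusive_blocks"] = [tuple(t) for t in d.get("sex_exclusive_blocks", [])]
        return cls(**d)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration: paths, thresholds, seed, manifest."""

    out_dir: str = "run_output"
    seed: int = 0
    #: variant records must have QUAL strictly greater than this to pass
    min_qual: float = 30.0
    #: sex-associated sites require depth strictly greater than this in all samples
    min_depth_exclusive: int = 2
    #: sex-exclusive coverage: the covered sex needs depth >= this ...
    exclusive_min_depth: int = 10
    #: ... in at least this many samples
    exclusive_min_samples: int = 3
    window: int = WINDOW_BP
    cluster_threshold: int = 30
    ds_lo: float = 0.01
    ds_hi: float = 2.0
    #: depth >= this counts a position as "covered" in coverage summaries
    coverage_min_depth: int = 1
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.ds_lo >= self.ds_hi:
            raise ConfigurationError("ds_lo must be < ds_hi")
        if self.cluster_threshold < 1:
            raise ConfigurationError("cluster_threshold must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "RunConfig":
        d = dict(d)
        if "simulation" in d:
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
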