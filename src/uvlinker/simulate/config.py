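"""Simulation configuration."""

from __future__ import annotations

from dataclasses import dataclass, field

from ..errors import ConfigError

#: gene classes recognized by the reference simulator, mapped to the segment
#: class their genes live on
GENE_CLASS_SEGMENTS = {
    "autosomal": "autosome",
    "male_specific": "V",
    "male_allele": "V",
    "female_specific": "U",
    "female_allele": "U",
    "mitochondrial": "mito",
    "chloroplast": "chloro",
}

SEGMENT_CLASSES = ("autosome", "U", "V", "mito", "chloro", "contaminant")


def _default_genes() -> dict[str, int]:
    return {
        "autosomal": 30,
        "male_specific": 6,
        "female_specific": 6,
        "male_allele": 4,
        "female_allele": 4,
        "mitochondrial": 6,
        "chloroplast": 6,
    }


@dataclass
class SimConfig:
    """Parameters of one synthetic study.

    Lengths are bp, GC values are fractions, ``depth`` is fold coverage per
    sample. The defaults describe a desk-scale genome: three 100 kb
    autosomes, 50 kb U and V chromosomes, two organelles, and a high-GC
    contaminant fraction — the same qualitative structure as a ~45% GC plant
    host sequenced together with a ~65% GC microbial community.
    """

    n_autosomes: int = 3
    autosome_len: int = 100_000
    u_len: int = 50_000
    v_len: int = 50_000
    organelle_lens: tuple[int, ...] = (20_000, 15_000)
    host_gc: float = 0.45
    contam_gc: float = 0.65
    n_contaminants: int = 2
    contam_len: int = 30_000
    contam_read_fraction: float = 0.0
    read_len: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 20.0
    organelle_depth_multiplier: float = 10.0
    error_rate: float = 0.0
    n_genes_per_class: dict[str, int] = field(default_factory=_default_genes)
    gene_len: int = 900
    omega_truth: float = 0.5
    kappa: float = 1.0
    branch_divergence: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_autosomes < 0 or self.u_len < 0 or self.v_len < 0:
            raise ConfigError("segment counts/lengths must be non-negative")
        if self.n_autosomes > 0 and self.autosome_len <= 0:
            raise ConfigError("autosome_len must be > 0 when autosomes requested")
        if any(l <= 0 for l in self.organelle_lens):
            raise ConfigError("zero-length organelle segment requested")
        if self.n_contaminants > 0 and self.contam_len <= 0:
            raise ConfigError("contam_len must be > 0 when contaminants requested")
        for name in ("host_gc", "contam_gc", "contam_read_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name}={v} outside [0, 1]")
        if self.read_len <= 0 or self.depth < 0:
            raise ConfigError("read_len must be > 0 and depth >= 0")
        if self.gene_len <= 0 or self.gene_len % 3:
            raise ConfigError("gene_len must be a positive multiple of 3")
        if self.omega_truth < 0 or self.kappa < 1:
            raise ConfigError("require omega >= 0 and kappa >= 1")
        if self.error_rate < 0 or self.error_rate > 1:
            raise ConfigError("error_rate outside [0, 1]")
        unknown = set(self.n_genes_per_class) - set(GENE_CLASS_SEGMENTS)
        if unknown:
            raise ConfigError(f"unknown gene classes: {sorted(unknown)}")
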