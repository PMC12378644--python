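"""Shared domain types for the spike-in quantification pipeline.

Coordinates are 0-based, half-open throughout. Abundance units are per
liter of filtered water; genome copies are haploid genome equivalents
(cells carry ``ploidy`` haploid copies each).
"""

from __future__ import annotations

from dataclasses import dataclass, field

DOMAIN_LABELS = ("bacteria", "archaea", "cyanobacteria", "eukaryote_phytoplankton")
MARKER_NAMES = ("recA", "radA", "psbO")

#: marker genes carried per haploid genome, by domain label
DOMAIN_MARKERS = {
    "bacteria": ("recA",),
    "archaea": ("radA",),
    "cyanobacteria": ("recA", "psbO"),
    "eukaryote_phytoplankton": ("psbO",),
}

STANDARD_CLASS = "standard_gene"
REFERENCE_CLASSES = (STANDARD_CLASS,) + MARKER_NAMES


@dataclass(frozen=True)
class MarkerLocus:
    """A single-copy gene locus on a genome (0-based, half-open)."""

    marker_name: str
    start: int
    end: int
    sequence: str

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"locus end ({self.end}) must exceed start ({self.start})")
        if len(self.sequence) != self.end - self.start:
            raise ValueError(
                f"sequence length {len(self.sequence)} != span {self.end - self.start}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


def _check_loci(loci: list[MarkerLocus], genome_length: int, owner: str) -> None:
    prev_end = -1
    for loc in sorted(loci, key=lambda l: l.start):
        if loc.start < 0 or loc.end > genome_length:
            raise ValueError(f"{owner}: locus [{loc.start},{loc.end}) outside genome")
        if loc.start < prev_end:
            raise ValueError(f"{owner}: overlapping loci")
        prev_end = loc.end


@dataclass
class TaxonSpec:
    """One community member: genome layout, ploidy, and true abundance."""

    taxon_id: str
    domain_label: str
    genome_length: int
    ploidy: int
    markers: list[MarkerLocus]
    true_cells_per_liter: float
    genome_sequence: str = ""

    def __post_init__(self) -> None:
        if self.domain_label not in DOMAIN_LABELS:
            raise ValueError(f"unknown domain_label {self.domain_label!r}")
        if self.ploidy < 1:
            raise ValueError("ploidy must be >= 1")
        if self.true_cells_per_liter < 0:
            raise ValueError("true_cells_per_liter must be >= 0")
        _check_loci(self.markers, self.genome_length, self.taxon_id)
        names = [m.marker_name for m in self.markers]
        if len(names) != len(set(names)):
            raise ValueError(f"{self.taxon_id}: duplicate marker on haploid genome")
        expected = set(DOMAIN_MARKERS[self.domain_label])
        if set(names) != expected:
            raise ValueError(
                f"{self.taxon_id}: domain {self.domain_label} requires markers "
                f"{sorted(expected)}, got {sorted(names)}"
            )
        if self.genome_sequence and len(self.genome_sequence) != self.genome_length:
            raise ValueError(f"{self.taxon_id}: genome sequence length mismatch")

    def marker(self, name: str) -> MarkerLocus:
        for m in self.markers:
            if m.marker_name == name:
                return m
        raise KeyError(name)


@dataclass
class StandardSpec:
    """A spiked genomic internal standard.

    ``s_p`` is the number of protein-coding genes in the standard genome
    (the denominator that converts standard-gene read counts into genome
    copies recovered); ``s_a`` is the number of genome copies added.
    """

    standard_id: str
    genome_length: int
    s_p: int
    gene_loci: list[MarkerLocus]
    s_a: float
    genome_sequence: str = ""

    def __post_init__(self) -> None:
        if self.s_p < 1:
            raise ValueError("s_p must be >= 1")
        if self.s_a <= 0:
            raise ValueError("s_a must be > 0")
        if len(self.gene_loci) != self.s_p:
            raise ValueError("number of gene loci must equal s_p")
        _check_loci(self.gene_loci, self.genome_length, self.standard_id)
        if self.genome_sequence and len(self.genome_sequence) != self.genome_length:
            raise ValueError(f"{self.standard_id}: genome sequence length mismatch")


@dataclass
class SampleSpec:
    """Per-sample simulation/metadata parameters."""

    sample_id: str
    volume_liters: float
    n_reads: int
    read_length: int
    per_marker_sensitivity: dict[str, float] = field(default_factory=dict)
    seed: int = 0
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.volume_liters <= 0:
            raise ValueError("volume_liters must be > 0")
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")
        if self.error_rate < 0:
            raise ValueError("error rate must be >= 0")
        for name, s in self.per_marker_sensitivity.items():
            if not (0 < s <= 1):
                raise ValueError(f"sensitivity for {name} must lie in (0, 1]")

    def sensitivity(self, marker_name: str) -> float:
        return self.per_marker_sensitivity.get(marker_name, 1.0)


@dataclass
class CommunityTruth:
    """Ground-truth community for one sample."""

    sample_id: str
    taxa: list[TaxonSpec]

    def taxon(self, taxon_id: str) -> TaxonSpec:
        for t in self.taxa:
            if t.taxon_id == taxon_id:
                return t
        raise KeyError(taxon_id)
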