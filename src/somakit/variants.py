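"""Shared somatic/germline variant containers."""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["SomaticVariant", "GermlineVariant", "PloidyAnnotation"]


@dataclass
class SomaticVariant:
    """One somatic small variant with read support.

    ``pos`` is 1-based (VCF convention).  ``context`` carries the
    pyrimidine-centred trinucleotide substitution class of an SNV, e.g.
    ``"A[C>T]G"``.  ``phase_set`` groups variants on one haplotype and is
    the basis for MNV merging.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    vtype: str                      # SNV | MNV | INDEL
    alt_count: int
    depth: int
    phase_set: int | None = None
    gene: str | None = None
    consequence: str | None = None  # synonymous|missense|nonsense|splice|...
    context: str | None = None
    clone_ccf: float | None = None  # simulation truth, absent on real input

    def __post_init__(self):
        if self.depth < 0 or not (0 <= self.alt_count <= max(self.depth, 1)):
            raise ValueError("invalid read support")
        if self.vtype == "MNV" and len(self.ref) < 2:
            raise ValueError("MNV must span >= 2 nucleotides")
        if self.vtype == "INDEL" and len(self.ref) == len(self.alt):
            raise ValueError("INDEL must change length")

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class GermlineVariant:
    """Heterozygous/homozygous germline variant with tumour read support."""

    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str | None
    genotype: str                   # HET | HOM
    pathogenic: bool = True
    consequence: str | None = None
    alt_count: int = 0              # normal-sample support
    depth: int = 0
    tumour_alt_count: int = 0
    tumour_depth: int = 0

    @property
    def tumour_vaf(self) -> float:
        return (self.tumour_alt_count / self.tumour_depth
                if self.tumour_depth else 0.0)

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class PloidyAnnotation:
    """Variant ploidy, biallelic status and clonality membership."""

    variant_ploidy: float
    local_cn: float
    biallelic: bool
    clonal_prob: float = 1.0
    subclonal_prob: float = 0.0
    driver_likelihood: float = 0.0

    def __post_init__(self):
        if self.variant_ploidy < 0:
            raise ValueError("variant ploidy must be >= 0")
        if abs(self.clonal_prob + self.subclonal_prob - 1.0) > 1e-9:
            raise ValueError("clonal + subclonal probability must equal 1")
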