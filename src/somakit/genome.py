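"""Genome, gene and microsatellite models.

The package operates on a self-contained genome description rather than a
reference FASTA: chromosomes with lengths, gene models with exon structure and
a synthetic coding sequence (used for consequence annotation and dN/dS
opportunity counting), and microsatellite annotations (used by the MSI
scorer).  The default build is a "mini" genome whose chromosome lengths are
GRCh37 scaled down 30-fold, which keeps whole-cohort simulations desk-sized
while preserving per-autosome logic such as the WGD rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np

__all__ = [
    "Chromosome",
    "GeneModel",
    "Microsatellite",
    "GenomeModel",
    "build_mini_genome",
    "GRCH37_LENGTHS",
    "ACMG_CANCER_GENES",
    "CURATED_GERMLINE_GENES",
    "GERMLINE_PANEL",
]

#: GRCh37 chromosome lengths in bp.
GRCH37_LENGTHS = {
    "1": 249250621, "2": 243199373, "3": 198022430, "4": 191154276,
    "5": 180915260, "6": 171115067, "7": 159138663, "8": 146364022,
    "9": 141213431, "10": 135534747, "11": 135006516, "12": 133851895,
    "13": 115169878, "14": 107349540, "15": 102531392, "16": 90354753,
    "17": 81195210, "18": 78077248, "19": 59128983, "20": 63025520,
    "21": 48129895, "22": 51304566, "X": 155270560, "Y": 59373566,
}

#: The 25 cancer-related genes of the ACMG secondary-findings list (v2.0).
ACMG_CANCER_GENES = (
    "APC", "BMPR1A", "BRCA1", "BRCA2", "MEN1", "MLH1", "MSH2", "MSH6",
    "MUTYH", "NF2", "PMS2", "PTEN", "RB1", "RET", "SDHAF2", "SDHB", "SDHC",
    "SDHD", "SMAD4", "STK11", "TP53", "TSC1", "TSC2", "VHL", "WT1",
)

#: Additional curated germline predisposition genes.
CURATED_GERMLINE_GENES = ("CDKN2A", "CHEK2", "BAP1", "ATM")

#: High-confidence germline predisposition panel (29 genes).
GERMLINE_PANEL = ACMG_CANCER_GENES + CURATED_GERMLINE_GENES

_STOPS = {"TAA", "TAG", "TGA"}

_CODON_TABLE = {}


def _codon_table() -> dict:
    """Standard genetic code as a codon -> amino-acid dict (stop = '*')."""
    if _CODON_TABLE:
        return _CODON_TABLE
    bases = "TCAG"
    aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
    i = 0
    for b1 in bases:
        for b2 in bases:
            for b3 in bases:
                _CODON_TABLE[b1 + b2 + b3] = aas[i]
                i += 1
    return _CODON_TABLE


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    is_autosome: bool

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: length must be > 0")


@dataclass(frozen=True)
class Microsatellite:
    """A short tandem repeat locus: ``unit_length`` 1 (homopolymer) to 4."""

    chrom: str
    start: int
    end: int
    unit_length: int
    repeat_count: int


@dataclass
class GeneModel:
    """Gene with exon structure and a synthetic coding sequence.

    Exons are half-open genomic intervals, ordered and disjoint; in this
    model every exonic base is coding ('+' strand throughout), so the CDS is
    the concatenation of the exon sequences and maps 1:1 onto exonic
    positions.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    role_label: str = "none"  # oncogene | tsg | none (simulation truth)
    is_panel: bool = False
    cds_seq: str = ""

    def __post_init__(self):
        if not self.exons:
            raise ValueError(f"{self.gene_id}: no exons")
        last = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon ({s},{e})")
            if last is not None and s < last:
                raise ValueError(f"{self.gene_id}: exons overlap or unordered")
            last = e
        if self.cds_seq and len(self.cds_seq) != self.coding_length:
            raise ValueError(f"{self.gene_id}: CDS length mismatch")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def length_bp(self) -> int:
        return self.end - self.start

    @property
    def coding_start(self) -> int:
        return self.start

    @property
    def coding_end(self) -> int:
        return self.end

    @property
    def coding_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def promoter(self) -> tuple[int, int]:
        """1 kb upstream window used for promoter-variant classification."""
        return (max(0, self.start - 1000), self.start)

    def contains(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def genomic_to_cds(self, pos: int) -> int | None:
        """0-based CDS index of a genomic position, or None if intronic."""
        off = 0
        for s, e in self.exons:
            if s <= pos < e:
                return off + (pos - s)
            off += e - s
        return None

    def cds_to_genomic(self, idx: int) -> int:
        off = 0
        for s, e in self.exons:
            if idx < off + (e - s):
                return s + (idx - off)
            off += e - s
        raise IndexError(f"{self.gene_id}: CDS index {idx} out of range")

    def exon_phase(self, exon_index: int) -> int:
        """Phase (CDS length mod 3) at the start of the given exon."""
        return sum(e - s for s, e in self.exons[:exon_index]) % 3

    def codon(self, cds_idx: int) -> tuple[str, int]:
        """Codon containing a CDS index and the position (0-2) within it."""
        ci = cds_idx // 3
        return self.cds_seq[3 * ci: 3 * ci + 3], cds_idx % 3

    def consequence(self, pos: int, ref: str, alt: str) -> str:
        """Coding consequence of an SNV at a genomic position.

        Returns one of 'synonymous', 'missense', 'nonsense', 'splice',
        'promoter' or 'intronic'/'intergenic' for non-coding positions.
        """
        idx = self.genomic_to_cds(pos)
        if idx is None:
            p0, p1 = self.promoter
            if p0 <= pos < p1:
                return "promoter"
            # splice: within 2 bp of an internal exon boundary
            for i, (s, e) in enumerate(self.exons):
                if i > 0 and s - 2 <= pos < s:
                    return "splice"
                if i < len(self.exons) - 1 and e <= pos < e + 2:
                    return "splice"
            return "intronic" if self.contains(pos) else "intergenic"
        table = _codon_table()
        codon, within = self.codon(idx)
        if codon[within] != ref:
            # tolerated: callers may pass signature-driven ref alleles
            codon = codon[:within] + ref + codon[within + 1:]
        new = codon[:within] + alt + codon[within + 1:]
        aa_ref, aa_alt = table[codon], table[new]
        if aa_alt == aa_ref:
            return "synonymous"
        if aa_alt == "*":
            return "nonsense"
        if aa_ref == "*":
            return "missense"  # stop-loss folded into missense
        return "missense"


@dataclass
class GenomeModel:
    chromosomes: list[Chromosome]
    genes: list[GeneModel] = field(default_factory=list)
    microsatellites: list[Microsatellite] = field(default_factory=list)

    def __post_init__(self):
        lengths = {c.name: c.length for c in self.chromosomes}
        for g in self.genes:
            if g.chrom not in lengths or g.end > lengths[g.chrom]:
                raise ValueError(f"gene {g.gene_id} outside chromosome")
        for m in self.microsatellites:
            if m.chrom not in lengths or m.end > lengths[m.chrom]:
                raise ValueError("microsatellite outside chromosome")

    @cached_property
    def _chrom_map(self) -> dict[str, Chromosome]:
        return {c.name: c for c in self.chromosomes}

    @cached_property
    def _gene_map(self) -> dict[str, GeneModel]:
        return {g.gene_id: g for g in self.genes}

    def chromosome(self, name: str) -> Chromosome:
        return self._chrom_map[name]

    def gene(self, gene_id: str) -> GeneModel:
        return self._gene_map[gene_id]

    @property
    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.is_autosome]

    @property
    def length_bp(self) -> int:
        return sum(c.length for c in self.chromosomes)

    @property
    def length_mb(self) -> float:
        return self.length_bp / 1e6

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return sorted((g for g in self.genes if g.chrom == chrom),
                      key=lambda g: g.start)

    def microsatellites_on(self, chrom: str) -> list[Microsatellite]:
        return [m for m in self.microsatellites if m.chrom == chrom]


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """Random CDS: ATG start, no internal stops, stop codon at the end."""
    bases = np.array(list("ACGT"))
    codons = ["ATG"]
    while len(codons) < n_codons - 1:
        c = "".join(rng.choice(bases, 3))
        if c not in _STOPS:
            codons.append(c)
    codons.append(("TAA", "TAG", "TGA")[rng.integers(3)])
    return "".join(codons)


# Simulation truth roles for the named gene complement of the mini-genome.
_ONCOGENES = ("KRAS", "PIK3CA", "BRAF", "EGFR", "MYC", "CCND1", "ERBB2",
              "TERT", "AR", "NRAS", "ALK", "ERG")
_TSGS = ("TP53", "CDKN2A", "PTEN", "RB1", "APC", "SMAD4", "ARID1A",
         "BRCA1", "BRCA2", "ATM", "CHEK2", "BAP1", "MLH1", "MSH2", "MSH6",
         "MUTYH", "STK11", "VHL", "WT1", "NF2", "MEN1", "PMS2", "RET",
         "SDHAF2", "SDHB", "SDHC", "SDHD", "TSC1", "TSC2", "BMPR1A")
_FUSION_PARTNERS = ("TMPRSS2", "EML4")  # 5' partners, role 'none'
_FRAGILE_GENES = ("FHIT", "DMD")  # long genes prone to passenger deletions


def build_mini_genome(seed: int = 13, scale: int = 30,
                      n_passengers: int = 40,
                      microsatellites_per_chrom: int = 40) -> GenomeModel:
    """Build the default desk-scale genome (GRCh37 lengths / ``scale``).

    Gene content: canonical oncogenes/TSGs (including the 29-gene germline
    predisposition panel), two long fragile-site genes, two 5' fusion
    partners and ``n_passengers`` anonymous passenger genes, each with a
    seeded synthetic CDS.  Coordinates are synthetic; names are used so that
    fixture panels (hotspots, fusions, germline panel) read naturally.
    """
    rng = np.random.default_rng(seed)
    chroms = [
        Chromosome(name, length // scale, name not in ("X", "Y"))
        for name, length in GRCH37_LENGTHS.items()
    ]
    named = ([(g, "oncogene") for g in _ONCOGENES]
             + [(g, "tsg") for g in _TSGS]
             + [(g, "none") for g in _FUSION_PARTNERS]
             + [(g, "none") for g in _FRAGILE_GENES]
             + [(f"PSG{i:03d}", "none") for i in range(1, n_passengers + 1)])
    autos = [c for c in chroms if c.is_autosome]
    genes: list[GeneModel] = []
    cursor = {c.name: int(0.05 * c.length) for c in chroms}
    for i, (name, role) in enumerate(named):
        chrom = autos[i % len(autos)]
        long_gene = name in _FRAGILE_GENES
        n_codons = int(rng.integers(120, 400))
        cds = _random_cds(rng, n_codons)
        cds_len = 3 * n_codons
        n_exons = int(rng.integers(2, 5)) if not long_gene else 5
        # split CDS length into exon chunks (multiples of 1 bp, total fixed)
        cuts = np.sort(rng.choice(np.arange(30, cds_len - 30), n_exons - 1,
                                  replace=False)) if n_exons > 1 else []
        sizes = np.diff(np.concatenate(([0], cuts, [cds_len]))).astype(int)
        start = cursor[chrom.name]
        exons = []
        pos = start
        span_target = 600_000 + int(rng.integers(0, 600_000)) if long_gene \
            else int(rng.integers(5_000, 60_000))
        intron = max(200, (span_target - cds_len) // max(1, n_exons - 1)) \
            if n_exons > 1 else 0
        for sz in sizes:
            exons.append((pos, pos + int(sz)))
            pos += int(sz) + intron
        genes.append(GeneModel(name, chrom.name, "+", exons,
                               role_label=role,
                               is_panel=role in ("oncogene", "tsg"),
                               cds_seq=cds))
        cursor[chrom.name] = genes[-1].end + int(rng.integers(20_000, 80_000))
        if cursor[chrom.name] > 0.9 * chrom.length:  # wrap safety
            cursor[chrom.name] = int(0.05 * chrom.length)
    # microsatellites in gene-free gaps
    micros: list[Microsatellite] = []
    for c in chroms:
        gene_ivs = [(g.start - 1000, g.end + 1000) for g in genes
                    if g.chrom == c.name]
        made = 0
        while made < microsatellites_per_chrom:
            pos = int(rng.integers(0, c.length - 100))
            if any(s <= pos < e for s, e in gene_ivs):
                continue
            unit = int(rng.integers(1, 5))
            reps = int(rng.integers(5, 13)) if unit == 1 \
                else int(rng.integers(4, 9))
            micros.append(Microsatellite(c.name, pos, pos + unit * reps,
                                         unit, reps))
            made += 1
    micros.sort(key=lambda m: (m.chrom, m.start))
    return GenomeModel(chroms, genes, micros)
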