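"""Pipeline configuration and decision thresholds.

``Thresholds`` collects every published decision constant of the
interpretation stack in one frozen dataclass so that boundary behaviour is
auditable in a single place.  ``TumourSimConfig`` parameterises the synthetic
tumour generator.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

__all__ = ["Thresholds", "GridConfig", "ReadCountModel", "CloneSpec",
           "PlantedEvents", "TumourSimConfig", "PipelineConfig"]


@dataclass(frozen=True)
class Thresholds:
    """Decision constants of the interpretation stack.

    Defaults reproduce the published rules; any override is the caller's
    responsibility to log (``PipelineConfig.describe_overrides``).
    """

    purity_qc: float = 0.20          # samples below are QC-failed
    wgd_major_ploidy: float = 1.5    # major allele ploidy above => duplicated
    wgd_autosome_fraction: float = 0.5
    wgd_min_autosomes: int = 11      # >= 11 duplicated autosomes => WGD
    biallelic_offset: float = 0.5    # biallelic iff v > CN - 0.5
    msi_score: float = 4.0           # MSI iff indels/Mb > 4
    amp_high: float = 3.0            # min exonic CN > 3 x ploidy
    amp_moderate: float = 2.0
    amp_low: float = 1.4
    homdel_max_cn: float = 0.5       # homozygous deletion iff CN < 0.5
    loh_significant_loss: float = 0.6  # CN < 0.6 x ploidy => significant loss
    tmb_eligible: float = 10.0       # eligible iff TMB > 10 /Mb
    smg_q: float = 0.01              # significantly-mutated-gene cutoff
    sig_min_fraction: float = 0.05   # signatures below 5% excluded
    sig_min_load: int = 300          # fitted load < 300 excluded
    fragile_min_gene_length: int = 500_000
    fragile_min_del_fraction: float = 0.30
    fragile_del_min: int = 20_000
    fragile_del_max: int = 1_000_000
    loh_minor_ploidy: float = 0.25   # minor allele ploidy below => LOH
    subclonal_ccf: float = 0.85      # peaks below (CCF-equivalent) subclonal
    hotspot_margin_nt: int = 5       # within 5 nt of a hotspot
    min_clonality_variants: int = 50
    biallelic_driver_fraction: float = 0.5  # TSG likelihood-override gate


@dataclass(frozen=True)
class GridConfig:
    """Purity/ploidy grid-search resolution."""

    purity_min: float = 0.08
    purity_max: float = 1.00
    purity_step: float = 0.01
    ploidy_min: float = 1.0
    ploidy_max: float = 8.0
    ploidy_step: float = 0.02


@dataclass(frozen=True)
class ReadCountModel:
    """Sequencing-depth model emulating the 106x tumour / 38x normal design."""

    tumour_depth: float = 106.0
    normal_depth: float = 38.0
    overdispersion: float = 0.1      # negative-binomial excess dispersion
    gc_bias_amplitude: float = 0.0   # relative depth-ratio distortion
    ratio_noise: float = 0.02        # depth-ratio rel. sd per 1 Mb segment
    het_snp_spacing: int = 1500      # bp between informative het SNPs

    def __post_init__(self):
        if self.tumour_depth <= 0 or self.normal_depth <= 0:
            raise ValueError("depths must be > 0")
        if self.overdispersion < 0:
            raise ValueError("overdispersion must be >= 0")


@dataclass(frozen=True)
class CloneSpec:
    """One tumour clone: cancer-cell fraction and its private variant count."""

    ccf: float
    n_variants: int


@dataclass(frozen=True)
class PlantedEvents:
    """Ground-truth driver events injected into a simulated sample."""

    hotspot_genes: tuple[str, ...] = ()
    biallelic_tsgs: tuple[str, ...] = ()
    amplified_genes: tuple[str, ...] = ()
    deleted_genes: tuple[str, ...] = ()
    fusions: tuple[tuple[str, str], ...] = ()
    germline: tuple[tuple[str, str], ...] = ()  # (gene, fate); fate in
    # {"loh_wild_type", "loh_variant", "second_hit", "none"}


@dataclass(frozen=True)
class TumourSimConfig:
    """Study conditions for one synthetic tumour sample.

    Defaults emulate a typical metastatic solid tumour: purity 0.65, a
    dominant clone plus a minor subclone carrying ~11% of point mutations,
    cohort-median mutational load scaled to the mini-genome, and moderate
    aneuploidy with obligatory LOH territory.
    """

    purity: float = 0.65
    wgd: bool = False
    clones: tuple[CloneSpec, ...] = (CloneSpec(1.0, 250), CloneSpec(0.4, 30))
    indel_count: int = 25
    mnv_pair_count: int = 5
    signature_mix: tuple[tuple[int, float], ...] = ((0, 0.7), (4, 0.3))
    msi_target: float = 0.0          # qualifying indels per Mb to inject
    aneuploid_fraction: float = 0.4  # fraction of autosomes with CN events
    wgd_early_fraction: float = 0.3  # clonal variants predating a WGD
    coding_fraction: float | None = 0.011  # human exome fraction of SNVs;
    # None => the mini-genome's own (much sparser) exon fraction
    sex: str = "XX"
    depth: ReadCountModel = ReadCountModel()
    planted: PlantedEvents = PlantedEvents()

    def validate(self) -> None:
        if not (0 < self.purity <= 1):
            raise ValueError(f"purity {self.purity} outside (0, 1]")
        n_clonal = sum(1 for c in self.clones if c.ccf == 1.0)
        if n_clonal != 1:
            raise ValueError("exactly one clone must have CCF 1.0")
        for c in self.clones:
            if c.ccf > 1:
                raise ValueError(f"clone CCF {c.ccf} > 1")
            if c.ccf != 1.0 and not (0.1 <= c.ccf <= 0.9):
                raise ValueError("subclonal CCFs restricted to 0.1-0.9")
        if self.msi_target < 0:
            raise ValueError("msi_target must be >= 0")
        if self.sex not in ("XX", "XY"):
            raise ValueError("sex must be 'XX' or 'XY'")


@dataclass
class PipelineConfig:
    """Top-level run configuration: genome mode, seed, grids, thresholds."""

    genome_mode: str = "mini"        # mini | full
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)
    grid: GridConfig = field(default_factory=GridConfig)
    n_samples: int = 20

    def describe_overrides(self) -> list[str]:
        """Human-readable list of thresholds differing from the defaults."""
        ref = Thresholds()
        out = []
        for f in dataclasses.fields(Thresholds):
            cur = getattr(self.thresholds, f.name)
            if cur != getattr(ref, f.name):
                out.append(f"threshold override: {f.name}="
                           f"{cur} (default {getattr(ref, f.name)})")
        return out

    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True,
                             default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
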