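"""Per-variant somatic interpretation.

Covers variant-ploidy inversion and biallelic status, clonal/subclonal
mixture modelling, MNV merging, MSI and TMB scoring, and multi-biopsy
sharing.  The central quantity is the variant ploidy

    v = VAF · (p·CN + nc·(1−p)) / p

— the absolute number of chromatids carrying the variant, obtained by
adjusting the observed VAF for purity and multiplying by the local copy
number mixture.  A variant is biallelic (no wild-type copy remains) when
v > CN − 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from .config import Thresholds
from .genome import GenomeModel
from .purity import CopyNumberSegment
from .simulate import normal_copy_number
from .variants import PloidyAnnotation, SomaticVariant

__all__ = ["ClonalityModel", "MsiResult", "merge_mnvs",
           "annotate_variant_ploidy", "annotate_sample", "fit_clonality",
           "compute_msi", "compute_tmb", "compare_biopsies",
           "AnnotatedBiopsy", "local_copy_number"]


def merge_mnvs(variants: list[SomaticVariant]) -> list[SomaticVariant]:
    """Merge runs of adjacent, phased SNVs into multi-nucleotide variants.

    SNVs merge when they are directly adjacent (gap 0) and share a phase
    set; all other variants pass through unchanged.  Read support of a
    merged MNV is the minimum over its constituents.
    """
    by_pos = sorted(variants, key=lambda v: (v.chrom, v.pos))
    out: list[SomaticVariant] = []
    run: list[SomaticVariant] = []

    def flush():
        if not run:
            return
        if len(run) == 1:
            out.append(run[0])
        else:
            first = run[0]
            out.append(SomaticVariant(
                first.chrom, first.pos,
                "".join(v.ref for v in run), "".join(v.alt for v in run),
                "MNV", min(v.alt_count for v in run),
                min(v.depth for v in run), phase_set=first.phase_set,
                gene=first.gene, consequence=first.consequence,
                clone_ccf=first.clone_ccf))
        run.clear()

    for v in by_pos:
        mergeable = (v.vtype == "SNV" and v.phase_set is not None)
        if (run and mergeable and run[-1].phase_set == v.phase_set
                and v.chrom == run[-1].chrom
                and v.pos == run[-1].pos + 1):
            run.append(v)
            continue
        flush()
        if mergeable:
            run.append(v)
        else:
            out.append(v)
    flush()
    out.sort(key=lambda v: (v.chrom, v.pos))
    return out


def annotate_variant_ploidy(variant: SomaticVariant, purity: float,
                            local_cn: float, normal_cn: int = 2,
                            thresholds: Thresholds = Thresholds()
                            ) -> PloidyAnnotation:
    """Variant ploidy and biallelic status for one variant."""
    if purity <= 0:
        raise ValueError("purity must be > 0")
    if local_cn < 0:
        raise ValueError("local copy number must be >= 0")
    v = variant.vaf * (purity * local_cn + normal_cn * (1 - purity)) / purity
    v = max(v, 0.0)
    biallelic = v > local_cn - thresholds.biallelic_offset
    return PloidyAnnotation(v, local_cn, biallelic)


def local_copy_number(segments: list[CopyNumberSegment], chrom: str,
                      pos: int) -> tuple[float, float]:
    """(total CN, minor allele ploidy) of the fitted segment at a locus."""
    for s in segments:
        if s.chrom == chrom and s.start <= pos - 1 < s.end:
            return s.total_cn, s.minor
    raise KeyError(f"no fitted segment at {chrom}:{pos}")


def annotate_sample(variants: list[SomaticVariant],
                    segments: list[CopyNumberSegment], purity: float,
                    sex: str = "XX",
                    thresholds: Thresholds = Thresholds()
                    ) -> list[PloidyAnnotation]:
    """Ploidy-annotate every variant of a sample against its fitted CN."""
    out = []
    for v in variants:
        cn, _ = local_copy_number(segments, v.chrom, v.pos)
        nc = normal_copy_number(v.chrom, sex)
        out.append(annotate_variant_ploidy(v, purity, cn, max(nc, 1),
                                           thresholds))
    return out


@dataclass
class ClonalityModel:
    """Clonal/subclonal peak decomposition of a sample's variant ploidies."""

    locations: np.ndarray           # peak means in ploidy space
    weights: np.ndarray             # mixture weights (sum to 1)
    is_subclonal: np.ndarray        # bool per peak
    subclonal_fraction: float       # total weight of subclonal peaks

    @property
    def peaks(self) -> list[tuple[float, float, bool]]:
        return [(float(m), float(w), bool(s)) for m, w, s in
                zip(self.locations, self.weights, self.is_subclonal)]


def fit_clonality(variant_ploidies: np.ndarray,
                  thresholds: Thresholds = Thresholds(),
                  max_peaks: int = 5, random_state: int = 0
                  ) -> tuple[ClonalityModel, np.ndarray]:
    """Fit clonal and subclonal peaks to a sample's variant ploidies.

    A Gaussian mixture in variant-ploidy space is fitted by EM with the
    peak count (1–5) chosen by BIC.  Peaks whose location is below the
    clonal boundary (CCF-equivalent 0.85 at single-chromatid multiplicity)
    are subclonal.  Returns the model plus each variant's subclonal
    membership probability; clonal + subclonal probability is exactly 1.

    Below 50 variants the decomposition is not attempted and a single
    clonal peak is returned.
    """
    x = np.asarray(variant_ploidies, dtype=float).reshape(-1, 1)
    if x.size == 0:
        raise ValueError("no variants")
    if x.size < thresholds.min_clonality_variants or np.ptp(x) < 1e-6:
        model = ClonalityModel(np.array([float(x.mean())]), np.array([1.0]),
                               np.array([False]), 0.0)
        return model, np.zeros(x.size)
    best, best_bic = None, np.inf
    for k in range(1, max_peaks + 1):
        gm = GaussianMixture(k, random_state=random_state, n_init=2,
                             reg_covar=1e-4)
        gm.fit(x)
        bic = gm.bic(x)
        if bic < best_bic - 1e-9:
            best, best_bic = gm, bic
    resp = best.predict_proba(x)
    weights = resp.mean(axis=0)     # exact E-step weights
    locations = best.means_.ravel()
    sub = locations < thresholds.subclonal_ccf
    subclonal_prob = resp[:, sub].sum(axis=1)
    model = ClonalityModel(locations, weights, sub,
                           float(weights[sub].sum()))
    return model, subclonal_prob


@dataclass
class MsiResult:
    qualifying_indels: int
    genome_mb: float
    score: float                    # indels per Mb
    status: str                     # MSI | MSS


def _qualifying_loci(genome: GenomeModel):
    loci: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for c in genome.chromosomes:
        ms = [m for m in genome.microsatellites_on(c.name)
              if (m.unit_length == 1 and m.repeat_count >= 5)
              or (2 <= m.unit_length <= 4 and m.repeat_count >= 4)]
        if ms:
            loci[c.name] = (np.array([m.start for m in ms]),
                            np.array([m.end for m in ms]))
    return loci


def compute_msi(variants: list[SomaticVariant], genome: GenomeModel,
                thresholds: Thresholds = Thresholds()) -> MsiResult:
    """MSI score: qualifying indels per Mb; status MSI when score > 4.

    An indel qualifies when its reference span overlaps a homopolymer of
    five or more bases, or a repeat of a 2–4 bp unit with repeat count
    four or more.
    """
    if genome.length_bp <= 0:
        raise ValueError("zero-length genome")
    loci = _qualifying_loci(genome)
    n = 0
    for v in variants:
        if v.vtype != "INDEL" or v.chrom not in loci:
            continue
        starts, ends = loci[v.chrom]
        v_start = v.pos - 1
        v_end = v.pos - 1 + len(v.ref)
        idx = int(np.searchsorted(starts, v_end, side="left")) - 1
        if idx >= 0 and ends[idx] > v_start:
            n += 1
    score = n / genome.length_mb
    status = "MSI" if score > thresholds.msi_score else "MSS"
    return MsiResult(n, genome.length_mb, score, status)


def compute_tmb(variants: list[SomaticVariant], genome: GenomeModel,
                thresholds: Thresholds = Thresholds()
                ) -> tuple[float, bool]:
    """Tumour mutational burden (all small-variant classes per Mb).

    The immunotherapy-eligibility flag is strict: TMB must exceed 10
    mutations per megabase.
    """
    tmb = len(variants) / genome.length_mb
    return tmb, tmb > thresholds.tmb_eligible


@dataclass
class AnnotatedBiopsy:
    """Variant set of one biopsy with clonality annotation."""

    patient_id: str
    variants: list[SomaticVariant]
    subclonal_prob: np.ndarray

    def keys(self, subclonal: bool, cut: float = 0.5) -> set:
        return {v.key for v, sp in zip(self.variants, self.subclonal_prob)
                if (sp >= cut) == subclonal}


def compare_biopsies(a: AnnotatedBiopsy, b: AnnotatedBiopsy
                     ) -> tuple[float, float]:
    """Shared fraction of clonal and of subclonal variants between biopsies.

    Variant identity is keyed on (chrom, pos, ref, alt); each fraction is
    computed over the union of the class across the two biopsies.
    """
    if a.patient_id != b.patient_id:
        raise ValueError("biopsies belong to different patients")
    out = []
    for subclonal in (False, True):
        ka, kb = a.keys(subclonal), b.keys(subclonal)
        union = ka | kb
        out.append(len(ka & kb) / len(union) if union else 0.0)
    return out[0], out[1]
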