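"""Purity, ploidy and allele-specific copy-number fitting.

The fitter inverts the tumour/normal mixture model on segmented B-allele
frequency (BAF) and depth-ratio observations.  For a segment with
allele-specific state (major M, minor m), total CN = M + m, tumour purity p
and normal copy number nc:

    expected depth ratio  r = (p·CN + nc·(1−p)) / nc
    expected folded BAF   b = (p·M + (1−p)) / (p·CN + 2·(1−p))   (nc = 2)

A grid search over purity (0.08–1.00, step 0.01) and candidate sample
ploidy (1.0–8.0, step 0.02) scores each hypothesis by the SNP-count-
weighted squared BAF deviation plus length-weighted squared depth-ratio
deviation from the nearest integer allele-specific state; the
integer-attracting behaviour comes from measuring deviations against that
nearest state.  Whole-genome duplication is called when the major allele
ploidy exceeds 1.5 over at least half of at least 11 autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import GridConfig, Thresholds
from .genome import GenomeModel
from .simulate import normal_copy_number

__all__ = ["SegmentObservation", "CopyNumberSegment", "PurityFit",
           "fit_purity_ploidy", "call_wgd", "classify_cna_categories",
           "chr_y_loss", "apply_sample_qc", "segments_from_dataframe"]


@dataclass(frozen=True)
class SegmentObservation:
    """Observed BAF/depth summary for one copy-number segment."""

    chrom: str
    start: int
    end: int
    baf: float                      # folded, in [0.5, 1]; NaN if no SNPs
    baf_count: int
    depth_ratio: float

    def __post_init__(self):
        if self.depth_ratio < 0 or self.baf_count < 0:
            raise ValueError("invalid segment observation")
        if self.baf_count > 0 and not (0.5 <= self.baf <= 1.0 + 1e-9):
            raise ValueError(f"folded BAF {self.baf} outside [0.5, 1]")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CopyNumberSegment:
    """Fitted allele-specific copy number over one segment."""

    chrom: str
    start: int
    end: int
    total_cn: float
    major: float
    minor: float

    def __post_init__(self):
        if not (self.major >= self.minor >= -1e-9):
            raise ValueError("require major >= minor >= 0")
        if abs(self.major + self.minor - self.total_cn) > 1e-6:
            raise ValueError("major + minor must equal total")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class PurityFit:
    purity: float
    ploidy: float
    score: float
    wgd: bool
    duplicated_autosomes: int
    qc_status: str                  # PASS | FAIL_NO_SOMATIC | FAIL_PURITY | FAIL_GC
    purity_unreliable: bool = False

    def __post_init__(self):
        if self.ploidy <= 0:
            raise ValueError("ploidy must be > 0")


def segments_from_dataframe(df: pd.DataFrame) -> list[SegmentObservation]:
    """Build observations from a segment TSV table, folding BAF to >= 0.5."""
    out = []
    for row in df.itertuples(index=False):
        baf = float(row.baf) if row.baf_count > 0 else np.nan
        if not np.isnan(baf):
            baf = max(baf, 1.0 - baf)
        out.append(SegmentObservation(str(row.chrom), int(row.start),
                                      int(row.end), baf, int(row.baf_count),
                                      float(row.depth_ratio)))
    return out


def _score_grid(p_grid, q_grid, L, baf, wb, ratio, spacing,
                aberration_penalty=1e-4):
    """Score every (purity, ploidy) hypothesis; returns (NP, NQ) array.

    ``aberration_penalty`` weights a parsimony term proportional to each
    implied state's allele distance from diploid (1,1); without it, high
    ploidy hypotheses — whose integer states tile observation space more
    densely — absorb read noise and alias the fit to multiples of the true
    ploidy.
    """
    wr = L / spacing
    wmean_r = float((L * ratio).sum() / L.sum())
    baf_f = np.where(np.isnan(baf), 0.5, baf)
    wb_f = np.where(np.isnan(baf), 0.0, wb)
    scores = np.empty((p_grid.size, q_grid.size))
    chunk = 12
    r = ratio[None, None, :]
    b = baf_f[None, None, :]
    for i0 in range(0, p_grid.size, chunk):
        p = p_grid[i0:i0 + chunk][:, None, None]
        q = q_grid[None, :, None]
        dh = p * q + 2 * (1 - p)
        norm = wmean_r / (dh / 2)
        with np.errstate(divide="ignore", invalid="ignore"):
            cn_impl = (2 * r / norm - 2 * (1 - p)) / p
            cn_int = np.maximum(np.round(cn_impl), 0.0)
            d = p * cn_int + 2 * (1 - p)
            maj_impl = (b * d - (1 - p)) / p
            maj_int = np.clip(np.round(maj_impl), np.ceil(cn_int / 2),
                              cn_int)
            exp_baf = np.where(d > 0, (p * maj_int + (1 - p)) /
                               np.where(d > 0, d, 1.0), 0.5)
            exp_r = norm * d / 2
        baf_term = wb_f[None, None, :] * (b - exp_baf) ** 2
        ratio_term = wr[None, None, :] * (r - exp_r) ** 2
        min_int = cn_int - maj_int
        pen_term = aberration_penalty * wr[None, None, :] * (
            np.abs(maj_int - 1) + np.abs(min_int - 1))
        scores[i0:i0 + chunk] = (baf_term + ratio_term + pen_term
                                 ).sum(axis=2)
    return scores, (wb_f.sum() + wr.sum())


def fit_purity_ploidy(segments: list[SegmentObservation],
                      grid: GridConfig = GridConfig(),
                      thresholds: Thresholds = Thresholds(),
                      sex: str = "XX",
                      het_snp_spacing: float = 1500.0
                      ) -> tuple[PurityFit, list[CopyNumberSegment]]:
    """Grid-search purity and ploidy; assign per-segment copy number.

    Ties on the score surface (flat in purity, e.g. a fully balanced
    genome) break towards the lowest candidate ploidy, then the lowest
    purity, and the fit is flagged ``purity_unreliable``.
    """
    if not segments:
        raise ValueError("no segments")
    auto = [s for s in segments
            if normal_copy_number(s.chrom, sex) == 2]
    if not any(s.baf_count > 0 for s in auto):
        raise ValueError("no informative segments (need heterozygous SNPs)")
    L = np.array([s.length for s in auto], dtype=float)
    baf = np.array([s.baf for s in auto], dtype=float)
    wb = np.array([s.baf_count for s in auto], dtype=float)
    ratio = np.array([s.depth_ratio for s in auto], dtype=float)

    p_grid = np.round(np.arange(grid.purity_min,
                                grid.purity_max + grid.purity_step / 2,
                                grid.purity_step), 6)
    q_grid = np.round(np.arange(grid.ploidy_min,
                                grid.ploidy_max + grid.ploidy_step / 2,
                                grid.ploidy_step), 6)
    scores, total_w = _score_grid(p_grid, q_grid, L, baf, wb, ratio,
                                  het_snp_spacing)
    smin = scores.min()
    tol = 1e-12 + 1e-9 * abs(smin)
    tie_p, tie_q = np.where(scores <= smin + tol)
    # prefer the lowest ploidy, then the lowest purity
    order = np.lexsort((p_grid[tie_p], q_grid[tie_q]))
    pi, qi = tie_p[order[0]], tie_q[order[0]]
    purity = float(p_grid[pi])
    q_hat = float(q_grid[qi])
    flat = np.unique(tie_p[q_grid[tie_q] == q_grid[qi]]).size > 5

    # real-valued copy number per segment under the chosen hypothesis
    wmean_r = float((L * ratio).sum() / L.sum())
    norm = wmean_r / ((purity * q_hat + 2 * (1 - purity)) / 2)
    cn_segments: list[CopyNumberSegment] = []
    for s in segments:
        nc = normal_copy_number(s.chrom, sex)
        if nc == 0:
            continue
        cn = max((nc * s.depth_ratio / norm - nc * (1 - purity)) / purity,
                 0.0)
        if nc == 1:
            major, minor = cn, 0.0
        elif s.baf_count > 0 and not np.isnan(s.baf):
            d = purity * cn + 2 * (1 - purity)
            major = (s.baf * d - (1 - purity)) / purity if d > 0 else cn
            major = float(np.clip(major, cn / 2, cn))
            minor = cn - major
        else:
            major = minor = cn / 2
        cn_segments.append(CopyNumberSegment(s.chrom, s.start, s.end, cn,
                                             round(major, 9),
                                             round(minor, 9)))
    lw = np.array([c.length for c in cn_segments], dtype=float)
    cns = np.array([c.total_cn for c in cn_segments])
    ploidy = float((lw * cns).sum() / lw.sum())
    qc = "FAIL_PURITY" if purity < thresholds.purity_qc else "PASS"
    fit = PurityFit(purity, ploidy, float(smin / total_w), False, 0, qc,
                    purity_unreliable=flat)
    return fit, cn_segments


def call_wgd(segments: list[CopyNumberSegment], genome: GenomeModel,
             thresholds: Thresholds = Thresholds()) -> tuple[bool, int]:
    """Whole-genome duplication call from fitted allele-specific CN.

    An autosome counts as duplicated when the fraction of its fitted length
    with major allele ploidy > 1.5 is at least 50%; WGD is called when at
    least 11 autosomes are duplicated.
    """
    if not segments:
        raise ValueError("empty segment list")
    autos = {c.name for c in genome.autosomes}
    dup = 0
    for chrom in autos:
        segs = [s for s in segments if s.chrom == chrom]
        if not segs:
            continue
        total = sum(s.length for s in segs)
        above = sum(s.length for s in segs
                    if s.major > thresholds.wgd_major_ploidy)
        if total > 0 and above / total >= thresholds.wgd_autosome_fraction:
            dup += 1
    return dup >= thresholds.wgd_min_autosomes, dup


def min_exonic_cn(segments: list[CopyNumberSegment], gene
                  ) -> tuple[float, float]:
    """Minimum exonic (total CN, minor allele ploidy) for a gene."""
    best_cn, best_minor = np.inf, np.inf
    for s in segments:
        if s.chrom != gene.chrom:
            continue
        for es, ee in gene.exons:
            if s.start < ee and s.end > es:
                best_cn = min(best_cn, s.total_cn)
                best_minor = min(best_minor, s.minor)
    if not np.isfinite(best_cn):
        raise ValueError(f"gene {gene.gene_id} not covered by any segment")
    return float(best_cn), float(best_minor)


def classify_cna_categories(segments: list[CopyNumberSegment],
                            genes, ploidy: float,
                            thresholds: Thresholds = Thresholds()
                            ) -> pd.DataFrame:
    """Per-gene loss-ring and gain-ring CNA category.

    Loss ring: homozygous deletion (min exonic CN < 0.5), else LOH (minor
    allele ploidy below the LOH bound) split into significant loss
    (CN < 0.6 x sample ploidy) versus near copy-neutral.  Gain ring: high
    (> 3x ploidy), moderate (> 2x) and low (> 1.4x) amplification.
    """
    rows = []
    for gene in genes:
        cn, minor = min_exonic_cn(segments, gene)
        if cn < thresholds.homdel_max_cn:
            loss = "homozygous_deletion"
        elif minor < thresholds.loh_minor_ploidy:
            loss = ("loh_significant_loss"
                    if cn < thresholds.loh_significant_loss * ploidy
                    else "loh_copy_neutral")
        else:
            loss = "none"
        if cn > thresholds.amp_high * ploidy:
            gain = "amp_high"
        elif cn > thresholds.amp_moderate * ploidy:
            gain = "amp_moderate"
        elif cn > thresholds.amp_low * ploidy:
            gain = "amp_low"
        else:
            gain = "none"
        rows.append(dict(gene=gene.gene_id, loss_category=loss,
                         gain_category=gain, min_exonic_cn=cn,
                         min_exonic_minor=minor))
    return pd.DataFrame(rows)


def chr_y_loss(segments: list[CopyNumberSegment], sex: str,
               thresholds: Thresholds = Thresholds()) -> bool:
    """Chromosome-Y loss for male samples (length-weighted Y CN < 0.5)."""
    if sex != "XY":
        return False
    ys = [s for s in segments if s.chrom == "Y"]
    if not ys:
        return False
    w = sum(s.length for s in ys)
    cn = sum(s.length * s.total_cn for s in ys) / w
    return cn < thresholds.homdel_max_cn


def apply_sample_qc(records: pd.DataFrame,
                    thresholds: Thresholds = Thresholds(),
                    gc_threshold: float = 0.25) -> pd.DataFrame:
    """Cohort-level sample QC and multi-biopsy deduplication.

    Removes samples with zero somatic variants, fitted purity below 20% or
    a GC-bias metric above threshold, then keeps the highest-purity passing
    sample per patient.  ``records`` needs columns sample_id, patient_id,
    purity, somatic_count and (optionally) gc_metric; the returned frame
    adds ``qc_status`` and ``kept``.
    """
    rec = records.copy()
    if "gc_metric" not in rec:
        rec["gc_metric"] = 0.0
    status = []
    for row in rec.itertuples(index=False):
        if row.somatic_count == 0:
            status.append("FAIL_NO_SOMATIC")
        elif row.purity < thresholds.purity_qc:
            status.append("FAIL_PURITY")
        elif row.gc_metric > gc_threshold:
            status.append("FAIL_GC")
        else:
            status.append("PASS")
    rec["qc_status"] = status
    rec["kept"] = False
    passing = rec[rec.qc_status == "PASS"]
    for _, grp in passing.groupby("patient_id"):
        best = grp.purity.idxmax()
        rec.loc[best, "kept"] = True
    return rec
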