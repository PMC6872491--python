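"""Purity/ploidy fitting, WGD calling, CNA categories and sample QC."""

import numpy as np
import pandas as pd
import pytest

from somakit.config import TumourSimConfig
from somakit.purity import (CopyNumberSegment, SegmentObservation,
                            apply_sample_qc, call_wgd,
                            classify_cna_categories, chr_y_loss,
                            fit_purity_ploidy, min_exonic_cn,
                            segments_from_dataframe)
from somakit.simulate import simulate_cohort


def _flat_segments(n=22, baf=0.5, ratio=1.0, length=3_000_000):
    return [SegmentObservation(str(i + 1), 0, length, baf, 2000, ratio)
            for i in range(n)]


def test_diploid_degeneracy_reports_lowest_purity():
    """A fully balanced diploid genome leaves purity unidentified: the fit
    reports ploidy 2, every segment (1,1) and flags purity unreliable."""
    fit, cn = fit_purity_ploidy(_flat_segments())
    assert fit.ploidy == pytest.approx(2.0, abs=1e-6)
    assert fit.purity == pytest.approx(0.08)   # lowest grid value
    assert fit.purity_unreliable
    for s in cn:
        assert s.total_cn == pytest.approx(2.0, abs=1e-6)
        assert s.major == pytest.approx(1.0, abs=1e-6)


def test_fit_errors_without_informative_segments():
    with pytest.raises(ValueError):
        fit_purity_ploidy([])
    segs = [SegmentObservation("1", 0, 1000, np.nan, 0, 1.0)]
    with pytest.raises(ValueError):
        fit_purity_ploidy(segs)


def test_fit_invariants_on_simulated_samples(genome, fixtures):
    """major + minor = total on every fitted segment; sample ploidy equals
    the length-weighted mean CN to 1e-6; low purity fails QC."""
    sims = simulate_cohort(genome, 4, TumourSimConfig(), seed=3,
                           fixtures=fixtures, purity_range=(0.25, 0.95))
    for sim in sims:
        fit, cn = fit_purity_ploidy(segments_from_dataframe(sim.segments),
                                    sex=sim.truth.sex)
        for s in cn:
            assert abs(s.major + s.minor - s.total_cn) < 1e-6
            assert s.major >= s.minor >= 0
        w = np.array([s.length for s in cn], float)
        tot = np.array([s.total_cn for s in cn])
        assert fit.ploidy == pytest.approx((w * tot).sum() / w.sum(),
                                           abs=1e-6)
        assert fit.qc_status == ("FAIL_PURITY" if fit.purity < 0.20
                                 else "PASS")


def test_low_purity_sample_fails_qc(genome, fixtures):
    sims = simulate_cohort(genome, 1, TumourSimConfig(), seed=8,
                           fixtures=fixtures, purity_range=(0.10, 0.10))
    fit, _ = fit_purity_ploidy(segments_from_dataframe(sims[0].segments),
                               sex=sims[0].truth.sex)
    assert fit.purity < 0.20
    assert fit.qc_status == "FAIL_PURITY"


def _full_autosome_segments(genome, duplicated):
    segs = []
    for i, c in enumerate(genome.autosomes):
        major, minor = (2, 1) if i < duplicated else (1, 1)
        segs.append(CopyNumberSegment(c.name, 0, c.length, major + minor,
                                      major, minor))
    return segs


@pytest.mark.parametrize("k,expected", [(22, True), (11, True), (10, False),
                                        (0, False)])
def test_wgd_duplicated_autosome_threshold(genome, k, expected):
    wgd, count = call_wgd(_full_autosome_segments(genome, k), genome)
    assert wgd is expected
    assert count == k


def test_wgd_all_balanced_tetraploid(genome):
    segs = [CopyNumberSegment(c.name, 0, c.length, 4.0, 2.0, 2.0)
            for c in genome.autosomes]
    assert call_wgd(segs, genome) == (True, 22)


def test_wgd_invariant_to_segment_subdivision(genome):
    base = _full_autosome_segments(genome, 13)
    split = []
    for s in base:
        mid = (s.start + s.end) // 2
        split.append(CopyNumberSegment(s.chrom, s.start, mid, s.total_cn,
                                       s.major, s.minor))
        split.append(CopyNumberSegment(s.chrom, mid, s.end, s.total_cn,
                                       s.major, s.minor))
    assert call_wgd(base, genome) == call_wgd(split, genome)


def test_wgd_empty_segments_error(genome):
    with pytest.raises(ValueError):
        call_wgd([], genome)


def test_wgd_half_autosome_counts_as_duplicated(genome):
    """Exactly 50% of an autosome above major 1.5 counts (at least half)."""
    segs = []
    for i, c in enumerate(genome.autosomes):
        half = c.length // 2
        if i < 11 and c.length % 2 == 0:
            segs.append(CopyNumberSegment(c.name, 0, half, 3.0, 2.0, 1.0))
            segs.append(CopyNumberSegment(c.name, half, c.length, 2.0, 1.0,
                                          1.0))
        else:
            segs.append(CopyNumberSegment(c.name, 0, c.length, 2.0, 1.0,
                                          1.0))
    even = sum(1 for i, c in enumerate(genome.autosomes)
               if i < 11 and c.length % 2 == 0)
    _, count = call_wgd(segs, genome)
    assert count == even


def _gene(genome):
    return genome.genes_on("1")[0]


def _gene_segment(genome, cn, minor):
    g = _gene(genome)
    return [CopyNumberSegment(g.chrom, 0, genome.chromosome("1").length,
                              cn, cn - minor, minor)]


@pytest.mark.parametrize("cn,minor,ploidy,loss,gain", [
    (1.0, 0.0, 2.0, "loh_significant_loss", "none"),
    (3.0, 1.0, 2.0, "none", "amp_low"),
    (2.0, 0.0, 2.0, "loh_copy_neutral", "none"),
    (0.2, 0.0, 2.0, "homozygous_deletion", "none"),
    (7.0, 1.0, 2.0, "none", "amp_high"),
    (4.5, 1.0, 2.0, "none", "amp_moderate"),
])
def test_cna_category_rules(genome, cn, minor, ploidy, loss, gain):
    cats = classify_cna_categories(_gene_segment(genome, cn, minor),
                                   [_gene(genome)], ploidy)
    row = cats.iloc[0]
    assert row.loss_category == loss
    assert row.gain_category == gain


def test_min_exonic_cn_takes_minimum_over_exons(genome):
    g = _gene(genome)
    mid = (g.exons[0][1] + g.exons[-1][0]) // 2 if len(g.exons) > 1 \
        else (g.start + g.end) // 2
    segs = [CopyNumberSegment(g.chrom, 0, mid, 3.0, 2.0, 1.0),
            CopyNumberSegment(g.chrom, mid, genome.chromosome(g.chrom
                                                              ).length,
                              0.3, 0.3, 0.0)]
    cn, minor = min_exonic_cn(segs, g)
    assert cn == pytest.approx(0.3)
    with pytest.raises(ValueError):
        min_exonic_cn([CopyNumberSegment("22", 0, 100, 2, 1, 1)], g)


def test_chr_y_loss_only_for_males():
    segs = [CopyNumberSegment("Y", 0, 1_000_000, 0.1, 0.1, 0.0)]
    assert chr_y_loss(segs, "XY") is True
    assert chr_y_loss(segs, "XX") is False
    gained = [CopyNumberSegment("Y", 0, 1_000_000, 1.0, 1.0, 0.0)]
    assert chr_y_loss(gained, "XY") is False


def test_sample_qc_rules_and_biopsy_dedup():
    rec = pd.DataFrame([
        dict(sample_id="A1", patient_id="PA", purity=0.35,
             somatic_count=100, gc_metric=0.0),
        dict(sample_id="A2", patient_id="PA", purity=0.62,
             somatic_count=100, gc_metric=0.0),
        dict(sample_id="B1", patient_id="PB", purity=0.50,
             somatic_count=0, gc_metric=0.0),
        dict(sample_id="C1", patient_id="PC", purity=0.10,
             somatic_count=50, gc_metric=0.0),
        dict(sample_id="D1", patient_id="PD", purity=0.80,
             somatic_count=10, gc_metric=0.9),
    ])
    out = apply_sample_qc(rec)
    status = dict(zip(out.sample_id, out.qc_status))
    kept = set(out[out.kept].sample_id)
    assert status["B1"] == "FAIL_NO_SOMATIC"
    assert status["C1"] == "FAIL_PURITY"
    assert status["D1"] == "FAIL_GC"
    assert kept == {"A2"}           # highest-purity biopsy of patient PA


def test_sample_qc_identity_when_all_pass():
    rec = pd.DataFrame([dict(sample_id=f"S{i}", patient_id=f"P{i}",
                             purity=0.5, somatic_count=10, gc_metric=0.0)
                        for i in range(4)])
    out = apply_sample_qc(rec)
    assert out.kept.all()
    assert (out.qc_status == "PASS").all()
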