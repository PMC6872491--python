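"""Driver catalogue: roles, panel, peel-off, likelihoods, germline logic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import somakit.drivers as drv
from somakit.dnds import run_dnds, simulate_coding_cohort
from somakit.genome import GeneModel, GenomeModel
from somakit.purity import CopyNumberSegment
from somakit.variants import GermlineVariant, PloidyAnnotation, \
    SomaticVariant


# ------------------------------------------------------------- gene roles

def test_role_classifier_feature_extremes_and_holdout_accuracy():
    train = drv.make_role_training(seed=0, n=300)
    test = drv.make_role_training(seed=1, n=200)
    clf = drv.GeneRoleClassifier(seed=0).fit(train, train.role)
    pred = clf.predict(test)
    acc = (pred.role.values == test.role.values).mean()
    assert acc >= 0.9
    extremes = pd.DataFrame(dict(
        gene=["pure_tsg", "pure_onc"],
        frac_truncating=[0.95, 0.0],
        missense_concentration=[0.05, 0.95],
        biallelic_fraction=[0.9, 0.1],
        inframe_indel_fraction=[0.0, 0.1]))
    out = clf.predict(extremes)
    assert list(out.role) == ["tsg", "oncogene"]


def test_untrained_classifier_raises():
    with pytest.raises(RuntimeError):
        drv.GeneRoleClassifier().predict(drv.make_role_training(n=10))


# ------------------------------------------------------------ gene panel

def test_panel_union_arithmetic_and_q_gate():
    cohort = pd.DataFrame(dict(gene=["A", "B", "C", "X"],
                               q=[0.001, 0.005, 0.009, 0.02]))
    external = pd.DataFrame(dict(gene=["C", "D", "E", "F"],
                                 q=[0.0001] * 4))
    curated = ["G", "H", "I", "J", "K"]
    roles = {g: "oncogene" for g in "ABCDEFGHIJK"}
    panel = drv.build_gene_panel(cohort, external, curated, roles)
    # 3 + 4 + 5 with one overlap (C) = 11; X excluded at q = 0.02
    assert len(panel) == 11
    assert "X" not in set(panel.gene)
    assert not panel.gene.duplicated().any()
    row = panel[panel.gene == "C"].iloc[0]
    assert row.smg_cohort and row.smg_external and not row.curated
    with pytest.raises(ValueError):
        drv.build_gene_panel(cohort, external, ["Z"], roles)


# --------------------------------------------------------------- peel-off

from tests_oracle_peel import (oracle_peaks as _oracle_peaks,
                               peak_genome as _peak_genome,
                               planted_events as _planted_events)


def test_single_planted_peak_recovered_amid_broad_gains():
    genome = _peak_genome()
    events = _planted_events(100, [((0, 12), (0, 10)),    # broad background
                                   ((5, 6), (10, 40))])   # focal over G05
    peaks = drv.find_cn_peaks(events, genome, "amp", min_support=5)
    assert peaks[0].target_gene == "G05"
    assert peaks[0].support == 40
    oracle = _oracle_peaks(events, list(events.columns), 5)
    assert [(p.genes, p.support) for p in peaks] == oracle


def test_two_independent_peaks_in_support_order():
    genome = _peak_genome()
    events = _planted_events(100, [((2, 3), (0, 30)),
                                   ((8, 9), (30, 80))])
    peaks = drv.find_cn_peaks(events, genome, "amp", min_support=5)
    assert [p.target_gene for p in peaks] == ["G08", "G02"]
    assert [p.support for p in peaks] == [50, 30]
    oracle = _oracle_peaks(events, list(events.columns), 5)
    assert [(p.genes, p.support) for p in peaks] == oracle


def test_peel_off_sample_order_invariance_and_removal():
    genome = _peak_genome()
    events = _planted_events(60, [((0, 12), (0, 10)), ((5, 6), (10, 40)),
                                  ((9, 10), (35, 55))])
    peaks = drv.find_cn_peaks(events, genome, "amp", min_support=5)
    shuffled = events.sample(frac=1.0, random_state=3)
    peaks2 = drv.find_cn_peaks(shuffled, genome, "amp", min_support=5)
    assert [(p.target_gene, p.support) for p in peaks] == \
        [(p.target_gene, p.support) for p in peaks2]
    # removing every supporter of the top peak removes it on re-run
    top = peaks[0]
    supporters = events.index[events[top.target_gene]]
    reduced = events.copy()
    reduced.loc[supporters, list(top.genes)] = False
    again = drv.find_cn_peaks(reduced, genome, "amp", min_support=5)
    assert all(p.target_gene != top.target_gene for p in again)


def test_panel_gene_preferred_as_target():
    genome = _peak_genome()
    events = _planted_events(50, [((4, 7), (0, 30))])
    peaks = drv.find_cn_peaks(events, genome, "amp",
                              panel_genes={"G06"}, min_support=5)
    assert peaks[0].target_gene == "G06"


def test_no_events_returns_empty():
    genome = _peak_genome()
    events = _planted_events(20, [])
    assert drv.find_cn_peaks(events, genome, "amp") == []


def test_fragile_site_requires_length_and_size_profile(genome):
    fhit = genome.gene("FHIT")
    assert fhit.length_bp > 500_000
    peak = drv.AmpDelPeak(fhit.chrom, fhit.start, fhit.end, "del", 10,
                          "FHIT", ("FHIT",))
    sizes_mid = [50_000] * 4 + [5_000] * 6            # 40% in 20kb-1Mb
    out = drv.annotate_fragile_sites([peak], genome,
                                     {"FHIT": sizes_mid})
    assert out[0].fragile_site
    peak2 = drv.AmpDelPeak(fhit.chrom, fhit.start, fhit.end, "del", 10,
                           "FHIT", ("FHIT",))
    sizes_low = [50_000] * 3 + [5_000] * 7            # 30% exactly: strict
    out = drv.annotate_fragile_sites([peak2], genome,
                                     {"FHIT": sizes_low})
    assert not out[0].fragile_site
    short_gene = next(g for g in genome.genes if g.length_bp < 500_000
                      and g.chrom != "Y")
    peak3 = drv.AmpDelPeak(short_gene.chrom, short_gene.start,
                           short_gene.end, "del", 10, short_gene.gene_id,
                           (short_gene.gene_id,))
    out = drv.annotate_fragile_sites([peak3], genome,
                                     {short_gene.gene_id: sizes_mid})
    assert not out[0].fragile_site


# ---------------------------------------------------------- point drivers

def _point_setup(genome, site_tables):
    cohort = simulate_coding_cohort(genome, 80, 40, seed=21,
                                    site_tables=site_tables,
                                    excess={"KRAS": ("missense", 10.0),
                                            "TP53": ("nonsense", 10.0)})
    dnds = run_dnds(cohort, genome, site_tables)
    panel = pd.DataFrame(dict(gene=["KRAS", "TP53"],
                              role=["oncogene", "tsg"],
                              smg_cohort=[True, True],
                              smg_external=[False, False],
                              curated=[True, True]))
    return dnds, panel


def _ann(v=1.0, cn=2.0, biallelic=False):
    return PloidyAnnotation(v, cn, biallelic)


def test_point_driver_inclusion_rules(genome, site_tables, fixtures):
    dnds, panel = _point_setup(genome, site_tables)
    kras = genome.gene("KRAS")
    syn = SomaticVariant(kras.chrom, kras.start + 1, "C", "T", "SNV", 30,
                         60, gene="KRAS", consequence="synonymous")
    non_panel = SomaticVariant("1", 5, "C", "T", "SNV", 30, 60,
                               gene="PSG001", consequence="missense")
    nonsense_in_onc = SomaticVariant(kras.chrom, kras.start + 2, "C", "A",
                                     "SNV", 30, 60, gene="KRAS",
                                     consequence="nonsense")
    mis = SomaticVariant(kras.chrom, kras.start + 3, "C", "A", "SNV", 30,
                         60, gene="KRAS", consequence="missense")
    variants = [syn, non_panel, nonsense_in_onc, mis]
    anns = [_ann() for _ in variants]
    out = drv.call_point_drivers("S", variants, anns, panel, dnds, 3.0,
                                 3.0, fixtures.hotspots)
    assert len(out) == 1 and out[0].detail.endswith(f"{mis.pos}:C:A")


def test_hotspot_override_and_tmb_monotonicity(genome, site_tables,
                                               fixtures):
    dnds, panel = _point_setup(genome, site_tables)
    hs = fixtures.hotspots[fixtures.hotspots.gene == "KRAS"].iloc[0]
    at_hotspot = SomaticVariant(hs.chrom, int(hs.pos) + 5, hs.ref, hs.alt,
                                "SNV", 30, 60, gene="KRAS",
                                consequence="missense")
    out = drv.call_point_drivers("S", [at_hotspot], [_ann()], panel, dnds,
                                 1.0, 3.0, fixtures.hotspots)
    assert out[0].likelihood >= 0.99 and out[0].hotspot
    far = SomaticVariant(hs.chrom, int(hs.pos) + 500, "C", "A", "SNV", 30,
                         60, gene="KRAS", consequence="missense")
    low = drv.call_point_drivers("S", [far], [_ann()], panel, dnds,
                                 3.0, 3.0, fixtures.hotspots)[0]
    high = drv.call_point_drivers("S", [far], [_ann()], panel, dnds,
                                  300.0, 3.0, fixtures.hotspots)[0]
    assert 0.0 < high.likelihood < low.likelihood <= 1.0
    # brute-force evaluation of the likelihood formula
    row = dnds.gene_class("KRAS", "missense")
    excess = max(row.observed - row.expected, 0.0)
    expect_low = excess / (excess + row.expected * 3.0 / 3.0)
    assert low.likelihood == pytest.approx(expect_low, abs=1e-9)


def test_biallelic_tsg_override(genome, site_tables, fixtures):
    dnds, panel = _point_setup(genome, site_tables)
    tp53 = genome.gene("TP53")
    v = SomaticVariant(tp53.chrom, tp53.start + 1, "C", "A", "SNV", 30, 60,
                       gene="TP53", consequence="nonsense")
    out = drv.call_point_drivers("S", [v], [_ann(1.0, 1.0, True)], panel,
                                 dnds, 3.0, 3.0, fixtures.hotspots,
                                 biallelic_fractions={"TP53": 0.9})
    assert out[0].likelihood >= 0.99 and out[0].biallelic
    out = drv.call_point_drivers("S", [v], [_ann(1.0, 2.0, False)], panel,
                                 dnds, 3.0, 3.0, fixtures.hotspots,
                                 biallelic_fractions={"TP53": 0.2})
    assert out[0].likelihood < 0.99


def test_panel_missing_role_raises():
    panel = pd.DataFrame(dict(gene=["KRAS"], role=[None]))
    v = SomaticVariant("1", 10, "C", "T", "SNV", 30, 60, gene="KRAS",
                       consequence="missense")
    with pytest.raises(Exception):
        drv.call_point_drivers("S", [v], [_ann()], panel, None, 1.0, 1.0,
                               pd.DataFrame(columns=["gene", "chrom",
                                                     "pos", "ref", "alt"]))


# ----------------------------------------------------- CN/fusion drivers

def test_amplification_and_deletion_driver_rules(genome, fixtures):
    panel = pd.DataFrame(dict(gene=["ERBB2", "PTEN"],
                              role=["oncogene", "tsg"]))
    cna = pd.DataFrame([
        dict(gene="ERBB2", min_exonic_cn=7.0, min_exonic_minor=1.0,
             loss_category="none", gain_category="amp_high"),
        dict(gene="PTEN", min_exonic_cn=0.3, min_exonic_minor=0.0,
             loss_category="homozygous_deletion", gain_category="none"),
        dict(gene="ERBB2", min_exonic_cn=5.9, min_exonic_minor=1.0,
             loss_category="none", gain_category="amp_moderate"),
    ])
    svs = pd.DataFrame(columns=["chrom1", "pos1", "orient1", "chrom2",
                                "pos2", "orient2", "svtype"])
    out = drv.call_cn_and_fusion_drivers("S", cna, 2.0, svs, [], panel,
                                         fixtures.known_fusions, genome)
    classes = {(e.gene, e.event_class) for e in out}
    assert ("ERBB2", "amplification") in classes
    assert ("PTEN", "homozygous_deletion") in classes
    assert len([e for e in out if e.event_class == "amplification"]) == 1


def test_known_fusion_in_frame_classification(genome, fixtures):
    g5, g3 = genome.gene("EML4"), genome.gene("ALK")
    pair = None
    for i in range(len(g5.exons) - 1):
        for j in range(len(g3.exons) - 1):
            if g5.exon_phase(i + 1) == g3.exon_phase(j + 1):
                pair = (i, j)
    assert pair is not None
    i, j = pair
    sv = pd.Series(dict(
        chrom1=g5.chrom, pos1=g5.exons[i][1] + 10, orient1="+",
        chrom2=g3.chrom, pos2=g3.exons[j][1] + 10, orient2="-",
        svtype="TRA"))
    hit = drv.classify_fusion(sv, genome, fixtures.known_fusions)
    assert hit == dict(five_gene="EML4", three_gene="ALK",
                       kind="in_frame_coding")
    # phase-incompatible introns do not call an in-frame fusion
    bad = None
    for i2 in range(len(g5.exons) - 1):
        for j2 in range(len(g3.exons) - 1):
            if g5.exon_phase(i2 + 1) != g3.exon_phase(j2 + 1):
                bad = (i2, j2)
    if bad:
        i2, j2 = bad
        sv_bad = pd.Series(dict(
            chrom1=g5.chrom, pos1=g5.exons[i2][1] + 10, orient1="+",
            chrom2=g3.chrom, pos2=g3.exons[j2][1] + 10, orient2="-",
            svtype="TRA"))
        assert drv.classify_fusion(sv_bad, genome,
                                   fixtures.known_fusions) is None


def test_intragenic_inframe_exon_deletion(genome, fixtures):
    gene = next(g for g in genome.genes if len(g.exons) >= 3
                and (g.exons[1][1] - g.exons[1][0]) % 3 == 0)
    # breakpoints in the flanking introns: exactly one in-frame exon deleted
    lo = gene.exons[0][1] + 10 + 1
    hi = gene.exons[1][1] + 10 + 1
    sv = pd.Series(dict(chrom1=gene.chrom, pos1=lo, orient1="+",
                        chrom2=gene.chrom, pos2=hi, orient2="-",
                        svtype="DEL"))
    hit = drv.classify_fusion(sv, genome, fixtures.known_fusions)
    assert hit is not None and hit["kind"] == "intragenic_deletion"


# --------------------------------------------------------------- germline

def _germ(gene, genome, tumour_vaf, depth=200):
    g = genome.gene(gene)
    return GermlineVariant(g.chrom, g.start + 1, "C", "T", gene, "HET",
                           pathogenic=True, alt_count=20, depth=40,
                           tumour_alt_count=int(tumour_vaf * depth),
                           tumour_depth=depth)


def _loh_segment(gene, genome, cn=1.0, minor=0.0):
    g = genome.gene(gene)
    return [CopyNumberSegment(g.chrom, 0, genome.chromosome(g.chrom).length,
                              cn, cn - minor, minor)]


def test_germline_loss_of_wild_type(genome):
    # purity 1, LOH CN 1, tumour VAF 1.0 => all copies carry the variant
    gv = _germ("BRCA1", genome, 1.0)
    out = drv.call_germline_drivers("S", [gv], _loh_segment("BRCA1",
                                                            genome),
                                    [], 1.0, ("BRCA1",))
    assert len(out) == 1 and out[0].biallelic
    assert "wild_type_lost=True" in out[0].detail


def test_germline_loss_of_variant_not_reported(genome):
    gv = _germ("BRCA1", genome, 0.0)
    out = drv.call_germline_drivers("S", [gv], _loh_segment("BRCA1",
                                                            genome),
                                    [], 1.0, ("BRCA1",))
    assert out == []


def test_germline_second_hit_and_panel_gate(genome):
    gv = _germ("BRCA1", genome, 0.5)
    seg = _loh_segment("BRCA1", genome, cn=2.0, minor=1.0)
    somatic = [SomaticVariant(gv.chrom, gv.pos + 100, "C", "A", "SNV", 30,
                              60, gene="BRCA1", consequence="nonsense")]
    out = drv.call_germline_drivers("S", [gv], seg, somatic, 1.0,
                                    ("BRCA1",))
    assert out and out[0].biallelic and "second_hit=True" in out[0].detail
    # outside the high-confidence panel: silently dropped
    out = drv.call_germline_drivers("S", [gv], seg, somatic, 1.0,
                                    ("TP53",))
    assert out == []


# ------------------------------------------------------ cohort summaries

def test_cooccurrence_matches_exact_enumeration():
    samples = [f"S{i}" for i in range(20)]
    rows = ([dict(sample=f"S{i}", gene="A", event_class="point",
                  likelihood=1.0) for i in range(10)]
            + [dict(sample=f"S{i}", gene="B", event_class="point",
                    likelihood=1.0) for i in range(10, 20)])
    cat = pd.DataFrame(rows)
    out = drv.driver_cooccurrence(cat, samples)
    row = out.iloc[0]
    assert row.direction == "mutually_exclusive"
    # hypergeometric enumeration for table [[0,10],[10,0]]
    expected_p = stats.fisher_exact([[0, 10], [10, 0]])[1]
    assert row.p == pytest.approx(expected_p)
    brute = sum(stats.hypergeom.pmf(k, 20, 10, 10)
                for k in range(11)
                if stats.hypergeom.pmf(k, 20, 10, 10)
                <= stats.hypergeom.pmf(0, 20, 10, 10) + 1e-12)
    assert row.p == pytest.approx(brute, rel=1e-6)


def test_cooccurrence_single_gene_empty():
    cat = pd.DataFrame([dict(sample="S0", gene="A", event_class="point",
                             likelihood=1.0)])
    assert drv.driver_cooccurrence(cat, ["S0", "S1"]).empty


def test_summarize_driver_counts_is_likelihood_sum():
    cat = pd.DataFrame([
        dict(sample="S1", gene="A", event_class="point", likelihood=1.0,
             subclonal_prob=0.0),
        dict(sample="S1", gene="B", event_class="amplification",
             likelihood=0.5, subclonal_prob=0.4),
        dict(sample="S2", gene="C", event_class="point", likelihood=0.25,
             subclonal_prob=1.0),
    ])
    out = drv.summarize_driver_counts(cat).set_index("sample")
    assert out.loc["S1"].driver_burden == pytest.approx(1.5)
    assert out.loc["S1"].subclonal_driver_burden == pytest.approx(0.2)
    assert out.loc["S2"].subclonal_driver_burden == pytest.approx(0.25)
    # brute-force oracle over a random catalogue
    rng = np.random.default_rng(0)
    rand = pd.DataFrame(dict(
        sample=rng.choice(["X", "Y"], 50),
        gene=[f"G{i}" for i in range(50)],
        event_class="point",
        likelihood=rng.uniform(0, 1, 50),
        subclonal_prob=rng.uniform(0, 1, 50)))
    out = drv.summarize_driver_counts(rand).set_index("sample")
    for s in ("X", "Y"):
        sub = rand[rand["sample"] == s]
        assert out.loc[s].driver_burden == pytest.approx(
            sub.likelihood.sum())
        assert out.loc[s].subclonal_driver_burden == pytest.approx(
            (sub.likelihood * sub.subclonal_prob).sum())
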