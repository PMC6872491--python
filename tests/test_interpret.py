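"""Variant ploidy, clonality, MNV merging, MSI/TMB scoring, biopsies."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from somakit.config import CloneSpec, TumourSimConfig
from somakit.genome import Chromosome, GenomeModel, Microsatellite
from somakit.interpret import (AnnotatedBiopsy, annotate_variant_ploidy,
                               compare_biopsies, compute_msi, compute_tmb,
                               fit_clonality, merge_mnvs)
from somakit.variants import PloidyAnnotation, SomaticVariant


def _snv(chrom="1", pos=100, alt_count=50, depth=100, phase_set=None,
         ref="C", alt="T"):
    return SomaticVariant(chrom, pos, ref, alt, "SNV", alt_count, depth,
                          phase_set=phase_set)


# ------------------------------------------------------------ MNV merging

def test_adjacent_phased_snvs_merge_to_dinucleotide():
    merged = merge_mnvs([_snv(pos=100, phase_set=1),
                         _snv(pos=101, phase_set=1)])
    assert len(merged) == 1
    assert merged[0].vtype == "MNV" and len(merged[0].ref) == 2


def test_phase_set_and_adjacency_required():
    out = merge_mnvs([_snv(pos=100, phase_set=1), _snv(pos=101,
                                                       phase_set=2)])
    assert all(v.vtype == "SNV" for v in out) and len(out) == 2
    out = merge_mnvs([_snv(pos=100, phase_set=1), _snv(pos=102,
                                                       phase_set=1)])
    assert all(v.vtype == "SNV" for v in out) and len(out) == 2
    out = merge_mnvs([_snv(pos=100), _snv(pos=101)])  # unphased
    assert all(v.vtype == "SNV" for v in out)


def test_trinucleotide_run_merges_exhaustively():
    """All contiguity patterns of three phased SNVs behave correctly."""
    variants = [_snv(pos=p, phase_set=9) for p in (100, 101, 102)]
    merged = merge_mnvs(variants)
    assert len(merged) == 1 and len(merged[0].ref) == 3
    # gap in the run: only the adjacent pair merges
    variants = [_snv(pos=p, phase_set=9) for p in (100, 101, 103)]
    merged = merge_mnvs(variants)
    assert sorted(len(v.ref) for v in merged) == [1, 2]


# ------------------------------------------------------- variant ploidy

@pytest.mark.parametrize("purity,cn,vaf,expected_v,expected_biallelic", [
    (1.0, 2.0, 0.5, 1.0, False),           # 1.0 <= 1.5
    (0.5, 4.0, 1 / 3, 2.0, False),         # closed-form inversion
    (1.0, 1.0, 1.0, 1.0, True),            # LOH locus, 1.0 > 0.5
])
def test_variant_ploidy_examples(purity, cn, vaf, expected_v,
                                 expected_biallelic):
    var = _snv(alt_count=int(vaf * 600_000), depth=600_000)
    ann = annotate_variant_ploidy(var, purity, cn)
    assert ann.variant_ploidy == pytest.approx(expected_v, abs=1e-5)
    assert ann.biallelic is expected_biallelic


def test_variant_ploidy_requires_positive_purity():
    with pytest.raises(ValueError):
        annotate_variant_ploidy(_snv(), 0.0, 2.0)


@settings(max_examples=200, deadline=None)
@given(vaf=st.floats(0.01, 1.0), purity=st.floats(0.05, 1.0),
       cn=st.floats(0.0, 8.0))
def test_biallelic_rule_exact(vaf, purity, cn):
    """The biallelic flag is exactly v > CN - 0.5 for any (v, CN)."""
    depth = 1_000_000
    var = _snv(alt_count=int(round(vaf * depth)), depth=depth)
    ann = annotate_variant_ploidy(var, purity, cn)
    assert ann.biallelic == (ann.variant_ploidy > cn - 0.5)


def test_ploidy_inversion_round_trip():
    """Simulate VAFs at known variant ploidy; mean inverted v within 3 SE."""
    rng = np.random.default_rng(4)
    p, cn, v_true = 0.5, 4.0, 2.0
    vaf_true = p * v_true / (p * cn + 2 * (1 - p))
    depths = rng.poisson(100, 3000).clip(min=1)
    alts = rng.binomial(depths, vaf_true)
    v_hat = [annotate_variant_ploidy(
        _snv(alt_count=int(a), depth=int(d)), p, cn).variant_ploidy
        for a, d in zip(alts, depths)]
    v_hat = np.array(v_hat)
    se = v_hat.std() / np.sqrt(v_hat.size)
    assert abs(v_hat.mean() - v_true) < 3 * se


def test_annotation_probability_invariant():
    ann = PloidyAnnotation(1.0, 2.0, False, clonal_prob=0.7,
                           subclonal_prob=0.3)
    assert ann.clonal_prob + ann.subclonal_prob == 1.0
    with pytest.raises(ValueError):
        PloidyAnnotation(1.0, 2.0, False, clonal_prob=0.7,
                         subclonal_prob=0.4)


# ------------------------------------------------------------- clonality

def test_single_clonal_peak_for_tight_cluster():
    rng = np.random.default_rng(0)
    v = rng.normal(1.0, 0.05, 500)
    model, sp = fit_clonality(v)
    assert model.subclonal_fraction < 0.05
    assert np.all(sp <= 1.0) and np.all(sp >= 0.0)


def test_clonality_fraction_equals_weighted_variant_mean():
    rng = np.random.default_rng(1)
    v = np.concatenate([rng.normal(1.0, 0.08, 700),
                        rng.normal(0.4, 0.06, 300)])
    model, sp = fit_clonality(v)
    assert model.subclonal_fraction == pytest.approx(sp.mean(), abs=1e-6)
    assert model.weights.sum() == pytest.approx(1.0, abs=1e-9)
    assert model.subclonal_fraction == pytest.approx(0.3, abs=0.05)


def test_clonality_small_input_returns_single_peak():
    model, sp = fit_clonality(np.full(20, 0.9))
    assert len(model.peaks) == 1 and model.subclonal_fraction == 0.0
    with pytest.raises(ValueError):
        fit_clonality(np.array([]))


# ------------------------------------------------------------------- MSI

def _toy_ms_genome():
    chrom = Chromosome("1", 10_000_000, True)
    ms = [Microsatellite("1", 1000, 1008, 1, 8),       # homopolymer >= 5
          Microsatellite("1", 5000, 5008, 2, 4),       # dinucleotide x4
          Microsatellite("1", 9000, 9012, 4, 3)]       # only 3 units
    return GenomeModel([chrom], [], ms)


def test_msi_scorer_matches_brute_force_overlap():
    genome = _toy_ms_genome()
    rng = np.random.default_rng(2)
    variants = []
    for _ in range(300):
        pos = int(rng.integers(1, 10_000_000))
        variants.append(SomaticVariant("1", pos, "AT", "A", "INDEL", 20,
                                       60))
    res = compute_msi(variants, genome)
    qualifying = [m for m in genome.microsatellites
                  if (m.unit_length == 1 and m.repeat_count >= 5)
                  or (2 <= m.unit_length <= 4 and m.repeat_count >= 4)]
    brute = sum(
        1 for v in variants
        if any(m.start < v.pos - 1 + len(v.ref) and m.end > v.pos - 1
               for m in qualifying))
    assert res.qualifying_indels == brute


def test_msi_boundary_is_strict():
    """Score exactly 4 is MSS; any score above 4 is MSI."""
    chrom = Chromosome("1", 3_100_000_000, True)
    genome = GenomeModel([chrom], [],
                         [Microsatellite("1", 1000, 1010, 1, 10)])
    def score(n):
        variants = [SomaticVariant("1", 1001, "AT", "A", "INDEL", 20, 60)
                    ] * n
        return compute_msi(variants, genome)
    assert score(12_400).status == "MSS"
    assert score(12_400).score == pytest.approx(4.0)
    assert score(12_500).status == "MSI"
    assert score(0).score == 0.0 and score(0).status == "MSS"


def test_msi_classification_of_injected_sample(genome, fixtures):
    from somakit.simulate import simulate_sample
    cfg = TumourSimConfig(msi_target=12.0)
    sim = simulate_sample(genome, cfg, seed=6, fixtures=fixtures)
    assert compute_msi(sim.somatic, genome).status == "MSI"


# ------------------------------------------------------------------- TMB

def test_tmb_boundary_is_strict():
    chrom = Chromosome("1", 3_100_000_000, True)
    genome = GenomeModel([chrom], [], [])
    mk = lambda n: [SomaticVariant("1", 10, "C", "T", "SNV", 20, 60)] * n
    tmb, eligible = compute_tmb(mk(31_000), genome)
    assert tmb == pytest.approx(10.0) and not eligible
    tmb, eligible = compute_tmb(mk(40_000), genome)
    assert eligible
    tmb, eligible = compute_tmb([], genome)
    assert tmb == 0.0 and not eligible


# ---------------------------------------------------------- biopsy pairs

def _biopsy(patient, keys, subcl):
    variants = [SomaticVariant("1", p, "C", "T", "SNV", 30, 60)
                for p in keys]
    return AnnotatedBiopsy(patient, variants, np.array(subcl))


def test_compare_biopsies_identical_and_disjoint():
    a = _biopsy("P1", [1, 2, 3], [0.0, 0.0, 1.0])
    b = _biopsy("P1", [1, 2, 3], [0.0, 0.0, 1.0])
    assert compare_biopsies(a, b) == (1.0, 1.0)
    c = _biopsy("P1", [7, 8], [0.0, 1.0])
    assert compare_biopsies(a, c) == (0.0, 0.0)
    with pytest.raises(ValueError):
        compare_biopsies(a, _biopsy("P2", [1], [0.0]))


def test_compare_biopsies_recovers_generated_structure(genome, fixtures):
    from somakit.purity import fit_purity_ploidy, segments_from_dataframe
    from somakit.interpret import annotate_sample
    from somakit.simulate import simulate_biopsy_pair
    cfg = TumourSimConfig(purity=0.85,
                          clones=(CloneSpec(1.0, 500), CloneSpec(0.4, 200)),
                          indel_count=0, mnv_pair_count=0)
    a, b = simulate_biopsy_pair(genome, cfg, seed=12, fixtures=fixtures,
                                shared_subclonal=0.3)
    def annotate(sim):
        fit, cn = fit_purity_ploidy(segments_from_dataframe(sim.segments),
                                    sex="XX")
        ann = annotate_sample(sim.somatic, cn, fit.purity, "XX")
        _, sp = fit_clonality(np.array([x.variant_ploidy for x in ann]))
        return AnnotatedBiopsy(sim.truth.patient_id, sim.somatic, sp)
    shared_clonal, shared_sub = compare_biopsies(annotate(a), annotate(b))
    # truth: clonal fully shared; subclonal union fraction k/(2-k) for
    # retention k = 0.3
    assert shared_clonal == pytest.approx(1.0, abs=0.05)
    assert shared_sub == pytest.approx(0.3 / (2 - 0.3), abs=0.05)
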