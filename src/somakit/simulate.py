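"""Synthetic tumour genome generator.

Produces fully specified tumour samples — ground truth plus observables —
under the mixture model the interpretation stack inverts:

* allele-specific copy-number segments, optionally whole-genome duplicated;
* segment B-allele frequency and depth ratio derived from purity and local
  copy number, with binomial/negative-binomial read sampling;
* clonal and subclonal point mutations whose VAFs follow binomial sampling
  with success probability p·m·c / (p·CN + nc·(1−p)) at the simulated depth
  (m = chromatid multiplicity, c = cancer-cell fraction, nc = normal copy
  number at the locus);
* microsatellite indel bursts for MSI, trinucleotide-context SNVs drawn from
  signature mixtures, germline predisposition variants with or without
  somatic second hits, and SV breakpoints forming fusions.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CloneSpec, PlantedEvents, ReadCountModel, TumourSimConfig
from .fixtures import FixtureSet, find_coding_snv
from .genome import GenomeModel
from .signatures import CONTEXTS, context_of
from .variants import GermlineVariant, SomaticVariant

__all__ = ["SegmentTruth", "TruthSample", "SimulatedSample",
           "simulate_sample", "simulate_cohort", "simulate_biopsy_pair",
           "inject_msi"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SegmentTruth:
    chrom: str
    start: int
    end: int
    major: int
    minor: int

    def __post_init__(self):
        if not (self.major >= self.minor >= 0):
            raise ValueError("require major >= minor >= 0")

    @property
    def total(self) -> int:
        return self.major + self.minor


@dataclass
class TruthSample:
    sample_id: str
    patient_id: str
    cancer_type: str
    purity: float
    sex: str
    wgd: bool
    segments: list[SegmentTruth]
    clones: tuple[CloneSpec, ...]
    planted: PlantedEvents
    msi_target: float = 0.0

    @property
    def msi_status(self) -> str:
        return "MSI" if self.msi_target > 4 else "MSS"

    @property
    def ploidy(self) -> float:
        w = np.array([s.end - s.start for s in self.segments], dtype=float)
        cn = np.array([s.total for s in self.segments], dtype=float)
        return float((w * cn).sum() / w.sum())


@dataclass
class SimulatedSample:
    """Truth plus observables for one simulated tumour."""

    truth: TruthSample
    segments: pd.DataFrame          # chrom,start,end,baf,baf_count,depth_ratio
    somatic: list[SomaticVariant]
    germline: list[GermlineVariant]
    svs: pd.DataFrame               # chrom1,pos1,orient1,chrom2,pos2,orient2,type
    seed: int

    def write(self, outdir) -> None:
        from . import io
        io.write_sample(self, outdir)


def normal_copy_number(chrom: str, sex: str) -> int:
    if chrom == "X":
        return 2 if sex == "XX" else 1
    if chrom == "Y":
        return 0 if sex == "XX" else 1
    return 2


class _Profile:
    """Mutable per-chromosome allele-specific copy-number profile."""

    def __init__(self, genome: GenomeModel, sex: str):
        self.segs: dict[str, list[list]] = {}
        for c in genome.chromosomes:
            nc = normal_copy_number(c.name, sex)
            if nc == 0:
                continue
            base = (1, 1) if nc == 2 else (1, 0)
            self.segs[c.name] = [[0, c.length, base[0], base[1]]]

    def overlay(self, chrom: str, start: int, end: int,
                major: int, minor: int) -> None:
        if chrom not in self.segs:
            return
        out = []
        for s, e, ma, mi in self.segs[chrom]:
            if e <= start or s >= end:
                out.append([s, e, ma, mi])
                continue
            if s < start:
                out.append([s, start, ma, mi])
            if e > end:
                out.append([end, e, ma, mi])
        out.append([max(start, 0), min(end, self._chrom_end(chrom)), major,
                    minor])
        out.sort()
        self.segs[chrom] = out

    def _chrom_end(self, chrom: str) -> int:
        return max(e for _, e, _, _ in self.segs[chrom])

    def scale(self, factor: int) -> None:
        for segs in self.segs.values():
            for seg in segs:
                seg[2] *= factor
                seg[3] *= factor

    def state_at(self, chrom: str, pos: int) -> tuple[int, int]:
        for s, e, ma, mi in self.segs.get(chrom, []):
            if s <= pos < e:
                return ma, mi
        raise KeyError(f"{chrom}:{pos} outside profile")

    def to_truth(self) -> list[SegmentTruth]:
        out = []
        for chrom in self.segs:
            for s, e, ma, mi in self.segs[chrom]:
                out.append(SegmentTruth(chrom, s, e, ma, mi))
        return out


_PALETTE = [(1, 0), (2, 0), (2, 1), (3, 1), (2, 2), (3, 2)]
_PALETTE_P = [0.15, 0.15, 0.35, 0.15, 0.10, 0.10]
_WGD_PALETTE = [(2, 1), (3, 2), (4, 2), (3, 1), (2, 0), (4, 3), (1, 0)]
_WGD_P = [0.30, 0.20, 0.15, 0.15, 0.10, 0.05, 0.05]


def _build_profile(genome: GenomeModel, cfg: TumourSimConfig,
                   rng: np.random.Generator) -> _Profile:
    prof = _Profile(genome, cfg.sex)
    autos = [c for c in genome.autosomes]
    if cfg.wgd:
        prof.scale(2)
        palette, pp = _WGD_PALETTE, _WGD_P
    else:
        palette, pp = _PALETTE, _PALETTE_P
    k = int(round(cfg.aneuploid_fraction * len(autos)))
    chosen = rng.choice(len(autos), size=k, replace=False)
    loh_seen = 0
    for ci in chosen:
        c = autos[ci]
        ma, mi = palette[rng.choice(len(palette), p=pp)]
        if rng.random() < 0.5:  # arm-level event
            half = c.length // 2
            if rng.random() < 0.5:
                prof.overlay(c.name, 0, half, ma, mi)
            else:
                prof.overlay(c.name, half, c.length, ma, mi)
        else:
            prof.overlay(c.name, 0, c.length, ma, mi)
        if mi == 0:
            loh_seen += 1
    # guarantee LOH territory: breaks the purity/ploidy half-grid degeneracy
    # and mirrors the pervasive LOH of real tumours
    if loh_seen < 2 and k > 0:
        spare = [c for i, c in enumerate(autos) if i not in set(chosen)]
        for c, state in zip(spare[:2], [(2, 0), (1, 0)]):
            prof.overlay(c.name, 0, c.length // 2, *state)
    return prof


def _overlay_planted(prof: _Profile, genome: GenomeModel,
                     cfg: TumourSimConfig) -> None:
    margin = 10_000
    for gene in cfg.planted.biallelic_tsgs:
        g = genome.gene(gene)
        prof.overlay(g.chrom, max(0, g.start - margin), g.end + margin, 1, 0)
    for gene, fate in cfg.planted.germline:
        if fate.startswith("loh"):
            g = genome.gene(gene)
            prof.overlay(g.chrom, max(0, g.start - margin), g.end + margin,
                         1, 0)
    # focal amplifications / homozygous deletions relative to current ploidy
    truth = TruthSample("", "", "", cfg.purity, cfg.sex, cfg.wgd,
                        prof.to_truth(), cfg.clones, cfg.planted)
    ploidy = truth.ploidy
    # high-level amplifications sit well above the 3x-ploidy call boundary
    # in real tumours (typically 10-30+ copies); 5x ploidy emulates that
    for gene in cfg.planted.amplified_genes:
        g = genome.gene(gene)
        total = max(int(np.ceil(5.0 * ploidy)), 8)
        prof.overlay(g.chrom, max(0, g.start - margin), g.end + margin,
                     total - 1, 1)
    for gene in cfg.planted.deleted_genes:
        g = genome.gene(gene)
        prof.overlay(g.chrom, max(0, g.start - 25_000), g.end + 25_000, 0, 0)


def _draw_depth(rng: np.random.Generator, mean: float,
                model: ReadCountModel, size=None) -> np.ndarray:
    mean = max(mean, 1.0)
    if model.overdispersion <= 0:
        return rng.poisson(mean, size=size)
    n = 1.0 / model.overdispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p, size=size)


def _segment_observables(prof: _Profile, cfg: TumourSimConfig,
                         rng: np.random.Generator) -> pd.DataFrame:
    p = cfg.purity
    dm = cfg.depth
    rows = []
    for chrom, segs in prof.segs.items():
        nc = normal_copy_number(chrom, cfg.sex)
        for s, e, ma, mi in segs:
            length = e - s
            d = p * (ma + mi) + nc * (1 - p)
            r_true = d / nc
            sd = min(dm.ratio_noise * np.sqrt(1e6 / length), 0.2)
            r_obs = r_true * (1 + rng.normal(0, sd))
            if dm.gc_bias_amplitude > 0:
                r_obs *= 1 + dm.gc_bias_amplitude * rng.uniform(-1, 1)
            r_obs = max(r_obs, 0.0)
            if nc == 2 and d > 0:
                n_snps = max(3, int(round(length / dm.het_snp_spacing)))
                b_true = (p * ma + (1 - p)) / d
                depths = _draw_depth(rng, dm.tumour_depth * r_true / 2 * nc,
                                     dm, size=n_snps)
                depths = np.maximum(depths, 1)
                alts = rng.binomial(depths, min(b_true, 1.0))
                baf = float(alts.sum() / depths.sum())
            else:
                n_snps, baf = 0, np.nan
            rows.append(dict(chrom=chrom, start=s, end=e, baf=baf,
                             baf_count=n_snps, depth_ratio=float(r_obs)))
    return pd.DataFrame(rows)


@dataclass
class _VariantTruth:
    chrom: str
    pos: int                        # 1-based
    ref: str
    alt: str
    vtype: str
    ccf: float
    multiplicity: int
    phase_set: int | None = None
    gene: str | None = None
    consequence: str | None = None
    context: str | None = None


def _position_sampler(prof: _Profile, rng: np.random.Generator):
    chroms = list(prof.segs)
    lengths = np.array([prof._chrom_end(c) for c in chroms], dtype=float)
    cum = np.cumsum(lengths)

    def draw() -> tuple[str, int]:
        for _ in range(50):
            x = rng.uniform(0, cum[-1])
            ci = int(np.searchsorted(cum, x))
            pos = int(x - (cum[ci - 1] if ci else 0.0))
            chrom = chroms[ci]
            ma, mi = prof.state_at(chrom, pos)
            if ma + mi > 0:
                return chrom, pos
        raise RuntimeError("could not place variant outside deleted regions")

    return draw


def _signature_context(rng: np.random.Generator, probs: np.ndarray
                       ) -> tuple[str, str, str]:
    idx = int(rng.choice(96, p=probs))
    label = CONTEXTS[idx]
    ref, alt = label[2], label[4]
    return label, ref, alt


def _context_probs(cfg: TumourSimConfig, fixtures: FixtureSet | None
                   ) -> np.ndarray:
    if fixtures is None:
        return np.full(96, 1 / 96)
    w = np.zeros(96)
    for sig_idx, weight in cfg.signature_mix:
        w += weight * fixtures.signatures[:, sig_idx]
    return w / w.sum()


def _point_variant_truths(genome: GenomeModel, prof: _Profile,
                          cfg: TumourSimConfig, fixtures: FixtureSet | None,
                          rng: np.random.Generator) -> list[_VariantTruth]:
    probs = _context_probs(cfg, fixtures)
    draw_pos = _position_sampler(prof, rng)
    coding_bp = sum(g.coding_length for g in genome.genes)
    coding_frac = (cfg.coding_fraction if cfg.coding_fraction is not None
                   else coding_bp / genome.length_bp)
    out: list[_VariantTruth] = []
    phase_counter = 1
    for clone in cfg.clones:
        for _ in range(clone.n_variants):
            if rng.random() < coding_frac and genome.genes:
                g = genome.genes[int(rng.integers(len(genome.genes)))]
                idx = int(rng.integers(len(g.cds_seq)))
                ref = g.cds_seq[idx]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                pos0 = g.cds_to_genomic(idx)
                five = g.cds_seq[max(idx - 1, 0)]
                three = g.cds_seq[min(idx + 1, len(g.cds_seq) - 1)]
                out.append(_VariantTruth(
                    g.chrom, pos0 + 1, ref, alt, "SNV", clone.ccf,
                    _mult(prof, g.chrom, pos0, clone.ccf, cfg, rng),
                    gene=g.gene_id,
                    consequence=g.consequence(pos0, ref, alt),
                    context=context_of(five, ref, alt, three)))
            else:
                chrom, pos0 = draw_pos()
                label, ref, alt = _signature_context(rng, probs)
                out.append(_VariantTruth(
                    chrom, pos0 + 1, ref, alt, "SNV", clone.ccf,
                    _mult(prof, chrom, pos0, clone.ccf, cfg, rng),
                    context=label))
    # phased adjacent SNV runs (MNV truth)
    for _ in range(cfg.mnv_pair_count):
        chrom, pos0 = draw_pos()
        m = _mult(prof, chrom, pos0, 1.0, cfg, rng)
        for off in range(2):
            label, ref, alt = _signature_context(rng, probs)
            out.append(_VariantTruth(chrom, pos0 + 1 + off, ref, alt, "SNV",
                                     1.0, m, phase_set=phase_counter,
                                     context=label))
        phase_counter += 1
    # background indels away from microsatellites
    for _ in range(cfg.indel_count):
        chrom, pos0 = draw_pos()
        b1, b2 = (str(b) for b in rng.choice(_BASES, 2))
        if rng.random() < 0.5:
            ref, alt = b1 + b2, b1
        else:
            ref, alt = b1, b1 + b2
        out.append(_VariantTruth(chrom, pos0 + 1, ref, alt, "INDEL", 1.0,
                                 _mult(prof, chrom, pos0, 1.0, cfg, rng)))
    return out


def _mult(prof: _Profile, chrom: str, pos0: int, ccf: float,
          cfg: TumourSimConfig, rng: np.random.Generator) -> int:
    ma, mi = prof.state_at(chrom, pos0)
    if (cfg.wgd and ccf == 1.0 and ma >= 2
            and rng.random() < cfg.wgd_early_fraction):
        return 2
    return 1


def _planted_point_truths(genome: GenomeModel, prof: _Profile,
                          cfg: TumourSimConfig, fixtures: FixtureSet | None
                          ) -> list[_VariantTruth]:
    out = []
    for gene in cfg.planted.hotspot_genes:
        if fixtures is None:
            raise ValueError("hotspot planting requires fixture resources")
        row = fixtures.hotspots[fixtures.hotspots.gene == gene].iloc[0]
        out.append(_VariantTruth(row.chrom, int(row.pos), row.ref, row.alt,
                                 "SNV", 1.0, 1, gene=gene,
                                 consequence="missense"))
    for gene in cfg.planted.biallelic_tsgs:
        g = genome.gene(gene)
        pos, ref, alt = find_coding_snv(g, "nonsense")
        ma, _ = prof.state_at(g.chrom, pos - 1)
        out.append(_VariantTruth(g.chrom, pos, ref, alt, "SNV", 1.0, ma,
                                 gene=gene, consequence="nonsense"))
    return out


def _observe(truths: list[_VariantTruth], prof: _Profile,
             cfg: TumourSimConfig, rng: np.random.Generator
             ) -> list[SomaticVariant]:
    p = cfg.purity
    dm = cfg.depth
    out = []
    for t in truths:
        nc = normal_copy_number(t.chrom, cfg.sex)
        ma, mi = prof.state_at(t.chrom, t.pos - 1)
        d = p * (ma + mi) + nc * (1 - p)
        if d <= 0:
            continue
        vaf = min(p * t.multiplicity * t.ccf / d, 1.0)
        depth = int(_draw_depth(rng, dm.tumour_depth * d / 2, dm))
        depth = max(depth, 1)
        alt_count = int(rng.binomial(depth, vaf))
        if alt_count == 0:
            continue
        out.append(SomaticVariant(t.chrom, t.pos, t.ref, t.alt, t.vtype,
                                  alt_count, depth, phase_set=t.phase_set,
                                  gene=t.gene, consequence=t.consequence,
                                  context=t.context, clone_ccf=t.ccf))
    chrom_order = {c: i for i, c in enumerate(prof.segs)}
    out.sort(key=lambda v: (chrom_order.get(v.chrom, 99), v.pos))
    return out


def _germline_variants(genome: GenomeModel, prof: _Profile,
                       cfg: TumourSimConfig, rng: np.random.Generator
                       ) -> tuple[list[GermlineVariant], list[_VariantTruth]]:
    p = cfg.purity
    dm = cfg.depth
    out, extra_somatic = [], []
    for gene, fate in cfg.planted.germline:
        g = genome.gene(gene)
        pos, ref, alt = find_coding_snv(g, "missense",
                                        start_codon=len(g.cds_seq) // 9)
        ma, mi = prof.state_at(g.chrom, pos - 1)
        nc = normal_copy_number(g.chrom, cfg.sex)
        d = p * (ma + mi) + nc * (1 - p)
        if fate == "loh_wild_type":
            n_var = ma            # all remaining tumour copies carry the ALT
        elif fate == "loh_variant":
            n_var = 0
        else:
            n_var = 1
        t_vaf = (p * n_var + (1 - p)) / d if d > 0 else 0.0
        n_depth = max(int(_draw_depth(rng, dm.normal_depth, dm)), 1)
        n_alt = int(rng.binomial(n_depth, 0.5))
        t_depth = max(int(_draw_depth(rng, dm.tumour_depth * d / 2, dm)), 1)
        t_alt = int(rng.binomial(t_depth, min(t_vaf, 1.0)))
        out.append(GermlineVariant(g.chrom, pos, ref, alt, gene, "HET",
                                   pathogenic=True, consequence="missense",
                                   alt_count=n_alt, depth=n_depth,
                                   tumour_alt_count=t_alt,
                                   tumour_depth=t_depth))
        if fate == "second_hit":
            pos2, ref2, alt2 = find_coding_snv(g, "nonsense",
                                               start_codon=2 * len(
                                                   g.cds_seq) // 9)
            extra_somatic.append(_VariantTruth(g.chrom, pos2, ref2, alt2,
                                               "SNV", 1.0, 1, gene=gene,
                                               consequence="nonsense"))
    return out, extra_somatic


def _fusion_svs(genome: GenomeModel, cfg: TumourSimConfig) -> pd.DataFrame:
    rows = []
    for g5_name, g3_name in cfg.planted.fusions:
        g5, g3 = genome.gene(g5_name), genome.gene(g3_name)
        pair = None
        for i in range(len(g5.exons) - 1):
            for j in range(len(g3.exons) - 1):
                if g5.exon_phase(i + 1) == g3.exon_phase(j + 1):
                    pair = (i, j)
                    break
            if pair:
                break
        i, j = pair if pair else (0, 0)
        pos1 = g5.exons[i][1] + (g5.exons[i + 1][0] - g5.exons[i][1]) // 2
        pos2 = g3.exons[j][1] + (g3.exons[j + 1][0] - g3.exons[j][1]) // 2
        svtype = "DEL" if g5.chrom == g3.chrom else "TRA"
        rows.append(dict(chrom1=g5.chrom, pos1=pos1 + 1, orient1="+",
                         chrom2=g3.chrom, pos2=pos2 + 1, orient2="-",
                         svtype=svtype))
    cols = ["chrom1", "pos1", "orient1", "chrom2", "pos2", "orient2",
            "svtype"]
    return pd.DataFrame(rows, columns=cols)


def simulate_sample(genome: GenomeModel, config: TumourSimConfig, seed: int,
                    fixtures: FixtureSet | None = None,
                    sample_id: str = "S001", patient_id: str | None = None,
                    cancer_type: str = "OTHER") -> SimulatedSample:
    """Simulate one tumour sample: ground truth plus observable data.

    Deterministic given ``seed``; all randomness flows from one generator.
    """
    config.validate()
    if not genome.chromosomes:
        raise ValueError("empty genome")
    rng = np.random.default_rng(seed)
    prof = _build_profile(genome, config, rng)
    _overlay_planted(prof, genome, config)
    segments = _segment_observables(prof, config, rng)
    truths = _point_variant_truths(genome, prof, config, fixtures, rng)
    truths += _planted_point_truths(genome, prof, config, fixtures)
    germline, extra = _germline_variants(genome, prof, config, rng)
    truths += extra
    somatic = _observe(truths, prof, config, rng)
    svs = _fusion_svs(genome, config)
    truth = TruthSample(sample_id, patient_id or sample_id, cancer_type,
                        config.purity, config.sex, config.wgd,
                        prof.to_truth(), config.clones, config.planted,
                        msi_target=config.msi_target)
    sim = SimulatedSample(truth, segments, somatic, germline, svs, seed)
    if config.msi_target > 0:
        sim = inject_msi(sim, genome, config.msi_target, seed + 104729)
    return sim


def inject_msi(sim: SimulatedSample, genome: GenomeModel,
               target_score: float, seed: int) -> SimulatedSample:
    """Inject microsatellite indels to a target qualifying-indel density.

    The number of injected indels is Poisson with mean
    ``target_score x genome Mb``; every indel lands inside a qualifying
    microsatellite (homopolymer of >= 5 bases, or a 2-4 bp unit repeated
    >= 4 times) and is clonal with multiplicity 1.
    """
    if target_score < 0:
        raise ValueError("target_score must be >= 0")
    if not genome.microsatellites:
        raise ValueError("genome has no microsatellite annotations")
    rng = np.random.default_rng(seed)
    qual = [m for m in genome.microsatellites
            if (m.unit_length == 1 and m.repeat_count >= 5)
            or (2 <= m.unit_length <= 4 and m.repeat_count >= 4)]
    usable = [m for m in qual if m.chrom in
              {s.chrom for s in sim.truth.segments}]
    n = int(rng.poisson(target_score * genome.length_mb))
    p = sim.truth.purity
    dm = ReadCountModel()
    prof_states = {}
    for s in sim.truth.segments:
        prof_states.setdefault(s.chrom, []).append(s)
    new_vars = list(sim.somatic)
    for _ in range(n):
        m = usable[int(rng.integers(len(usable)))]
        pos0 = int(rng.integers(m.start, m.end))
        seg = next(s for s in prof_states[m.chrom]
                   if s.start <= pos0 < s.end)
        nc = normal_copy_number(m.chrom, sim.truth.sex)
        d = p * seg.total + nc * (1 - p)
        if d <= 0:
            continue
        unit = "".join(rng.choice(_BASES, m.unit_length))
        base = str(rng.choice(_BASES))
        if rng.random() < 0.5:
            ref, alt = base + unit, base
        else:
            ref, alt = base, base + unit
        vaf = min(p / d, 1.0)
        depth = max(int(_draw_depth(rng, dm.tumour_depth * d / 2, dm)), 1)
        alt_count = int(rng.binomial(depth, vaf))
        if alt_count == 0:
            continue
        new_vars.append(SomaticVariant(m.chrom, pos0 + 1, ref, alt, "INDEL",
                                       alt_count, depth, clone_ccf=1.0))
    truth = dataclasses.replace(sim.truth, msi_target=target_score)
    chrom_order = {c.name: i for i, c in enumerate(genome.chromosomes)}
    new_vars.sort(key=lambda v: (chrom_order.get(v.chrom, 99), v.pos))
    return SimulatedSample(truth, sim.segments, new_vars, sim.germline,
                           sim.svs, sim.seed)


def simulate_cohort(genome: GenomeModel, n: int, config: TumourSimConfig,
                    seed: int, fixtures: FixtureSet | None = None,
                    purity_range: tuple[float, float] = (0.2, 1.0),
                    wgd_probability: float = 0.56,
                    planted_plan: list[PlantedEvents] | None = None,
                    cancer_types: list[str] | None = None
                    ) -> list[SimulatedSample]:
    """Simulate ``n`` independent samples with per-sample derived seeds.

    Purity is drawn uniformly from ``purity_range`` and WGD is Bernoulli
    with the cohort-level rate (default 0.56, the rate observed in
    metastatic tumours).  ``planted_plan`` optionally assigns planted events
    per sample.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    master = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sub_seed = int(master.integers(2 ** 31))
        purity = float(np.round(master.uniform(*purity_range), 3))
        wgd = bool(master.random() < wgd_probability)
        planted = (planted_plan[i] if planted_plan is not None
                   else config.planted)
        ctype = (cancer_types[i] if cancer_types is not None
                 else config_default_type(i))
        cfg = dataclasses.replace(config, purity=purity, wgd=wgd,
                                  planted=planted)
        out.append(simulate_sample(genome, cfg, sub_seed, fixtures,
                                   sample_id=f"S{i + 1:03d}",
                                   patient_id=f"P{i + 1:03d}",
                                   cancer_type=ctype))
    return out


def config_default_type(i: int) -> str:
    types = ["BREAST", "COLORECTAL", "LUNG", "PROSTATE", "SKIN", "OTHER"]
    return types[i % len(types)]


def simulate_biopsy_pair(genome: GenomeModel, config: TumourSimConfig,
                         seed: int, fixtures: FixtureSet | None = None,
                         shared_subclonal: float = 0.3,
                         patient_id: str = "P001"
                         ) -> tuple[SimulatedSample, SimulatedSample]:
    """Two biopsies of one patient: clonal variants shared, subclonal mixed.

    Biopsy B keeps every clonal variant of biopsy A, retains a fraction
    ``shared_subclonal`` of A's subclonal variants, replaces the rest with
    private subclonal variants, and re-draws all read support.
    """
    rng = np.random.default_rng(seed)
    sim_a = simulate_sample(genome, config, int(rng.integers(2 ** 31)),
                            fixtures, sample_id=f"{patient_id}-A",
                            patient_id=patient_id)
    prof = _Profile(genome, config.sex)
    prof.segs = {}
    for s in sim_a.truth.segments:
        prof.segs.setdefault(s.chrom, []).append(
            [s.start, s.end, s.major, s.minor])
    clonal = [v for v in sim_a.somatic if (v.clone_ccf or 1.0) == 1.0]
    subclonal = [v for v in sim_a.somatic if (v.clone_ccf or 1.0) < 1.0]
    keep = int(round(shared_subclonal * len(subclonal)))
    shared_sub = subclonal[:keep]
    truths = []
    for v in clonal + shared_sub:
        truths.append(_VariantTruth(v.chrom, v.pos, v.ref, v.alt, v.vtype,
                                    v.clone_ccf or 1.0, 1,
                                    phase_set=v.phase_set, gene=v.gene,
                                    consequence=v.consequence,
                                    context=v.context))
    # private subclonal variants of biopsy B
    sub_ccfs = [c.ccf for c in config.clones if c.ccf < 1.0] or [0.4]
    probs = _context_probs(config, fixtures)
    draw_pos = _position_sampler(prof, rng)
    for _ in range(len(subclonal) - keep):
        chrom, pos0 = draw_pos()
        label, ref, alt = _signature_context(rng, probs)
        ccf = float(rng.choice(sub_ccfs))
        truths.append(_VariantTruth(chrom, pos0 + 1, ref, alt, "SNV", ccf, 1,
                                    context=label))
    somatic_b = _observe(truths, prof, config, rng)
    segments_b = _segment_observables(prof, config, rng)
    truth_b = dataclasses.replace(sim_a.truth, sample_id=f"{patient_id}-B")
    sim_b = SimulatedSample(truth_b, segments_b, somatic_b,
                            list(sim_a.germline), sim_a.svs.copy(), seed)
    return sim_a, sim_b
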