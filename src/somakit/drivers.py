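"""Driver catalogue construction.

Builds the per-sample catalogue of candidate driver events across variant
classes — point mutations, high-level amplifications, homozygous deletions,
fusions and germline predisposition variants — with a likelihood score in
[0, 1] for each event.  Point-mutation likelihoods combine the gene/class
driver excess from the dN/dS analysis with the sample's mutational burden:

    likelihood = E / (E + P_sample),   P_sample = expected_passengers x
                                                  burden_sample / burden_mean

so that the same variant scores lower in a hypermutated sample.  Oncogene
variants at or within five nucleotides of a known hotspot, and biallelic
TSG variants in genes with a high biallelic driver fraction, are raised to
at least 0.99.

Copy-number peaks are discovered per chromosome with an iterative
GISTIC-like peel-off, and deletion peaks are annotated as common fragile
sites when the gene is long (> 500 kb) and > 30% of its deletions are
20 kb–1 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from statsmodels.stats.multitest import multipletests

from .config import Thresholds
from .dnds import DndsResult
from .genome import GeneModel, GenomeModel
from .variants import GermlineVariant, PloidyAnnotation, SomaticVariant

__all__ = ["DriverEvent", "AmpDelPeak", "GeneRoleClassifier",
           "make_role_training", "build_gene_panel", "find_cn_peaks",
           "annotate_fragile_sites", "call_point_drivers",
           "call_cn_and_fusion_drivers", "call_germline_drivers",
           "driver_cooccurrence", "summarize_driver_counts",
           "classify_fusion"]


@dataclass
class DriverEvent:
    sample: str
    gene: str
    event_class: str    # point|amplification|homozygous_deletion|fusion|
    #                     germline|msi
    detail: str = ""
    likelihood: float = 1.0
    biallelic: bool = False
    hotspot: bool = False
    fragile_site: bool = False
    subclonal_prob: float = 0.0

    def __post_init__(self):
        if not (0.0 <= self.likelihood <= 1.0):
            raise ValueError("likelihood outside [0, 1]")


@dataclass
class AmpDelPeak:
    chrom: str
    start: int
    end: int
    direction: str                  # amp | del
    support: int
    target_gene: str
    genes: tuple[str, ...]
    fragile_site: bool = False

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("empty peak interval")
        if self.target_gene not in self.genes:
            raise ValueError("target gene must lie inside the peak")


# ---------------------------------------------------------------- gene roles

class GeneRoleClassifier:
    """Logistic TSG/oncogene classifier over per-gene mutation features.

    Features: fraction of truncating variants, missense recurrence
    concentration, biallelic fraction, in-frame indel fraction.
    """

    FEATURES = ("frac_truncating", "missense_concentration",
                "biallelic_fraction", "inframe_indel_fraction")

    def __init__(self, seed: int = 0):
        self._model = LogisticRegression(random_state=seed, max_iter=500)
        self._fitted = False

    def fit(self, features: pd.DataFrame, labels: pd.Series
            ) -> "GeneRoleClassifier":
        self._model.fit(features[list(self.FEATURES)].to_numpy(),
                        (labels == "tsg").astype(int))
        self._fitted = True
        return self

    def predict(self, features: pd.DataFrame) -> pd.DataFrame:
        if not self._fitted:
            raise RuntimeError("classifier not trained")
        x = features[list(self.FEATURES)].to_numpy()
        p_tsg = self._model.predict_proba(x)[:, 1]
        return pd.DataFrame(dict(
            gene=features.gene if "gene" in features else np.arange(len(x)),
            role=np.where(p_tsg >= 0.5, "tsg", "oncogene"),
            role_probability=np.maximum(p_tsg, 1 - p_tsg)))


def make_role_training(seed: int = 0, n: int = 300) -> pd.DataFrame:
    """Synthetic labelled feature set emulating curated role annotation.

    TSG-like genes carry many truncating, dispersed, frequently biallelic
    variants; oncogene-like genes carry concentrated missense variants.
    """
    rng = np.random.default_rng(seed)
    half = n // 2
    tsg = pd.DataFrame(dict(
        gene=[f"TSG_{i}" for i in range(half)],
        frac_truncating=rng.beta(8, 4, half),
        missense_concentration=rng.beta(1.5, 8, half),
        biallelic_fraction=rng.beta(8, 3, half),
        inframe_indel_fraction=rng.beta(1, 20, half),
        role="tsg"))
    onc = pd.DataFrame(dict(
        gene=[f"ONC_{i}" for i in range(n - half)],
        frac_truncating=rng.beta(1, 20, n - half),
        missense_concentration=rng.beta(8, 2, n - half),
        biallelic_fraction=rng.beta(2, 8, n - half),
        inframe_indel_fraction=rng.beta(2, 10, n - half),
        role="oncogene"))
    return pd.concat([tsg, onc], ignore_index=True)


def build_gene_panel(cohort_smg: pd.DataFrame,
                     external_smg: pd.DataFrame,
                     curated: list[str],
                     roles: dict[str, str],
                     q_threshold: float = 0.01) -> pd.DataFrame:
    """Union gene panel: cohort SMGs, external SMGs (both at q < 0.01) and
    curated genes, with provenance flags and a role for every member."""

    def sig(df):
        if df is None or df.empty:
            return set()
        return set(df[df.q < q_threshold].gene)

    smg_c, smg_e = sig(cohort_smg), sig(external_smg)
    genes = sorted(smg_c | smg_e | set(curated))
    rows = []
    for g in genes:
        role = roles.get(g)
        if role is None:
            raise ValueError(f"panel gene {g} lacks a role")
        rows.append(dict(gene=g, smg_cohort=g in smg_c,
                         smg_external=g in smg_e, curated=g in curated,
                         role=role))
    return pd.DataFrame(rows)


# --------------------------------------------------------------- CN peaks

def find_cn_peaks(events: pd.DataFrame, genome: GenomeModel, direction: str,
                  panel_genes: set[str] | None = None,
                  min_support: int | None = None) -> list[AmpDelPeak]:
    """Iterative GISTIC-like peel-off peak discovery, per chromosome.

    ``events`` is a boolean samples x genes matrix of qualifying events
    (amplification or deletion).  Per chromosome the gene with maximal
    support seeds a peak — the maximal contiguous run of genes whose
    supporting-sample set equals the seed's; each supporting sample's
    contiguous event run through the seed is then removed and the search
    repeats until support falls below ``max(5, 2% of cohort)``.  The peak's
    target gene follows fixed curation rules: panel gene in the peak, else
    the shortest gene in the peak, else the seed gene.  Deletions exclude
    the Y chromosome.
    """
    if events.empty:
        return []
    n_samples = len(events)
    stop = min_support if min_support is not None else max(
        5, int(np.ceil(0.02 * n_samples)))
    panel_genes = panel_genes or set()
    peaks: list[AmpDelPeak] = []
    gene_models = {g.gene_id: g for g in genome.genes}
    for chrom in [c.name for c in genome.chromosomes]:
        if direction == "del" and chrom == "Y":
            continue
        order = [g.gene_id for g in genome.genes_on(chrom)
                 if g.gene_id in events.columns]
        if not order:
            continue
        m = events[order].to_numpy(copy=True)
        samples = list(events.index)
        while True:
            counts = m.sum(axis=0)
            if counts.max() < stop:
                break
            j = int(counts.argmax())
            seed_set = frozenset(np.flatnonzero(m[:, j]))
            lo = j
            while lo > 0 and frozenset(
                    np.flatnonzero(m[:, lo - 1])) == seed_set:
                lo -= 1
            hi = j
            while hi + 1 < len(order) and frozenset(
                    np.flatnonzero(m[:, hi + 1])) == seed_set:
                hi += 1
            peak_genes = tuple(order[lo:hi + 1])
            target = _curate_target(peak_genes, order[j], panel_genes,
                                    gene_models)
            start = min(gene_models[g].start for g in peak_genes)
            end = max(gene_models[g].end for g in peak_genes)
            peaks.append(AmpDelPeak(chrom, start, end, direction,
                                    len(seed_set), target, peak_genes))
            for si in seed_set:   # peel off the run through the seed locus
                a = j
                while a > 0 and m[si, a - 1]:
                    a -= 1
                b = j
                while b + 1 < len(order) and m[si, b + 1]:
                    b += 1
                m[si, a:b + 1] = False
    peaks.sort(key=lambda p: -p.support)
    return peaks


def _curate_target(peak_genes, seed_gene, panel_genes, gene_models) -> str:
    in_panel = [g for g in peak_genes if g in panel_genes]
    if in_panel:
        return in_panel[0] if seed_gene not in in_panel else seed_gene
    shortest = min(peak_genes, key=lambda g: gene_models[g].length_bp)
    return shortest


def annotate_fragile_sites(peaks: list[AmpDelPeak], genome: GenomeModel,
                           deletion_sizes: dict[str, list[int]],
                           thresholds: Thresholds = Thresholds()
                           ) -> list[AmpDelPeak]:
    """Flag deletion peaks whose target gene looks like a fragile site.

    Requires both gene length > 500 kb and more than 30% of the gene's
    observed deletions sized between 20 kb and 1 Mb.
    """
    for p in peaks:
        if p.direction != "del":
            continue
        gene = genome.gene(p.target_gene)
        sizes = deletion_sizes.get(p.target_gene, [])
        if gene.length_bp <= thresholds.fragile_min_gene_length or not sizes:
            continue
        mid = sum(thresholds.fragile_del_min <= s <= thresholds.fragile_del_max
                  for s in sizes)
        if mid / len(sizes) > thresholds.fragile_min_del_fraction:
            p.fragile_site = True
    return peaks


# ------------------------------------------------------------ point drivers

_CSQ_TO_CLS = {"missense": "missense", "nonsense": "nonsense",
               "splice": "splice"}


def _near_hotspot(variant: SomaticVariant, hotspots: pd.DataFrame,
                  margin: int) -> bool:
    sub = hotspots[hotspots.gene == variant.gene]
    return any(abs(int(row.pos) - variant.pos) <= margin
               for row in sub.itertuples(index=False))


def call_point_drivers(sample_id: str, variants: list[SomaticVariant],
                       annotations: list[PloidyAnnotation],
                       panel: pd.DataFrame, dnds: DndsResult | None,
                       sample_burden: float, cohort_mean_burden: float,
                       hotspots: pd.DataFrame,
                       biallelic_fractions: dict[str, float] | None = None,
                       subclonal_probs: np.ndarray | None = None,
                       thresholds: Thresholds = Thresholds(),
                       promoter_genes: tuple[str, ...] = ("TERT",)
                       ) -> list[DriverEvent]:
    """Point-mutation driver events with per-sample likelihoods.

    Inclusion rules per gene role: oncogenes take missense variants and
    in-frame indels; TSGs take any non-synonymous or essential-splice
    point mutation and indels.  Non-coding variants are limited to
    promoter mutations of ``promoter_genes``.
    """
    roles = dict(zip(panel.gene, panel.role))
    biallelic_fractions = biallelic_fractions or {}
    sp = (subclonal_probs if subclonal_probs is not None
          else np.zeros(len(variants)))
    out = []
    for v, ann, sub_p in zip(variants, annotations, sp):
        if v.gene not in roles:
            continue
        role = roles[v.gene]
        if role not in ("oncogene", "tsg"):
            raise ValueError(f"panel gene {v.gene} lacks a role")
        if v.vtype == "INDEL":
            inframe = abs(len(v.ref) - len(v.alt)) % 3 == 0
            if role == "oncogene" and not inframe:
                continue
            cls = "indel"
        elif v.consequence == "promoter":
            if v.gene not in promoter_genes:
                continue
            cls = None
        elif role == "oncogene":
            if v.consequence not in ("missense",):
                continue
            cls = _CSQ_TO_CLS[v.consequence]
        else:  # tsg
            if v.consequence not in ("missense", "nonsense", "splice"):
                continue
            cls = _CSQ_TO_CLS[v.consequence]
        if cls is None:
            # recurrent promoter hotspot: treated as known pathogenic
            like = 0.99
        else:
            like = _point_likelihood(v.gene, cls, dnds, sample_burden,
                                     cohort_mean_burden)
        hot = False
        if role == "oncogene" and v.vtype != "INDEL" and _near_hotspot(
                v, hotspots, thresholds.hotspot_margin_nt):
            like = max(like, 0.99)
            hot = True
        if (role == "tsg" and ann.biallelic
                and biallelic_fractions.get(v.gene, 0.0)
                > thresholds.biallelic_driver_fraction):
            like = max(like, 0.99)
        out.append(DriverEvent(sample_id, v.gene, "point",
                               detail=f"{v.chrom}:{v.pos}:{v.ref}:{v.alt}",
                               likelihood=min(like, 1.0),
                               biallelic=ann.biallelic, hotspot=hot,
                               subclonal_prob=float(sub_p)))
    return out


def _point_likelihood(gene: str, cls: str, dnds: DndsResult | None,
                      burden: float, mean_burden: float) -> float:
    if dnds is None:
        return 0.0
    row = dnds.gene_class(gene, cls)
    if row is None:
        return 0.0
    excess = max(float(row.observed) - float(row.expected), 0.0)
    passengers = float(row.expected) * (burden / max(mean_burden, 1e-12))
    if excess <= 0:
        return 0.0
    return excess / (excess + passengers)


# --------------------------------------------------- CN and fusion drivers

def _intron_index(gene: GeneModel, pos1: int) -> int | None:
    pos = pos1 - 1
    for i in range(len(gene.exons) - 1):
        if gene.exons[i][1] <= pos < gene.exons[i + 1][0]:
            return i
    return None


def classify_fusion(sv_row, genome: GenomeModel,
                    known_fusions: pd.DataFrame) -> dict | None:
    """Classify one SV breakpoint pair as a candidate fusion.

    Returns a dict with keys (five_gene, three_gene, kind) where kind is
    'in_frame_coding', 'cis_activating' or 'intragenic_deletion', or None
    when the SV does not produce a known in-frame or activating fusion.
    """
    g5 = next((g for g in genome.genes_on(sv_row.chrom1)
               if g.contains(int(sv_row.pos1) - 1)), None)
    g3 = next((g for g in genome.genes_on(sv_row.chrom2)
               if g.contains(int(sv_row.pos2) - 1)), None)
    if g5 is not None and g3 is not None and g5.gene_id == g3.gene_id:
        # deletion internal to one gene: in-frame exon deletion?
        lo, hi = sorted((int(sv_row.pos1), int(sv_row.pos2)))
        deleted = sum(min(hi - 1, ee) - max(lo - 1, es)
                      for es, ee in g5.exons
                      if es < hi - 1 and ee > lo - 1)
        if deleted > 0 and deleted % 3 == 0:
            return dict(five_gene=g5.gene_id, three_gene=g5.gene_id,
                        kind="intragenic_deletion")
        return None
    if g3 is None and sv_row.chrom2 is not None:
        # breakpoint upstream of a gene: 5' regulatory repositioning
        g3 = next((g for g in genome.genes_on(sv_row.chrom2)
                   if g.promoter[0] <= int(sv_row.pos2) - 1 < g.promoter[1]),
                  None)
        if g3 is not None and _known_pair(known_fusions, None, g3.gene_id):
            return dict(five_gene=g5.gene_id if g5 else "intergenic",
                        three_gene=g3.gene_id, kind="cis_activating")
        return None
    if g5 is None or g3 is None:
        return None
    if not _known_pair(known_fusions, g5.gene_id, g3.gene_id):
        return None
    i = _intron_index(g5, int(sv_row.pos1))
    j = _intron_index(g3, int(sv_row.pos2))
    if i is None or j is None:
        return None
    if g5.exon_phase(i + 1) == g3.exon_phase(j + 1):
        return dict(five_gene=g5.gene_id, three_gene=g3.gene_id,
                    kind="in_frame_coding")
    return None


def _known_pair(known: pd.DataFrame, five: str | None, three: str) -> bool:
    for row in known.itertuples(index=False):
        if row.three_gene == three and (row.promiscuous_3p or five is None
                                        or row.five_gene == five):
            return True
    return False


def call_cn_and_fusion_drivers(sample_id: str, gene_cna: pd.DataFrame,
                               ploidy: float, svs: pd.DataFrame,
                               peaks: list[AmpDelPeak], panel: pd.DataFrame,
                               known_fusions: pd.DataFrame,
                               genome: GenomeModel,
                               thresholds: Thresholds = Thresholds()
                               ) -> list[DriverEvent]:
    """Copy-number and fusion driver events for one sample.

    Amplification drivers: min exonic CN > 3 x sample ploidy in a
    significantly amplified target gene or panel oncogene.  Deletion
    drivers: min exonic CN < 0.5 in a significantly deleted target gene or
    panel TSG (Y excluded).  Fusions: known/promiscuous in-frame coding
    fusions, cis-activating 5' repositionings and in-frame intragenic exon
    deletions.
    """
    roles = dict(zip(panel.gene, panel.role))
    amp_targets = {p.target_gene for p in peaks if p.direction == "amp"}
    del_targets = {p.target_gene for p in peaks if p.direction == "del"}
    fragile = {p.target_gene for p in peaks if p.fragile_site}
    out = []
    gene_chrom = {g.gene_id: g.chrom for g in genome.genes}
    for row in gene_cna.itertuples(index=False):
        g = row.gene
        if (row.min_exonic_cn > thresholds.amp_high * ploidy
                and (g in amp_targets or roles.get(g) == "oncogene")):
            out.append(DriverEvent(sample_id, g, "amplification",
                                   detail=f"cn={row.min_exonic_cn:.2f}"))
        if (row.min_exonic_cn < thresholds.homdel_max_cn
                and gene_chrom.get(g) != "Y"
                and (g in del_targets or roles.get(g) == "tsg")):
            out.append(DriverEvent(sample_id, g, "homozygous_deletion",
                                   detail=f"cn={row.min_exonic_cn:.2f}",
                                   biallelic=True,
                                   fragile_site=g in fragile))
    for sv in svs.itertuples(index=False):
        hit = classify_fusion(sv, genome, known_fusions)
        if hit is not None:
            out.append(DriverEvent(sample_id, hit["three_gene"], "fusion",
                                   detail=f"{hit['five_gene']}-"
                                          f"{hit['three_gene']}:"
                                          f"{hit['kind']}"))
    return out


# ----------------------------------------------------------- germline

def call_germline_drivers(sample_id: str,
                          germline: list[GermlineVariant],
                          cn_segments, somatic: list[SomaticVariant],
                          purity: float,
                          germline_panel: tuple[str, ...],
                          thresholds: Thresholds = Thresholds()
                          ) -> list[DriverEvent]:
    """Germline predisposition drivers with loss-of-wild-type assessment.

    Only pathogenic variants in the high-confidence 29-gene panel are
    reported.  For each, the tumour allele configuration decides whether
    the wild type or the variant itself was lost: at an LOH locus the
    variant ploidy (from tumour VAF) near the local CN means the wild type
    is lost; near zero means the variant allele was lost.  A somatic
    non-synonymous hit in the same gene counts as a second hit.
    """
    from .interpret import local_copy_number
    somatic_hit_genes = {v.gene for v in somatic if v.gene
                         and (v.consequence in ("missense", "nonsense",
                                                "splice")
                              or v.vtype == "INDEL")}
    out = []
    for gv in germline:
        if not gv.pathogenic or gv.gene not in germline_panel:
            continue
        cn, minor = local_copy_number(cn_segments, gv.chrom, gv.pos)
        d = purity * cn + 2 * (1 - purity)
        n_var = ((gv.tumour_vaf * d - (1 - purity)) / purity
                 if purity > 0 else 0.0)
        loh = minor < thresholds.loh_minor_ploidy
        wild_type_lost = loh and n_var > cn - thresholds.biallelic_offset
        variant_lost = loh and n_var < thresholds.biallelic_offset
        second_hit = gv.gene in somatic_hit_genes
        if variant_lost and not second_hit:
            # the predisposition allele itself was lost: not a driver hit
            continue
        out.append(DriverEvent(
            sample_id, gv.gene, "germline",
            detail=(f"{gv.chrom}:{gv.pos}:{gv.ref}:{gv.alt};"
                    f"genotype={gv.genotype};"
                    f"wild_type_lost={wild_type_lost};"
                    f"second_hit={second_hit}"),
            likelihood=1.0,
            biallelic=wild_type_lost or second_hit or gv.genotype == "HOM"))
    return out


# ----------------------------------------------------- cohort summaries

def driver_cooccurrence(catalogue: pd.DataFrame, all_samples: list[str],
                        min_likelihood: float = 0.5) -> pd.DataFrame:
    """Pairwise driver co-occurrence: two-sided Fisher test per gene pair.

    Positive direction = co-occurring, negative = mutually exclusive,
    with Benjamini-Hochberg q-values.
    """
    cat = catalogue[catalogue.likelihood >= min_likelihood]
    genes = sorted(cat.gene.unique())
    mutated = {g: set(cat[cat.gene == g]["sample"]) for g in genes}
    n = len(all_samples)
    rows = []
    for i, ga in enumerate(genes):
        for gb in genes[i + 1:]:
            a, b = mutated[ga], mutated[gb]
            both = len(a & b)
            only_a = len(a) - both
            only_b = len(b) - both
            neither = n - both - only_a - only_b
            odds, p = stats.fisher_exact([[both, only_a],
                                          [only_b, neither]])
            direction = "co_occurring" if (both * neither
                                           > only_a * only_b) else \
                "mutually_exclusive"
            rows.append(dict(gene_a=ga, gene_b=gb, both=both,
                             only_a=only_a, only_b=only_b, neither=neither,
                             odds_ratio=odds, p=p, direction=direction))
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q"] = multipletests(out.p, method="fdr_bh")[1]
    return out


def summarize_driver_counts(catalogue: pd.DataFrame) -> pd.DataFrame:
    """Per-sample driver burden: sum of likelihoods, overall and subclonal.

    The subclonal driver burden is the sum of subclonal probability x
    driver likelihood across the catalogue.
    """
    if catalogue.empty:
        return pd.DataFrame(columns=["sample", "driver_burden",
                                     "subclonal_driver_burden"])
    cat = catalogue.copy()
    cat["subclonal_load"] = cat.likelihood * cat.subclonal_prob
    per_class = (cat.pivot_table(index="sample", columns="event_class",
                                 values="likelihood", aggfunc="sum",
                                 fill_value=0.0))
    out = pd.DataFrame(dict(
        driver_burden=cat.groupby("sample").likelihood.sum(),
        subclonal_driver_burden=cat.groupby("sample").subclonal_load.sum()))
    out = out.join(per_class).fillna(0.0).reset_index()
    return out


def catalogue_to_frame(events: list[DriverEvent]) -> pd.DataFrame:
    cols = ["sample", "gene", "event_class", "detail", "likelihood",
            "biallelic", "hotspot", "fragile_site", "subclonal_prob"]
    return pd.DataFrame([{c: getattr(e, c) for c in cols} for e in events],
                        columns=cols)
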