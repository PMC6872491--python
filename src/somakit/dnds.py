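"""Simplified dN/dS driver-gene testing.

Per-trinucleotide-context mutation rates are estimated from synonymous
sites cohort-wide; expected nonsynonymous counts per gene and variant class
follow from context-resolved opportunity counting over the gene's coding
sequence; each gene x class is tested against the neutral null (dN/dS = 1)
with a one-sided Poisson test and Benjamini-Hochberg correction.  Genes at
q < 0.01 are flagged significant.

This is deliberately a reduced model: no covariates and no shrinkage across
genes — the neutral null and the q-value gate are preserved, nothing else.
Splice and indel classes have no sequence context here; their expected
counts are opportunity-proportional shares of the cohort totals, so the
global ratio for those classes is 1 by construction while per-gene excess
remains testable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GeneModel, GenomeModel
from .signatures import context_index, context_of
from .variants import SomaticVariant

__all__ = ["GeneSites", "build_site_tables", "DndsResult", "run_dnds",
           "simulate_coding_cohort"]

CLASSES = ("synonymous", "missense", "nonsense")
_CLS_IDX = {c: i for i, c in enumerate(CLASSES)}


@dataclass
class GeneSites:
    """All possible SNVs of a gene's CDS, class- and context-resolved."""

    gene_id: str
    cds_pos: np.ndarray             # site CDS index per possible SNV
    cls: np.ndarray                 # 0 syn, 1 mis, 2 non
    ctx: np.ndarray                 # 96-context index
    ref: np.ndarray                 # ref base per SNV (unicode)
    alt: np.ndarray
    opportunity: np.ndarray         # (3, 96) count of possible SNVs
    splice_sites: int               # possible splice-disrupting SNVs

    @property
    def coding_length(self) -> int:
        return self.cds_pos.max() + 1 if self.cds_pos.size else 0


def _gene_sites(gene: GeneModel) -> GeneSites:
    seq = gene.cds_seq
    n = len(seq)
    pos_l, cls_l, ctx_l, ref_l, alt_l = [], [], [], [], []
    for idx in range(n):
        ref = seq[idx]
        five = seq[idx - 1] if idx else seq[0]
        three = seq[idx + 1] if idx < n - 1 else seq[-1]
        gpos = gene.cds_to_genomic(idx)
        for alt in "ACGT":
            if alt == ref:
                continue
            csq = gene.consequence(gpos, ref, alt)
            if csq not in _CLS_IDX:
                continue
            pos_l.append(idx)
            cls_l.append(_CLS_IDX[csq])
            ctx_l.append(context_index(context_of(five, ref, alt, three)))
            ref_l.append(ref)
            alt_l.append(alt)
    cls = np.array(cls_l, dtype=np.int8)
    ctx = np.array(ctx_l, dtype=np.int16)
    opp = np.zeros((3, 96))
    np.add.at(opp, (cls, ctx), 1.0)
    splice = 3 * 4 * (len(gene.exons) - 1)  # 2+2 intronic bases per junction
    return GeneSites(gene.gene_id, np.array(pos_l), cls, ctx,
                     np.array(ref_l), np.array(alt_l), opp, splice)


def build_site_tables(genome: GenomeModel) -> dict[str, GeneSites]:
    return {g.gene_id: _gene_sites(g) for g in genome.genes}


@dataclass
class DndsResult:
    """Per gene x class selection test plus global class-level ratios."""

    table: pd.DataFrame             # gene, cls, observed, expected, ratio, p, q
    global_ratio: dict[str, float]
    n_samples: int

    def significant_genes(self, q_cut: float = 0.01) -> set[str]:
        sig = self.table[(self.table.q < q_cut)
                         & (self.table.cls != "synonymous")]
        return set(sig.gene)

    def gene_class(self, gene: str, cls: str) -> pd.Series:
        sub = self.table[(self.table.gene == gene) & (self.table.cls == cls)]
        return sub.iloc[0] if len(sub) else None


def _observed_counts(cohort, genes: set[str]) -> pd.DataFrame:
    rows = []
    for sample in cohort:
        for v in sample:
            if v.gene not in genes:
                continue
            if v.vtype == "INDEL":
                cls = "indel"
            elif v.consequence in ("synonymous", "missense", "nonsense",
                                   "splice"):
                cls = v.consequence
            else:
                continue
            rows.append((v.gene, cls))
    return pd.DataFrame(rows, columns=["gene", "cls"])


def run_dnds(cohort: list[list[SomaticVariant]], genome: GenomeModel,
             site_tables: dict[str, GeneSites] | None = None,
             q_threshold: float = 0.01) -> DndsResult:
    """Test every gene for mutation excess over the context-rate null.

    ``cohort`` is one variant list per sample; variants must carry gene and
    consequence annotation.  Raises if the cohort is empty or contains no
    synonymous variants (rates unidentifiable).
    """
    if not cohort or all(len(s) == 0 for s in cohort):
        raise ValueError("empty cohort")
    sites = site_tables or build_site_tables(genome)
    genes = set(sites)
    obs = _observed_counts(cohort, genes)
    n_samples = len(cohort)
    syn = obs[obs.cls == "synonymous"]
    if syn.empty:
        raise ValueError("no synonymous variants; context rates "
                         "unidentifiable")
    # context rates from synonymous sites, cohort-wide
    syn_opp = np.sum([s.opportunity[0] for s in sites.values()], axis=0)
    syn_ctx = np.zeros(96)
    for sample in cohort:
        for v in sample:
            if v.consequence == "synonymous" and v.context:
                syn_ctx[context_index(v.context)] += 1
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(syn_opp > 0, syn_ctx / np.maximum(syn_opp, 1), 0.0)
    # fallback for unobservable contexts: global mean synonymous rate
    global_rate = syn_ctx.sum() / syn_opp.sum()
    rate = np.where(syn_opp > 0, rate, global_rate)

    counts = obs.groupby(["gene", "cls"]).size()
    total_coding = sum(s.coding_length for s in sites.values())
    total_splice = sum(s.splice_sites for s in sites.values())
    total_indel = int((obs.cls == "indel").sum())
    total_splice_obs = int((obs.cls == "splice").sum())

    rows = []
    for gid, s in sites.items():
        for cls in ("synonymous", "missense", "nonsense"):
            exp = float(s.opportunity[_CLS_IDX[cls]] @ rate)
            o = int(counts.get((gid, cls), 0))
            rows.append(dict(gene=gid, cls=cls, observed=o, expected=exp))
        exp_sp = (total_splice_obs * s.splice_sites / total_splice
                  if total_splice else 0.0)
        rows.append(dict(gene=gid, cls="splice",
                         observed=int(counts.get((gid, "splice"), 0)),
                         expected=exp_sp))
        exp_ind = total_indel * s.coding_length / total_coding
        rows.append(dict(gene=gid, cls="indel",
                         observed=int(counts.get((gid, "indel"), 0)),
                         expected=exp_ind))
    tab = pd.DataFrame(rows)
    with np.errstate(divide="ignore", invalid="ignore"):
        tab["ratio"] = np.where(tab.expected > 0,
                                tab.observed / tab.expected, np.nan)
    # one-sided Poisson excess test; synonymous rows are the calibration
    # class and are not tested
    testable = (tab.cls != "synonymous") & (tab.expected > 0)
    pvals = np.ones(len(tab))
    pvals[testable.values] = stats.poisson.sf(
        tab.observed[testable] - 1, tab.expected[testable])
    tab["p"] = pvals
    tab["q"] = 1.0
    if testable.any():
        tab.loc[testable, "q"] = multipletests(tab.p[testable],
                                               method="fdr_bh")[1]
    tab["significant"] = (tab.q < q_threshold) & testable
    glob = {}
    for cls in ("missense", "nonsense", "splice", "indel"):
        sub = tab[tab.cls == cls]
        glob[cls] = float(sub.observed.sum() / max(sub.expected.sum(),
                                                   1e-12))
    return DndsResult(tab, glob, n_samples)


def simulate_coding_cohort(genome: GenomeModel, n_samples: int,
                           muts_per_sample: int, seed: int,
                           site_tables: dict[str, GeneSites] | None = None,
                           excess: dict[str, tuple[str, float]] | None = None,
                           context_weights: np.ndarray | None = None,
                           indels_per_sample: int = 0
                           ) -> list[list[SomaticVariant]]:
    """Simulate coding mutations under the neutral context model.

    Every possible coding SNV receives a weight proportional to its
    context mutability (uniform by default); ``excess`` multiplies the
    weights of one gene's sites of a given class, planting positive
    selection.  Variants are emitted fully annotated with nominal read
    support, ready for ``run_dnds``.
    """
    rng = np.random.default_rng(seed)
    sites = site_tables or build_site_tables(genome)
    gene_ids, gpos, refs, alts, csq, w = [], [], [], [], [], []
    for gid, s in sites.items():
        gene = genome.gene(gid)
        wt = (context_weights[s.ctx] if context_weights is not None
              else np.ones(s.ctx.size))
        wt = wt.astype(float).copy()
        if excess and gid in excess:
            cls_name, factor = excess[gid]
            wt[s.cls == _CLS_IDX[cls_name]] *= factor
        gene_ids.extend([gid] * s.cds_pos.size)
        gpos.extend(gene.cds_to_genomic(int(i)) + 1 for i in s.cds_pos)
        refs.extend(str(r) for r in s.ref)
        alts.extend(str(a) for a in s.alt)
        csq.extend(CLASSES[int(c)] for c in s.cls)
        w.append(wt)
    weights = np.concatenate(w)
    weights = weights / weights.sum()
    chroms = {gid: genome.gene(gid).chrom for gid in sites}
    cohort = []
    for _ in range(n_samples):
        picks = rng.choice(len(gene_ids), size=muts_per_sample, p=weights)
        sample = []
        for k in picks:
            gid = gene_ids[k]
            s = sites[gid]
            # context for rate re-estimation
            gene = genome.gene(gid)
            seq = gene.cds_seq
            # recover cds idx from stored arrays (parallel ordering)
            sample.append(SomaticVariant(
                chroms[gid], int(gpos[k]), refs[k], alts[k], "SNV",
                30, 60, gene=gid, consequence=csq[k],
                context=_site_context(seq, gene, int(gpos[k]), refs[k],
                                      alts[k])))
        for _ in range(indels_per_sample):
            k = int(rng.integers(len(gene_ids)))
            gid = gene_ids[k]
            sample.append(SomaticVariant(
                chroms[gid], int(gpos[k]), refs[k] + "A", refs[k], "INDEL",
                30, 60, gene=gid, consequence="indel"))
        cohort.append(sample)
    return cohort


def _site_context(seq: str, gene: GeneModel, pos1: int, ref: str,
                  alt: str) -> str:
    idx = gene.genomic_to_cds(pos1 - 1)
    five = seq[idx - 1] if idx else seq[0]
    three = seq[idx + 1] if idx < len(seq) - 1 else seq[-1]
    return context_of(five, ref, alt, three)
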