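"""Fixture knowledgebases for the synthetic cohort.

Generates the reference resources every downstream stage needs — gene panel
with oncogene/TSG roles, mutation hotspots, known fusion pairs, a synthetic
signature matrix, a clinical-evidence knowledgebase and a small disease
ontology — so the whole stack runs without any download.  The signature
matrix and the evidence records are synthetic stand-ins for curated public
catalogues; files are written with a ``_synthetic`` marker in the name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GERMLINE_PANEL, GeneModel, GenomeModel
from .signatures import random_signature_matrix

__all__ = ["FixtureSet", "make_fixture_resources", "write_fixtures",
           "load_fixtures", "find_coding_snv"]


def find_coding_snv(gene: GeneModel, kind: str,
                    start_codon: int | None = None) -> tuple[int, str, str]:
    """Deterministically locate an SNV of the requested consequence.

    Returns (genomic position 1-based, ref, alt) for the first CDS site at
    or after ``start_codon`` (default: middle of the CDS) whose substitution
    is classified as ``kind`` ('missense', 'nonsense' or 'synonymous').
    """
    n = len(gene.cds_seq)
    begin = 3 * (start_codon if start_codon is not None else n // 6)
    for idx in list(range(begin, n)) + list(range(3, begin)):
        ref = gene.cds_seq[idx]
        for alt in "ACGT":
            if alt == ref:
                continue
            pos0 = gene.cds_to_genomic(idx)
            if gene.consequence(pos0, ref, alt) == kind:
                return pos0 + 1, ref, alt
    raise ValueError(f"no {kind} site found in {gene.gene_id}")


@dataclass
class FixtureSet:
    panel: pd.DataFrame              # gene, role, smg_cohort/smg_external/curated
    hotspots: pd.DataFrame           # gene, chrom, pos, ref, alt
    known_fusions: pd.DataFrame      # five_gene, three_gene, promiscuous_3p
    signatures: np.ndarray           # (96, 30), columns sum to 1
    signature_names: tuple[str, ...]
    evidence: list[dict]             # raw knowledgebase records
    ontology: dict[str, str]         # child DOID -> parent DOID
    doid_names: dict[str, str] = field(default_factory=dict)
    cancer_type_doid: dict[str, str] = field(default_factory=dict)
    germline_panel: tuple[str, ...] = GERMLINE_PANEL

    def hotspot_sites(self, gene: str) -> list[tuple[str, int]]:
        sub = self.hotspots[self.hotspots.gene == gene]
        return list(zip(sub.chrom, sub.pos))


_ONTOLOGY = {
    "DOID:1612": "DOID:162",   # breast cancer -> cancer
    "DOID:3856": "DOID:1612",  # breast lobular carcinoma -> breast cancer
    "DOID:1909": "DOID:162",   # melanoma -> cancer
    "DOID:9256": "DOID:162",   # colorectal cancer -> cancer
    "DOID:3905": "DOID:162",   # lung carcinoma -> cancer
    "DOID:10283": "DOID:162",  # prostate cancer -> cancer
}

_DOID_NAMES = {
    "DOID:162": "cancer", "DOID:1612": "breast cancer",
    "DOID:3856": "breast lobular carcinoma", "DOID:1909": "melanoma",
    "DOID:9256": "colorectal cancer", "DOID:3905": "lung carcinoma",
    "DOID:10283": "prostate cancer",
}

_TYPE_DOID = {
    "BREAST": "DOID:1612", "BREAST_LOBULAR": "DOID:3856",
    "SKIN": "DOID:1909", "COLORECTAL": "DOID:9256", "LUNG": "DOID:3905",
    "PROSTATE": "DOID:10283", "OTHER": "DOID:162",
}


def _evidence_records(hotspots: pd.DataFrame) -> list[dict]:
    def hs(gene):
        row = hotspots[hotspots.gene == gene].iloc[0]
        return f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}"

    rec = [
        dict(gene="BRAF", event_class="point", detail=hs("BRAF"),
             drug="BRAF-inhibitor", level="A", direction="sensitivity",
             doid="DOID:1909"),
        dict(gene="BRAF", event_class="point", detail=hs("BRAF"),
             drug="BRAF-inhibitor", level="A", direction="sensitivity",
             doid="DOID:1909"),  # duplicate across sources, deduplicated
        dict(gene="KRAS", event_class="point", detail=None,
             drug="EGFR-antibody", level="A", direction="resistance",
             doid="DOID:9256"),
        dict(gene="EGFR", event_class="amplification", detail=None,
             drug="EGFR-antibody", level="B", direction="sensitivity",
             doid="DOID:9256"),
        dict(gene="ERBB2", event_class="amplification", detail=None,
             drug="HER2-antibody", level="A", direction="sensitivity",
             doid="DOID:1612"),
        dict(gene="PIK3CA", event_class="point", detail=None,
             drug="HER2-antibody", level="B", direction="resistance",
             doid="DOID:1612"),
        dict(gene="ALK", event_class="fusion", detail=None,
             drug="ALK-inhibitor", level="A", direction="sensitivity",
             doid="DOID:3905"),
        dict(gene=None, event_class="msi", detail=None,
             drug="PD1-inhibitor", level="A", direction="sensitivity",
             doid="DOID:162"),
        dict(gene="PTEN", event_class="homozygous_deletion", detail=None,
             drug="AKT-inhibitor", level="B", direction="sensitivity",
             doid="DOID:10283"),
        dict(gene="PIK3CA", event_class="point", detail=hs("PIK3CA"),
             drug="PI3K-inhibitor", level="A", direction="sensitivity",
             doid="DOID:1612"),
        dict(gene="MYC", event_class="amplification", detail=None,
             drug="experimental-agent", level="C", direction="sensitivity",
             doid="DOID:162"),  # below-threshold level, dropped on load
    ]
    return rec


def make_fixture_resources(genome: GenomeModel, seed: int = 0) -> FixtureSet:
    """Build the full fixture set for a genome; deterministic given seed."""
    panel_rows = [
        dict(gene=g.gene_id, role=g.role_label, smg_cohort=False,
             smg_external=False, curated=True)
        for g in genome.genes if g.is_panel
    ]
    panel = pd.DataFrame(panel_rows)

    hs_rows = []
    for g in genome.genes:
        if g.role_label != "oncogene":
            continue
        pos, ref, alt = find_coding_snv(g, "missense")
        hs_rows.append(dict(gene=g.gene_id, chrom=g.chrom, pos=pos,
                            ref=ref, alt=alt))
    hotspots = pd.DataFrame(hs_rows)

    fusions = pd.DataFrame([
        dict(five_gene="TMPRSS2", three_gene="ERG", promiscuous_3p=False),
        dict(five_gene="EML4", three_gene="ALK", promiscuous_3p=True),
    ])

    sig = random_signature_matrix(30, seed=seed)
    names = tuple(f"S{i + 1}" for i in range(30))
    return FixtureSet(panel, hotspots, fusions, sig, names,
                      _evidence_records(hotspots), dict(_ONTOLOGY),
                      dict(_DOID_NAMES), dict(_TYPE_DOID))


def write_fixtures(fix: FixtureSet, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fix.panel.to_csv(outdir / "gene_panel.tsv", sep="\t", index=False)
    fix.hotspots.to_csv(outdir / "hotspots.tsv", sep="\t", index=False)
    fix.known_fusions.to_csv(outdir / "known_fusions.tsv", sep="\t",
                             index=False)
    sig = pd.DataFrame(fix.signatures, columns=list(fix.signature_names))
    sig.to_csv(outdir / "signatures_synthetic.tsv", sep="\t", index=False)
    with open(outdir / "evidence_kb_synthetic.json", "w") as fh:
        json.dump(fix.evidence, fh, indent=1)
    pd.DataFrame([{"child": c, "parent": p} for c, p in fix.ontology.items()]
                 ).to_csv(outdir / "ontology.tsv", sep="\t", index=False)
    pd.DataFrame([{"cancer_type": t, "doid": d}
                  for t, d in fix.cancer_type_doid.items()]
                 ).to_csv(outdir / "doid_map.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": list(fix.germline_panel)}).to_csv(
        outdir / "germline_panel.tsv", sep="\t", index=False)


def load_fixtures(indir: str | Path) -> FixtureSet:
    indir = Path(indir)
    panel = pd.read_csv(indir / "gene_panel.tsv", sep="\t")
    hotspots = pd.read_csv(indir / "hotspots.tsv", sep="\t")
    fusions = pd.read_csv(indir / "known_fusions.tsv", sep="\t")
    sig = pd.read_csv(indir / "signatures_synthetic.tsv", sep="\t")
    with open(indir / "evidence_kb_synthetic.json") as fh:
        evidence = json.load(fh)
    ont = pd.read_csv(indir / "ontology.tsv", sep="\t")
    doid_map = pd.read_csv(indir / "doid_map.tsv", sep="\t")
    germ = pd.read_csv(indir / "germline_panel.tsv", sep="\t")
    return FixtureSet(panel, hotspots, fusions, sig.to_numpy(),
                      tuple(sig.columns), evidence,
                      dict(zip(ont.child, ont.parent)), dict(_DOID_NAMES),
                      dict(zip(doid_map.cancer_type, doid_map.doid)),
                      tuple(germ.gene))
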