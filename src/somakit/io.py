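"""Readers and writers for the pipeline's file formats.

Observables are exchanged as plain-text standard formats: minimal VCF 4.2
for somatic and germline small variants (sites-only records with read
support in INFO), TSV for segments and SV breakpoints, JSON for simulation
truth.  VCFs are parsed back with cyvcf2.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from cyvcf2 import VCF

from .config import CloneSpec, PlantedEvents
from .simulate import SegmentTruth, SimulatedSample, TruthSample
from .variants import GermlineVariant, SomaticVariant

__all__ = ["write_sample", "read_sample", "write_somatic_vcf",
           "read_somatic_vcf", "write_germline_vcf", "read_germline_vcf"]

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant class">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
##INFO=<ID=VRC,Number=1,Type=Integer,Description="Variant-supporting reads">
##INFO=<ID=PS,Number=1,Type=Integer,Description="Phase set">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene annotation">
##INFO=<ID=CSQ,Number=1,Type=String,Description="Coding consequence">
##INFO=<ID=TNC,Number=1,Type=String,Description="Trinucleotide context">
##INFO=<ID=GT,Number=1,Type=String,Description="Germline genotype">
##INFO=<ID=PATH,Number=0,Type=Flag,Description="Pathogenic">
##INFO=<ID=TAC,Number=1,Type=Integer,Description="Tumour alt reads">
##INFO=<ID=TDP,Number=1,Type=Integer,Description="Tumour depth">
"""


def _contig_lines(chrom_lengths: dict[str, int]) -> str:
    return "".join(f"##contig=<ID={c},length={n}>\n"
                   for c, n in chrom_lengths.items())


def _info_str(parts: dict) -> str:
    toks = []
    for k, v in parts.items():
        if v is None or v == "":
            continue
        toks.append(k if v is True else f"{k}={v}")
    return ";".join(toks) if toks else "."


def write_somatic_vcf(variants: list[SomaticVariant], path: str | Path,
                      chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(chrom_lengths))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = _info_str(dict(TYPE=v.vtype, DP=v.depth, VRC=v.alt_count,
                                  PS=v.phase_set, GENE=v.gene,
                                  CSQ=v.consequence, TNC=v.context))
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"{info}\n")


def read_somatic_vcf(path: str | Path) -> list[SomaticVariant]:
    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        out.append(SomaticVariant(
            rec.CHROM, rec.POS, rec.REF, rec.ALT[0],
            info.get("TYPE", "SNV"), int(info.get("VRC", 0)),
            int(info.get("DP", 0)),
            phase_set=(int(info["PS"]) if "PS" in info else None),
            gene=info.get("GENE"), consequence=info.get("CSQ"),
            context=info.get("TNC")))
    return out


def write_germline_vcf(variants: list[GermlineVariant], path: str | Path,
                       chrom_lengths: dict[str, int]) -> None:
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        fh.write(_contig_lines(chrom_lengths))
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in variants:
            info = _info_str(dict(GT=v.genotype, DP=v.depth, VRC=v.alt_count,
                                  GENE=v.gene, CSQ=v.consequence,
                                  TAC=v.tumour_alt_count,
                                  TDP=v.tumour_depth,
                                  PATH=v.pathogenic or None))
            fh.write(f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                     f"{info}\n")


def read_germline_vcf(path: str | Path) -> list[GermlineVariant]:
    out = []
    for rec in VCF(str(path)):
        info = dict(rec.INFO)
        out.append(GermlineVariant(
            rec.CHROM, rec.POS, rec.REF, rec.ALT[0], info.get("GENE"),
            info.get("GT", "HET"), pathogenic=bool(info.get("PATH", False)),
            consequence=info.get("CSQ"), alt_count=int(info.get("VRC", 0)),
            depth=int(info.get("DP", 0)),
            tumour_alt_count=int(info.get("TAC", 0)),
            tumour_depth=int(info.get("TDP", 0))))
    return out


def _truth_to_dict(t: TruthSample) -> dict:
    d = dataclasses.asdict(t)
    d["segments"] = [dataclasses.asdict(s) for s in t.segments]
    return d


def _truth_from_dict(d: dict) -> TruthSample:
    segs = [SegmentTruth(**s) for s in d["segments"]]
    clones = tuple(CloneSpec(*c) if isinstance(c, (list, tuple))
                   else CloneSpec(**c) for c in d["clones"])
    planted = d["planted"]
    planted = PlantedEvents(
        hotspot_genes=tuple(planted["hotspot_genes"]),
        biallelic_tsgs=tuple(planted["biallelic_tsgs"]),
        amplified_genes=tuple(planted["amplified_genes"]),
        deleted_genes=tuple(planted["deleted_genes"]),
        fusions=tuple(tuple(f) for f in planted["fusions"]),
        germline=tuple(tuple(g) for g in planted["germline"]))
    return TruthSample(d["sample_id"], d["patient_id"], d["cancer_type"],
                       d["purity"], d["sex"], d["wgd"], segs, clones,
                       planted, msi_target=d.get("msi_target", 0.0))


def write_sample(sim: SimulatedSample, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sid = sim.truth.sample_id
    lengths = (sim.segments.groupby("chrom", sort=False)["end"].max()
               .astype(int).to_dict())
    sim.segments.to_csv(outdir / f"{sid}.segments.tsv", sep="\t",
                        index=False, float_format="%.6g")
    write_somatic_vcf(sim.somatic, outdir / f"{sid}.somatic.vcf", lengths)
    write_germline_vcf(sim.germline, outdir / f"{sid}.germline.vcf", lengths)
    sim.svs.to_csv(outdir / f"{sid}.sv.tsv", sep="\t", index=False)
    with open(outdir / f"{sid}.truth.json", "w") as fh:
        json.dump(dict(seed=sim.seed, truth=_truth_to_dict(sim.truth)), fh,
                  indent=1)


def read_sample(indir: str | Path, sample_id: str) -> SimulatedSample:
    indir = Path(indir)
    segments = pd.read_csv(indir / f"{sample_id}.segments.tsv", sep="\t",
                           dtype={"chrom": str})
    somatic = read_somatic_vcf(indir / f"{sample_id}.somatic.vcf")
    germline = read_germline_vcf(indir / f"{sample_id}.germline.vcf")
    svs = pd.read_csv(indir / f"{sample_id}.sv.tsv", sep="\t",
                      dtype={"chrom1": str, "chrom2": str})
    with open(indir / f"{sample_id}.truth.json") as fh:
        payload = json.load(fh)
    return SimulatedSample(_truth_from_dict(payload["truth"]), segments,
                           somatic, germline, svs, payload["seed"])
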