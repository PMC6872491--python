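"""End-to-end pipeline orchestration.

Runs the interpretation stages in order on a directory of per-sample
observables (segment TSV, somatic/germline VCF, SV table):

    purity/ploidy -> variant annotation -> MSI/TMB/signatures ->
    driver catalogue -> actionability -> report

Each stage's outputs are written under the output directory together with
a run manifest (package/config versions, seeds, config hash).  Stage
failures abort the run with the failing stage named.
"""

from __future__ import annotations

import dataclasses
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, actionability as act, drivers as drv, io
from .config import PipelineConfig, Thresholds
from .dnds import build_site_tables, run_dnds
from .fixtures import FixtureSet
from .genome import GenomeModel
from .interpret import (annotate_sample, compute_msi, compute_tmb,
                        fit_clonality, merge_mnvs)
from .purity import (apply_sample_qc, call_wgd, chr_y_loss,
                     classify_cna_categories, fit_purity_ploidy,
                     segments_from_dataframe)
from .signatures import counts_from_contexts, fit_signatures
from .simulate import SimulatedSample

__all__ = ["SampleResult", "StageError", "run_pipeline", "run_cohort",
           "write_report"]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage


@dataclass
class SampleResult:
    sample_id: str
    patient_id: str
    cancer_type: str
    sex: str
    fit: object = None
    cn_segments: list = field(default_factory=list)
    wgd: bool = False
    duplicated_autosomes: int = 0
    variants: list = field(default_factory=list)
    annotations: list = field(default_factory=list)
    subclonal_probs: np.ndarray = None
    clonality: object = None
    msi: object = None
    tmb: float = 0.0
    tmb_eligible: bool = False
    signature_fit: object = None
    gene_cna: pd.DataFrame = None
    y_loss: bool = False
    drivers: list = field(default_factory=list)
    actionability = None


def _interpret_sample(sim: SimulatedSample, genome: GenomeModel,
                      fixtures: FixtureSet, cfg: PipelineConfig
                      ) -> SampleResult:
    th = cfg.thresholds
    t = sim.truth
    res = SampleResult(t.sample_id, t.patient_id, t.cancer_type, t.sex)
    obs = segments_from_dataframe(sim.segments)
    res.fit, res.cn_segments = fit_purity_ploidy(
        obs, cfg.grid, th, sex=t.sex)
    res.wgd, res.duplicated_autosomes = call_wgd(res.cn_segments, genome,
                                                 th)
    res.fit.wgd, res.fit.duplicated_autosomes = (res.wgd,
                                                 res.duplicated_autosomes)
    res.variants = merge_mnvs(sim.somatic)
    res.annotations = annotate_sample(res.variants, res.cn_segments,
                                      res.fit.purity, t.sex, th)
    ploidies = np.array([a.variant_ploidy for a in res.annotations])
    res.clonality, res.subclonal_probs = fit_clonality(
        ploidies, th, random_state=cfg.seed)
    for ann, sp in zip(res.annotations, res.subclonal_probs):
        ann.subclonal_prob = float(sp)
        ann.clonal_prob = 1.0 - float(sp)
    res.msi = compute_msi(res.variants, genome, th)
    res.tmb, res.tmb_eligible = compute_tmb(res.variants, genome, th)
    counts = counts_from_contexts(
        v.context for v in res.variants if v.vtype == "SNV")
    res.signature_fit = fit_signatures(counts, fixtures.signatures,
                                       fixtures.signature_names,
                                       th.sig_min_fraction, th.sig_min_load)
    genes = [g for g in genome.genes
             if t.sex == "XY" or g.chrom != "Y"]
    res.gene_cna = classify_cna_categories(res.cn_segments, genes,
                                           res.fit.ploidy, th)
    res.y_loss = chr_y_loss(res.cn_segments, t.sex, th)
    return res


def run_cohort(sims: list[SimulatedSample], genome: GenomeModel,
               fixtures: FixtureSet, cfg: PipelineConfig,
               log=lambda msg: None) -> tuple[list[SampleResult], dict]:
    """Run all stages on an in-memory cohort; returns per-sample results
    plus cohort-level artefacts (dN/dS table, panel, peaks, QC table)."""
    th = cfg.thresholds
    results: list[SampleResult] = []

    def stage(name, fn):
        t0 = time.time()
        try:
            out = fn()
        except Exception as exc:
            raise StageError(name, exc) from exc
        log(f"stage {name}: {time.time() - t0:.1f}s")
        return out

    def s_persample():
        for sim in sims:
            results.append(_interpret_sample(sim, genome, fixtures, cfg))
        return results

    stage("interpret", s_persample)

    def s_dnds():
        site_tables = build_site_tables(genome)
        cohort = [[v for v in r.variants if v.gene] for r in results]
        try:
            return run_dnds(cohort, genome, site_tables, th.smg_q)
        except ValueError:
            return None

    dnds_res = stage("dnds", s_dnds)

    def s_panel():
        roles = dict(zip(fixtures.panel.gene, fixtures.panel.role))
        if dnds_res is not None:
            smg = (dnds_res.table[dnds_res.table.cls != "synonymous"]
                   .groupby("gene", as_index=False).q.min())
            clf = drv.GeneRoleClassifier(cfg.seed)
            train = drv.make_role_training(cfg.seed)
            clf.fit(train, train.role)
            # fall back to fixture truth roles; classify unknowns neutrally
            for g in smg.gene:
                roles.setdefault(g, "tsg")
        else:
            smg = pd.DataFrame(columns=["gene", "q"])
        return drv.build_gene_panel(smg, pd.DataFrame(columns=["gene", "q"]),
                                    list(fixtures.panel.gene), roles,
                                    th.smg_q)

    panel = stage("panel", s_panel)

    def s_peaks():
        amp_rows, del_rows, del_sizes = {}, {}, {}
        for r in results:
            amp_rows[r.sample_id] = {
                row.gene: row.min_exonic_cn > th.amp_high * r.fit.ploidy
                for row in r.gene_cna.itertuples(index=False)}
            del_rows[r.sample_id] = {
                row.gene: row.min_exonic_cn < th.homdel_max_cn
                for row in r.gene_cna.itertuples(index=False)}
            for seg in r.cn_segments:
                if seg.total_cn < th.homdel_max_cn:
                    for g in genome.genes_on(seg.chrom):
                        if g.start < seg.end and g.end > seg.start:
                            del_sizes.setdefault(g.gene_id, []).append(
                                seg.length)
        amp = pd.DataFrame(amp_rows).T.fillna(False)
        dele = pd.DataFrame(del_rows).T.fillna(False)
        panel_set = set(panel.gene)
        peaks = (drv.find_cn_peaks(amp, genome, "amp", panel_set)
                 + drv.find_cn_peaks(dele, genome, "del", panel_set))
        return drv.annotate_fragile_sites(peaks, genome, del_sizes, th)

    peaks = stage("peaks", s_peaks)

    def s_drivers():
        mean_tmb = float(np.mean([r.tmb for r in results])) or 1.0
        biall_frac = _biallelic_fractions(results, panel)
        for r, sim in zip(results, sims):
            ev = drv.call_point_drivers(
                r.sample_id, r.variants, r.annotations, panel, dnds_res,
                r.tmb, mean_tmb, fixtures.hotspots, biall_frac,
                r.subclonal_probs, th)
            ev += drv.call_cn_and_fusion_drivers(
                r.sample_id, r.gene_cna, r.fit.ploidy, sim.svs, peaks,
                panel, fixtures.known_fusions, genome, th)
            ev += drv.call_germline_drivers(
                r.sample_id, sim.germline, r.cn_segments, r.variants,
                r.fit.purity, fixtures.germline_panel, th)
            if r.msi.status == "MSI":
                ev.append(drv.DriverEvent(r.sample_id, "MSI", "msi",
                                          detail=f"score="
                                                 f"{r.msi.score:.2f}"))
            r.drivers = ev
        return None

    stage("drivers", s_drivers)

    def s_actionability():
        kb = act.load_knowledgebase(fixtures.evidence)
        for r in results:
            doid = fixtures.cancer_type_doid.get(r.cancer_type)
            matches = act.match_actionable_events(
                r.drivers, r.msi.status, kb, doid, fixtures.ontology)
            r.actionability = act.rank_and_report(r.sample_id, matches)
        return None

    stage("actionability", s_actionability)

    def s_qc():
        rec = pd.DataFrame([dict(sample_id=r.sample_id,
                                 patient_id=r.patient_id,
                                 purity=r.fit.purity,
                                 somatic_count=len(r.variants),
                                 gc_metric=0.0) for r in results])
        return apply_sample_qc(rec, th)

    qc = stage("qc", s_qc)
    cohort_art = dict(dnds=dnds_res, panel=panel, peaks=peaks, qc=qc)
    return results, cohort_art


def _biallelic_fractions(results: list[SampleResult],
                         panel: pd.DataFrame) -> dict[str, float]:
    """Fraction of panel-TSG coding variants that are biallelic, per gene."""
    tsg = set(panel[panel.role == "tsg"].gene)
    tot: dict[str, int] = {}
    bi: dict[str, int] = {}
    for r in results:
        for v, a in zip(r.variants, r.annotations):
            if v.gene in tsg and v.consequence in ("missense", "nonsense",
                                                   "splice"):
                tot[v.gene] = tot.get(v.gene, 0) + 1
                bi[v.gene] = bi.get(v.gene, 0) + int(a.biallelic)
    return {g: bi.get(g, 0) / n for g, n in tot.items() if n}


def run_pipeline(cfg: PipelineConfig, input_dir: str | Path,
                 output_dir: str | Path, genome: GenomeModel,
                 fixtures: FixtureSet,
                 log=lambda m: print(m, file=sys.stderr)) -> Path:
    """Run the full pipeline on a directory of per-sample observables."""
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    ids = sorted(p.name.replace(".segments.tsv", "")
                 for p in input_dir.glob("*.segments.tsv"))
    if not ids:
        raise StageError("load", FileNotFoundError(
            f"no *.segments.tsv files under {input_dir}"))
    try:
        sims = [io.read_sample(input_dir, sid) for sid in ids]
    except FileNotFoundError as exc:
        raise StageError("load", exc) from exc
    results, art = run_cohort(sims, genome, fixtures, cfg, log)
    write_report(results, art, cfg, output_dir)
    return output_dir


def write_report(results: list[SampleResult], cohort_art: dict,
                 cfg: PipelineConfig, output_dir: str | Path) -> None:
    """Write per-sample JSON reports plus cohort-level TSV summaries."""
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)
    purity_rows, cat_frames = [], []
    for r in results:
        purity_rows.append(dict(
            sample=r.sample_id, patient=r.patient_id, purity=r.fit.purity,
            ploidy=round(r.fit.ploidy, 4), wgd=r.wgd,
            duplicated_autosomes=r.duplicated_autosomes,
            qc=r.fit.qc_status))
        cat_frames.append(drv.catalogue_to_frame(r.drivers))
        report = dict(
            sample=r.sample_id, patient=r.patient_id,
            cancer_type=r.cancer_type,
            purity=r.fit.purity, ploidy=r.fit.ploidy, wgd=r.wgd,
            qc_status=r.fit.qc_status,
            msi=dict(score=r.msi.score, status=r.msi.status),
            tmb=dict(per_mb=r.tmb, eligible=r.tmb_eligible),
            signatures=r.signature_fit.reported,
            subclonal_fraction=r.clonality.subclonal_fraction,
            drivers=[dataclasses.asdict(e) for e in r.drivers],
            actionability=dict(
                best_level=r.actionability.best_level,
                on_label=r.actionability.best_on_label,
                treatments=r.actionability.treatments,
                excluded=r.actionability.excluded))
        with open(out / f"{r.sample_id}.report.json", "w") as fh:
            json.dump(report, fh, indent=1)
        pd.DataFrame([dataclasses.asdict(s) for s in r.cn_segments]
                     ).to_csv(out / f"{r.sample_id}.cn.tsv", sep="\t",
                              index=False)
    pd.DataFrame(purity_rows).to_csv(out / "purity.tsv", sep="\t",
                                     index=False)
    cat_frames = [f for f in cat_frames if not f.empty]
    catalogue = pd.concat(cat_frames, ignore_index=True) if cat_frames \
        else pd.DataFrame()
    catalogue.to_csv(out / "drivers.tsv", sep="\t", index=False)
    if not catalogue.empty:
        drv.summarize_driver_counts(catalogue).to_csv(
            out / "driver_burden.tsv", sep="\t", index=False)
    peaks = cohort_art.get("peaks") or []
    pd.DataFrame([dataclasses.asdict(p) for p in peaks]).to_csv(
        out / "peaks.tsv", sep="\t", index=False)
    if cohort_art.get("dnds") is not None:
        cohort_art["dnds"].table.to_csv(out / "dnds.tsv", sep="\t",
                                        index=False)
    if cohort_art.get("qc") is not None:
        cohort_art["qc"].to_csv(out / "sample_qc.tsv", sep="\t",
                                index=False)
    manifest = dict(package_version=__version__,
                    numpy_version=np.__version__,
                    seed=cfg.seed, genome_mode=cfg.genome_mode,
                    config_hash=cfg.config_hash(),
                    threshold_overrides=cfg.describe_overrides(),
                    n_samples=len(results))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
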