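"""Per-variant interpretation: clonality, MSI, TMB and signature refits.

For every sample: merge MNVs, invert VAFs to variant ploidies against the
fitted copy number, decompose clonal/subclonal peaks, score MSI and TMB
and refit the signature mixture.  Writes results/interpretation.tsv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from somakit import io
from somakit.fixtures import load_fixtures
from somakit.genome import build_mini_genome
from somakit.interpret import (annotate_sample, compute_msi, compute_tmb,
                               fit_clonality, merge_mnvs)
from somakit.purity import fit_purity_ploidy, segments_from_dataframe
from somakit.signatures import counts_from_contexts, fit_signatures

ROOT = Path(__file__).parents[1] / "results"
DATA = Path(__file__).parents[1] / "scratch" / "cohort"


def main():
    genome = build_mini_genome()
    fixtures = load_fixtures(DATA / "fixtures")
    sample_dir = DATA / "samples"
    rows = []
    for f in sorted(sample_dir.glob("*.segments.tsv")):
        sid = f.name.replace(".segments.tsv", "")
        sim = io.read_sample(sample_dir, sid)
        fit, cn = fit_purity_ploidy(segments_from_dataframe(sim.segments),
                                    sex=sim.truth.sex)
        variants = merge_mnvs(sim.somatic)
        ann = annotate_sample(variants, cn, fit.purity, sim.truth.sex)
        model, _ = fit_clonality(
            np.array([a.variant_ploidy for a in ann]))
        msi = compute_msi(variants, genome)
        tmb, eligible = compute_tmb(variants, genome)
        sig = fit_signatures(counts_from_contexts(
            v.context for v in variants if v.vtype == "SNV"),
            fixtures.signatures, fixtures.signature_names)
        rows.append(dict(
            sample=sid, n_variants=len(variants),
            n_mnv=sum(v.vtype == "MNV" for v in variants),
            biallelic_fraction=round(
                np.mean([a.biallelic for a in ann]), 4),
            subclonal_fraction=round(model.subclonal_fraction, 4),
            msi_score=round(msi.score, 3), msi_status=msi.status,
            tmb=round(tmb, 3), tmb_eligible=eligible,
            reported_signatures=",".join(sig.reported) or "none"))
    df = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "interpretation.tsv", sep="\t", index=False)
    print(f"{(df.msi_status == 'MSI').sum()} MSI sample(s); "
          f"median TMB {df.tmb.median():.2f}/Mb; median subclonal "
          f"fraction {df.subclonal_fraction.median():.3f}")
    print(f"wrote {ROOT / 'interpretation.tsv'}")


if __name__ == "__main__":
    main()
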