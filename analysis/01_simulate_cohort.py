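"""Simulate the study cohort: 20 synthetic metastatic tumour genomes.

Writes per-sample observables (segment TSV, somatic/germline VCF, SV table,
truth JSON) and the fixture knowledgebases under results/cohort/.  Purity is
drawn from 0.2-1.0, 56% of samples carry a whole-genome duplication, and a
rotating subset of samples carries planted driver events of every class so
the downstream stages have known truth to recover.
"""

from pathlib import Path

from somakit.config import PlantedEvents, TumourSimConfig
from somakit.fixtures import make_fixture_resources, write_fixtures
from somakit.genome import build_mini_genome
from somakit.simulate import simulate_cohort

SEED = 20240917
# cohort data is bulky and regenerable: it lives under scratch/, while
# the numbered analyses write their summary tables under results/
OUT = Path(__file__).parents[1] / "scratch" / "cohort"

PLANTED = PlantedEvents(
    hotspot_genes=("BRAF",), biallelic_tsgs=("TP53",),
    amplified_genes=("ERBB2",), deleted_genes=("PTEN",),
    fusions=(("EML4", "ALK"),), germline=(("BRCA2", "loh_wild_type"),))


def main():
    genome = build_mini_genome()
    fixtures = make_fixture_resources(genome, seed=SEED)
    write_fixtures(fixtures, OUT / "fixtures")
    plan = [PLANTED if i % 2 == 0 else PlantedEvents() for i in range(20)]
    base = TumourSimConfig(msi_target=0.0)
    sims = simulate_cohort(genome, 20, base, SEED, fixtures,
                           purity_range=(0.2, 1.0), planted_plan=plan)
    # one hypermutated MSI sample, as in real cohorts (~2.5% of tumours)
    from somakit.simulate import inject_msi
    sims[7] = inject_msi(sims[7], genome, 12.0, SEED + 7)
    for sim in sims:
        sim.write(OUT / "samples")
    n_wgd = sum(s.truth.wgd for s in sims)
    print(f"wrote {len(sims)} samples ({n_wgd} with WGD, 1 MSI, "
          f"{sum(bool(p.hotspot_genes) for p in plan)} with planted "
          f"drivers) under {OUT}")


if __name__ == "__main__":
    main()
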