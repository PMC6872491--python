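"""Independent exhaustive peel-off oracle and toy cohort builders.

Shared by the unit and acceptance suites: the oracle re-implements the
peel-off semantics naively over dict-of-set supports, independent of the
vectorised implementation it checks.
"""

import numpy as np
import pandas as pd

from somakit.genome import Chromosome, GeneModel, GenomeModel


def peak_genome(n_genes=12):
    genes = [GeneModel(f"G{i:02d}", "1", "+",
                       [(100_000 * i, 100_000 * i + 1_500)])
             for i in range(n_genes)]
    return GenomeModel([Chromosome("1", 5_000_000, True)], genes, [])


def planted_events(n_samples, plan, n_genes=12):
    """plan: list of ((gene_lo, gene_hi), (sample_lo, sample_hi)) blocks."""
    m = np.zeros((n_samples, n_genes), dtype=bool)
    for (g0, g1), (s0, s1) in plan:
        m[s0:s1, g0:g1] = True
    return pd.DataFrame(m, index=[f"S{i}" for i in range(n_samples)],
                        columns=[f"G{i:02d}" for i in range(n_genes)])


def oracle_peaks(events: pd.DataFrame, order, stop):
    support = {g: set(events.index[events[g]]) for g in order}
    peaks = []
    while True:
        best = max(order, key=lambda g: len(support[g]))
        if len(support[best]) < stop:
            break
        seed = frozenset(support[best])
        j = order.index(best)
        lo = j
        while lo > 0 and frozenset(support[order[lo - 1]]) == seed:
            lo -= 1
        hi = j
        while hi + 1 < len(order) and frozenset(
                support[order[hi + 1]]) == seed:
            hi += 1
        peaks.append((tuple(order[lo:hi + 1]), len(seed)))
        for s in seed:
            a = j
            while a > 0 and s in support[order[a - 1]]:
                a -= 1
            b = j
            while b + 1 < len(order) and s in support[order[b + 1]]:
                b += 1
            for g in order[a:b + 1]:
                support[g].discard(s)
    return peaks
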