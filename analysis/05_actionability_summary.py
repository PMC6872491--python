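"""Summarise per-sample actionability over the pipeline reports.

Reads the per-sample JSON reports produced by 04 and tabulates the best
evidence level and label status per sample — the cohort's "fraction of
patients with a candidate actionable event".  Writes
results/actionability.tsv.
"""

import json
from pathlib import Path

import pandas as pd

ROOT = Path(__file__).parents[1] / "results"
DATA = Path(__file__).parents[1] / "scratch" / "pipeline"


def main():
    rows = []
    for f in sorted(DATA.glob("*.report.json")):
        rep = json.loads(f.read_text())
        act = rep["actionability"]
        rows.append(dict(
            sample=rep["sample"], cancer_type=rep["cancer_type"],
            best_level=act["best_level"] or "none",
            on_label=act["on_label"],
            n_treatments=len(act["treatments"]),
            n_excluded=len(act["excluded"]),
            msi=rep["msi"]["status"]))
    df = pd.DataFrame(rows)
    ROOT.mkdir(exist_ok=True)
    df.to_csv(ROOT / "actionability.tsv", sep="\t", index=False)
    frac = (df.best_level != "none").mean()
    by_level = df.best_level.value_counts().to_dict()
    print(f"actionable events in {frac:.0%} of samples; "
          f"best-level breakdown: {by_level}")
    print(f"wrote {ROOT / 'actionability.tsv'}")


if __name__ == "__main__":
    main()
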