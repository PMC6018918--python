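#!/usr/bin/env python
"""Simulate the study cohort: two groups of BOLD series with a planted
inter-regional over-connectivity effect in the mutant-like group.

Writes the cohort volumes under scratch/cohort/ (NIfTI + motion TSVs +
manifest) and a realized-effect summary under results/.
"""

from pathlib import Path

import pandas as pd

from fcdecode.io import save_cohort
from fcdecode.synthetic import CohortConfig, generate_bold_cohort, planted_pair_correlation

ROOT = Path(__file__).resolve().parents[1]
SEED = 1

config = CohortConfig(planted_corr_a=0.0, planted_corr_b=0.5, rng_seed=SEED)
cohort = generate_bold_cohort(config)
save_cohort(cohort, ROOT / "scratch" / "cohort")

rows = []
for group in ("a", "b"):
    planted = {"a": config.planted_corr_a, "b": config.planted_corr_b}[group]
    realized = planted_pair_correlation(cohort, group)
    rows.append(
        {
            "group": group,
            "n_subjects": len(cohort.group(group)),
            "planted_corr": planted,
            "realized_corr": round(realized, 4),
        }
    )
summary = pd.DataFrame(rows)

outdir = ROOT / "results"
outdir.mkdir(exist_ok=True)
summary.to_csv(outdir / "cohort_planted_effect.tsv", sep="\t", index=False)
print(f"Simulated {len(cohort.subjects)} subjects on grid {config.grid_shape}, "
      f"planted pair {config.planted_pair} (seed {SEED}).")
print(summary.to_string(index=False))
print("Realized cross-region correlations track the planted values; "
      "cohort written to scratch/cohort/.")
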