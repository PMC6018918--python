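#!/usr/bin/env python
"""Transcriptomic decoding of the over-connected region pair.

Generates the synthetic genes x regions expression-energy matrix with a
planted high-expression gene set in the focal pair, normalizes per gene,
runs both candidate-selection modes (dual-region top-20% intersection and
L1-ranked minimum-hypergeometric enrichment) over all annotation sets, and
establishes specificity with 10 random control region pairs.
"""

from pathlib import Path

from fcdecode.decoding import decode_pair, normalize_by_total, random_pair_control
from fcdecode.io import save_expression_tsv, save_gmt
from fcdecode.synthetic import PlantedExpressionConfig, generate_expression_matrix

ROOT = Path(__file__).resolve().parents[1]
results = ROOT / "results"
SEED = 1

config = PlantedExpressionConfig(enrichment_effect=5.0, rng_seed=SEED)
matrix, annotations = generate_expression_matrix(config)
save_expression_tsv(matrix, ROOT / "scratch" / "expression_energies.tsv")
save_gmt(annotations, ROOT / "scratch" / "gene_sets.gmt")

normalized = normalize_by_total(matrix)
pair = (
    normalized.region_labels[config.focal_pair[0]],
    normalized.region_labels[config.focal_pair[1]],
)

enrichment = decode_pair(normalized, pair, annotations, q=0.20)
enrichment.to_csv(results / "enrichment_results.tsv", sep="\t", index=False)

control = random_pair_control(
    normalized, annotations, focal_pair=pair, n_pairs=10, rng_seed=SEED
)
control.to_csv(results / "random_pair_control.tsv", sep="\t", index=False)

print(f"Decoded focal pair {pair} over {len(annotations)} gene sets "
      f"({config.n_genes} genes, {config.n_regions} regions, "
      f"planted boost x{config.enrichment_effect}).")
for mode in ("fixed", "mhg"):
    best = enrichment[enrichment["mode"] == mode].iloc[0]
    print(f"  {mode:5s} mode best set: {best['set']} (q = {best['q']:.3g})")
focal = int(control.loc[control["is_focal"], "n_significant_sets"].iloc[0])
med = control.loc[~control["is_focal"], "n_significant_sets"].median()
print(f"Significant sets: focal pair {focal} vs control median {med:.1f} "
      "(specificity holds when the focal count exceeds the controls).")
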