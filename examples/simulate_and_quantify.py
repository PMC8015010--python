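"""Simulate a 5+5 TMT experiment and run the inference pipeline.

Generates a synthetic proteome and peptide quant table with known ground
truth (including a planted 20.12-fold trioxidized GAPDH active-site
peptide), then runs co-isolation filtering, channel normalization,
per-peptide t-tests, BH correction and categorization.
"""

import numpy as np

from oxiprot import SyntheticConfig, generate_quant_table, run_quant, summarize_modifications

config = SyntheticConfig(n_proteins=40, n_peptides=400)
records, truth = generate_quant_table(config, np.random.default_rng(7))
run = run_quant(records)

print(f"{len(records)} peptide rows generated; {len(run.results)} quantified, "
      f"{len(run.detected_only)} detected-only, "
      f"{run.n_dropped_coisolation} dropped by the 30% co-isolation filter\n")

print("Top 3 fold changes (treated/control, BH-adjusted p, category):")
for r in sorted(run.results, key=lambda r: r.fold_change, reverse=True)[:3]:
    oxidized = [c for c, v in r.flags.as_dict().items() if v]
    print(f"  {r.peptide:<24} fold {r.fold_change:6.2f}  adj p {r.adj_p_value:.2e}  "
          f"{r.category}  {','.join(oxidized) or 'unmodified'}")

print("\nClass x category summary (counts, then percent of column total):")
print(summarize_modifications(run).render_text())
print("\nThe top peptide is the planted active-site peptide (true fold 20.12);")
print("on small tables the estimate compresses slightly because the planted")
print("peptide itself inflates the treated-channel totals used for normalization.")
print("The percent rows show the background oxidation fractions the generator planted.")
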