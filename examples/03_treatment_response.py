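"""Per-cytokine treatment-response statistics.

Simulates a study with four replicate fragments per tumor × arm (the
layout needed for within-tumor comparisons) and planted Th1-style
responses (IFNg/IP10 up under PD-1 blockade, IL17A/IL4 up under OX40
agonism), then runs the unpaired two-tailed Student t-tests.
"""

import secretoscope as sc

secretome, _, metadata, _ = sc.simulate_study(seed=3, replicates=4)
print(f"{secretome.values.shape[1]} explant fragments "
      f"({len(set(metadata.table['animal_id']))} tumors × 4 arms × 4 replicates)")

# one tumor, one cytokine: replicate fragments treated vs untreated
cmp_ = sc.compare_treatments(secretome, metadata, "IFNg", "anti-PD1",
                             animal_id="SCC-VII_a1")
print(f"\nSCC-VII tumor 1, IFNg, anti-PD1 vs untreated:")
print(f"  baseline mean = {cmp_.baseline_mean:.1f} pg/mL, "
      f"treated mean = {cmp_.treated_mean:.1f} pg/mL")
print(f"  t = {cmp_.t_statistic:.3f}, df = {cmp_.degrees_of_freedom}, "
      f"p = {cmp_.p_value:.4f}  [{cmp_.significance_stars}]")

# the full tidy table, pooled per tumor model, with a BH-adjusted column
table = sc.compare_all_treatments(secretome, metadata)
hits = table[table["p"] < 0.05].sort_values("p")
print(f"\n{len(table)} comparisons; {len(hits)} with raw p < 0.05. Top hits:")
print(hits.head(8)[["group", "arm", "cytokine", "t", "p", "stars", "p_bh"]]
      .to_string(index=False))
print("\nstars follow the raw-p convention (* <0.05, ** <0.01, *** <0.001); "
      "p_bh is the Benjamini–Hochberg adjusted value across all tests.")
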