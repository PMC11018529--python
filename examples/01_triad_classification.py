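"""Classify homoeolog expression bias categories for simulated triads.

Simulates replicate-level RNA-seq counts for 1:1:1 homoeolog triads with
planted balanced/dominant/suppressed categories, runs the TPM -> replicate
averaging -> simplex normalisation -> nearest-ideal-point pipeline, and
compares the recovered category table with the planted truth.
"""

import numpy as np

import polybias as pb

cfg = pb.SimulationConfig(n_groups=500, dominance_fold=8.0, nb_dispersion=0.05, seed=42)
counts, lengths, triads, truth = pb.simulate_expression(cfg)

tpm = pb.counts_to_tpm(counts, lengths)
averaged = pb.average_replicates(tpm)
percentages, per_triad = pb.categorize_species(averaged, triads)

print("Per-tissue bias category percentages (rows sum to 100):")
print(percentages.round(2).to_string())

expressed = per_triad[per_triad["expressed"]]
accuracy = np.mean(
    [row.category == truth.categories[row.group] for row in expressed.itertuples()]
)
print(f"\nPlanted-category recovery: {100 * accuracy:.1f}% "
      f"over {len(expressed)} triad-tissue calls")

abundance = pb.relative_subgenome_abundance(tpm, triads)
print("Relative transcript abundance per subgenome (%):", abundance.round(2).to_dict())
print("\nA dominant subgenome shows up as a higher abundance share and an excess")
print("of its *_dominant category; here categories follow the planted mixture.")
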