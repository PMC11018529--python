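"""Quantify expression-pattern shift within homoeolog groups.

Builds per-homoeolog tissue profiles, clusters them into 10 expression
groups (average linkage, correlation distance) and reports the fraction of
triads whose members land in different groups, plus a seeded subsampling
distribution for ploidy-matched comparisons.
"""

import polybias as pb

cfg = pb.SimulationConfig(n_groups=300, nb_dispersion=0.05, seed=7)
counts, lengths, triads, _ = pb.simulate_expression(cfg)
averaged = pb.average_replicates(pb.counts_to_tpm(counts, lengths))

profiles, gene_info = pb.build_profiles(averaged, triads)
assignments = pb.cluster_profiles(profiles, k=10)
result = pb.shifted_fraction(assignments, triads)
print(f"{100 * result.fraction:.1f}% of {len(result.shifted)} triads are shifted "
      "(members span more than one of the 10 expression groups)")

sub = pb.subsample_comparison(profiles, triads, n_target=150, n_reps=50, seed=1)
print(f"subsampled to 150 triads x 50 reps: mean shifted fraction "
      f"{100 * sub['mean']:.1f}% (95% interval "
      f"{100 * sub['ci'][0]:.1f}-{100 * sub['ci'][1]:.1f}%)")
print("\nA high shifted fraction means homoeologs rarely retain identical")
print("tissue expression patterns after polyploidization.")
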