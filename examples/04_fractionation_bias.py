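"""Windowed gene-retention tracks and biased fractionation.

Simulates an ordered reference gene list where subgenome B loses genes
three times as often as subgenome A, computes 100-gene sliding-window
retention fractions and compares the distributions with the two-sided
Wilcoxon rank-sum test.
"""

import polybias as pb

track, truth = pb.simulate_retention(
    n_reference_genes=8000,
    loss_prob_per_subgenome={"A": 0.1, "B": 0.3},
    seed=3,
)
windows = pb.windowed_retention(track, window=100, step=10)
print("windows per subgenome:", windows.groupby("subgenome").size().to_dict())
print("median retention fraction:")
print(windows.groupby("subgenome")["fraction"].median().round(3).to_string())

comparison = pb.compare_retention(windows)
row = comparison.iloc[0]
print(f"\nWilcoxon rank-sum A vs B: statistic={row['statistic']:.1f}, "
      f"p={row['pvalue']:.3g}, higher retention in subgenome {row['higher']}")

census = pb.group_ratio_census(track.presence.astype(int))
print("\nhomoeologous group ratio census (%):")
print(census.round(2).to_string())
print("\nUnequal retention between subgenomes (biased fractionation) is the")
print("structural side of subgenome dominance; 1:1 groups survive intact.")
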