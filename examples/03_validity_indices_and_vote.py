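"""Choose the cluster count with six internal validity indices and a vote.

Demonstrated on the published index grid for cluster counts 8-18 on two
patch-size datasets (12 index-by-dataset columns in total): each column
nominates its own optimum and the modal nomination wins.
"""

from stainclust import reference_table, select_optimal, vote

table = reference_table()
print("score grid (rows = candidate cluster counts):")
print(table.df.round(3).to_string())

optima = select_optimal(table)
print("\nper-column optima (argmin or argmax by the index's direction):")
print(optima.to_string())

mode, counts = vote(optima)
print(f"\nvote histogram: {dict(sorted(counts.items()))}")
print(f"chosen cluster count: {mode}")
print("-> 14 wins with 6 of 12 nominations; that is the cluster count used")
print("   for the whole-slide cluster maps.")
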