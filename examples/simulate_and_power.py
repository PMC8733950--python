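"""Simulate duplicated gene trees and measure test calibration and power.

Each simulated tree has a duplication at the root and one copy per species
in each clade; clade B's branch lengths are scaled by rate_b. At
rate_a == rate_b the rejection rate estimates the type-I error (should sit
near alpha); at rate_b = 3 it estimates power.
"""

from cladediv import SimSpec, power_sweep, simulate_duplicated_tree, write_newick

tree, truth = simulate_duplicated_tree(
    SimSpec(n_species=5, rate_a=1.0, rate_b=3.0, seed=7)
)
print("one simulated tree (k=5, rate ratio 3):")
print(" ", write_newick(tree))
print("  ground truth ratio:", truth.true_ratio)

table = power_sweep(
    [
        SimSpec(n_species=20, rate_a=1.0, rate_b=1.0, seed=101),  # null
        SimSpec(n_species=20, rate_a=1.0, rate_b=3.0, seed=101),  # alternative
    ],
    replicates=200,
    alpha=0.05,
)
cols = ["rate_b", "reject_student_t", "reject_welch_t",
        "reject_mann_whitney_u", "mean_student_t"]
print("\nrejection rates over 200 replicates (k=20 species, alpha=0.05):")
print(table[cols].to_string(index=False))
print(
    "\nRow 1 (equal rates): rejection ~ 0.05 = the nominal alpha. "
    "Row 2 (ratio 3):\nnear-certain rejection, and the negative mean t shows "
    "clade A is detected as the\nless diverged copy."
)
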