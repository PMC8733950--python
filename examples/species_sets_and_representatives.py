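"""Species-set (Venn/superset) analysis and representative-leaf selection.

Clade A holds a copy in three species, one of them twice (an isoform or
in-clade paralog); clade B lost its copy in species sp3. The superset
relation suggests clade A's gene is the essential duplicate, and the
duplicated sp1 entry in clade A is collapsed to its least diverged leaf
before the divergence test.
"""

from cladediv import AnalysisConfig, compare_clades, parse_newick

NEWICK = (
    "((((gA_sp1:0.05,gA_sp1b:0.60):0.05,gA_sp2:0.15):0.1,gA_sp3:0.2)cladeA:0.1,"
    "((gB_sp1:0.3,gB_sp2:0.5):0.2,gB_sp4:0.4)cladeB:0.1)duplication;"
)

tree = parse_newick(NEWICK)
report = compare_clades(
    tree,
    AnalysisConfig(
        clade_a_label="cladeA",
        clade_b_label="cladeB",
        species_pattern="sp[0-9]+",
    ),
)

s = report.species_sets
print(f"species common to both clades : {s.common} {list(s.common_species)}")
print(f"unique to clade A             : {s.unique_a} {list(s.unique_a_species)}")
print(f"unique to clade B             : {s.unique_b} {list(s.unique_b_species)}")
print(f"relation                      : {s.relation}")
print(f"clade A representatives       : {report.clade_a.representatives}")
print(f"pruned comparison size        : {report.clade_a.pruned_leaf_count} species")
print(
    "\n'overlap'/'A_superset' etc. describe the FULL clades; the test itself "
    "ran only on\nthe common species, with sp1 in clade A represented by its "
    "least diverged leaf."
)
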