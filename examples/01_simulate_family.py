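"""Simulate a gene family evolving on a species tree, with ground truth.

A single ancestral gene descends through a 12-taxon tree, duplicating and
dying as a Poisson process; a forced duplication on the stem of clade A
creates two paralogue groups, one of which (the ".bc" copy) evolves twice
as fast. The truth table records which taxa retain which paralogue group.
"""

from exomertrace import SimulationConfig, simulate_family, truth_table
from exomertrace.simulate import DEFAULT_NEO_CLADE, default_species_tree

config = SimulationConfig(
    species_tree=default_species_tree(),
    dup_rate=0.05,      # duplications per substitution/site of branch length
    loss_rate=0.1,      # losses per substitution/site
    root_length=200,    # residues in the ancestral protein
    neo_clade=DEFAULT_NEO_CLADE,
    neo_multiplier=2.0,  # rate acceleration of the neofunctionalized copy
    seed=7,
)
family = simulate_family(config)

print(f"{len(family.sequences)} sequences across {len(family.taxa)} taxa")
print("paralogue groups:", sorted(set(family.orthogroups.values())))
print()
print(truth_table(family).frame.astype(int))
print()
print("Rows are taxa, columns are surviving paralogue groups; 1 means the")
print("taxon retains at least one copy of that group. 'fam.bb'/'fam.bc'")
print("are the two daughters of the forced duplication in clade A.")
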