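"""Generate a synthetic twin-family pedigree and summarize its composition.

Families are MZ/DZ twin pairs with structural parents (phenotyped with
register-like probabilities), occasional siblings and twin spouses.
Phenotypes are bivariate (pre-pandemic / pandemic QoL) drawn from the
published ACE truth; here we discretize onto the 1-10 ladder.
"""

from qolped import SimConfig, simulate, summarize_sample, write_pedigree

cfg = SimConfig(n_families=500, seed=11, discretize=True)
ped = simulate(cfg)
write_pedigree(ped, "example_pedigree.tsv", header_comment=f"seed={cfg.seed}")

print(f"{len(ped)} individuals in {ped.n_families} families -> example_pedigree.tsv\n")
print(summarize_sample(ped).to_string(index=False))
print("\nEach row: individuals with data and mean (sd) age per role and occasion;")
print("'n_both' counts those observed at both occasions.")
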