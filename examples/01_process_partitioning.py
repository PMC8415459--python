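"""Partition community assembly into ecological processes.

Simulates a metacommunity under environmental selection (conserved
niches, Gaussian filtering), computes betaNTI against a tip-shuffling
phylogenetic null and Raup-Crick(Bray-Curtis) against a
richness/abundance-preserving taxonomic null, classifies every sample
pair into one of five processes, and prints the process fractions and
the selection-to-dispersal-limitation ratio (SDER).
"""

import numpy as np

from ecoassembly import assembly as asm
from ecoassembly.simulate import SimulationConfig, simulate_regime, simulate_sites, simulate_tree
from ecoassembly.trees import cophenetic_matrix

cfg = SimulationConfig(
    n_sites=24, n_taxa=150, reads_per_sample=1000,
    regime="selection", niche_strength=0.5, trait_conservatism=1.0, seed=42,
)
tree = simulate_tree(cfg.n_taxa, seed=cfg.seed)
sites = simulate_sites(cfg.n_sites, seed=cfg.seed)
table, truth = simulate_regime(cfg, tree=tree, sites=sites)

D = cophenetic_matrix(tree)
bnti, bmntd, degenerate = asm.bnti(table, D, n_null=299, seed=1)
rc = asm.raup_crick_bray(table, n_null=299, seed=1)
pairs = asm.pair_table(bnti, bmntd, rc, degenerate)
summary = asm.process_summary(pairs["process"], rc_df=rc)

print(f"regime simulated: {truth.regime} (sigma = {cfg.niche_strength})")
print(f"community pairs classified: {len(pairs)}")
for process, frac in summary.fractions.items():
    print(f"  {process:24s} {100 * frac:5.1f} %")
sder = "infinite" if summary.sder_infinite else f"{summary.sder_null:.2f}"
print(f"SDER (selection / dispersal limitation): {sder}")
print(f"RC-only stochastic fraction (|RC| > 0.95): {100 * summary.stochastic_fraction_rc:.1f} %")
# Under selection with conserved niches, variable selection dominates and
# SDER is large; a neutral run at low migration would instead put most
# pairs under dispersal limitation (SDER << 1).
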