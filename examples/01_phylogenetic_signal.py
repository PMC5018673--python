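"""Fit Pagel's lambda to a genus-level characteristic and compare models.

Simulates a 200-genus dated tree with traits evolving under intermediate
phylogenetic signal (lambda = 0.3), then fits the three candidate models —
estimated lambda, no phylogenetic dependence (lambda = 0) and Brownian
motion (lambda = 1) — and prints a Table-1-style comparison.  The best
model has delta-AIC 0; worse models carry negative values.
"""

from amaztraits import SimulationConfig, compare_models, simulate_traits, simulate_tree
from amaztraits.trait_table import match_tree_and_traits

cfg = SimulationConfig(n_tips=200, seed=42)
tree = simulate_tree(cfg)
table = simulate_traits(tree, cfg)

pt, x = match_tree_and_traits(tree, table, "log10_species_richness")
mc = compare_models(pt, x)

print(f"log10 species richness, n = {len(x)} genera")
print(f"{'model':<28}{'lambda':>8}{'lnL':>12}{'dAIC':>9}")
for mode, label in (
    ("ml", "Estimated lambda"),
    ("fixed_zero", "No phylogenetic dependence"),
    ("fixed_one", "Brownian motion"),
):
    f = mc.fits[mode]
    print(f"{label:<28}{f.lam:>8.2f}{f.loglik:>12.2f}{mc.delta_aic[mode]:>9.1f}")
print(
    "\nAn intermediate estimated lambda (generating value 0.3; at n = 200 the"
    "\nestimate scatters by roughly +/- 0.15) with dAIC 0 means the trait"
    "\ncarries significant but partial phylogenetic signal: both the pure"
    "\nBrownian and the star-phylogeny model fit worse."
)
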