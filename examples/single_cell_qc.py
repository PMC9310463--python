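"""Droplet QC with the per-cell zeta score.

Simulates 10,000 droplets (intact cells, empty droplets, broken cells,
stripped nuclei), computes each cell's zeta (area under its binned
count/feature curve), places the data-driven cutoff at the low-side
reflection point of the high-quality population, and compares metrics by AUC.
"""

import numpy as np

from zetascreen import sc_qc, synthetic

sim = synthetic.simulate_droplets(synthetic.DropletSimConfig(seed=1))
table = sc_qc.qc_table(sim.to_anndata())
cls = sim.obs["droplet_class"].to_numpy()

cut, info = sc_qc.zeta_cutoff(table["zeta_cell"].to_numpy())
print(f"zeta cutoff = {cut:.0f} (method: {info['method']})")
for c in ("high_quality", "empty", "broken", "stripped_nucleus"):
    frac = (table["zeta_cell"][cls == c] >= cut).mean()
    print(f"  {c:17s}: {frac:6.1%} pass")
# Intact cells pass almost completely while ambient-only droplets are
# rejected.  Damaged classes straddle the cutoff: the zeta integrates depth
# and diversity, so severe leakage fails while mild leakage passes - %mt
# (below) is the complementary signal that singles out broken cells.

keep = np.isin(cls, ["high_quality", "broken"])
aucs = sc_qc.compare_metrics(table[keep], cls[keep] == "high_quality")
print("\nbroken-vs-intact discrimination (AUC):")
print(aucs.round(3).to_string())
# The integrated zeta out-ranks nFeature because a leaky cell loses counts
# proportionally but keeps detecting most of its genes.
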