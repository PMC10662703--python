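"""Counting-based selection scan: NG86 dN/dS, SLAC-style sites, group contrast.

Simulates a foreground clade evolving with omega 0.6 against an omega 0.2
background (the alpine/lowland design), then estimates pairwise omega,
scans sites, and tests the foreground-background contrast by permutation.
"""

import itertools
import math
import statistics

import mitosel as m

cfg = m.SimulationConfig(seed=9, n_tips=16, n_codons=400, depth=0.3,
                         omega_foreground=0.6, omega_background=0.2)
tree = m.simulate_tree(cfg)
aln, truth = m.simulate_codon_evolution(tree, cfg)

omegas = []
for a, b in itertools.combinations(aln.records, 2):
    res = m.ng86_pairwise(a.residues, b.residues)
    if not math.isnan(res.omega):
        omegas.append(res.omega)
print(f"mean pairwise NG86 omega: {statistics.mean(omegas):.3f} "
      f"(true foreground {truth.true_omega['foreground']}, "
      f"background {truth.true_omega['background']})")

sites = m.slac_site_test(aln, tree, threshold=0.1)
flagged = [s for s in sites if s.classification != "neutral"]
print(f"SLAC-style scan: {len(flagged)} / {len(sites)} sites flagged at p<0.1 "
      f"({sum(s.classification == 'negative' for s in flagged)} negative)")

labels = {t.name: t.group for t in tree.tips}
contrast = m.group_omega_contrast(aln, tree, labels, n_perm=999, seed=3)
print(f"group contrast: omega_fg={contrast.omega_foreground:.3f} "
      f"omega_bg={contrast.omega_background:.3f} "
      f"delta={contrast.delta:.3f} p_perm={contrast.p_perm:.4f}")
print("\nA positive delta with small p indicates faster nonsynonymous"
      "\nevolution on foreground (alpine-coded) terminal branches.")
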