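"""Codon-usage bias of simulated AT-rich mitochondrial genes.

Simulates a small set of species under purifying selection with 80% AT
content, then computes the standard codon-bias suite per species: ENC,
GC3s, GC12, PR2 coordinates, and the neutrality regression across species.
"""

import mitosel as m

cfg = m.SimulationConfig(seed=1, n_tips=8, n_codons=400, depth=0.3)
tree = m.simulate_tree(cfg)
aln, _ = m.simulate_codon_evolution(tree, cfg)

points = []
print(f"{'species':<8}{'ENC':>8}{'GC3s':>8}{'GC12':>8}{'PR2x':>8}{'PR2y':>8}")
for rec in aln.records:
    s = m.codon_usage_summary(rec.residues)
    points.append((s.gc3s, s.gc12))
    print(f"{rec.id:<8}{s.enc:>8.2f}{s.gc3s:>8.3f}{s.gc12:>8.3f}"
          f"{s.pr2_x:>8.3f}{s.pr2_y:>8.3f}")

fit = m.neutrality_regression(points)
print(f"\nneutrality plot: slope={fit.slope:.3f}  R2={fit.r_squared:.3f}")
print(f"expected ENC at mean GC3s: "
      f"{m.enc_expected(sum(p[0] for p in points) / len(points)):.2f}")
print("\nENC near its AT-rich mutational expectation and PR2 near (0.5, 0.5)"
      "\nmean the bias here is compositional; low ENC relative to the curve"
      "\nwould instead point to selection on codon usage.")
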