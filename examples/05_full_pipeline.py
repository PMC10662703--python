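"""Full pipeline run on a synthetic scenario.

Generates the 'foreground_elevated' fixture bundle (a foreground clade at
omega 0.6 vs 0.2, AT-rich codons, altitude-correlated environment), runs
every stage, and lists the emitted report tables.  Equivalent shell call:

    mitosel all --scenario foreground_elevated --seed 7 --out out/
"""

import mitosel as m

cfg = m.PipelineConfig(
    seed=7, out_dir="out_example", scenario="foreground_elevated",
    n_tips=12, gene_codons={"ATP6": 259, "COX1": 528, "ND2": 403},
    n_perm_mantel=999, n_perm_contrast=499,
)
bundle = m.run_pipeline(cfg)

for name, df in bundle.tables.items():
    print(f"{name:<24} {df.shape[0]:>5} rows -> {bundle.paths[name].name}")

gc = bundle.tables["group_contrast"]
print("\nper-gene foreground/background omega contrast:")
print(gc[["gene", "omega_foreground", "omega_background", "p_perm"]]
      .to_string(index=False))
print("\nEach TSV carries '#' provenance comments; rerunning with the same"
      "\nseed and config reproduces the tables byte for byte.")
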