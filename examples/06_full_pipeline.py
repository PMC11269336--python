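"""End-to-end run: cohort -> preprocess -> CV -> fit -> permute -> bootstrap
-> stratified effects, with all outputs written under out/example_run/.

Mirrors `neurocca run` on the command line; a rerun with the same config
and seed reproduces every number exactly.
"""

from neurocca import RunConfig, hbn_like_spec, run_cbcl_variant, run_full_analysis

config = RunConfig(
    input=hbn_like_spec(latent_corrs=(0.25, 0.18), seed=101),
    n_perm=1000, n_boot=1000, seed=7, out_dir="out/example_run",
)
report = run_full_analysis(config)
print("selected (k, reg):", (report.cv.best_k, report.cv.best_reg))
print("canonical correlations:", report.model.canonical_correlations.round(3))
print("permutation p-values:  ", report.permutation.p_values.round(4))
print("bootstrap stable flags:", report.bootstrap.stable_flags)
print("significant & stable components:", report.n_significant_stable)

variant = run_cbcl_variant(config)
print("\nCBCL-augmented cognitive block (5 variables):")
print("augmented correlations:", variant["augmented"].model.canonical_correlations.round(3))
print("within base bootstrap CI:", variant["augmented_corrs_within_base_ci"])
print("outputs written to out/example_run/ (see manifest.json)")
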