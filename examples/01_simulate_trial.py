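"""Generate a replicated field trial with latent genetics and grain yield.

Builds a three-replicate alpha-lattice of 168 entries, draws genotype,
genotype-by-environment and plot-error effects, and checks that the realized
effect variances track their targets.
"""
import phenospectra as ps

design = ps.generate_trial_design(
    "alpha_lattice", 168, r=3, x=2, block_size=12, seed=1
)
print(f"{design.design_kind}: {design.n_entries} entries x {design.r} reps "
      f"x {design.x} environments -> {design.n_plots} plots")

table, truth = ps.simulate_genetic_values(
    design, sigma_G2=0.16, sigma_GE2=0.04, sigma_eps2=0.08,
    genetic_corr_yield=0.7, trait_mean=-1.0, seed=2,
)
print(table[["plot_id", "genotype", "latent_trait", "water_proxy", "yield_"]].head())

realized_g = truth.genotype_effects["trait_effect"].var(ddof=1)
print(f"realized genotype variance {realized_g:.3f} (target {truth.sigma_G2})")
print("Each plot's canopy trait = genotype + GxE + plot error; grain yield "
      "shares genotype effects at the configured genetic correlation.")
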