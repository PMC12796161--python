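"""Deconfound, fit a regularized CCA, and read off loadings.

Assembles the combined model (sleep + depression + GMV vs motor), removes
age/age2/sex/TIV with training-only statistics, fits the solver at a fixed
penalty pair, and prints the first mode's canonical correlation, the
strongest loadings, and the redundancy index of the motor domain.
"""

from modecca import (
    apply_deconfounder,
    assemble_model_matrices,
    compute_loadings,
    fit_deconfounder,
    fit_rcca,
    generate_cohort,
    redundancy_index,
    standard_model_definitions,
)
from modecca.experiments import planted_spec

spec = planted_spec(500, rho=0.5, seed=3,
                    domain_sizes={"psqi": 7, "asr": 11, "gmv": 12, "motor": 5})
bundle = generate_cohort(spec)
model_def = standard_model_definitions(bundle)["psqi+asr+gmv"]
asm = assemble_model_matrices(bundle, model_def)

sx = fit_deconfounder(asm.X, asm.x_confounds)
sy = fit_deconfounder(asm.Y, asm.y_confounds)
Xt = apply_deconfounder(sx, asm.X, asm.x_confounds)
Yt = apply_deconfounder(sy, asm.Y, asm.y_confounds)

model = fit_rcca(Xt, Yt, cx=0.5, cy=0.5, n_modes=1)
tab = compute_loadings(model, Xt, Yt)
r = model.train_correlations[0]
ri = redundancy_index(tab.y_loadings["mode_1"], r)

print(f"training canonical correlation (mode 1): {r:.3f}")
print("\nstrongest X-side loadings (correlation of each variable with its variate):")
print(tab.x_loadings["mode_1"].abs().nlargest(5).round(3).to_string())
print(f"\nredundancy index of the motor domain: {ri:.3f}")
print("= mean squared motor loading x squared canonical correlation:")
print("  the share of motor variance explained through the behavioral/brain variate")
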