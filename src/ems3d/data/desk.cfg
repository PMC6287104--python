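# Desk-scale configuration: small grid for toy molecules and tests
grid_points_per_side = 65
spacing = 0.5
ionic_strength = 0.15
eps_protein = 2
eps_solvent = 78
temperature = 310
probe_radius = 1.4
convergence_tol = 1e-6
max_iterations = 20000
sigma = 3
delta = 4
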