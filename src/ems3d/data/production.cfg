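# Production configuration: protein-scale solver and skin parameters
grid_points_per_side = 353
spacing = 0.33
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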