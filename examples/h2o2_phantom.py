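"""Hydrogen-peroxide spread from two over-producing cells in a tissue patch.

Builds the 26-body voxel phantom (cells 60% of a 16 x 17 x 19 um box,
two central bodies on the measurement axis), then solves the linear
reaction-convection-diffusion problem with the two central bodies
producing at the glutamate-stimulated rate and everything else at the
normal rate.  Reports the pre-steady-state maximum along the central
axis and the steady-state profile.
"""

from mitoros import (FieldState, assemble_operator, axis_profile,
                     generate_phantom, solve_transient, steady_state)

phantom = generate_phantom(seed=0)
print(f"phantom: {len(phantom.bodies)} bodies, cell fraction "
      f"{phantom.cell_fraction_analytic:.3f}, high-production fraction "
      f"{100 * phantom.high_fraction_analytic:.2f}%")
print(f"volume-weighted mean initial H2O2: "
      f"{phantom.mean_initial_concentration():.2f} nM")

op = assemble_operator(phantom)
init = FieldState(phantom.initial_concentration(), 0.0)
fields, info = solve_transient(op, init, [0.003], dt_max=1e-4,
                               track_axis=phantom)
excess = 100.0 * (info["axis_max"] - 10.0) / 10.0
print(f"pre-steady-state axis maximum: {info['axis_max']:.3f} nM at "
      f"{1000 * info['axis_max_time']:.2f} ms "
      f"(+{excess:.1f}% above the 10 nM initial cell level)")

ss = steady_state(op)
xs, prof = axis_profile(ss, phantom)
print(f"steady-state axis maximum: {prof.max():.2f} nM -- the transient "
      "excess is a pre-steady-state phenomenon; at steady state the open "
      "boundaries drain the patch below its initial level.")
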