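"""Glutamate-driven bistability of the respiratory chain.

Sweeps buffered external glutamate up and back down over the isolated-
mitochondria model (5 mM succinate, rotenone).  Rising glutamate drains
oxaloacetate through the aminotransferase, releasing the complex II
brake; past a threshold the quinone pool collapses into near-complete
reduction and Qo-site semiquinone (high ROS) -- and stays there when
glutamate is lowered again (hysteresis).
"""

from mitoros import glutamate_sweep

model, up = glutamate_sweep(0.0, 100.0, 26, "up")
print("up-sweep (glutamate uM, ubiquinol fraction, Qo-semiquinone fraction):")
for p in up.points[::5]:
    o = p.observables
    print(f"  {1000 * p.parameter:6.1f}  {o['qh2_fraction']:.4f}  "
          f"{o['sq_qo_fraction']:.4f}  [{p.branch_label}]")
print(f"jump detected at {1000 * up.jump_parameter:.1f} uM glutamate")

_, down = glutamate_sweep(100.0, 0.0, 26, "down",
                          x_start=up.points[-1].x, model=model)
print(f"\ndown-sweep reverse jump: {down.jump_parameter} "
      f"(None = the chain stays on the high-ROS branch: hysteresis)")
print(f"ubiquinol fraction back at 0 glutamate: "
      f"{down.points[-1].observables['qh2_fraction']:.4f}")
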