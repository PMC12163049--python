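"""Drive indicators toward a target with the feedback controller.

First the scalar worked example (loss contracts by exactly 1/4 per step at
learning rate 0.25), then a three-scenario comparison on the seeded urban
instance: business-as-usual vs moderate vs aggressive intervention.
"""

import numpy as np

from remf.adaptive_control import (
    ControllerConfig,
    controller_step,
    integrated_burden,
    loss,
    run_scenario,
)
from remf.scenario_io import generate_synthetic_scenario

# scalar contraction: E(I) = 2 - I, target 0, eta = 0.25
cfg = ControllerConfig(E_star=[0.0], eta=0.25, I_min=[0.0], I_max=[np.inf])
M = np.array([[1.0]])
I = np.array([0.0])
losses = []
for _ in range(5):
    E = np.array([2.0]) - M @ I
    losses.append(loss(E, cfg.E_star))
    I = controller_step(I, E, cfg, M)
print("controller losses:", [round(x, 4) for x in losses],
      "(each step multiplies the loss by 1/4)")

# scenario comparison: integrated burden of each intervention intensity
scenario = generate_synthetic_scenario("urban-small", seed=1)
print("\nintegrated indicator burden over t in [0, 10]:")
for mode in ("bau", "moderate", "aggressive"):
    traj = run_scenario(scenario.state0, scenario.coupling, scenario.controller,
                        scenario.run.t_end, mode, step=scenario.run.step)
    print(f"  {mode:<10s} {integrated_burden(traj):9.3f}")
print()
print("The burden is the time-integral of the L1 size of the indicator")
print("vector; with a monotone mitigation pathway it decreases as the")
print("intervention ceiling rises from zero (BAU) to half to full.")
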