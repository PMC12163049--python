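"""Run the ecological sub-models: resources, competition, biodiversity.

Shows logistic resource recovery against its closed form, a two-species
competition pair settling to its coexistence equilibrium, and a
biodiversity forecast under a composed restoration intervention.
"""

import numpy as np

from remf.ecosystem_dynamics import (
    BiodivParams,
    ResourceParams,
    SpeciesParams,
    biodiversity_rate,
    compose_biodiv_intervention,
    integrate_resource,
    integrate_species,
    project_biodiversity,
)

# logistic resource, no extraction: sigmoid toward the carrying capacity
r, K, R0 = 0.8, 10.0, 1.0
times, levels = integrate_resource(ResourceParams(r=r, K_cap=K), R0, 10.0, 0.01)
analytic = K / (1 + ((K - R0) / R0) * np.exp(-r * times))
print(f"resource at t=10: {levels[-1]:.6f} (closed form {analytic[-1]:.6f}, "
      f"max traj error {np.max(np.abs(levels - analytic)):.2e})")

# two competing species: equilibrium solves c N* = r
rates = np.array([1.0, 1.0])
comp = np.array([[2.0, 1.0], [1.0, 2.0]])
_, pops = integrate_species(SpeciesParams(r_i=rates, c_comp=comp), [0.2, 0.6], 60.0, 0.01)
N_star = np.linalg.solve(comp, rates)
print(f"competition equilibrium: simulated {np.round(pops[-1], 6)} vs "
      f"linear-system solution {np.round(N_star, 6)}")

# biodiversity forecast under a restoration+protection+monitoring package
biodiv = BiodivParams(gamma=0.3, delta=0.5, H_R=0.4, S_P=0.3, E_M=0.3)
I_B = compose_biodiv_intervention(biodiv)
rate_fn = lambda t: biodiversity_rate(biodiv, Q_h=1.5, N_tot=float(pops[-1].sum()),
                                      S=0.8, I_B=I_B)
B_future = project_biodiversity(2.0, rate_fn, dt_horizon=5.0)
print(f"biodiversity index forecast over 5 time units: 2.0 -> {B_future:.4f} "
      f"(intervention I_B = {I_B:.2f})")
print()
print("The forecast integrates the habitat-driven growth term minus stress")
print("plus the composed intervention effort, in biodiversity-rate units.")
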