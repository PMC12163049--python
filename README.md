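# remf — coupled environment–activity–intervention modelling

`remf` is a simulation and decision-support library for environmental-health
and ecosystem management questions of the form: *given how human activity
drives environmental degradation, how should limited intervention budgets be
deployed, and what does each strategy buy?* It is aimed at modellers and
methods researchers who want a transparent, fully testable sandbox for
coupled ecosystem dynamics and adaptive intervention policy — every rate law
is a small, documented function with a closed-form or independent oracle
behind it, and every experiment is a seeded, serializable scenario.

## The model

The core state is the triple (**E**, **A**, **I**): environmental indicators
(pollutant burden, resource level, biodiversity, carbon, water quality),
anthropogenic activity intensities, and intervention efforts. They evolve as

```
dE/dt = C·A + C′:(A ⊗ A) − M·I + N(t)
dA/dt = −K·A + D·E
dI/dt = N_r·E − L·I
```

where C couples activity to impact, C′ adds quadratic cross-dependencies,
M is the mitigation-efficiency matrix, K regulates activity, D feeds
degradation back into activity, and N_r/L make intervention effort
responsive and transient. Integration is fixed-step classical RK4 with
non-negativity clipping on A and I.

Around this core sit:

- a conservative finite-difference solver for the 2-D advection–diffusion
  pollutant equation ∂P/∂t + v·∇P = D∇²P + S − R, with CFL guarding,
  emission-reduction/removal-enhancement controls and a permissible
  rate-of-change check;
- ecological rate laws: logistic resource renewal with extraction and
  degradation, habitat quality, Lotka–Volterra competition (plus a
  stress/protection variant), a biodiversity index, carbon and water
  balances, and monitoring-uncertainty decay;
- an adaptive feedback controller that drives **E** toward a target **E\***
  by the projected descent step I′ = clip(I + 2η·Mᵀ(E − E\*), I_min, I_max)
  on the loss L = ‖E − E\*‖², fired at a fixed control interval;
- a budget-constrained multi-objective optimizer, max Σ w_k O_k(I) subject
  to Σ C_i I_i ≤ B and box bounds, solved by multi-start projected gradient
  ascent with an exact KKT projection onto the budgeted box;
- stakeholder mathematics: engagement scaling φ = 1 + αC_eng of intervention
  effectiveness, community-driven effort γ·P_com, and proportional fair
  allocation R_s = B·β_sP_sN_s / Σβ_jP_jN_j;
- scenario tooling: seeded synthetic presets, YAML/JSON configs, tidy-CSV
  trajectories, deterministic JSON reports and a small CLI.

## Worked example

Compare intervention intensities on a seeded urban scenario
(`examples/04_feedback_control.py`):

```python
from remf.adaptive_control import integrated_burden, run_scenario
from remf.scenario_io import generate_synthetic_scenario

scenario = generate_synthetic_scenario("urban-small", seed=1)
for mode in ("bau", "moderate", "aggressive"):
    traj = run_scenario(scenario.state0, scenario.coupling,
                        scenario.controller, scenario.run.t_end, mode,
                        step=scenario.run.step)
    print(mode, round(integrated_burden(traj), 3))
```

prints

```
bau 208.932
moderate 185.726
aggressive 172.182
```

The burden is ∫‖E(t)‖₁dt over the 10-unit horizon: business-as-usual (no
intervention) accumulates the most indicator burden; raising the controller's
effort ceiling from half to full reduces it further. The same comparison is
available from the shell:

```bash
remf generate --preset urban-small --seed 1 --out s.yaml
remf scenarios --config s.yaml --out out/
remf optimize  --config s.yaml --out solution.json
```

The other scripts in `examples/` each exercise one capability — coupled
dynamics and stress accumulation, plume transport and emission control,
ecological closed forms, budgeted optimization and projection, and
stakeholder allocation — and print a line explaining their numbers.

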