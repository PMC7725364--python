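# swarminfer

Simulate collective motion and infer the rules of interaction back from the
trajectories.

Averaging (force-matching) methods are a standard way to infer how animals
in moving groups — fish shoals, bird flocks, insect swarms — respond to
their neighbours: bin each individual's instantaneous turn rate and speed
change against the relative position of its group mates and average per
bin.  The resulting *interaction surfaces* suggest where repulsion,
attraction and blind zones lie.  But how accurate is that picture?
`swarminfer` answers the question with simulation: it generates trajectories
from two classic models whose rules are known exactly, runs the averaging
method on them, and measures how well the inferred surfaces recover the
prescribed rules.

The package provides:

* **Simulators** — a discrete-time zonal flocking model (zones of
  repulsion / orientation / attraction with radii `r_r < r_o < r_a`, a rear
  blind wedge of angle `ω_blind`, a maximum turning rate `θ`, heading noise
  `η`) and a continuous-time swarm ODE
  `dv_i/dt = (α − β|v_i|²)v_i − (1/N) Σ_j ∇U(|x_i − x_j|)` with the Morse
  potential `U(r) = −C_A e^{−r/l_A} + C_R e^{−r/l_R}`, integrated with RK4.
* **Kinematics** — forward-difference velocities, headings, signed turn
  rates (deg/s, positive = anticlockwise) and speed changes.
* **Averaging** — focal-frame relative coordinates and overlapping-bin mean
  response surfaces, optionally per focal-speed class, poolable across
  replicates.
* **State classification** — polarisation `p_group` and angular momentum
  `m_group`, fragmentation detection, and parallel/cohesion/mill/swarm
  labels.
* **Zone estimation** — the apparent repulsion-zone radius via a
  three-point circumcircle on the near-field repulsion boundary, and the
  apparent blind angle via the rear no-response wedge.
* **Analytic baselines** — closed-form single-partner response fields for
  both models, used as independent oracles.

See `docs/methods.md` for the models, estimators and design choices in
detail.

## Worked example

Simulate ten zonal-model groups (N = 25, prescribed repulsion radius
`r_r = 2`, blind angle 90°), pool the replicates that exhibit cohesion, and
estimate the zone geometry from the inferred turn-rate surface:

```python
import swarminfer as si

params = si.ZonalParams(N=25, r_r=2.0, delta_r_o=1.0, delta_r_a=11.0,
                        omega_blind=90.0, n_steps=1000)
trajs = si.collect_replicates(params, "cohesion", n_target=10, master_seed=1)

surface = si.surface_from_trajectories(trajs, si.GridSpec(), "turn_rate")
fit = si.fit_repulsion_zone(surface)
blind = si.estimate_blind_angle(surface, radius=fit.radius)
print(f"prescribed r_r = {params.r_r}, estimated radius = {fit.radius:.3f}")
print(f"prescribed blind angle = {params.omega_blind}, "
      f"wedge = {blind.angle:.1f} deg (evident: {blind.evident})")
```

Output:

```
prescribed r_r = 2.0, estimated radius = 2.007
prescribed blind angle = 90.0, wedge = 68.0 deg (evident: True)
```

The radius estimate lands within half a bin of the prescribed 2.0.  The
rear wedge is real but under-measured on the default 1-unit bins, which
smear its edges; re-running the estimate on the fine grid
(`si.FINE_GRID`, 0.25-unit bins) resolves the blind angle to within a few
degrees of the prescribed 90°.  The same machinery is exposed on the
command line (`swarminfer simulate | classify | infer | estimate-zones |
run-experiment | fixtures`).

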