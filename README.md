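# rxnscale

Multiscale analysis of reaction-kinetics models of collective behaviour.

Many systems — chemical networks, decision-making in animal groups,
predator–prey ecology, opinion dynamics, robot swarms — are naturally
recorded as reaction rules: *who interacts with whom, what they become, and
at what rate*. `rxnscale` takes a plain-text rule set such as

```
U -> A : g_A
A + U -> A + A : r_A
A + B -> B + U : s
```

and produces, from the same model object, every standard level of
description:

* **Mean field** — mass-action ODEs with drift
  `dX/dt = Σ_i (β_iX − α_iX) r_i Π_j x_j^{α_ij}`, numerical integration,
  phase portraits, fixed points classified by Jacobian eigenvalues.
* **Bifurcations** — native pseudo-arclength continuation of equilibria in
  one parameter with detection of limit points (folds) and branch points
  (e.g. pitchforks), including automatic branch switching.
* **Finite-population noise** — the chemical master equation
  `∂P/∂t = Σ_i r_i V (Π_k E_k^{α_k−β_k} − 1) Π_j ((n_j))_{α_j} V^{−α_j} P`
  built symbolically; its van Kampen system-size expansion
  (`n = VΦ + √V η`) yielding the macroscopic equations at order `√V` and a
  linear Fokker–Planck equation at order `V⁰`; moment equations
  `d⟨η⟩/dt = A⟨η⟩`, `d⟨ηηᵀ⟩/dt = A⟨ηηᵀ⟩ + ⟨ηηᵀ⟩Aᵀ + B`; stationary
  covariances from the Lyapunov equation `AC + CAᵀ + B = 0`; lagged
  correlations `e^{Aτ}C`; 1-σ noise ellipses.
* **Exact stochastic simulation** — Gillespie's direct method with
  falling-factorial propensities, single trajectories and ensembles.
* **Spatial noise** — rules compiled to per-agent probabilistic finite
  state machines run in synchronous timesteps on interaction graphs
  (complete, Erdős–Rényi, Barabási–Albert, static or dynamic random
  geometric graphs with correlated random walks), with the timestep
  calibrated automatically so agent time matches ODE/SSA time.

All levels are mutually consistent: the expansion's macroscopic equations
equal the mass-action ODEs, SSA propensities equal the master-equation
coefficients, and agent simulations on a complete graph reproduce SSA
statistics.

## Worked example

The stop-signal model of honeybee nest-site choice: uncommitted scouts `U`
commit to sites A/B (discovery `g`, recruitment `r`), revert (`a`), and
committed bees cross-inhibit (`s`). Rates are re-expressed through site
qualities `v_A = μ + Δ/2`, `v_B = μ − Δ/2`:

```python
from rxnscale import load_fixture, derive_odes, find_fixed_points

model, params = load_fixture("honeybee_reduced")   # U eliminated: U = N - A - B
odes = derive_odes(model, "counts")
print(odes.drift[0])
# -A**2*Delta/2 - A**2*mu - A*B*Delta/2 - A*B*mu - A*B*s + A*Delta*N/2
#   - A*Delta/2 + A*N*mu - A*mu - A/(Delta/2 + mu) - B*Delta/2 - B*mu
#   + Delta*N/2 + N*mu

fps = find_fixed_points(
    odes, {"Delta": 0.0, "mu": 3.0, "s": 10.0, "N": 20.0},
    domain=[(0, 20), (0, 20)], constraint=lambda z: z.sum() <= 20,
)
for fp in fps:
    print(fp.classification, [round(v, 3) for v in fp.location])
# stable   [0.002, 19.887]
# saddle   [4.239, 4.239]
# stable   [19.887, 0.002]
```

Two committed attractors coexist with a symmetric saddle: strong
cross-inhibition makes the swarm break decision deadlock. The same model's
stochastic side:

```python
from rxnscale import derive_master_equation, van_kampen_expand, stationary_covariance

model, _ = load_fixture("toy_birth_annihilation")   # (A) -> X : k,  X + X -> 0 : h
lnr = van_kampen_expand(derive_master_equation(model))
print(lnr.drift_matrix, lnr.diffusion_matrix)
# Matrix([[-4*Phi_X*h]])  Matrix([[Phi_A*k + 4*Phi_X**2*h]])

fp = find_fixed_points(lnr.macroscopic_odes, {"k": 1, "h": 1, "Phi_A": 1}, [(0, 2)])[0]
cov = stationary_covariance(lnr, fp, {"k": 1, "h": 1, "Phi_A": 1})
print(round(fp.location[0], 5), round(cov.covariance[0, 0], 5))
# 0.70711 0.53033
```

The fixed point sits at `Φ* = 1/√2` and the stationary fluctuation variance
is `C = B/(2|A|) = 3/(8Φ*) ≈ 0.53033`, which a 400-run Gillespie ensemble at
`V = 200` reproduces (see `tests/test_acceptance.py`).

Model files in the plain-text `.rxn` grammar live under `examples/`; a
command-line interface mirrors the library:

```sh
rxnscale parse toy_birth_annihilation --show-odes --show-master
rxnscale bifurcation honeybee_reduced --params Delta=0,mu=4,N=1 \
    --param s --response "A - B" --range 0:15 --init 0.3,0.3 --domain 0:1,0:1
rxnscale ssa honeybee --params mu=3,Delta=0,s=3 --init 50,0,0 -V 50 --tmax 10 --runs 10 --seed 1
```

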