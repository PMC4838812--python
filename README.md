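# wendling

Simulation and dynamical-systems analysis of the extended Wendling neural
mass model of epileptic depth-EEG.

The package is aimed at computational neuroscientists and epilepsy modellers
who use lumped-parameter ("neural mass") models to synthesize depth-EEG, and
at anyone who needs a carefully tested reference implementation of this
widely used four-population model: pyramidal cells, excitatory interneurons,
slow dendritic-projecting inhibitory interneurons, and fast
somatic-projecting inhibitory interneurons.

## The model

Each synaptic pathway is a critically damped second-order filter turning a
presynaptic pulse density into a postsynaptic potential,

    ÿ(t) = K k u(t) − 2k ẏ(t) − k² y(t),

with gain/rate pairs (K, k) ∈ {(A, a), (B, b), (G, g)} for excitation, slow
inhibition and fast inhibition, and each population converts summed membrane
potential back to a pulse density through the sigmoid

    S(v) = 2e₀ / (1 + exp(r (v₀ − v))),    v₀ = 6 mV, e₀ = 2.5 s⁻¹, r = 0.56 mV⁻¹.

Written in first-order form this gives ten ODEs; the EEG-like output is
y_out = y₁ − y₂ − y₃. The pyramidal drive p(t) is white noise (mean 90 s⁻¹,
SD 30 s⁻¹), which makes the system a set of stochastic differential
equations. The package provides:

* **`wendling.model`** — parameters, sigmoid, the full 10-equation drift,
  the algebraically equivalent reduced 8-equation drift (the duplicated
  slow-inhibition filter merged away), and the exact mappings between the
  two state spaces.
* **`wendling.integrators`** — fixed-step integration. `euler_classical`
  and `rk4_classical` treat p(t) as an ordinary input, which scales the
  noise by the step size h and makes the output variance shrink ∝ h — the
  historical artifact this package demonstrates. `euler_sde` is the
  corrected Euler–Maruyama update whose noise increment
  A·a·σ·√(h_ref·h)·r_n (h_ref = 1 ms) keeps the variance stable under step
  refinement and coincides exactly with classical Euler at h = h_ref.
  Also: multi-phase scenario driver, variance and DC-removal utilities.
* **`wendling.dynamics`** — equilibria via the combined scalar nullcline
  equation, analytic Jacobians, eigenvalue stability classification, branch
  tracing over the slow inhibitory gain B, and bisection localization of
  the saddle-node and stability-transition bifurcations that organize the
  background → spiking → gamma progression and its DC offset.
* **`wendling` CLI** — `simulate`, `equilibria`, `bifurcation`, `phases`;
  deterministic, seed-reproducible CSV/JSON artifacts.

## Worked example

```sh
$ wendling equilibria --A 5 --B 45 --G 20 --p-mean 90
y_out = -0.124 mV  [stable]  max Re(lambda) = -24.0 1/s
y_out =  2.526 mV  [unstable]  max Re(lambda) = 46.9 1/s
y_out =  5.087 mV  [unstable]  max Re(lambda) = 20.0 1/s
```

In the background regime (B = 45) the system is tristable on paper but only
the node at −0.124 mV attracts; that value is the DC offset of the
simulated EEG around which the noise-driven fluctuations ride. Sweeping B
downward:

```sh
$ wendling bifurcation --range 30:45 --grid 1 --resolution 0.01
saddle_node at B = 37.2930 (bracket [37.2891, 37.2969])
```

the stable node collides with a saddle at B ≈ 37.3 and a limit cycle
(sustained spiking) takes over. A noisy simulation in the gamma regime:

```sh
$ wendling simulate --A 5 --B 40 --G 20 --scheme rk4 --h 0.001 \
      --duration 11 --discard 1 --seed 1 --out run
samples: 11001  mean: 0.585727 mV  variance: 0.0698157 mV^2
```

Re-running with `--h 0.0001` drops the variance to ≈ 0.007 mV² — the
classical-integration artifact (nothing converged; the noise just got
scaled by a smaller h). With `--scheme sde-euler` the variance stays
≈ 0.07–0.08 mV² across step sizes.

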