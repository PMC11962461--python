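# eetnet

Stochastic thermodynamics of excitation energy transfer (EET) networks,
built for the photosystem II (PSII) supercomplex and systems like it.

Light-harvesting antennas such as the dimeric C₂S₂M₂/C₂S₂ PSII
supercomplexes have a nearly *flat* energy landscape: the lowest levels
of the protein subunits (CP43, CP47, CP26, CP29, CP24, the S- and
M-LHCII trimers) are almost degenerate, so the drive toward the
reaction center (RC) cannot be a simple energy funnel.  `eetnet`
quantifies the entropic and enthalpic components of that drive from a
kinetic rate matrix: it propagates the classical master equation on a
detailed-balanced excitonic network, decomposes the free energy change
of the relaxing ensemble in time, and extracts the observables that
characterize the network's design — population contraction times,
trap splitting probabilities, mean first passage (trapping) times, and
excitation lifetimes — under open/closed RC and antenna-complement
scenarios.

## Model

States are excitons with energies $E_j$ (cm⁻¹).  The population vector
$P(t) = \{p_1(t), p_2(t), \dots\}$ evolves by direct integration of the
master equation

$$P(t) = e^{Kt} P(0),$$

where $k_{ij}$ is the transfer rate $j \to i$ in ps⁻¹ and the closed
network satisfies detailed balance,
$k_{ij}/k_{ji} = e^{-(E_i - E_j)/k_B T}$ with
$k_B = 0.695035$ cm⁻¹ K⁻¹, guaranteeing Boltzmann equilibrium and a
thermodynamic reading of the dynamics.  Open RCs are modelled as
irreversible traps fed by the lowest-energy RC state (the
charge-transfer state); fluorescence loss is distributed over states
proportionally to the squared transition dipole (state-average rate
1/16 ns⁻¹) with a uniform nonradiative loss (1/2 ns⁻¹).

Along a trajectory the package computes the Shannon entropy
$S(t) = -k_B \sum_j p_j \ln p_j$, the mean energy of the surviving
excitations $H(t) = \sum_j p_j E_j$, and the decomposition

$$\Delta G(t) = \Delta H(t) - T\,\Delta S(t)$$

relative to the initial condition.  The time of the entropy maximum is
the **population contraction time** — the switch from entropic
spreading over the near-degenerate landscape to directed, increasingly
common pathways toward the trap.  The enthalpy-peak time marks the
switch from uphill to downhill ensemble energy flow.  For closed
networks $\Delta G(t)$ is provably non-increasing (H-theorem), which the
test suite verifies at 10⁻¹⁰ $k_BT$ resolution.

Because the deposited PSII rate matrices are external artifacts, the
package ships a first-class synthetic generator
(`eetnet.synth`): dimeric, mirror-symmetric PSII-mimetic networks with
fast intra-subunit / slow inter-subunit transfer, Gaussian site-energy
disorder over many realizations, a CT trap state per monomer, and exact
detailed balance via a symmetric Boltzmann-factor split.  Every
pipeline stage is testable without any download; absolute PSII
timescales are not claimed.

## Worked example

```python
import eetnet as e

net = e.generate_mimic(e.MimicSpec(seed=7))          # 142-state dimer mimic
rep = e.check_detailed_balance(net, tol=1e-9)

sc  = e.Scenario(network=net, losses=e.LossSpec())   # both RCs open + losses
sys = e.build_generator(sc)
ic  = e.delta_initial_condition(sys, "S-LHCII-B_m1_00")

traj = e.propagate(sys, ic)                          # master equation
th   = e.free_energy_series(traj, sys)               # S, H, dG series
s    = e.summarize(th)
fate = e.splitting_probabilities(sys, ic)
```

Output for this peripheral-antenna excitation:

```
mimic: 142 states, 8 subunits x 2 monomers
detailed balance: True (worst deviation 3.33e-16)
contraction time: 3.45 ps (entropy max 3.42 k_B)
enthalpy peak: 11.4 cm^-1 at 0.02 ps
fate: trap1 0.834, trap2 0.156, fluorescence 0.0012, nonradiative 0.0093
trapping MFPT: 18.7 ps
```

The excitation first disperses (entropy rises for 3.45 ps, peaking at
3.42 $k_B$ over the ~5 $k_B$ ceiling of ln 142) with only a brief,
weak uphill phase (11.4 cm⁻¹ ≪ $k_BT \approx 208$ cm⁻¹), then
contracts onto trapping pathways; 99% of the population reaches an RC
trap, preferring the same-monomer RC 5:1, with an 18.7 ps mean
trapping time.  Sweeping all initial states
(`eetnet.sweep_initial_conditions` / `eetnet.aggregate_by_subunit`)
shows the design gradient: RC-adjacent subunits contract fastest and
trap almost exclusively in their own monomer, while the bridging
M-trimer states contract last and split nearly 50/50.

A command-line interface wraps the same pipeline:

```
eetnet synth --seed 7 --out-dir net/
eetnet validate --rates net/rates.tsv --states net/states.tsv
eetnet report --rates net/rates.tsv --states net/states.tsv --out-dir out/
```

External rate matrices are consumed as dense TSV/CSV or Matrix Market
files plus a tab-separated state table (`state_id`, `subunit`,
`monomer`, `pigment`, `energy_cm1`, `x`, `y`, `z`, `dipole_sq`,
`is_chl_a`); the dense convention is column-source (column *j* holds
the outflows of state *j*), with a `transpose` flag for the opposite
convention.

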