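# Methods

## Model and assumptions

`eetnet` works with classical continuous-time Markov chains on exciton
states.  A network is a pair (state table, rate matrix): element
`K[i, j]` is the transfer rate j → i in ps⁻¹ and the matrix is held in
generator convention (diagonal = −column sums), so the master equation
is `dP/dt = K P` and `P(t) = exp(Kt) P(0)`.  Quantum coherence is not
modelled; the exciton basis and the rates are inputs.  Closed networks
must satisfy pairwise detailed balance with respect to the Boltzmann
distribution of the state energies at the bath temperature,

    k_ij / k_ji = exp(-(E_i - E_j) / k_B T),   k_B = 0.695035 cm⁻¹ K⁻¹,

which both fixes the stationary state and licenses the free-energy
decomposition below.  Units are fixed throughout: ps⁻¹ for rates, cm⁻¹
for energies, K for temperature, Å for coordinates.

Irreversible reaction-center (RC) traps are the one sanctioned
violation of detailed balance: each monomer's trap drains its
charge-transfer (CT) state — by default the lowest-energy RC-subunit
state — at a phenomenological rate (default 1 ps⁻¹, configurable; a
fast, irreversible drain consistent with near-unity trapping yield).
Loss channels add a per-state fluorescence rate proportional to the
squared transition dipole, rescaled so the state average is the
reciprocal of the mean fluorescence lifetime (default 1/16 ns⁻¹ =
6.25 × 10⁻⁵ ps⁻¹), plus a uniform nonradiative rate (default
1/2 ns⁻¹ = 5 × 10⁻⁴ ps⁻¹).  States without dipole metadata fall back
to the uniform mean.  A closed RC keeps its states in the network with
trap rate zero — transfer through the closed RC's pigments continues.
Antenna edits (e.g. C₂S₂M₂ → C₂S₂) delete whole subunits; detailed
balance of the remaining closed part is preserved by construction, and
a removal that strands states from every sink warns rather than fails.

The open system is represented as a transient generator over the kept
excitonic states plus four explicit absorbing sinks (trap 1, trap 2,
fluorescence, nonradiative), so total probability is conserved exactly
and every absorption statistic has a linear-solve form:

    absorption probabilities  b   = R (−T)⁻¹ P(0)
    mean absorption time      τ   = 1ᵀ (−T)⁻¹ P(0)

with T the transient block and R the sink-inflow rates.  The mean
first passage time to the traps is computed with losses disabled
(absorption is then certain and τ equals the time integral of the
surviving probability); the excitation lifetime is the same integral
with all sinks active, reported alongside a single-exponential fit to
the tail of the survival curve (over the last decade of times before
the survival drops below 10⁻¹²), since "fluorescence lifetime" is often
quoted as a tail decay constant.  A vectorized Gillespie simulator
provides an independent stochastic cross-check of the same chain; the
suite requires agreement within three binomial standard errors at 10⁴
trajectories.

## Free-energy decomposition

Along a trajectory the package computes the Shannon entropy
S(t) = −k_B Σ p ln p (natural log, k_B units internally; the −TΔS
presentation converts to cm⁻¹ via 0.695035·T), the mean energy H(t) of
the surviving excitations, and ΔG(t) = ΔH(t) − TΔS(t) with changes
relative to t = 0.  Sinks are excluded from S and H.

Two conventions matter under traps:

* **Entropy** defaults to *raw* mode — evaluated on the unnormalized
  surviving populations.  From a delta start S rises from zero, peaks,
  and decays back to zero as the population absorbs, so the
  **population contraction time** (the entropy maximum) is always
  well defined.  A *conditional* mode (renormalize by surviving mass
  first) is available for comparison; the two coincide for closed
  networks.  Sweeps surface the ambiguity rather than hide it: when the
  alternative normalization moves a state's contraction time by more
  than 10%, the alternative value is emitted in a separate column
  (`contraction_time_alt_ps`), NaN otherwise.
* **Enthalpy** is always the *conditional* mean energy of the
  survivors.  The raw sum Σ p E is not invariant to the arbitrary
  energy zero once mass absorbs (it decays by ≈ E₀ × absorbed mass,
  i.e. thousands of cm⁻¹ for electronic energies), which would swamp
  the ~100 cm⁻¹ scale of genuine uphill/downhill transfer and violate
  the flat-landscape identity ΔH ≡ 0.  The conditional mean is
  shift-invariant and reads as the ensemble energy of excitations
  still en route — consistent with interpreting the reported series as
  conditioned on eventually reaching the RC.

For closed detailed-balanced networks, ΔG(t) equals
k_BT·[D(p(t)‖π) − D(p(0)‖π)] (KL divergence to the Boltzmann
distribution), hence is monotonically non-increasing; the suite
enforces this at every grid step to 10⁻¹⁰ k_BT.

Extracted times (contraction time, enthalpy-peak time) are located on
the output grid and refined by golden-section search on the
continuously propagated series within the bracketing interval, to
±0.1 ps — an order finer than whole-ps reporting.  Ties break to the
earliest time; an entropy series that is maximal at t = 0 (monotone
non-increasing) yields a contraction time of 0; a maximum at the final
grid point raises, with the instruction to extend the grid.

## Numerics

* **Propagator.**  Open systems are propagated by interval-wise dense
  matrix exponentials (backward-stable scaling-and-squaring applied to
  the extended generator), which is robust for non-symmetric, possibly
  defective generators and meets a 10⁻⁹ relative-accuracy contract on
  the two-state closed form.  Closed detailed-balanced generators are
  symmetrizable (reversible chains): `propagate` detects this and
  switches to the symmetric spectral factorization
  S = D⁻¹KD, D = diag(√π), propagating the *deviation from
  equilibrium* (which has no stationary-mode component analytically).
  This path is exact in the symmetrizable case, avoids the round-off
  random walk of 600 sequential exponentials, and keeps the late-time
  ΔG plateau flat to ~10⁻¹¹ k_BT.
* **Time grid.**  Default: t = 0 plus 600 log-spaced points over
  [10⁻², 10⁵] ps, spanning sub-ps intra-subunit equilibration through
  nanosecond-scale loss.
* **Degenerate inputs.**  Negative populations from round-off are
  clipped at −10⁻¹² → 0.  Rows whose surviving mass has fully decayed
  carry the last defined conditional enthalpy forward.  Absorption
  solves check sink reachability first and name the stranded states in
  the error.  One-sided rates (forward without reverse) fail closed-
  network validation unless designated as trap transitions.  The
  diagonal of an input matrix is always re-derived from the
  off-diagonal rates (zero-diagonal and generator files are both
  accepted), with column sums computed in sorted order so that
  mirror-symmetric dimers stay bit-exactly symmetric.
* **Averaged matrices.**  The disorder-averaged rate matrix (mean of
  off-diagonal rates, diagonal rebuilt, ensemble-mean energies) is the
  working single-matrix surrogate for a disorder ensemble.  Each
  realization is exactly detailed balanced with respect to its own
  energies; the average is only approximately so, and is therefore
  propagated by the general expm path.

## Synthetic PSII mimic

The generator emulates the statistical structure the analysis assumes,
not the real Hamiltonian.  Default layout: two mirror-image monomers of
8 subunits (RC, CP43, CP47, CP26, CP29, CP24, one S- and one M-trimer
subunit; 71 states per monomer, 142 total) with a D1-side chain
RC–CP43–CP26–S-LHCII and a D2-side chain RC–CP47–CP29–CP24–M-LHCII.
The M trimers bridge the monomers; the two cores also touch weakly
(CP47↔CP43 at 2% of the inter-subunit coupling scale), which keeps the
dimer connected when the M trimers are removed without washing out
monomer identity.  Couplings are symmetric and log-uniform around
2.0 ps⁻¹ within subunits and 0.1 ps⁻¹ between adjacent subunits; rates
follow the symmetric Boltzmann split k_ij = c_ij·exp(−(E_i−E_j)/2k_BT),
which is exactly detailed balanced for any symmetric c — the mimic
claims the thermodynamic constraint, not the microscopic
(Redfield/Förster) rate theory.

Site energies are subunit means (near-degenerate around 15000 cm⁻¹,
the flat-landscape premise) plus Gaussian static disorder with
σ = 80 cm⁻¹ — a free parameter standing in for literature
inhomogeneous-broadening widths, exposed per spec.  Chl b sites are
blue-shifted by 400 cm⁻¹ (giving the characteristic purely-downhill
Chl b relaxation); each monomer's CT state is pinned 150 cm⁻¹ below
the rest of its RC manifold.  Disorder ensembles share topology,
couplings and dipoles and redraw only energies, seed-reproducibly.
Control landscapes (`funnel` / `flat` chains with matched couplings)
isolate the enthalpic-drive contrast.

What passing tests on the mimic do **not** show: agreement with the
real supercomplex's absolute timescales (the mimic's contraction times
are a few ps, not tens of ps — its inter-subunit connectivity is
denser than the real coupling map), per-pigment energetics, or the
exciton→site localization structure of the real matrices (site basis
and exciton basis coincide in the mimic).  What they do show: the
machinery — detailed-balance validation, propagation, free-energy
decomposition, absorption statistics, sweeps — is correct against
closed forms, quadrature, kinetic Monte Carlo and brute-force grids,
and the directional physics (peripheral starts contract later; closing
an RC slows its own side disproportionately; funnels contract faster
than flat landscapes; D1-side starts prefer the same-monomer RC) holds
across disorder seeds.

## Problem sizes

Defaults keep everything desk-scale: the 142-state mimic, 500-member
disorder ensembles, 10⁴-trajectory Gillespie cross-checks, 10⁵-point
brute-force grids for refinement oracles, and 20-seed directional
panels.  A full 142-state sweep (propagation, thermodynamics,
splitting, MFPT and lifetime for every initial state) runs in a few
seconds on one CPU; `scripts/acceptance.py` completes in about half a
minute.

## Known limitations

* The pipeline consumes a rate matrix; it does not derive one from
  structures or Hamiltonians.
* No density-matrix (coherent) dynamics; no charge-separation
  back-transfer, radical-pair states or water-splitting chemistry.
* The trap rate is phenomenological and unquantified by the underlying
  report; observables that depend on it (contraction times under
  traps, MFPTs) should be read relative to a stated trap rate, and a
  sensitivity sweep over `TrapSpec.trap_rate` is the recommended
  diagnostic.
* Exciton→site projection requires a localization map as an input
  artifact; without one the site basis is assumed.
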