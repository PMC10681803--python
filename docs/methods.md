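# Methods

## The model

`parbcond` implements a coarse-grained model of partition-complex formation:
a ParB-decorated DNA polymer in which one-dimensional protein kinetics on the
chain couple to three-dimensional chain conformation through valence-limited
protein-protein bridging.

### DNA polymer

The DNA is a bead-spring chain of `n_beads` spherical beads of diameter
sigma, with 1 bead = 5.5 nm = 16 bp.  All quantities are in reduced units
(sigma = eps = k_BT = m = 1).  Interactions:

* **Excluded volume** — shifted, truncated Lennard-Jones,
  `U = 4 eps [(s/r)^12 - (s/r)^6 + 1/4]` for `r <= 2^(1/6) sigma`, 0 beyond
  (purely repulsive).
* **Bonds** — FENE, `U = -0.5 k R0^2 ln(1 - (r/R0)^2)` with
  `k = 30 eps/sigma^2`, `R0 = 1.5 sigma`, summed with the LJ term of the same
  pair (so bonded pairs are excluded from the non-bonded sum).
* **Bending** — `U = k_theta (1 - cos theta)` on consecutive bond pairs with
  `k_theta = 10 k_BT`; theta = 0 for collinear bonds.  The discrete-chain
  prediction for the bond-correlation decay is
  `<cos theta> = coth(k) - 1/k ~ 0.900` at k = 10, i.e. a persistence length
  `l_p = -1/ln(0.9) ~ 9.5 beads ~ 52 nm`; "l_p ~ 10 beads ~ 55 nm" at the
  stated coarse-graining.

Dynamics are NVT Langevin (damping gamma = 1, mass 1) integrated with
velocity-Verlet at `dt = 0.002 tau_MD`.  Friction and thermal kicks enter as
forces; the kicks are uniform random variables with variance
`2 gamma m k_BT / dt` (the usual cheap substitute for Gaussians in Langevin
thermostats — velocities become Gaussian by accumulation over the damping
time).  The measured `<v^2>` per component is within 0.1% of k_BT/m and
microcanonical (gamma = 0, k_BT = 0) energy drift is ~1e-7 eps/step.  The
Brownian time `tau_B = 500 dt` is the clock of the kinetic layer; with water
viscosity it maps to 0.5 us.  No periodic boundaries; chain ends are free.

**Initialization.**  Chains start from a self-avoiding discrete worm-like
chain: bond directions drawn from the Boltzmann weight of the bending
potential (inverse-transform sampling of `p(cos) ~ exp(k cos)`), with beads
resampled if they land within 0.8 sigma of an earlier bead.  This puts local
statistics exactly at equilibrium and global size close to it, so the
windowed-Rg^2 stationarity criterion (consecutive 200-tau_B window means
agreeing within 2% or within sampling noise) is reached within a few hundred
tau_B.  Relaxing a straight-line start instead would cost >1e5 tau_B for the
chain lengths used here, with no benefit for any measured observable.

### ParB kinetics (implicit protein layer)

ParB is a per-bead occupancy flag, updated once per tau_B between Langevin
blocks, in fixed order (unload -> slide -> load -> recruit; rates are all
<< 1/tau_B, so ordering effects are second order in the rates):

* **Loading** at the parS bead (chain midpoint) with probability
  `min(kappa_on, 1)` per sweep, rejected if parS is occupied.
* **Unloading** of each bound ParB with probability `kappa_off = 0.001` per
  tau_B (mean residence 1000 tau_B = 0.5 ms); unloading deletes the bridges
  anchored at that bead.
* **1D sliding**: each bound ParB steps left/right with probability 0.125
  each per tau_B (D = 0.125 sigma^2/tau_B, MSD = 2 D t), rejected at chain
  ends and onto occupied beads.  A bridged ParB that hops drags its bridge
  anchor along if the partner is still within the interaction cutoff, else
  the bridge is dropped.
* **Recruitment**: each bound ParB attempts with probability
  `min(kappa_on, 1)` per sweep; in-cis (p = 0.083) to a uniformly chosen
  1D-adjacent bead, otherwise in-trans to a uniformly chosen unoccupied bead
  within 2 sigma Euclidean distance and at least 3 beads away along the
  chain.  The trans:cis weight ratio is 11.

The control parameter is `kappa = kappa_on / kappa_off`, the proxy for bulk
ParB concentration.

### Bridging (DoD vs MoD)

Occupied beads within `rc = 2 sigma` may form bridges governed by a Morse
potential `U = D0 (e^(-2 a r) - 2 e^(-a r))`, `a = 0.5/sigma`, cut (without
shift, as defined) at rc.  The per-bead number of simultaneous bridges is
capped by the **valency**: 1 = dimer-of-dimers (one-to-one bridges only),
2 = multimer-of-dimers (bridge chains/oligomers).  The bridge set is
refreshed every sweep: stale pairs (beyond rc or unloaded) are dropped,
eligible new pairs (both occupied, r < rc, 1D separation >= 3, spare
valency) are activated in random scan order.  The Morse force acts between
bead centers of active pairs during the next Langevin block.

Design choice: the reference implementation uses valence-capped isotropic
center-to-center bonding with explicit pair bookkeeping rather than rigid
antipodal patches.  The patch geometry (offset, rotational inertia) is not
what controls the phenomenology — the valency is — and an isotropic cap
makes the valency an exact, assertable invariant.  Because the Morse minimum
sits at r = 0, the equilibrium bridge distance (~0.9 sigma) comes from the
Morse-LJ balance.

## Phase behaviour and its measurement

Coupled runs alternate 500-step Langevin blocks with kinetic sweeps.
Observables per sweep: Rg^2, bound count, bridge count; occupancy/bridge
snapshots every `dump_interval` sweeps.  Conformations are classified
against the bare-chain `<Rg^2>`: **collapsed** if the late-window (final
third) mean is below 0.5x bare, else **spread** if occupied beads span more
than 50% of the chain, else **localized**.  Both thresholds are exposed in
the API; they separate the three regimes robustly at the sizes used here.

The condensation transition is **bistable**: near the critical kappa,
replicas are either open or collapsed, and spontaneous nucleation from the
open coil is a rare event.  In pilot runs at eps = 10, kappa = 10 (300
beads) takeoff occurred at ~1e4 tau_B and compaction kept coarsening for
several 1e4 tau_B more.  Tests that probe the valency contrast therefore
interrogate the two branches directly: the MoD system must *hold* a
condensed start (compact lattice-snake conformation, fully loaded chain) at
Rg^2 < 0.3x bare, while the DoD system started from the equilibrated coil
must stay open.  This is the same physical claim — valency 2 is required for
a stable partition-complex condensate — measured where the dynamics are
fast enough to sample.

The cooperativity check sweeps kappa in {2, 5, 8, 11, 14, 17, 20} at
eps = 10 (MoD, 300 beads, 6000 tau_B each, one replica) and fits
`N_max kappa^H / (K^H + kappa^H)`.  At this reduced scale the fitted Hill
coefficient comfortably exceeds 2 (switch-like loading); the absolute H of
the full-scale (1000-bead, multi-hour) sweep is not reproduced at desk
scale.

**Known limitation — stationary bound count.**  With the per-ParB
recruitment reading, the condensed branch saturates near full occupancy:
warm-started 1000-bead runs at kappa = 8, eps = 10 plateau at ~800 bound
ParB, not at the ~100 scale one might expect for a partial condensate.
Recruitment success in a dense globule stays above kappa_off/kappa_on until
almost no free beads remain, so the stationary count is set by chain length.
A globally shared recruitment budget, or explicit patch geometry limiting
the local contact count, would cap this lower; the per-ParB reading is kept
because it is the one stated for this model, and the discrepancy is reported
rather than tuned away.

## Quantification pipelines

### Condensate size and tension (fluorescence stretching assay)

Image stacks are median-filtered (3x3 default), background-subtracted with a
white tophat (15-px structuring element), and an 11-pixel band across the
DNA axis is summed per position per frame to build the kymograph.  A 10x10
median window would annihilate diffraction-limited spots (sigma_PSF ~ 1.5
px) outright, so the default window is 3 px and is config-exposed.  Spots
are detected per frame as maxima exceeding the column median + 5 MAD and
linked by nearest neighbour (max displacement 5 px/frame, gaps up to 3
frames).  `I_cond` integrates +-5 px around the spot after subtracting the
per-pixel baseline estimated from non-condensate columns (so uncondensed DNA
running through the spot region is not counted); `I_total` integrates the
whole DNA.  Then

    L_cond = I_cond / I_total * L,  L = 42.5 kb,

and the tension outside the condensate follows the 7-coefficient WLC
interpolation

    F = (k_BT / L_p) [ 1/(4 (1-r)^2) - 1/4 + sum_i a_i r^i ],

with `r = R / L_out^c`, `L_out^c = alpha * (L - L_cond) * 0.342 nm/bp`,
`alpha = 1.0357` (SxG intercalation at 25 nM), `L_p = 39.7 nm`, T = 293 K.
The per-bp rise is 0.342 nm (the standard B-DNA value; a 0.324 nm variant
appears in some descriptions and the parameter is config-exposed).
FRAP recovery integrates the kymograph over the full DNA, normalizes to the
pre-bleach mean and fits `c + A(1 - e^(-t/tau))`.

### RNAP dwell times

50 Hz traces are moving-average filtered to 1 Hz (50-sample window), cut
into first-passage times through consecutive 5-nt windows (back-crossings
extend the following dwell — backtracks inflate long dwells), and binned on
a log axis (10 bins/decade) into a normalized density with per-bin SDs from
100 bootstrap resamples.  A gamma density is least-squares fitted to the
bins inside the elongation region (0.1-1 s); its peak `t_bar =
(shape-1)*scale` gives the elongation rate `k = 5 nt / t_bar`.  Pause
probabilities are the density integrals over 1-5 s (short/elemental) and
>5 s (long/backtrack), with bins straddling a boundary contributing pro
rata.

## Synthetic data: what it emulates, what it does not

* **Kymograph generator** — a transverse-Gaussian DNA band (62 px ~ 8 um at
  0.13 um/px) carrying conserved total intensity, of which a programmed
  fraction sits in a Gaussian condensate spot (sigma_PSF = 1.5 px) whose
  position diffuses; Poisson photon noise; optional photobleach with
  exponential exchange recovery.  It does not emulate DNA transverse
  fluctuations, drift, uneven illumination, or camera read noise, so passing
  the 5%/10% closed-loop recovery bounds demonstrates correctness of the
  pipeline arithmetic and robustness to shot noise, not performance on
  adversarial real imaging.
* **Transcription generator** — per-5-nt-window elongation times drawn from
  a Gamma distribution whose *mode* is `5/rate` (so the peak-based rate
  definition recovers the programmed 9.2 nt/s exactly), with at most one
  pause per window: short pauses uniform on 1.2-4.0 s, long on 6-20 s, at
  exactly known per-window probabilities.  The default Gamma shape is 20,
  narrower than literal single-nt stepping (shape 5), chosen so that the
  elongation peak does not leak into the 1-5 s region and the three
  dwell-time regions stay separable — the property the region-integral
  definition of pause probabilities presumes.  Sampling 50 Hz, additive
  Gaussian noise (1 nt SD), traces truncated at 5000 nt.
* **Test chains** — deterministic straight/hairpin/globule conformations
  with designed contact geometry for exact assertions on neighbour lists and
  valency caps.

## Problem sizes and tolerances used by the test suite

* Persistence length: 200 beads, 10 replicas, 15 frames every 25 tau_B after
  equilibration; fit over separations 1-30; tolerance +-20%.
* Valency contrast: 300 beads, 3 replicas per mode, 5000 tau_B each;
  bare baseline 4 replicas x 2000 tau_B.
* Occupancy plateau: 1000 beads, 3 replicas, warm start (15% occupancy
  block), 2500 tau_B, late-third time average.
* kappa sweep: 7 values, 6000 tau_B each, single replica.
* Closed-loop recovery: ~1e4 dwells (10 traces x 5000 nt); 50-frame
  kymograph trajectory; 180-frame FRAP movie.

Numerical details: pair lists are cell-binned Verlet lists (skin 0.4 sigma,
refresh at half-skin displacement); FENE overstretch or non-finite
coordinates abort a run with the offending step index; curve fits use
scipy's Levenberg-Marquardt/TRF with documented initial guesses; all
stochastic layers take a numpy PCG64 generator and every simulation output
records its seed.
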