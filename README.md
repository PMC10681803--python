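# parbcond

Coarse-grained modelling of ParB-mediated DNA condensation, together with the
quantification pipelines used to analyze the matching single-molecule assays
— all exercisable on synthetic data.

## The problem

Bacterial chromosome segregation relies on the partition complex: the
CTP-hydrolyzing protein ParB loads at a single 16-bp *parS* site, slides
along the DNA as a clamp, recruits further ParB dimers in-cis and in-trans,
and bridges distal DNA segments.  Transient, valence-limited ParB–ParB
bridges condense tens of kilobases of DNA around *parS* into a dynamic
nucleoprotein condensate that nevertheless lets RNA polymerase transcribe
through it.  `parbcond` is for people who want to simulate and quantify this
system: polymer physicists studying bridging-induced collapse, and
single-molecule biophysicists quantifying condensate size, DNA tension,
FRAP recovery and transcription pausing.

## The model

The DNA is a semiflexible bead-spring chain (1 bead = σ = 5.5 nm = 16 bp):
WCA excluded volume, FENE bonds (k = 30 ε/σ², R₀ = 1.5 σ), bending
U = k_θ(1 − cos θ) with k_θ = 10 k_BT (persistence length ≈ 10 beads
≈ 55 nm), integrated by velocity-Verlet Langevin dynamics (γ = 1,
dt = 0.002).  Every Brownian time τ_B = 500 dt, an implicit-ParB kinetic
layer acts on the bead lattice: loading at *parS* at rate κ_on, unloading at
κ_off = 10⁻³/τ_B, 1D sliding (hop probability 0.125 per direction per τ_B,
with hard-core exclusion), and recruitment by each bound ParB — in-cis
(p = 0.083) to an adjacent bead or in-trans (p = 0.917) to a spatially
proximal bead (≤ 2 σ, ≥ 3 beads away in 1D).  Occupied beads within 2 σ
interact through a Morse potential U(r) = D₀(e^(−2αr) − 2e^(−αr)) with a
per-bead **valency** cap: valency 1 (dimer-of-dimers) permits only
one-to-one bridges, valency 2 (multimer-of-dimers) permits oligomeric bridge
networks.  Sweeping the bridge strength ε = D₀ and the loading ratio
κ = κ_on/κ_off maps localized, spread, and collapsed phases; loading is
cooperative (switch-like, Hill-type) because each recruited ParB recruits
further.

The analysis side implements the standard single-molecule quantifications:
kymograph construction (median filter, white-tophat background subtraction,
11-px band integration), condensate tracking, condensate size
L_cond = (I_cond/I)·L with L = 42.5 kb, DNA tension from the 7-coefficient
worm-like-chain force–extension interpolation, FRAP exchange-time fitting,
and RNAP dwell-time statistics (5-nt first-passage windows, 1 Hz filtering,
log-binned densities with 100× bootstrap, gamma-peak elongation rate
k = N/t̄, pause probabilities as density integrals over 1–5 s and > 5 s).

## Worked example

```python
from parbcond import (BridgeParams, ForceField, KineticParams,
                      run_condensation)

res = run_condensation(n_beads=200, ff=ForceField(),
                       kp=KineticParams(kappa_on=0.015),   # kappa = 15
                       bp=BridgeParams(D0=10.0, valency=2),  # MoD, eps = 10
                       n_sweeps=12000, seed=42)
print(res.late_rg2, res.late_n_bound)
```

Running `python examples/02_condensation_run.py` (which executes exactly
this system and writes the observable time series) prints:

```
initial Rg^2:    492.8 sigma^2
late    Rg^2:    317.3 sigma^2
bound ParB (late mean): 195
active bridges at end : 178
beads visited by ParB : 200/200
(the bridge network keeps compacting the chain on 1e4-1e5 tau_B timescales)
time series written to condensation_observables.csv
```

i.e. at κ = 15, ε = 10 in the multimer-of-dimers mode, ParB loading is
supercritical: it spreads from *parS* over the whole chain (195 of 200 beads
bound in the late-time average), the bridge network percolates (178 active
bridges) and compaction sets in, continuing to coarsen on longer timescales.
`examples/03_valency_contrast.py` probes the two branches of the bistable
transition and prints:

```
bare-chain Rg^2: 424 +- 110 sigma^2
MoD from condensate: late Rg^2 =     80 sigma^2 = 0.19 x bare -> holds the condensate
DoD from open coil : late Rg^2 =    341 sigma^2 = 0.80 x bare -> stays open
```

— valency 2 sustains the condensate while valency 1 cannot condense, the
dimer-of-dimers vs multimer-of-dimers contrast at ε = 10, κ = 10.  Examples
01/04/05/06 demonstrate the persistence-length measurement and the
kymograph / dwell-time / FRAP pipelines, each printing the recovered numbers
next to the programmed ground truth.

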