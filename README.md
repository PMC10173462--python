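# permcycle

Permeation-cycle analysis of potassium-channel molecular-dynamics
trajectories: selectivity-filter occupancy coding, Markov state models,
permeation-cycle extraction and reduction, mean first passage times, net
fluxes, and single-channel currents.

## The problem

The selectivity filter (SF) of a K⁺ channel — the conserved TVGYG motif
contributed by each of four (pseudo-)symmetric chains — stacks backbone
carbonyl and threonine hydroxyl oxygens into rings that enclose six axial
binding sites, S0, S1, S2, S3, S4 and Scav (extracellular → intracellular).
How K⁺ ions and water move through these sites distinguishes competing
conduction mechanisms: **direct knock-on** (ions in direct contact, S2/S3
dehydrated, no water co-transport) versus **soft knock-on** (alternating
ion/water columns, 1:1 water copermeation). Raw MD trajectories contain
this information only implicitly; `permcycle` makes it explicit and
quantitative.

## The method

1. **Occupancy coding.** Per frame, each site's boundaries are the
   z-coordinates of the centers of mass of its oxygen rings (the bottom of
   Scav is 4 Å below the hydroxyl ring). A site holding a K⁺ codes `K`,
   a water `W`, both `C`, neither `0`, giving a six-character state such
   as `WKK0KW`.
2. **Markov state model.** Transitions between states are counted at lag
   τ (default 20 ps) and row-normalized, `T_ij(τ) = C_ij(τ)/Σ_j C_ij(τ)`.
   The stationary distribution ρ is the left eigenvector at λ = 1;
   relaxation times are `t_m = −τ/ln|λ_m|` (the modulus handles the
   complex spectra of this driven, irreversible process); Markovianity is
   checked with the Chapman–Kolmogorov test `T(kτ) ≈ T(τ)^k`.
3. **Ion jumps and current.** The pore is split into 8 compartments
   (intracellular, Scav…S0, extracellular); the net signed boundary
   crossings J of all ions give the current `I = e·J/(N_b·T)` with
   `N_b = 7` crossings per complete permeation.
4. **Permeation cycles.** Each ion's arrival on the extracellular side
   defines an event; the state sequence between the bracketing visits to
   an anchor state (canonically `WKK0KW`) is a permeation cycle. Cycles
   are *reduced* to their nonrepeating first-arrival states, removing
   oscillations that carry no net ion jumps. Edge probabilities are
   cycle-conditioned (fraction of reduced cycles containing the edge), and
   per-edge mean first passage times are estimated from independent
   passages with BCa bootstrap intervals, restricted to passages accruing
   fewer than `N_b` jumps (i.e. within one cycle). Net fluxes
   `f_ij = T_ij ρ_i − T_ji ρ_j` come from the full trajectories.
5. **Synthetic ground truth.** A first-class generator plants permeation
   events under either mechanism in a rigid model filter and returns
   coordinates together with the exact state sequence, jump trace and
   event list, so every stage of the pipeline is testable against known
   answers.

## Worked example

Generate a direct knock-on run with 10 planted permeations and analyze it:

```sh
$ permcycle simulate -o demo --n-permeations 10 --seed 3
305 frames, 10 planted events, J=70

$ permcycle cycles demo/states.tsv --edges-out demo/edges.csv --seed 3
anchor WKK0KW; 10 events; coverage 1.000; 1 distinct reduced cycles

$ permcycle current demo/states.tsv
synthetic-direct_knockon: J=70 T=6.08 ns I=263.5 pA

$ permcycle msm demo/states.tsv -o demo/model.json --ck demo/ck.csv --ck-floor 20
6 states; slowest relaxation 232 ps
CK k=2: deviation 0.0800
CK k=3: deviation 0.2160
CK k=5: deviation 0.6064
```

Reading the output: all 10 planted events were recovered (`J = 70 = 7×10`
boundary crossings), every event closes as a cycle through the anchor
`WKK0KW` (coverage 1.000), and the single reduced cycle is the planted
loop — `demo/edges.csv` lists each of its edges with cycle-conditioned
probability 1.0 and its MFPT. The current follows from the jump count and
the 6.08 ns duration. The large Chapman–Kolmogorov deviations flag the
scripted generator's deterministic (non-Markovian) dynamics — exactly
what the test is for. A full report bundle (model JSON, event JSON,
reduced cycles, edge tables, GraphML/DOT graphs, summary) comes from
`permcycle run config.yaml -o outdir`; real trajectories enter through
`permcycle encode topology.pdb traj.xtc -o states.tsv`.

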