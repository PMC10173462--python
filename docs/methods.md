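# Methods

This note documents the models, conventions and numerical choices behind
`permcycle`, in the spirit of the methods documentation shipped with
established simulation-analysis packages. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Geometry: binding-site boundaries

The selectivity filter is located by exact matching of one-letter residue
motifs (`TVGYG`, `TIGYG`, `TVGFG` by default, user-extensible) against
every chain; at least two matches are required, and all matches must have
the same residue count. The motif's first residue must be a threonine —
its hydroxyl oxygen ring forms the S4/Scav divider.

Seven boundary planes enclose the six sites. Planes 0–5 are the
mass-weighted center-of-mass z of one oxygen ring each (carbonyl O of the
5th, 4th, 3rd, 2nd, 1st motif residue, then the threonine hydroxyl O);
plane 6 — the bottom of the solvent-exposed cavity site Scav — carries no
atoms and sits a configurable depth (default 4.0 Å) below plane 5. S4 is
therefore bounded by the threonine carbonyl ring above and its hydroxyl
ring below, the only assignment that tiles all six sites contiguously.
For the top of S0 two conventions are offered: the carbonyl ring of the
top motif residue (default, consistent with the tiling of S1–S4) or an
offset plane mirroring the Scav construction (`s0_mode="offset"`).

Boundaries are recomputed every frame; the filter breathes and no time
averaging is applied. Each site's radial reference axis is the (x, y)
center of mass of the oxygen atoms bounding *that* site, not a global
pore axis — for a distorted filter the local ring center is the better
realization of the symmetry axis (a global axis can be emulated by
supplying rigid boundaries).

## Occupancy coding

A particle occupies site k when `z_lower(k) < z ≤ z_upper(k)` (ties on a
divider go to the lower site; any fixed convention prevents double
assignment) and its distance from the site axis is at most 4.0 Å. The
radial cutoff is applied to waters as well as ions; whether that is the
intended convention for waters is genuinely open, so the cutoff is
configurable. Waters are located by their oxygen only. Site multiplicity
is not encoded: two ions in one site still code `K`, as the alphabet
{K, W, C, 0} has no multi-occupancy symbol.

## Ion jumps, events, current

Jump bookkeeping is one-dimensional: each ion is binned by z alone into 8
compartments — intracellular (0), Scav (1), S4 (2), S3 (3), S2 (4),
S1 (5), S0 (6), extracellular (7) — without the radial cutoff, so an ion
grazing the cutoff wall cannot spuriously reset its count. Per frame
pair, the signed level difference of every ion accumulates into J(t);
forward and backward crossings cancel, and one complete permeation
contributes exactly N_b = 7 (configurable). An ion that vanishes
mid-filter (periodic-image artifact) has its contribution frozen until it
reappears in a bulk compartment.

A permeation event fires when an ion arrives in the extracellular
compartment having last come from the intracellular side. Ions already
inside the filter at the first frame carry no history; under the
positive-voltage assumption built into event extraction they are treated
as having entered from the intracellular side, so the initial filter load
is counted when it conducts. When only a state-sequence file is available
(no per-ion coordinates), events are inferred from the jump trace: one
event whenever its running maximum advances by another N_b.

Current is `I = e·J/(N_b·T)` with T the elapsed time between first and
last frame, reported in pA; the sign convention is positive for
intracellular → extracellular flux. Water crossings are counted by the
same compartment logic (for the copermeation ratio) but carry no charge.

## Markov state models

Counting is sliding-window (every (t, t+τ) pair contributes) — standard
MSM practice that maximizes statistics. The lag defaults to 20 ps and
must be an integer multiple of the frame interval. States with no
outgoing counts are pruned (iteratively, with their incoming counts)
rather than closed with self-loops: a probability-1 self-loop would
fabricate an absorbing state and corrupt the stationary distribution.

The process is driven and irreversible, so no detailed-balance constraint
is imposed and eigenvalues may be complex; relaxation times use the
eigenvalue modulus, `t_m = −τ/ln|λ_m|`, with |λ| within 1e−12 of 1
reported as +∞. The stationary distribution is the left λ = 1
eigenvector (real part, negatives clipped at −1e−12, renormalized),
computed only after verifying strong connectivity; a reducible matrix
raises with its communicating classes listed.

The Chapman–Kolmogorov test compares T(kτ) estimated directly from data
with T(τ)^k. The deviation metric is the maximum absolute entrywise
difference — the most conservative scalar summary of a test usually
shown graphically — restricted to states visited at least a configurable
floor of times (default 100), since poorly sampled rows carry no
evidence. Self-transition curves per retained state are returned for
plotting.

Net fluxes `f_ij = T_ij ρ_i − T_ji ρ_j` are computed from the pooled
full-trajectory model, never from reduced cycles.

## Cycles and reduction

Raw cycles span from the last anchor visit strictly before an ion's
crossing to the first anchor visit at or after it — the minimal window in
which the filter leaves its reference occupancy and returns. The anchor
is chosen automatically as the state most often visited on both sides of
a crossing (within the window delimited by neighboring crossings), with
ties preferring the canonical `WKK0KW`; events that never bracket the
anchor count against the coverage fraction.

Reduction keeps the nonrepeating, first-arrived states: scanning forward,
a recurrence of a kept state with **zero net jump advance** since its
first arrival deletes the intervening excursion (a trivial oscillation —
"net" matters, jumps may fluctuate and cancel); a recurrence **with**
jump advance is dropped unless it is the terminal anchor closing the
cycle; consecutive duplicates merge. The scan is idempotent and leaves
interior states unique; the test suite verifies it exhaustively against
an independent rule-rewriting oracle on all anchored sequences of length
≤ 8 over 4 states (with zero and with randomized jump annotations).

Edge probabilities are cycle-conditioned — the fraction of reduced cycles
containing the ordered edge — with normal-approximation binomial 95%
CIs. They are distinct from MSM transition probabilities, and after
reduction the outgoing probabilities of a state sum to at most 1.

## Mean first passage times

A passage opens at an arrival in the source state and ends at the next
occurrence of the target; the next passage starts only after that, so
passages never overlap. By the strong Markov property non-overlapping
passages are independent draws of the first passage time, which makes
both the standard error and the BCa bootstrap (default B = 10 000,
confidence 0.95) valid; overlapping windows would bias neither the mean
nor the intervals' center but would understate uncertainty. A passage is
kept only if fewer than N_b net jumps accrued between its endpoints,
restricting it to a single permeation cycle; the bound is configurable
and can be disabled (it is disabled when validating against the
fundamental-matrix linear-solve oracle, which knows nothing of jumps).
Passages pool across trajectories before bootstrapping. MFPTs are
reported in ns; an undefined MFPT (no qualifying passage) is reported as
missing, never as 0.

## Synthetic generator

The generator is a fixture factory, not an MD engine: no forces,
electrostatics or membrane. The filter is rigid (boundary planes fixed at
[15.5, 12.4, 9.3, 6.2, 3.1, 0.0, −4.0] Å, i.e. 3.1 Å site heights
matching typical carbonyl-ring spacings), and positional jitter
(default σ = 0.3 Å, a realistic sub-Å thermal scale well under half a
site height) is applied to mobile particles only, isolating analysis
correctness from geometry noise.

Direct knock-on follows the dominant dry-filter loop

    WKK0KW → C0K0KW → C0K0KC → C0KKWC → C0KK0C → CK0KKW → WKK0KW

with explicit particle bookkeeping (each loop: one ion enters Scav from
the cavity, one leaves S0 for the extracellular side, a transient water
shuttles Scav↔S4; exactly 7 net ion jumps, no water crossing). Soft
knock-on alternates the `WKWKWK`/`KWKWKW` column with concerted one-site
shifts; two shifts eject one ion and one water (1:1 copermeation) and
again accrue 7 ion jumps. Each loop state is held for a fixed dwell
derived from the requested frame count; moves occur between dwell blocks,
so frame-to-frame level changes stay physical. States, jump counts and
events are recorded from the script itself and are exact by construction;
coordinates (reservoir particles included) can be exported as an
in-memory MDAnalysis Universe or PDB + XTC files for end-to-end tests.

What the generator does *not* emulate — filter breathing, sub-dwell
recrossings, heterogeneous branch structure, ions bypassing the radial
cutoff, finite-temperature disorder beyond Gaussian jitter — bounds what
passing tests show about real trajectories: they certify the bookkeeping
and estimators, not force-field physics.

## Problem sizes and defaults

Chain-recovery and calibration checks use 10⁵-step sequences (multinomial
standard error ≈ 0.01 on transition probabilities, hence the 0.02
acceptance band); MFPT calibration uses 20 random 5-state chains; planted
recovery uses 50 events. Bootstrap B is reducible in configuration for
quick runs. Cross-trajectory uncertainty for currents uses the
t-distribution with n = number of independent trajectories.

## Known limitations

- Exact motif matching only; degenerate or gapped filter sequences need a
  user-supplied pattern.
- Single cation species per run; no Na⁺/Rb⁺/Cs⁺ discrimination, no
  cavity sites below Scav, no water-permeation current.
- No reversible MSM estimators, PCCA coarse-graining or hidden Markov
  models — the target process is explicitly nonequilibrium.
- The jump-trace event route cannot attribute events to specific ions;
  ion-resolved analysis requires coordinates.
- Graph rendering to images is intentionally out of scope; exports are
  GraphML, DOT and JSON.
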