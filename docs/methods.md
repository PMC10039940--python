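# Methods

This note documents the models, estimators and numerical choices behind
`amparkit`, what the synthetic generators do and do not emulate, and the
known limitations.

## Contact persistence

A residue pair is in contact in a frame when at least one heavy atom of
each residue lies **strictly** within the contact cutoff (default 4.0 Å);
hydrogens are never considered. Strict `<` at the boundary is a
measure-zero choice on real coordinates but makes behaviour deterministic
on constructed fixtures. Persistence is the contacting fraction of
analysed frames. Analysis frames are selected by (1) discarding all
frames with time ≤ `exclude_time` (default 100 ns, interpreted against
frame times, not frame counts) as equilibration, and (2) subsampling to
`stride_time` (default 100 ps) using the trajectory's stored frame
interval.

Two evaluation paths exist — a vectorised dense path for small
interfaces and a per-frame k-d-tree path for large ones — with identical
semantics; the test suite holds both to an independent brute-force
double-loop recount, exactly.

Averaging over structurally identical subunit copies uses ordered chain
groups (`[["A","C"], ["B","D"], ["B'","D'"]]`: position *k* of every
group belongs to subunit copy *k*). A pair absent from a copy or a
replicate contributes zero, i.e. the reported fraction is
`sum / (n_replicates × n_copies)`. Absence-as-zero keeps fractions
comparable across interfaces; a contact formed in only one copy is
genuinely half as persistent at the complex level.

Single-structure neighbour counting (`static_neighbor_contacts`) uses a
separate 4.5 Å cutoff and reports, per residue, the number of its heavy
atoms having at least one partner heavy atom within the cutoff — the
"atoms contributing to the interaction" measure used to colour interface
maps.

Centre-of-mass distance series are mass-weighted over all heavy atoms of
each residue by default; a side-chain-only scope (backbone N/CA/C/O/OXT
excluded) is provided because the literature rarely states which scope a
centre-of-mass plot uses. Neither scope is asserted as canonical; the
scope is recorded on the output. Occupancy of a distance series is the
fraction of frames strictly below a caller-supplied cutoff — the
threshold defining "engaged" is not standardised, so it is an explicit
parameter.

## Difference maps and pathways

The difference map reports `delta = P_ligand − P_apo` over the union of
pairs (missing pairs read as zero) and retains a pair only when
`max(P_apo, P_ligand) ≥ persistence_floor` **and**
`|delta| ≥ delta_floor` (both default 0.10). Using the *larger* of the
two persistences for the first floor is a deliberate interpretation of
the dual exclusion rule: it keeps contacts that appear only upon ligand
binding (which are mechanistically the interesting ones) and makes the
retained set identical in either comparison direction, with deltas
negating — an antisymmetry the tests enforce. The comparison refuses maps
with different interfaces or analysis settings; comparing like gating
states (open vs open, resting vs resting) is the caller's responsibility.

Pathway graphs take every pair at or above `edge_threshold` (default
0.50 — "high persistence" is not quantified in the literature, so the
threshold is explicit and recorded in provenance) as an undirected edge
weighted by persistence. Routes are ranked by the widest-path criterion:
maximise the minimum edge weight along the path, breaking ties by fewer
hops and then lexicographic residue order. The ranking is implemented as
a best-first search whose key (−bottleneck, length, path) is monotone
under edge extension, so the first arrival at a target is optimal;
optimality is verified against exhaustive simple-path enumeration on
small random graphs. Up to *k* distinct paths per source–target
combination are enumerated in rank order (expansion is capped on
pathological dense graphs, with a warning). Any supplied interface maps —
including intra-subunit ones — may contribute edges; which maps were used
is recorded.

## Structural comparison

Superposition uses the closed-form SVD (Kabsch) solution with the
reflection branch excluded; atoms are paired by (chain, residue number,
atom name), unpaired atoms dropped with a warning, and selections with
fewer than three non-collinear pairs rejected. RMSD is reported over the
paired selection after the transform. The implementation is cross-checked
against MDAnalysis' superposition in the tests.

Displacement fields report per-residue reference→mobile vectors of a
representative atom (Cα by default) after the caller has aligned the
structures on an anchor selection of their choice — the anchor choice is
scientific, not numerical, and is deliberately left to the caller.

Pore profiles follow the inscribed-sphere idea: at each z along a channel
axis the probe centre is optimised in the plane to maximise
`min_a (|c − x_a| − r_vdW(a))`. Instead of a Monte-Carlo walk the
optimiser is a deterministic pattern search (8-neighbour moves, grid
refinement 1.0 → 0.1 → 0.01 Å, local search started from the axis
point), so profiles are bit-reproducible. Radii are capped at 10 Å
("open pore"). The van der Waals table shipped (C 1.70, N 1.55, O 1.52,
S 1.80, P 1.80 Å; default 1.70 Å) is a standard element table; tools
with different tables will differ by ~0.1 Å in absolute radius, which is
why cross-tool comparisons should use radius *differences*. The axis is
either two explicit points or a principal axis of a selection: the
longest axis for an elongated bundle, or the plane normal
(`axis_pick="plane-normal"`) for a ring of gate residues. Step default
0.25 Å.

`DEFAULT_TMD_SELECTION` ("name CA resid 40-220,506-640,780-824") is an
*approximate* Cα selection of the receptor/TARP transmembrane sector for
LBD-TMD models (TARP transmembrane helices plus receptor pre-M1–M3 and
M4); exact helix boundaries vary between constructs, and RMSD values over
this selection should be read with a ±0.1 Å tolerance.

## Desensitization kinetics

Conventions: inward currents negative; percentages computed on
magnitudes; baseline is the 50 ms pre-pulse mean.

- **Peak.** `detect_peak` returns the raw baseline-subtracted extremum —
  exact on noise-free traces, biased upward by extreme-value selection on
  noisy ones. The noise-robust estimate is `DesensFit.peak_fit`: the
  fitted decay model extrapolated to the response onset, where onset is
  the mid-rise (50%-of-peak) crossing preceding the extremum. The onset
  is the right reference because the raw argmax time jitters by a few
  samples under noise and an exponential extrapolated to a late reference
  is systematically low.
- **Decay fit.** From the first post-peak sample at ≤95% of the peak to
  10 ms before pulse end (the end guard avoids solution-exchange
  artefacts at the valve step), least squares of
  `I_ss + Σ A_i exp(−t/τ_i)` with 1 or 2 components, amplitudes bounded
  non-negative, τ ∈ [0.01 ms, 50 s]. `n_exp="auto"` picks 1 vs 2 by the
  small-sample-corrected Akaike criterion; an explicit `n_exp` always
  overrides, since the appropriate model class is often known per
  construct. Fitted amplitudes are extrapolated back to the response
  onset before computing `τ_w = Σ τ_i A_i / Σ A_i`, so `τ_w` refers to
  the physical peak, not the (arbitrary) fit-window start.
- **Equilibrium.** Steady state is operationalised as the mean of the
  final 50 ms of the pulse; the percentage is reported both from that raw
  mean (vs raw peak) and from the fitted plateau (vs fitted peak),
  because which variant a given lab reports is usually unstated.
- **Resensitization.** The excess steady-state current after
  desensitization: end-of-pulse mean minus the post-peak trough of a 2 ms
  moving-average copy (smoothing is used only to locate the trough, never
  on values entering averages), as % of peak, clamped at zero; a trough
  at the epoch end (monotone decay) reports 0 with a note. When the decay
  tail and the resensitization rise overlap in time this measure
  structurally under-reports the generator's planted fraction by a few
  tenths of a point to ~1 point — a property of the definition, not of
  the estimator.
- **Wash-in time-courses.** Per-sweep τ series are fit with a single
  exponential `plateau + (start − plateau) exp(−t/τ_mod)`; τ_mod is
  reported in seconds (sweeps are seconds apart, so a millisecond-scale
  wash-in constant would be physically meaningless). Direction is NAM if
  plateau < start, PAM if greater, "none" when the fitted span is within
  twice the residual noise.

## Synthetic generators

All generators are pure functions of spec + seed (bit-reproducible).

- **Contact trajectories.** Each declared residue pair switches between a
  bound distance (3.5 Å) and an unbound distance (9 Å) following a
  two-state Markov chain with `p_on = k·p`, `p_off = k·(1−p)`, so the
  stationary occupancy is exactly `p` and `k = p_on + p_off` sets the
  relaxation rate per frame. Distances are realised geometrically (the
  partner residue translated along the pair axis, with small Gaussian
  jitter), and every pseudo-residue carries a hydrogen, so the contact
  detector is exercised end to end on coordinates including hydrogen
  exclusion. The empirical occupancy of a finite chain has standard error
  `sqrt(p(1−p)/ESS)` with `ESS = n(1−λ)/(1+λ)`, `λ = 1−k`; recovery
  tests use a 3-SE band. The generator does not emulate force-field
  physics, solvent, or correlated multi-pair dynamics — passing tests
  show the *statistics* are computed correctly, not that real receptors
  behave like the toy.
- **Current traces.** The recording protocol is fixed at the values used
  for receptor/TARP kinetics work: 2 s glutamate pulses every 5 s,
  20 kHz sampling, −60 mV inward currents; defaults τ_f = 3 ms,
  τ_s = 30 ms, 75% fast fraction and 10% equilibrium current are in the
  range reported for γ8-containing receptors. Noise is white Gaussian;
  real recordings add series-resistance filtering, drift and stimulus
  artefacts that the generator does not model. Resensitization is
  modelled as an additive slow rising exponential — a phenomenological
  "excess steady-state current", deliberately agnostic about mechanism.
- **Pore fixtures.** Rings of carbon pseudo-atoms at ring radius
  `r(z) + r_vdW` realise a prescribed profile; where the wall is steep the
  3D probe also touches neighbouring rings and reads slightly below the
  per-ring radius, so fixtures assert the constriction, not the steep
  flanks.

## Problem sizes

Test and acceptance runs use deliberately small problems chosen to make
the statistics decisive: contact oracles on ≤10 residues × ≤500 frames,
Markov recovery on 4000-frame chains (ESS ≈ 100 at k = 0.05), widest-path
enumeration on ≤12-node graphs (exhaustive enumeration stays exact),
Monte-Carlo kinetics on 50–100 seeded traces. These sizes give 3-SE/95%
criteria real statistical teeth while keeping any single check in seconds.

## Known limitations

- PDB only (no mmCIF); insertion codes rejected; alternate locations
  other than blank/'A' dropped with a warning; multi-model PDB is the
  only trajectory output format besides DCD.
- No hydrogen-bond geometry (donor–acceptor angles) or water-mediated
  bridge detection; persistence is a pure distance criterion.
- Difference maps are descriptive; no inferential statistics are
  attached to deltas.
- The pore probe is a rigid-sphere measure; no conductance estimation.
- Desensitization fits assume a clean pulse epoch; stacked drug
  applications within one epoch are out of scope.
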