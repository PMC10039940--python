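# amparkit

Analysis toolkit for studying how auxiliary-subunit-targeted modulators
act on AMPA-type glutamate receptors (AMPARs). AMPARs in the hippocampus
assemble with the auxiliary subunit TARP γ8, and γ8-selective negative
allosteric modulators (NAMs) are an emerging class of anti-epileptic
drugs. Characterising their mechanism combines three kinds of evidence —
molecular-dynamics (MD) simulations of receptor/TARP complexes, rigid-body
comparison of cryo-EM structures, and whole-cell patch-clamp kinetics —
and `amparkit` implements the computational analyses for all three as a
tested, reusable library:

- **Contact persistence** — for residues *i*, *j* and trajectory frames
  *t*, the fraction of frames in which any heavy-atom pair is strictly
  within a cutoff (4.0 Å by default):
  `P(i,j) = (1/T) Σ_t 1[min_{a∈i,b∈j} |x_a(t) − x_b(t)| < d_c]`,
  computed after discarding an initial equilibration stretch (100 ns
  default), subsampling to an analysis stride (100 ps default), and
  averaging over structurally identical subunit copies and repeat runs.
- **Difference maps** — per-pair persistence changes between conditions
  (e.g. apo vs ligand-bound), retaining a pair only when
  `max(P_apo, P_lig) ≥ 0.10` **and** `|P_lig − P_apo| ≥ 0.10`
  (both floors configurable), so noise contacts and unchanged contacts
  drop out while ligand-gained contacts survive.
- **Allosteric pathways** — high-persistence contacts form an undirected
  residue graph; candidate routes from a ligand site to the channel gate
  are ranked by the widest-path (maximum-bottleneck) criterion:
  maximise `min_{(u,v)∈path} P(u,v)`.
- **Structural comparison** — closed-form Kabsch superposition and RMSD,
  per-residue displacement-vector fields between conformational states,
  and deterministic sphere-probe pore-radius profiles
  `r(z) = max_c min_a (|c − x_a| − r_vdW(a))` along a channel axis.
- **Desensitization kinetics** — peak detection, decay fits
  `I(t) = I_ss + Σ A_i exp(−t/τ_i)` from the 95%-of-peak point, the
  amplitude-weighted time constant
  `τ_w = τ_f A_f/(A_f+A_s) + τ_s A_s/(A_f+A_s)`, equilibrium and
  resensitization percentages, modulator wash-in time-courses, and
  group summaries (mean ± SEM).
- **Synthetic ground truth** — generators for multi-chain trajectories
  with two-state Markov contact dynamics, for glutamate-pulse current
  traces (2 s pulses every 5 s, 20 kHz sampling, bi-exponential
  desensitization, steady-state and resensitization components, Gaussian
  noise), and for pore fixtures with analytic radii — so every analysis
  stage is testable without external data.

The audience is structural/computational biophysicists and
electrophysiologists who want these measures reproducible and unit-tested
rather than embedded in one-off scripts.

## Worked example

`examples/desensitization_kinetics.py` simulates one noisy glutamate
pulse (inward current, −1000 pA peak, τ_f = 3 ms, τ_s = 30 ms, 75% fast,
10% equilibrium current, 2% noise) and fits it:

```
peak current         -993.2 pA (raw) /    -993.2 pA (fitted)
tau_fast               3.01 ms   (planted 3.00)
tau_slow              30.15 ms   (planted 30.00)
weighted tau_w         9.83 ms   (planted 0.75*3 + 0.25*30 = 9.75)
equilibrium           10.02 %    (planted 10.0)
resensitization        0.00 %    (planted 0)
```

The fitted τ_w lands within 1% of the ground-truth 9.75 ms at 2% noise.
The other example scripts (`contact_persistence.py`,
`difference_map_and_pathway.py`, `pore_profile.py`, `superposition.py`)
each build a small synthetic input, run one analysis stage and print the
result next to the planted truth.

A thin CLI mirrors the library for shell pipelines
(`amparkit simulate-traj | contacts | diffmap | pathway | distances |
rmsd | pore | ephys-fit | summarize`); every run writes a manifest with
the resolved configuration, input digests and seed.

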