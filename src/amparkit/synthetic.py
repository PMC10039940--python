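"""Synthetic trajectories, current traces and pore fixtures with known
ground truth.

The trajectory generator realises residue-pair contact dynamics as a
two-state (bound/unbound) Markov chain on the pair's inter-atom distance,
so every downstream contact statistic can be checked against the planted
stationary occupancy. The current-trace generator emulates the whole-cell
recording protocol used for ligand-gated channel kinetics: glutamate
applied in 2 s pulses every 5 s, sampled at 20 kHz, with bi-exponential
desensitization, a steady-state (equilibrium) component, an optional slow
resensitization creep and additive Gaussian noise. Neither generator aims
at physical force-field realism; they are measurement test-beds.

All generators are pure functions of their spec plus seed.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .system import MolecularSystem
from .ephys import CurrentTrace

__all__ = [
    "PairDynamicsSpec",
    "TraceSpec",
    "simulate_contact_trajectory",
    "simulate_current_trace",
    "simulate_modulation_timecourse",
    "make_toy_pore",
    "markov_stationary_se",
]


@dataclass(frozen=True)
class PairDynamicsSpec:
    """Contact dynamics of one residue pair.

    ``pair`` holds two ``(chain_id, residue_number)`` identities. The pair
    switches between a bound state (closest-atom distance ``d_bound``) and
    an unbound state (``d_unbound``) following a two-state Markov chain
    with stationary contact occupancy ``stationary_p``. ``k_switch`` is
    the total per-frame relaxation rate (p_on + p_off); Gaussian jitter of
    sd ``jitter_sd`` Å is added to the realised distance.
    """

    pair: tuple[tuple[str, int], tuple[str, int]]
    stationary_p: float = 0.5
    k_switch: float = 0.05
    d_bound: float = 3.5
    d_unbound: float = 9.0
    jitter_sd: float = 0.05

    def transition_probs(self) -> tuple[float, float]:
        """(p_on, p_off) per frame; stationary distribution equals
        ``stationary_p`` by construction."""
        p_on = self.k_switch * self.stationary_p
        p_off = self.k_switch * (1.0 - self.stationary_p)
        if not (0.0 <= p_on <= 1.0 and 0.0 <= p_off <= 1.0):
            raise ParameterError(
                f"k_switch={self.k_switch} with stationary_p="
                f"{self.stationary_p} implies transition probabilities "
                f"outside [0, 1]")
        return p_on, p_off

    def validate(self, contact_cutoff: float = 4.0) -> None:
        if not 0.0 <= self.stationary_p <= 1.0:
            raise ParameterError(f"stationary_p={self.stationary_p} outside [0, 1]")
        if not self.d_bound < contact_cutoff < self.d_unbound:
            raise ParameterError(
                f"need d_bound < cutoff < d_unbound, got {self.d_bound} / "
                f"{contact_cutoff} / {self.d_unbound}")
        self.transition_probs()


def markov_stationary_se(p: float, k_switch: float, n_frames: int) -> float:
    """Standard error of the empirical occupancy of the two-state chain.

    The chain's lag-1 autocorrelation is ``lambda = 1 - k_switch``; the
    effective sample size is ``n (1 - lambda) / (1 + lambda)``.
    """
    lam = 1.0 - k_switch
    ess = n_frames * (1.0 - lam) / (1.0 + lam)
    return math.sqrt(max(p * (1.0 - p), 1e-12) / max(ess, 1.0))


def _simulate_states(spec: PairDynamicsSpec, n_frames: int,
                     rng: np.random.Generator) -> np.ndarray:
    p_on, p_off = spec.transition_probs()
    states = np.empty(n_frames, dtype=bool)
    u = rng.random(n_frames)
    states[0] = u[0] < spec.stationary_p
    for k in range(1, n_frames):
        if states[k - 1]:
            states[k] = u[k] >= p_off
        else:
            states[k] = u[k] < p_on
    return states


def simulate_contact_trajectory(specs: Sequence[PairDynamicsSpec],
                                n_frames: int = 1000,
                                frame_dt: float = 100.0,
                                seed: int = 0,
                                contact_cutoff: float = 4.0,
                                ) -> tuple[MolecularSystem, dict]:
    """Generate a toy multi-chain trajectory realising the requested
    contact dynamics geometrically.

    Each declared chain receives at least two pseudo-residues of three
    atoms (two heavy carbons plus one hydrogen, so hydrogen exclusion is
    exercised end to end). Residues live on a 30 Å lattice; for each
    specified pair the partner residue is displaced along the pair axis so
    that the closest heavy-atom distance follows the planted two-state
    chain; unspecified pairs stay far beyond twice the cutoff.

    Returns the system and a ground-truth dict mapping each spec's pair to
    its boolean per-frame contact states. ``frame_dt`` is in ps.
    """
    if n_frames < 2:
        raise ParameterError("n_frames must be >= 2")
    residues_in_specs: set[tuple[str, int]] = set()
    for spec in specs:
        spec.validate(contact_cutoff)
        for res in spec.pair:
            if res in residues_in_specs:
                raise ParameterError(
                    f"residue {res} appears in more than one pair spec")
            residues_in_specs.add(res)

    # topology: declared residues plus a filler so every chain has >= 2
    chains: dict[str, list[int]] = {}
    for res in sorted(residues_in_specs):
        chains.setdefault(res[0], []).append(res[1])
    if not chains:
        raise ParameterError("no pairs specified")
    for cid, resids in chains.items():
        if len(resids) < 2:
            filler = max(resids) + 1
            while (cid, filler) in residues_in_specs:
                filler += 1
            resids.append(filler)
    # local atom geometry of one pseudo-residue: CA at the anchor, CB
    # 1.5 Å away in +y, HB a hydrogen next to CB
    local = {"CA": np.array([0.0, 0.0, 0.0]),
             "CB": np.array([0.0, 1.5, 0.0]),
             "HB": np.array([0.0, 1.5, 1.0])}

    rows = []
    anchors: dict[tuple[str, int], np.ndarray] = {}
    lattice = 30.0
    site = 0
    paired_b = {spec.pair[1]: spec for spec in specs}
    for cid in sorted(chains):
        for resid in sorted(chains[cid]):
            res = (cid, resid)
            if res in paired_b:
                # partner placed relative to its mate below
                continue
            anchors[res] = np.array([lattice * (site % 7),
                                     lattice * (site // 7), 0.0])
            site += 1
    for spec in specs:
        res_a, res_b = spec.pair
        # partner anchored along +x from the mate; distance varies per frame
        anchors[res_b] = anchors[res_a] + np.array([spec.d_unbound, 0.0, 0.0])

    order: list[tuple[str, int]] = []
    atom_id = 0
    for cid in sorted(chains):
        for resid in sorted(chains[cid]):
            order.append((cid, resid))
            for name, off in local.items():
                rows.append(dict(atom_id=atom_id, atom_name=name,
                                 element="H" if name.startswith("H") else "C",
                                 residue_number=resid, residue_name="ALA",
                                 chain_id=cid,
                                 is_heavy=not name.startswith("H"),
                                 is_hetero=False))
                atom_id += 1
    atoms = pd.DataFrame.from_records(rows)

    rng = np.random.default_rng(seed)
    base = np.empty((len(order) * 3, 3))
    for ri, res in enumerate(order):
        for k, off in enumerate(local.values()):
            base[ri * 3 + k] = anchors[res] + off
    frames = np.repeat(base[None, :, :], n_frames, axis=0)

    truth: dict[tuple, np.ndarray] = {}
    res_pos = {res: i for i, res in enumerate(order)}
    for spec in specs:
        states = _simulate_states(spec, n_frames, rng)
        jitter = rng.normal(0.0, spec.jitter_sd, size=n_frames)
        dist = np.where(states, spec.d_bound, spec.d_unbound) + jitter
        bi = res_pos[spec.pair[1]] * 3
        # translate the whole partner residue along +x so that its CA sits
        # at the prescribed closest-atom distance from the mate's CA
        ax = anchors[spec.pair[0]][0]
        for k in range(3):
            frames[:, bi + k, 0] = ax + dist + base[bi + k, 0] - base[bi, 0]
        truth[spec.pair] = states
    times = np.arange(n_frames) * frame_dt / 1000.0  # ns
    system = MolecularSystem(atoms=atoms, frames=frames, frame_times=times)
    return system, truth


@dataclass(frozen=True)
class TraceSpec:
    """Parameters of a synthetic whole-cell current trace.

    Times in s except the kinetic time constants (ms); currents in pA
    (negative ``peak_amp`` = inward). During each pulse the current is

    ``peak_amp * [eq + f_f (1-eq-res) e^(-t/tau_f) + (1-f_f)(1-eq-res)
    e^(-t/tau_s) + res (1 - e^(-t/tau_resens))]``

    plus Gaussian noise; zero (plus noise) between pulses.
    """

    pulse_start: float = 0.2
    pulse_len: float = 2.0
    sweep_interval: float = 5.0
    n_sweeps: int = 1
    peak_amp: float = -1000.0
    tau_f: float = 3.0
    tau_s: float = 30.0
    frac_fast: float = 0.75
    equilibrium_frac: float = 0.10
    resens_frac: float = 0.0
    tau_resens: float = 300.0
    noise_sd: float = 0.0
    sample_rate: float = 20_000.0
    seed: int = 0

    def validate(self) -> None:
        if not self.tau_f < self.tau_s:
            raise ParameterError("tau_f must be < tau_s")
        if not 0.0 <= self.frac_fast <= 1.0:
            raise ParameterError("frac_fast outside [0, 1]")
        if self.equilibrium_frac < 0 or self.resens_frac < 0:
            raise ParameterError("fractions must be >= 0")
        if self.equilibrium_frac + self.resens_frac > 1.0:
            raise ParameterError("equilibrium_frac + resens_frac must be <= 1")
        if self.pulse_start + self.pulse_len > self.sweep_interval:
            raise ParameterError("pulse does not fit in the sweep interval")


def pulse_waveform(spec: TraceSpec, t_in_pulse: np.ndarray) -> np.ndarray:
    """Noise-free in-pulse current for times (s) measured from pulse onset."""
    tf, ts_, tr = (spec.tau_f / 1e3, spec.tau_s / 1e3, spec.tau_resens / 1e3)
    decay_amp = 1.0 - spec.equilibrium_frac - spec.resens_frac
    return spec.peak_amp * (
        spec.equilibrium_frac
        + spec.frac_fast * decay_amp * np.exp(-t_in_pulse / tf)
        + (1.0 - spec.frac_fast) * decay_amp * np.exp(-t_in_pulse / ts_)
        + spec.resens_frac * (1.0 - np.exp(-t_in_pulse / tr)))


def simulate_current_trace(spec: TraceSpec) -> CurrentTrace:
    """Generate a stimulus-annotated current trace from ``spec``."""
    spec.validate()
    n = int(round(spec.sweep_interval * spec.n_sweeps * spec.sample_rate))
    times = np.arange(n) / spec.sample_rate
    currents = np.zeros(n)
    epochs = []
    for k in range(spec.n_sweeps):
        t0 = k * spec.sweep_interval + spec.pulse_start
        t1 = t0 + spec.pulse_len
        mask = (times >= t0) & (times < t1)
        currents[mask] = pulse_waveform(spec, times[mask] - t0)
        epochs.append((t0, t1))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        currents = currents + rng.normal(0.0, spec.noise_sd, size=n)
    return CurrentTrace(times=times, currents=currents, epochs=epochs,
                        sample_rate=spec.sample_rate,
                        metadata=dict(holding_mV=-60.0, agonist="10 mM glutamate",
                                      synthetic=True, seed=spec.seed))


def simulate_modulation_timecourse(tau_start: float, tau_plateau: float,
                                   tau_mod: float, sweep_interval: float = 5.0,
                                   n_sweeps: int = 40, noise_sd: float = 0.0,
                                   seed: int = 0) -> pd.DataFrame:
    """Sweep-indexed desensitization-τ series during modulator wash-in.

    ``tau_start``/``tau_plateau`` are per-sweep desensitization time
    constants (ms); ``tau_mod`` (s) is the wash-in time constant of the
    modulatory effect: tau(k) = plateau + (start - plateau)
    exp(-k * sweep_interval / tau_mod) + noise.
    """
    if n_sweeps < 3:
        raise ParameterError("n_sweeps must be >= 3")
    k = np.arange(n_sweeps)
    t = k * sweep_interval
    tau = tau_plateau + (tau_start - tau_plateau) * np.exp(-t / tau_mod)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        tau = tau + rng.normal(0.0, noise_sd, size=n_sweeps)
    return pd.DataFrame(dict(sweep=k, time_s=t, tau_ms=tau))


def make_toy_pore(radius_profile: Sequence[tuple[float, float]],
                  wall_atom_spacing: float = 1.0,
                  vdw_radius: float = 1.70) -> MolecularSystem:
    """Rings of carbon pseudo-atoms realising a prescribed pore profile.

    At each ``(z, r)`` a ring of radius ``r + vdw_radius`` is built, so the
    maximal inscribed probe sphere at that z has radius ≈ r. Radii must
    exceed the wall atom's van der Waals radius for the fixture to be
    meaningful as an enclosed pore.
    """
    rows = []
    coords = []
    atom_id = 0
    for ri, (z, r) in enumerate(radius_profile):
        if r <= 0:
            raise ParameterError(f"non-positive pore radius {r} at z={z}")
        ring_r = r + vdw_radius
        n_ring = max(8, int(math.ceil(2 * math.pi * ring_r / wall_atom_spacing)))
        for k in range(n_ring):
            ang = 2 * math.pi * k / n_ring
            coords.append((ring_r * math.cos(ang), ring_r * math.sin(ang), z))
            rows.append(dict(atom_id=atom_id, atom_name=f"C{k + 1}",
                             element="C", residue_number=ri + 1,
                             residue_name="RNG", chain_id="P",
                             is_heavy=True, is_hetero=False))
            atom_id += 1
    atoms = pd.DataFrame.from_records(rows)
    return MolecularSystem(atoms=atoms, frames=np.asarray(coords)[None, :, :])
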