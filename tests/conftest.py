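"""Shared fixtures: hand-built systems, PDB text helpers and independent
brute-force oracles used to cross-check the package's optimized paths."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from amparkit.system import MolecularSystem


def build_system(atom_specs, frames, frame_times=()):
    """Construct a MolecularSystem from simple tuples.

    ``atom_specs``: iterable of (atom_name, element, resid, resname, chain);
    ``frames``: (n_frames, n_atoms, 3) array-like.
    """
    rows = []
    for i, (name, element, resid, resname, chain) in enumerate(atom_specs):
        rows.append(dict(atom_id=i, atom_name=name, element=element,
                         residue_number=resid, residue_name=resname,
                         chain_id=chain, is_heavy=element not in ("H", "D"),
                         is_hetero=False))
    return MolecularSystem(atoms=pd.DataFrame.from_records(rows),
                           frames=np.asarray(frames, dtype=float),
                           frame_times=np.asarray(frame_times, dtype=float))


def pdb_atom_line(serial, name, resname, chain, resid, x, y, z,
                  element="", record="ATOM", altloc=" ", icode=" "):
    """A correctly column-aligned PDB coordinate record."""
    name_f = f" {name:<3s}" if len(name) < 4 else f"{name:<4s}"
    return (f"{record:<6s}{serial:>5d} {name_f}{altloc}{resname:>3s} "
            f"{chain:1s}{resid:>4d}{icode}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{element:>2s}\n")


def random_toy_system(rng, max_residues=10, max_frames=500,
                      atoms_per_residue=2, box=12.0, with_hydrogens=True):
    """A random multi-chain system for oracle sweeps: residues split over
    chains A/B, coordinates random-walking between frames."""
    n_res = int(rng.integers(2, max_residues + 1))
    n_frames = (1 if max_frames == 1
                else int(rng.integers(2, max_frames + 1)))
    specs = []
    for r in range(n_res):
        chain = "A" if r < (n_res + 1) // 2 else "B"
        for a in range(atoms_per_residue):
            specs.append((f"C{a + 1}", "C", r + 1, "ALA", chain))
        if with_hydrogens:
            specs.append((f"H{1}", "H", r + 1, "ALA", chain))
    n_atoms = len(specs)
    start = rng.uniform(0, box, size=(n_atoms, 3))
    steps = rng.normal(0, 0.8, size=(n_frames - 1, n_atoms, 3))
    frames = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    times = np.arange(n_frames) * 0.1  # ns
    return build_system(specs, frames, times)


def brute_force_contacts(system, chain_a, chain_b, cutoff):
    """Independent double-loop contact oracle: per frame, the set of
    residue pairs (one per chain) with any heavy-atom distance < cutoff."""
    atoms = system.atoms
    chain = atoms.chain_id.to_numpy()
    resid = atoms.residue_number.to_numpy()
    resname = atoms.residue_name.to_numpy()
    heavy = atoms.is_heavy.to_numpy()

    def residue_index(which):
        residues = sorted(set(
            (chain[i], int(resid[i]), resname[i])
            for i in range(len(atoms)) if chain[i] == which))
        idx = {r: [i for i in range(len(atoms))
                   if chain[i] == r[0] and resid[i] == r[1] and heavy[i]]
               for r in residues}
        return residues, idx

    residues_a, idx_a = residue_index(chain_a)
    residues_b, idx_b = residue_index(chain_b)
    per_frame = []
    for f in range(system.n_frames):
        coords = system.frames[f]
        found = set()
        for ra in residues_a:
            for rb in residues_b:
                hit = False
                for i in idx_a[ra]:
                    for j in idx_b[rb]:
                        if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                            hit = True
                            break
                    if hit:
                        break
                if hit:
                    found.add((ra, rb))
        per_frame.append(found)
    return per_frame


@pytest.fixture
def rng():
    return np.random.default_rng(20230325)
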