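"""Residue-contact statistics over MD trajectories.

A residue pair is "in contact" in a frame when at least one heavy atom of
each residue lies strictly within a distance cutoff (4.0 Å by default;
hydrogens are never considered). Contact persistence is the fraction of
analysed frames in which a pair is in contact, computed after discarding an
initial equilibration stretch and subsampling to the analysis stride, and
optionally averaged over structurally identical subunit copies and repeat
simulations.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .errors import (CoverageError, MixingError, SelectionError)
from .system import (BACKBONE_NAMES, EquivalenceMap, MolecularSystem,
                     ResidueKey, RunConfig, Selection)

__all__ = [
    "ContactMap",
    "DistanceSeries",
    "frame_contacts",
    "contact_persistence",
    "average_maps",
    "static_neighbor_contacts",
    "com_distance_series",
    "occupancy",
    "contact_map_to_table",
    "contact_map_from_table",
]

PairKey = tuple[ResidueKey, ResidueKey]

# above this many atom-pair combinations per frame, switch from the
# vectorised dense evaluation to a KD-tree; both give identical results
_DENSE_PAIR_LIMIT = 250_000


@dataclass
class ContactMap:
    """Residue-pair persistence fractions for one interface/condition."""

    interface: tuple[str, str]
    entries: dict[PairKey, float]
    n_frames_used: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for pair, frac in self.entries.items():
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"persistence {frac} for {pair} outside [0, 1]")

    def get(self, res_a: ResidueKey, res_b: ResidueKey) -> float:
        """Symmetric lookup; absent pairs read as 0."""
        return self.entries.get((res_a, res_b),
                                self.entries.get((res_b, res_a), 0.0))


@dataclass
class DistanceSeries:
    """Per-frame distance between two residue centres of mass."""

    pair: tuple[ResidueKey, ResidueKey]
    times: np.ndarray  # ns
    distances: np.ndarray  # Å
    com_scope: str = "all-heavy"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.distances = np.asarray(self.distances, dtype=float)
        if self.times.shape != self.distances.shape:
            raise ValueError("times and distances differ in length")
        if self.distances.size and self.distances.min() <= 0:
            raise ValueError("non-positive distance in series")


def _selection_atoms(system: MolecularSystem, sel: Selection | str,
                     heavy: bool = True) -> np.ndarray:
    idx = system.select(sel)
    if heavy:
        idx = idx[system.atoms.is_heavy.to_numpy()[idx]]
    if idx.size == 0:
        label = sel if isinstance(sel, str) else sel.label or repr(sel)
        raise SelectionError(f"selection {label!r} matches no heavy atoms")
    return idx


def _check_disjoint(system: MolecularSystem, idx_a: np.ndarray,
                    idx_b: np.ndarray) -> None:
    keys = system.atom_residue_keys()
    res_a = {keys[i] for i in idx_a}
    res_b = {keys[i] for i in idx_b}
    shared = res_a & res_b
    if shared:
        raise SelectionError(
            f"selections share residues (must be residue-disjoint): "
            f"{sorted(shared)[:3]}{'...' if len(shared) > 3 else ''}")


def _pair_min_distances(coords: np.ndarray, idx_a: np.ndarray,
                        idx_b: np.ndarray, res_idx_a: np.ndarray,
                        res_idx_b: np.ndarray, n_ra: int, n_rb: int,
                        cutoff: float,
                        method: str) -> set[tuple[int, int]]:
    """Residue-index pairs with any inter-atom distance strictly < cutoff."""
    if method == "brute" or (method == "auto"
                             and idx_a.size * idx_b.size <= _DENSE_PAIR_LIMIT):
        d = np.linalg.norm(coords[idx_a][:, None, :] - coords[idx_b][None, :, :],
                           axis=-1)
        ai, bi = np.nonzero(d < cutoff)
        return set(zip(res_idx_a[ai].tolist(), res_idx_b[bi].tolist()))
    tree_a = cKDTree(coords[idx_a])
    tree_b = cKDTree(coords[idx_b])
    sparse = tree_a.sparse_distance_matrix(tree_b, max_distance=cutoff,
                                           output_type="coo_matrix")
    mask = sparse.data < cutoff  # strict inequality at the boundary
    return set(zip(res_idx_a[sparse.row[mask]].tolist(),
                   res_idx_b[sparse.col[mask]].tolist()))


def _resolve_interface(system: MolecularSystem,
                       selection_a: Selection | str,
                       selection_b: Selection | str):
    """Heavy-atom indices plus residue grouping for a residue-disjoint
    selection pair."""
    idx_a = _selection_atoms(system, selection_a)
    idx_b = _selection_atoms(system, selection_b)
    _check_disjoint(system, idx_a, idx_b)
    keys = system.atom_residue_keys()

    def group(idx: np.ndarray):
        residues: list[ResidueKey] = []
        seen: dict[ResidueKey, int] = {}
        res_idx = np.empty(idx.size, dtype=int)
        for pos, i in enumerate(idx):
            k = keys[i]
            if k not in seen:
                seen[k] = len(residues)
                residues.append(k)
            res_idx[pos] = seen[k]
        return residues, res_idx

    ra, res_idx_a = group(idx_a)
    rb, res_idx_b = group(idx_b)
    return idx_a, idx_b, ra, rb, res_idx_a, res_idx_b


def frame_contacts(system: MolecularSystem, frame: int,
                   selection_a: Selection | str, selection_b: Selection | str,
                   cutoff: float = 4.0,
                   method: Literal["auto", "brute", "kdtree"] = "auto",
                   ) -> set[PairKey]:
    """Residue pairs of two disjoint selections in contact in one frame."""
    idx_a, idx_b, ra, rb, res_idx_a, res_idx_b = _resolve_interface(
        system, selection_a, selection_b)
    pairs = _pair_min_distances(system.frames[frame], idx_a, idx_b,
                                res_idx_a, res_idx_b, len(ra), len(rb),
                                cutoff, method)
    return {(ra[i], rb[j]) for i, j in pairs}


def _analysis_frames(system: MolecularSystem, cfg: RunConfig) -> np.ndarray:
    """Frame indices retained after equilibration exclusion and striding."""
    n = system.n_frames
    if cfg.exclude_time > 0:
        if system.frame_times.size == 0:
            raise CoverageError(
                "exclude_time > 0 requires frame time metadata")
        if system.frame_times.max() <= cfg.exclude_time:
            raise CoverageError(
                f"trajectory ends at {system.frame_times.max():g} ns, within "
                f"the excluded first {cfg.exclude_time:g} ns")
        kept = np.flatnonzero(system.frame_times > cfg.exclude_time)
    else:
        kept = np.arange(n)
    if system.frame_times.size >= 2:
        native_ps = float(np.median(np.diff(system.frame_times))) * 1000.0
        stride = max(1, int(round(cfg.stride_time / native_ps)))
    else:
        stride = 1
    return kept[::stride]


def contact_persistence(system: MolecularSystem,
                        selection_a: Selection | str,
                        selection_b: Selection | str,
                        cfg: RunConfig | None = None,
                        method: Literal["auto", "brute", "kdtree"] = "auto",
                        interface: tuple[str, str] | None = None,
                        ) -> ContactMap:
    """Fraction of analysed frames each residue pair spends in contact.

    Frames within the first ``cfg.exclude_time`` ns are discarded and the
    rest strided to ``cfg.stride_time`` ps. Pairs never in contact are
    omitted from the map.
    """
    cfg = cfg or RunConfig()
    frames = _analysis_frames(system, cfg)
    idx_a, idx_b, ra, rb, res_idx_a, res_idx_b = _resolve_interface(
        system, selection_a, selection_b)
    n_used = len(frames)
    counts: dict[PairKey, int] = {}
    if method != "kdtree" and idx_a.size * idx_b.size <= _DENSE_PAIR_LIMIT:
        # vectorised over frame chunks; identical semantics (strict <) to
        # the per-frame route
        count_mat = np.zeros((len(ra), len(rb)), dtype=int)
        chunk = max(1, int(2_000_000 // max(1, idx_a.size * idx_b.size)))
        for start in range(0, n_used, chunk):
            sel = frames[start:start + chunk]
            ca = system.frames[sel][:, idx_a, :]
            cb = system.frames[sel][:, idx_b, :]
            below = (np.linalg.norm(ca[:, :, None, :] - cb[:, None, :, :],
                                    axis=-1) < cfg.contact_cutoff)
            for i in range(len(ra)):
                bi = below[:, res_idx_a == i, :]
                for j in range(len(rb)):
                    c = int(bi[:, :, res_idx_b == j].any(axis=(1, 2)).sum())
                    if c:
                        count_mat[i, j] += c
        for i in range(len(ra)):
            for j in range(len(rb)):
                if count_mat[i, j]:
                    counts[(ra[i], rb[j])] = int(count_mat[i, j])
    else:
        for fi in frames:
            pairs = _pair_min_distances(system.frames[int(fi)], idx_a, idx_b,
                                        res_idx_a, res_idx_b, len(ra), len(rb),
                                        cfg.contact_cutoff, method)
            for i, j in pairs:
                counts[(ra[i], rb[j])] = counts.get((ra[i], rb[j]), 0) + 1
    entries = {pair: c / n_used for pair, c in counts.items()}
    if interface is None:
        la = selection_a if isinstance(selection_a, str) else selection_a.label
        lb = selection_b if isinstance(selection_b, str) else selection_b.label
        interface = (la, lb)
    return ContactMap(
        interface=interface, entries=entries, n_frames_used=n_used,
        provenance=dict(cutoff=cfg.contact_cutoff,
                        exclude_time=cfg.exclude_time,
                        stride_time=cfg.stride_time,
                        averaged_over=[]))


_PROVENANCE_KEYS = ("cutoff", "exclude_time", "stride_time")


def average_maps(maps: Sequence[ContactMap], equiv: EquivalenceMap,
                 ) -> ContactMap:
    """Average persistence over replicate maps and equivalent subunit copies.

    Pairs are identified across copies by mapping each chain to its group
    representative; a pair absent from a copy or replicate contributes zero,
    so the output fraction is ``sum / (n_replicates * n_copies)``.
    """
    if not maps:
        raise MixingError("no maps to average")
    ref = {k: maps[0].provenance.get(k) for k in _PROVENANCE_KEYS}
    for m in maps[1:]:
        cur = {k: m.provenance.get(k) for k in _PROVENANCE_KEYS}
        if cur != ref:
            raise MixingError(
                f"inconsistent provenance: {cur} vs {ref}")

    def canon(res: ResidueKey) -> ResidueKey:
        return (equiv.representative(res[0]), res[1], res[2])

    sums: dict[PairKey, float] = {}
    copies: dict[PairKey, int] = {}
    for m in maps:
        for (res_a, res_b), frac in m.entries.items():
            pair = (canon(res_a), canon(res_b))
            n_cop = max(equiv.n_copies(res_a[0]), equiv.n_copies(res_b[0]))
            sums[pair] = sums.get(pair, 0.0) + frac
            copies[pair] = max(copies.get(pair, 1), n_cop)
    n_rep = len(maps)
    entries = {pair: s / (n_rep * copies[pair]) for pair, s in sums.items()}
    prov = dict(maps[0].provenance)
    prov["averaged_over"] = dict(
        replicates=equiv.replicate_ids or [f"map{i}" for i in range(n_rep)],
        subunit_groups=[list(g) for g in equiv.groups])
    return ContactMap(interface=maps[0].interface, entries=entries,
                      n_frames_used=maps[0].n_frames_used, provenance=prov)


def static_neighbor_contacts(system: MolecularSystem,
                             selection_a: Selection | str,
                             selection_b: Selection | str,
                             cutoff: float = 4.5,
                             frame: int = 0) -> dict[ResidueKey, int]:
    """Per-residue count of selection-A heavy atoms with at least one
    selection-B heavy atom strictly within ``cutoff`` (single structure).

    Residues with no contacting atoms are omitted (count 0 not reported).
    """
    idx_a = _selection_atoms(system, selection_a)
    idx_b = _selection_atoms(system, selection_b)
    _check_disjoint(system, idx_a, idx_b)
    coords = system.frames[frame]
    tree_b = cKDTree(coords[idx_b])
    dists, _ = tree_b.query(coords[idx_a], k=1)
    keys = system.atom_residue_keys()
    counts: dict[ResidueKey, int] = {}
    for ai, d in zip(idx_a, dists):
        if d < cutoff:
            k = keys[ai]
            counts[k] = counts.get(k, 0) + 1
    return counts


def com_distance_series(system: MolecularSystem,
                        residue_a: tuple[str, int],
                        residue_b: tuple[str, int],
                        com_scope: Literal["all-heavy", "side-chain-heavy"] = "all-heavy",
                        mass_weighted: bool = True) -> DistanceSeries:
    """Per-frame distance between the centres of mass of two residues.

    ``com_scope`` selects all heavy atoms of each residue (default) or only
    side-chain heavy atoms (backbone N/CA/C/O/OXT excluded); hydrogens are
    never included. Centres are mass-weighted by default.
    """
    def scope_idx(chain: str, resid: int) -> np.ndarray:
        idx = system.residue_atoms(chain, resid)
        heavy = system.atoms.is_heavy.to_numpy()[idx]
        idx = idx[heavy]
        if com_scope == "side-chain-heavy":
            names = system.atoms.atom_name.to_numpy()[idx]
            keep = ~np.isin(names, list(BACKBONE_NAMES))
            if keep.any():  # glycine has no side-chain heavy atoms: keep all
                idx = idx[keep]
        if idx.size == 0:
            raise SelectionError(
                f"residue {chain}:{resid} has no atoms in scope {com_scope}")
        return idx

    ia = scope_idx(*residue_a)
    ib = scope_idx(*residue_b)
    masses = system.masses()
    wa = masses[ia] if mass_weighted else np.ones(ia.size)
    wb = masses[ib] if mass_weighted else np.ones(ib.size)
    com_a = np.einsum("fij,i->fj", system.frames[:, ia, :], wa) / wa.sum()
    com_b = np.einsum("fij,i->fj", system.frames[:, ib, :], wb) / wb.sum()
    dists = np.linalg.norm(com_a - com_b, axis=1)
    times = (system.frame_times if system.frame_times.size
             else np.arange(system.n_frames, dtype=float))
    keys = system.atom_residue_keys()
    return DistanceSeries(pair=(keys[ia[0]], keys[ib[0]]), times=times,
                          distances=dists, com_scope=com_scope)


def occupancy(series: DistanceSeries, cutoff: float) -> float:
    """Fraction of frames with distance strictly below ``cutoff``."""
    if series.distances.size == 0:
        raise ValueError("empty distance series")
    return float(np.mean(series.distances < cutoff))


def contact_map_to_table(cmap: ContactMap) -> pd.DataFrame:
    rows = []
    for (ra, rb), frac in cmap.entries.items():
        rows.append(dict(chainA=ra[0], residA=ra[1], resnameA=ra[2],
                         chainB=rb[0], residB=rb[1], resnameB=rb[2],
                         persistence=frac, n_frames=cmap.n_frames_used))
    df = pd.DataFrame(rows, columns=["chainA", "residA", "resnameA",
                                     "chainB", "residB", "resnameB",
                                     "persistence", "n_frames"])
    return df.sort_values(["chainA", "residA", "chainB", "residB"],
                          kind="mergesort").reset_index(drop=True)


def contact_map_from_table(df: pd.DataFrame,
                           interface: tuple[str, str] = ("A", "B"),
                           provenance: dict | None = None) -> ContactMap:
    entries: dict[PairKey, float] = {}
    n_frames = int(df.n_frames.iloc[0]) if len(df) else 0
    for row in df.itertuples(index=False):
        pair = ((str(row.chainA), int(row.residA), str(row.resnameA)),
                (str(row.chainB), int(row.residB), str(row.resnameB)))
        entries[pair] = float(row.persistence)
    return ContactMap(interface=interface, entries=entries,
                      n_frames_used=n_frames, provenance=provenance or {})
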