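"""Rigid-body superposition, displacement fields and pore-radius profiles.

Superposition uses the closed-form least-squares (Kabsch) rotation with a
reflection guard. Pore profiling follows the inscribed-sphere idea: at
each position z along a channel axis, the largest sphere centred in that
plane that touches no atom's van der Waals surface is found by a
deterministic pattern search (grid refinement 1.0 → 0.1 → 0.01 Å) instead
of a Monte-Carlo walk, so profiles are exactly reproducible. The van der
Waals table shipped here (C 1.70, N 1.55, O 1.52, S 1.80 Å) is a standard
element table; tools using a different table will differ slightly in
absolute radii.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (DegenerateSelectionError, ParameterError, SelectionError,
                     WindowError)
from .system import MolecularSystem, Selection

__all__ = [
    "AlignmentResult",
    "DisplacementField",
    "PoreProfile",
    "VDW_RADII",
    "kabsch",
    "kabsch_align",
    "apply_alignment",
    "displacement_field",
    "pore_profile",
    "min_radius",
]

#: van der Waals radii (Å) used for pore profiling
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
             "H": 1.20, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98}
_DEFAULT_VDW = 1.70

#: radius at which a plane is reported as effectively open
OPEN_PORE_RADIUS = 10.0

#: Approximate Cα selection for the receptor/TARP transmembrane sector of
#: LBD-TMD models: TARP transmembrane helices (residues ~40-220 in TARP
#: numbering) plus the receptor pre-M1 through M3 stretch and the M4 helix.
#: The exact helix boundaries vary between constructs; treat this as a
#: documented starting point, not a canonical definition.
DEFAULT_TMD_SELECTION = "name CA resid 40-220,506-640,780-824"

#: Cα ring around the channel-gate constriction threonines (GluA1 Thr621 /
#: GluA2 Thr625 in rat numbering); use with ``axis_pick="plane-normal"``.
GATE_SELECTION = "name CA resid 617-629"


@dataclass
class AlignmentResult:
    rotation: np.ndarray      # 3x3, proper (det +1)
    translation: np.ndarray   # Å; x_aligned = x @ R.T + t
    rmsd: float               # Å over the paired selection
    n_atoms: int
    selection: str = ""

    def __post_init__(self) -> None:
        r = np.asarray(self.rotation, dtype=float)
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-8):
            raise ParameterError("rotation is not orthonormal")
        if np.linalg.det(r) < 0:
            raise ParameterError("rotation has negative determinant (reflection)")
        if self.rmsd < 0:
            raise ParameterError("negative rmsd")


def kabsch(mobile: np.ndarray, reference: np.ndarray,
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of paired points.

    Returns (R, t, rmsd) such that ``mobile @ R.T + t`` best fits
    ``reference`` in the least-squares sense, with the reflection branch
    of the SVD excluded.
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ParameterError("point sets must be matching (n, 3) arrays")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - pc @ R.T
    moved = P @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - Q) ** 2, axis=1))))
    return R, t, rmsd


def _paired_coords(mobile: MolecularSystem, reference: MolecularSystem,
                   selection: Selection | str, frame: int = 0,
                   ) -> tuple[np.ndarray, np.ndarray, int]:
    """Coordinates of atoms matched by (chain, resid, atom_name)."""
    cols = ["chain_id", "residue_number", "atom_name"]
    idx_m = mobile.select(selection)
    idx_r = reference.select(selection)
    if idx_m.size == 0 or idx_r.size == 0:
        raise SelectionError("selection matches no atoms in one structure")
    tm = mobile.atoms.iloc[idx_m][cols].assign(_im=idx_m)
    tr = reference.atoms.iloc[idx_r][cols].assign(_ir=idx_r)
    merged = tm.merge(tr, on=cols, how="inner")
    n_unpaired = (len(tm) - len(merged)) + (len(tr) - len(merged))
    if n_unpaired:
        warnings.warn(f"{n_unpaired} selected atoms had no counterpart and "
                      "were dropped from the superposition")
    if len(merged) < 3:
        raise DegenerateSelectionError(
            f"only {len(merged)} paired atoms; need >= 3 non-collinear")
    P = mobile.frames[frame][merged._im.to_numpy()]
    Q = reference.frames[frame][merged._ir.to_numpy()]
    centered = P - P.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise DegenerateSelectionError("paired atoms are collinear")
    return P, Q, len(merged)


def kabsch_align(mobile: MolecularSystem, reference: MolecularSystem,
                 selection: Selection | str = "name CA",
                 frame: int = 0) -> AlignmentResult:
    """Least-squares rigid superposition over a paired atom selection."""
    P, Q, n = _paired_coords(mobile, reference, selection, frame)
    R, t, rmsd = kabsch(P, Q)
    label = selection if isinstance(selection, str) else selection.label
    return AlignmentResult(rotation=R, translation=t, rmsd=rmsd,
                           n_atoms=n, selection=label)


def apply_alignment(system: MolecularSystem, result: AlignmentResult,
                    ) -> MolecularSystem:
    """Return a copy of ``system`` with all frames transformed."""
    frames = system.frames @ result.rotation.T + result.translation
    return MolecularSystem(atoms=system.atoms.copy(), frames=frames,
                           frame_times=system.frame_times.copy())


@dataclass
class DisplacementField:
    """Per-residue displacement vectors between two aligned models."""

    table: pd.DataFrame  # chain_id, residue_number, residue_name,
    #                      x0,y0,z0, x1,y1,z1, dx,dy,dz, magnitude


def displacement_field(aligned_mobile: MolecularSystem,
                       reference: MolecularSystem,
                       selection: Selection | str | None = None,
                       representative_atom: str = "CA",
                       frame: int = 0) -> DisplacementField:
    """Per-residue reference→mobile displacement of a representative atom.

    Both structures must already be in a common frame (align first on a
    caller-chosen anchor selection). Residues whose representative atom is
    missing from either structure are skipped with a warning.
    """
    def rep_atoms(system: MolecularSystem) -> pd.DataFrame:
        idx = (system.select(selection) if selection is not None
               else np.arange(system.n_atoms))
        sub = system.atoms.iloc[idx]
        sub = sub[sub.atom_name == representative_atom]
        return sub.assign(_idx=sub.index.to_numpy())

    am = rep_atoms(aligned_mobile)
    ar = rep_atoms(reference)
    cols = ["chain_id", "residue_number", "residue_name"]
    merged = am[cols + ["_idx"]].merge(ar[cols + ["_idx"]], on=cols,
                                       suffixes=("_m", "_r"), how="outer",
                                       indicator=True)
    skipped = merged[merged._merge != "both"]
    if len(skipped):
        warnings.warn(f"{len(skipped)} residues missing a "
                      f"{representative_atom!r} atom in one model; skipped")
    both = merged[merged._merge == "both"]
    start = reference.frames[frame][both._idx_r.to_numpy(dtype=int)]
    end = aligned_mobile.frames[frame][both._idx_m.to_numpy(dtype=int)]
    disp = end - start
    table = pd.DataFrame(dict(
        chain_id=both.chain_id.to_numpy(),
        residue_number=both.residue_number.to_numpy(),
        residue_name=both.residue_name.to_numpy(),
        x0=start[:, 0], y0=start[:, 1], z0=start[:, 2],
        x1=end[:, 0], y1=end[:, 1], z1=end[:, 2],
        dx=disp[:, 0], dy=disp[:, 1], dz=disp[:, 2],
        magnitude=np.linalg.norm(disp, axis=1),
    )).sort_values(["chain_id", "residue_number"],
                   kind="mergesort").reset_index(drop=True)
    return DisplacementField(table=table)


@dataclass
class PoreProfile:
    """Axial profile of the maximal inscribed sphere radius."""

    z: np.ndarray           # Å along the axis, strictly increasing
    radius: np.ndarray      # Å
    centres: np.ndarray     # (n, 3) lab-frame probe centres
    axis_origin: np.ndarray
    axis_direction: np.ndarray
    vdw_table: dict = field(default_factory=lambda: dict(VDW_RADII))

    def __post_init__(self) -> None:
        if np.any(np.diff(self.z) <= 0):
            raise ParameterError("z samples must be strictly increasing")
        if np.any(self.radius < 0):
            raise ParameterError("negative pore radius")


def _principal_axis(coords: np.ndarray, pick: str = "longest",
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and a principal direction of a point cloud.

    ``pick="longest"`` returns the direction of largest variance (an
    elongated bundle); ``pick="plane-normal"`` the smallest (the normal of
    a ring of gate residues).
    """
    centre = coords.mean(axis=0)
    cov = np.cov((coords - centre).T)
    w, v = np.linalg.eigh(cov)
    direction = v[:, np.argmax(w) if pick == "longest" else np.argmin(w)]
    if direction[2] < 0 or (direction[2] == 0 and direction[0] < 0):
        direction = -direction
    return centre, direction / np.linalg.norm(direction)


def _probe_radius(c2d: np.ndarray, z: float, atoms2d: np.ndarray,
                  atoms_z: np.ndarray, vdw: np.ndarray) -> float:
    d = np.sqrt((atoms2d[:, 0] - c2d[0]) ** 2 + (atoms2d[:, 1] - c2d[1]) ** 2
                + (atoms_z - z) ** 2) - vdw
    return float(d.min()) if d.size else OPEN_PORE_RADIUS


def pore_profile(system: MolecularSystem,
                 axis: tuple[np.ndarray, np.ndarray] | Selection | str | None = None,
                 z_range: tuple[float, float] = (-15.0, 15.0),
                 step: float = 0.25,
                 frame: int = 0,
                 vdw_table: dict | None = None,
                 axis_pick: str = "longest") -> PoreProfile:
    """Sphere-probe pore-radius profile along a channel axis.

    ``axis`` is either an explicit ``(origin, direction)`` pair or a
    selection whose Cα principal axis defines the pore axis (defaults to
    the principal axis of all heavy atoms). At each z the probe centre is
    optimized in the plane by a deterministic pattern search from the axis
    point; radii are capped at ``OPEN_PORE_RADIUS`` for open planes.
    """
    if step <= 0:
        raise ParameterError("step must be positive")
    table = vdw_table or VDW_RADII
    heavy = system.atoms.is_heavy.to_numpy()
    coords = system.frames[frame][heavy]
    elements = system.atoms.element.to_numpy()[heavy]
    vdw = np.array([table.get(e, _DEFAULT_VDW) for e in elements])

    if axis is None:
        origin, direction = _principal_axis(coords, axis_pick)
    elif isinstance(axis, (Selection, str)):
        idx = system.select(axis)
        sub = system.atoms.iloc[idx]
        ca = idx[(sub.atom_name == "CA").to_numpy()]
        pts = system.frames[frame][ca if ca.size >= 3 else idx]
        origin, direction = _principal_axis(pts, axis_pick)
    else:
        p0, p1 = (np.asarray(a, dtype=float) for a in axis)
        origin = p0
        direction = (p1 - p0) / np.linalg.norm(p1 - p0)

    # orthonormal in-plane basis
    ref = np.array([1.0, 0.0, 0.0])
    if abs(direction @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)

    # atom coordinates in the axis frame
    rel = coords - origin
    atoms_z = rel @ direction
    atoms2d = np.stack([rel @ u, rel @ v], axis=1)

    z_lo, z_hi = z_range
    zs = np.arange(z_lo, z_hi + 0.5 * step, step)
    radii = np.empty(zs.size)
    centres = np.empty((zs.size, 3))
    moves = np.array([(1, 0), (-1, 0), (0, 1), (0, -1),
                      (1, 1), (1, -1), (-1, 1), (-1, -1)], dtype=float)
    for i, z in enumerate(zs):
        near = np.abs(atoms_z - z) < (OPEN_PORE_RADIUS + vdw.max() + 1.0)
        a2d, az, avdw = atoms2d[near], atoms_z[near], vdw[near]
        c = np.zeros(2)
        best = _probe_radius(c, z, a2d, az, avdw)
        for scale in (1.0, 0.1, 0.01):
            improved = True
            it = 0
            while improved and it < 200:
                improved = False
                it += 1
                for mv in moves:
                    cand = c + mv * scale
                    r = _probe_radius(cand, z, a2d, az, avdw)
                    if r > best + 1e-12:
                        best, c = r, cand
                        improved = True
            if best >= OPEN_PORE_RADIUS:
                break
        radii[i] = min(best, OPEN_PORE_RADIUS)
        centres[i] = origin + c[0] * u + c[1] * v + z * direction
    return PoreProfile(z=zs, radius=radii, centres=centres,
                       axis_origin=origin, axis_direction=direction,
                       vdw_table=dict(table))


def min_radius(profile: PoreProfile,
               z_window: tuple[float, float] | None = None,
               ) -> tuple[float, float]:
    """(z, radius) of the narrowest point within a window (ties → smallest z)."""
    if z_window is None:
        mask = np.ones(profile.z.size, dtype=bool)
    else:
        lo, hi = z_window
        mask = (profile.z >= lo) & (profile.z <= hi)
    if not mask.any():
        raise WindowError(f"window {z_window} does not overlap the profile")
    z = profile.z[mask]
    r = profile.radius[mask]
    k = int(np.argmin(r))  # argmin returns the first (smallest z) minimum
    return float(z[k]), float(r[k])
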