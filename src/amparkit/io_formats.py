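"""Reading and writing the formats the pipeline touches.

Structures are exchanged as PDB (single- or multi-MODEL), trajectories as
DCD/XTC with a PDB topology (a multi-model PDB is accepted as a trajectory
fallback), tabular results as CSV. Coordinates are Å, trajectory time ns,
strides ps.
"""
from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable

import gemmi
import numpy as np
import pandas as pd

from .errors import (EmptyInputError, FormatError, ParameterError, ParseError,
                     TopologyError)
from .system import MolecularSystem, infer_element

__all__ = [
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_table",
]

_WATER_NAMES = {"HOH", "WAT", "TIP", "TIP3", "SOL", "DOD"}


def _prevalidate_pdb(path: Path) -> None:
    """Light syntactic scan so malformed coordinate lines are reported with
    their line number (tolerant PDB readers would silently skip them)."""
    with open(path, "r", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith(("ATOM  ", "HETATM")):
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(
                        f"{path}: malformed {line[:6].strip()} record at line "
                        f"{lineno}: fewer than 54 columns")
                try:
                    for lo, hi in ((30, 38), (38, 46), (46, 54)):
                        float(line[lo:hi])
                except ValueError:
                    raise ParseError(
                        f"{path}: malformed coordinate field at line {lineno}")


def read_structure(path: str | Path) -> MolecularSystem:
    """Read a PDB file into a :class:`MolecularSystem`.

    One frame per MODEL record (one frame if none). HETATM water/lipid
    records are retained but flagged ``is_hetero``. Alternate locations
    other than blank/'A' are dropped with a warning; insertion codes are
    rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    _prevalidate_pdb(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - gemmi detail
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0 or sum(res.__len__() for ch in st[0] for res in ch) == 0:
        raise EmptyInputError(f"{path}: no atoms found")

    dropped_altloc = 0
    records: list[dict] = []
    coords0: list[tuple[float, float, float]] = []
    atom_id = 0
    for chain in st[0]:
        for res in chain:
            if res.seqid.icode not in (" ", "", "\x00"):
                raise ParseError(
                    f"{path}: insertion code {res.seqid.icode!r} at "
                    f"{chain.name}:{res.seqid.num} is unsupported")
            for atom in res:
                if atom.altloc not in ("", "A", "\x00"):
                    dropped_altloc += 1
                    continue
                el = infer_element(atom.name, atom.element.name
                                   if atom.element.name != "X" else "")
                records.append(dict(
                    atom_id=atom_id,
                    atom_name=atom.name,
                    element=el,
                    residue_number=res.seqid.num,
                    residue_name=res.name,
                    chain_id=chain.name,
                    is_heavy=el not in ("H", "D"),
                    is_hetero=(res.het_flag == "H"),
                    is_water=res.name.upper() in _WATER_NAMES,
                ))
                coords0.append((atom.pos.x, atom.pos.y, atom.pos.z))
                atom_id += 1
    if dropped_altloc:
        warnings.warn(f"{path}: dropped {dropped_altloc} alternate-location "
                      "atoms (kept altloc blank/'A')")
    if not records:
        raise EmptyInputError(f"{path}: no atoms after filtering")

    atoms = pd.DataFrame.from_records(records)
    frames = [np.asarray(coords0, dtype=float)]
    for model in list(st)[1:]:
        coords = []
        for chain in model:
            for res in chain:
                for atom in res:
                    if atom.altloc not in ("", "A", "\x00"):
                        continue
                    coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
        if len(coords) != len(records):
            raise ParseError(
                f"{path}: MODEL {model.name} has {len(coords)} atoms, "
                f"expected {len(records)}")
        frames.append(np.asarray(coords, dtype=float))
    return MolecularSystem(atoms=atoms, frames=np.stack(frames))


def read_trajectory(topology: str | Path, traj: str | Path,
                    stride_time: float = 100.0,
                    native_dt_ps: float | None = None) -> MolecularSystem:
    """Read a DCD/XTC trajectory (or multi-model PDB fallback) against a PDB
    topology, subsampled to ``stride_time`` ps using the stored frame
    interval; ``native_dt_ps`` overrides missing interval metadata.
    """
    import MDAnalysis as mda

    topology = Path(topology)
    traj = Path(traj)
    base = read_structure(topology)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            u = mda.Universe(str(topology), str(traj))
    except (ValueError, IOError, EOFError) as exc:
        msg = str(exc)
        if "atoms" in msg.lower() and ("match" in msg.lower() or "number" in msg.lower()):
            raise TopologyError(f"{traj}: atom count does not match topology "
                                f"{topology}: {msg}") from exc
        raise FormatError(f"{traj}: unreadable trajectory: {msg}") from exc
    if u.atoms.n_atoms != base.n_atoms:
        raise TopologyError(
            f"{traj}: trajectory has {u.atoms.n_atoms} atoms but topology "
            f"{topology} resolves to {base.n_atoms}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        dt = float(native_dt_ps) if native_dt_ps else float(u.trajectory.dt)
    if dt <= 0:
        raise ParameterError(f"non-positive frame interval {dt} ps")
    stride = int(round(stride_time / dt))
    if stride < 1:
        raise ParameterError(
            f"stride_time={stride_time} ps is finer than the stored frame "
            f"interval {dt} ps")
    if abs(stride * dt - stride_time) > 1e-6 * max(1.0, stride_time):
        warnings.warn(f"stride_time={stride_time} ps is not a multiple of the "
                      f"frame interval {dt} ps; using every {stride}th frame "
                      f"({stride * dt} ps)")

    frames = []
    times = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for i, ts in enumerate(u.trajectory):
            if i % stride:
                continue
            frames.append(ts.positions.astype(float).copy())
            times.append(i * dt / 1000.0)
    return MolecularSystem(atoms=base.atoms.copy(), frames=np.stack(frames),
                           frame_times=np.asarray(times))


def write_structure(system: MolecularSystem, path: str | Path) -> Path:
    """Write all frames of a system as a multi-model PDB (1e-3 Å precision)."""
    path = Path(path)
    # group atoms (chain, residue) preserving file order; gemmi containers
    # copy by value, so each level must be fully built before being added
    atom_rows = list(system.atoms.itertuples(index=False))
    order = sorted(range(len(atom_rows)),
                   key=lambda i: (str(atom_rows[i].chain_id),
                                  int(atom_rows[i].residue_number), i))
    st = gemmi.Structure()
    st.name = "amparkit"
    for fi in range(system.n_frames):
        coords = system.frames[fi]
        model = gemmi.Model(str(fi + 1))
        cur_chain: gemmi.Chain | None = None
        cur_res: gemmi.Residue | None = None
        cur_cid, cur_rkey = None, None
        def flush_res():
            if cur_res is not None:
                cur_chain.add_residue(cur_res)
        def flush_chain():
            if cur_chain is not None:
                model.add_chain(cur_chain)
        for ai in order:
            row = atom_rows[ai]
            cid = str(row.chain_id)
            rkey = (cid, int(row.residue_number))
            if cid != cur_cid:
                flush_res()
                cur_res, cur_rkey = None, None
                flush_chain()
                cur_chain = gemmi.Chain(cid)
                cur_cid = cid
            if rkey != cur_rkey:
                flush_res()
                cur_res = gemmi.Residue()
                cur_res.name = str(row.residue_name)
                cur_res.seqid = gemmi.SeqId(int(row.residue_number), " ")
                cur_res.het_flag = "H" if getattr(row, "is_hetero", False) else "A"
                cur_rkey = rkey
            atom = gemmi.Atom()
            atom.name = str(row.atom_name)
            atom.element = gemmi.Element(str(row.element).capitalize())
            atom.pos = gemmi.Position(*coords[ai])
            cur_res.add_atom(atom)
        flush_res()
        flush_chain()
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))
    return path


def write_trajectory(system: MolecularSystem, topology_path: str | Path,
                     traj_path: str | Path,
                     frame_dt_ps: float = 100.0) -> tuple[Path, Path]:
    """Write a PDB topology (first frame) plus a DCD of all frames."""
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    topology_path = Path(topology_path)
    traj_path = Path(traj_path)
    first = MolecularSystem(atoms=system.atoms.copy(),
                            frames=system.frames[:1].copy())
    write_structure(first, topology_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(topology_path))
        u.load_new(system.frames.astype(np.float32), format=MemoryReader,
                   dt=frame_dt_ps)
        with mda.Writer(str(traj_path), system.n_atoms, dt=frame_dt_ps) as w:
            for _ in u.trajectory:
                w.write(u.atoms)
    return topology_path, traj_path


def write_table(records: pd.DataFrame | Iterable[dict], path: str | Path,
                key: list[str] | None = None,
                allow_empty: bool = False) -> Path:
    """Write records as CSV with a header row, 6-significant-digit floats
    and a deterministic row order (sorted by ``key`` or all columns)."""
    path = Path(path)
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    if df.empty and not allow_empty:
        raise EmptyInputError(f"refusing to write empty table to {path} "
                              "(pass allow_empty=True)")
    if not df.empty:
        sort_cols = key or [c for c in df.columns
                            if df[c].dtype == object or
                            np.issubdtype(df[c].dtype, np.integer)]
        if sort_cols:
            df = df.sort_values(sort_cols, kind="mergesort").reset_index(drop=True)
    try:
        df.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    except OSError as exc:
        raise OSError(f"cannot write table to {path}: {exc}") from exc
    return path
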