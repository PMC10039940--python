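"""Core in-memory containers: molecular systems, selections, run configuration.

Conventions used throughout the package: coordinates in Å, trajectory time
in ns, frame strides in ps. A residue is identified by the triple
``(chain_id, residue_number, residue_name)``.
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path
import numpy as np
import pandas as pd

from .errors import ParameterError, SelectionError

__all__ = [
    "MolecularSystem",
    "Selection",
    "RunConfig",
    "EquivalenceMap",
    "ResidueKey",
    "ATOMIC_MASSES",
    "BACKBONE_NAMES",
]

#: residue identity triple (chain_id, residue_number, residue_name)
ResidueKey = tuple[str, int, str]

# standard atomic masses (u) for centre-of-mass computations
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "F": 18.998, "CL": 35.45, "BR": 79.904,
    "I": 126.904, "NA": 22.990, "K": 39.098, "MG": 24.305, "CA": 40.078,
    "ZN": 65.38, "FE": 55.845,
}
_DEFAULT_MASS = 12.011

#: protein backbone heavy-atom names (side-chain scope excludes these)
BACKBONE_NAMES = frozenset({"N", "CA", "C", "O", "OXT"})


def infer_element(atom_name: str, element_field: str = "") -> str:
    """Infer a chemical element symbol for a PDB atom.

    The element column is used when present; otherwise the atom name is
    stripped of digits and a leading 'H' (after stripping) marks hydrogen,
    following the common CHARMM-style naming convention.
    """
    el = element_field.strip().upper()
    if el and el != "X":
        return el
    name = atom_name.strip()
    stripped = re.sub(r"^\d+", "", name)
    if not stripped:
        return "X"
    if stripped[0].upper() in ("H", "D"):
        return "H"
    # two-letter elements spelled in columns 13-14 (e.g. FE, ZN) are rare in
    # protein records; default to the first letter
    return stripped[0].upper()


@dataclass
class MolecularSystem:
    """A topology plus one or more coordinate frames.

    Parameters
    ----------
    atoms
        One row per atom with columns ``atom_id``, ``atom_name``,
        ``element``, ``residue_number``, ``residue_name``, ``chain_id``,
        ``is_heavy`` and ``is_hetero``.
    frames
        Array of shape ``(n_frames, n_atoms, 3)``, Å.
    frame_times
        Time of each frame in ns; empty for single structures without
        time metadata.
    """

    atoms: pd.DataFrame
    frames: np.ndarray
    frame_times: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 2:
            self.frames = self.frames[None, :, :]
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------
    def validate(self) -> None:
        required = {"atom_id", "atom_name", "element", "residue_number",
                    "residue_name", "chain_id", "is_heavy"}
        missing = required - set(self.atoms.columns)
        if missing:
            raise ParameterError(f"atom table missing columns: {sorted(missing)}")
        if "is_hetero" not in self.atoms.columns:
            self.atoms = self.atoms.assign(is_hetero=False)
        n = len(self.atoms)
        if self.frames.shape[1:] != (n, 3):
            raise ParameterError(
                f"frames shape {self.frames.shape} inconsistent with {n} atoms")
        if self.frame_times.size and self.frame_times.size != self.n_frames:
            raise ParameterError("frame_times length differs from frame count")
        key = self.atoms[["chain_id", "residue_number", "atom_name"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0]
            raise ParameterError(
                "duplicate atom identity (chain_id, residue_number, atom_name)="
                f"({dup.chain_id!r}, {dup.residue_number}, {dup.atom_name!r})")

    # -- basic accessors ----------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def residue_keys(self) -> pd.DataFrame:
        """Unique residues as a frame of (chain_id, residue_number, residue_name)."""
        return (self.atoms[["chain_id", "residue_number", "residue_name"]]
                .drop_duplicates().reset_index(drop=True))

    def atom_residue_keys(self) -> list[ResidueKey]:
        """Per-atom residue identity triples (length n_atoms)."""
        return list(zip(self.atoms.chain_id.tolist(),
                        self.atoms.residue_number.astype(int).tolist(),
                        self.atoms.residue_name.tolist()))

    # -- selections ---------------------------------------------------
    def select(self, selection: "Selection | str") -> np.ndarray:
        """Resolve a selection to sorted atom indices."""
        if isinstance(selection, str):
            selection = Selection.parse(selection)
        return selection.indices(self.atoms)

    def residue_atoms(self, chain_id: str, residue_number: int) -> np.ndarray:
        mask = ((self.atoms.chain_id == chain_id)
                & (self.atoms.residue_number == residue_number))
        idx = np.flatnonzero(mask.to_numpy())
        if idx.size == 0:
            raise SelectionError(
                f"residue {chain_id}:{residue_number} not present in topology")
        return idx

    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES.get(e, _DEFAULT_MASS)
                         for e in self.atoms.element], dtype=float)


_RANGE_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


@dataclass(frozen=True)
class Selection:
    """A declarative atom selection.

    Fields combine with logical AND; ``None`` means "no constraint".
    The string form accepts tokens like ``chain B' resid 140-215,300
    name CA heavy protein``.
    """

    chains: tuple[str, ...] | None = None
    resid_ranges: tuple[tuple[int, int], ...] | None = None
    names: tuple[str, ...] | None = None
    heavy_only: bool = False
    protein_only: bool = False
    label: str = ""

    @classmethod
    def parse(cls, text: str) -> "Selection":
        tokens = text.replace(",", " , ").split()
        # re-join comma-separated value lists
        chains: list[str] = []
        ranges: list[tuple[int, int]] = []
        names: list[str] = []
        heavy = False
        protein = False
        i = 0

        def collect_values(start: int) -> tuple[list[str], int]:
            vals: list[str] = []
            j = start
            expecting = True
            while j < len(tokens):
                tok = tokens[j]
                if tok == ",":
                    expecting = True
                    j += 1
                    continue
                if not expecting and tok in ("chain", "resid", "name", "heavy", "protein"):
                    break
                if tok in ("chain", "resid", "name", "heavy", "protein") and not vals:
                    break
                vals.append(tok)
                expecting = False
                j += 1
            return vals, j

        while i < len(tokens):
            tok = tokens[i]
            if tok == "chain":
                vals, i = collect_values(i + 1)
                chains.extend(vals)
            elif tok == "resid":
                vals, i = collect_values(i + 1)
                for v in vals:
                    m = _RANGE_RE.match(v)
                    if not m:
                        raise SelectionError(f"bad resid token {v!r} in {text!r}")
                    lo = int(m.group(1))
                    hi = int(m.group(2)) if m.group(2) else lo
                    ranges.append((lo, hi))
            elif tok == "name":
                vals, i = collect_values(i + 1)
                names.extend(vals)
            elif tok == "heavy":
                heavy = True
                i += 1
            elif tok == "protein":
                protein = True
                i += 1
            elif tok == ",":
                i += 1
            else:
                raise SelectionError(f"unrecognized selection token {tok!r} in {text!r}")
        return cls(chains=tuple(chains) or None,
                   resid_ranges=tuple(ranges) or None,
                   names=tuple(names) or None,
                   heavy_only=heavy, protein_only=protein, label=text)

    def indices(self, atoms: pd.DataFrame) -> np.ndarray:
        mask = np.ones(len(atoms), dtype=bool)
        if self.chains is not None:
            mask &= atoms.chain_id.isin(self.chains).to_numpy()
        if self.resid_ranges is not None:
            resid = atoms.residue_number.to_numpy()
            rmask = np.zeros(len(atoms), dtype=bool)
            for lo, hi in self.resid_ranges:
                rmask |= (resid >= lo) & (resid <= hi)
            mask &= rmask
        if self.names is not None:
            mask &= atoms.atom_name.isin(self.names).to_numpy()
        if self.heavy_only:
            mask &= atoms.is_heavy.to_numpy()
        if self.protein_only:
            mask &= ~atoms.is_hetero.to_numpy()
        return np.flatnonzero(mask)


@dataclass
class RunConfig:
    """Analysis parameters with the defaults used throughout.

    ``contact_cutoff`` (Å) is the heavy-atom distance defining a residue
    contact in trajectory analysis; ``static_cutoff`` (Å) the one used for
    single-structure neighbour counting; ``exclude_time`` (ns) drops the
    initial equilibration stretch; ``stride_time`` (ps) the analysis
    sampling interval; the two floors are the noise thresholds applied to
    difference maps; ``pathway_edge_threshold`` the minimum persistence for
    a pathway-graph edge.
    """

    contact_cutoff: float = 4.0
    static_cutoff: float = 4.5
    exclude_time: float = 100.0
    stride_time: float = 100.0
    persistence_floor: float = 0.10
    delta_floor: float = 0.10
    pathway_edge_threshold: float = 0.50
    seed: int = 0
    selections: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.contact_cutoff <= 0 or self.static_cutoff <= 0:
            raise ParameterError("cutoffs must be positive")
        for name in ("persistence_floor", "delta_floor", "pathway_edge_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name}={v} outside [0, 1]")
        if self.exclude_time < 0:
            raise ParameterError("exclude_time must be >= 0")
        if self.stride_time <= 0:
            raise ParameterError("stride_time must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")


@dataclass
class EquivalenceMap:
    """Structurally identical subunit copies and replicate labels.

    ``groups`` is a list of ordered chain-id lists; position *k* of every
    group belongs to subunit copy *k* (e.g. ``[["A", "C"], ["B", "D"],
    ["B'", "D'"]]`` for a two-copy receptor). Averaging treats a contact
    absent from a copy as zero so fractions stay comparable.
    """

    groups: list[list[str]] = field(default_factory=list)
    replicate_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.groups:
            for c in g:
                if c in seen:
                    raise ParameterError(f"chain {c!r} appears in more than one group")
                seen.add(c)

    def representative(self, chain_id: str) -> str:
        for g in self.groups:
            if chain_id in g:
                return g[0]
        return chain_id

    def n_copies(self, chain_id: str) -> int:
        for g in self.groups:
            if chain_id in g:
                return len(g)
        return 1
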