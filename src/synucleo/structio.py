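"""Structure, trajectory and table I/O.

Molecular structures are held in a deliberately small in-memory model
(:class:`Atom`, :class:`Structure`, :class:`Trajectory`): atoms carry the
identity fields the geometric analyses need (chain, residue, name, element,
position in Å) and nothing else.  Parsing and writing of PDB/mmCIF is
delegated to :mod:`gemmi`; multi-frame XYZ reading goes through MDAnalysis
when that optional dependency is present.

Conventions
-----------
* Coordinates are in Å throughout.
* Residue indices are taken verbatim from the source file (1-based, gaps
  allowed) and never renumbered, so author numbering such as the
  α-synuclein sequence positions survives round trips.
* Alternate locations: only blank or 'A' altlocs are kept; occupancies are
  ignored (single-conformer analysis).
* Hydrogens absent from the input are tolerated; operations that require
  them raise their own errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "StructureParseError",
    "TrajectoryError",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "write_table",
    "read_table",
]


class StructureParseError(ValueError):
    """A structure file could not be parsed under the requested standard."""


class TrajectoryError(ValueError):
    """Frames of a trajectory are structurally inconsistent."""


@dataclass(frozen=True)
class Atom:
    """One atom: identity plus a 3-D position in Å."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_index: int
    chain_id: str
    position: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError(f"atom {self.serial}: position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)
        if not self.chain_id:
            raise ValueError(f"atom {self.serial}: chain_id must be non-empty")


@dataclass
class Structure:
    """An ordered list of atoms grouped into chains and residues."""

    atoms: list[Atom]

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def positions(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.vstack([a.position for a in self.atoms])

    def with_positions(self, coords: np.ndarray) -> "Structure":
        """Copy of this structure with every atom moved to ``coords``."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValueError(
                f"coords shape {coords.shape} != ({len(self.atoms)}, 3)"
            )
        return Structure(
            [replace(a, position=coords[i].copy()) for i, a in enumerate(self.atoms)]
        )

    def residues(self) -> list[tuple[tuple[str, int], list[int]]]:
        """Residues as ((chain_id, residue_index), atom index list), file order."""
        out: list[tuple[tuple[str, int], list[int]]] = []
        key_pos: dict[tuple[str, int], int] = {}
        for i, a in enumerate(self.atoms):
            key = (a.chain_id, a.residue_index)
            if key not in key_pos:
                key_pos[key] = len(out)
                out.append((key, []))
            out[key_pos[key]][1].append(i)
        return out

    def chain_atom_indices(self, chain_id: str) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if a.chain_id == chain_id]

    def select(self, predicate) -> list[int]:
        return [i for i, a in enumerate(self.atoms) if predicate(a)]


@dataclass
class Trajectory:
    """Ordered coordinate frames over a single topology."""

    topology: Structure
    frames: list[np.ndarray]
    frame_times: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = self.topology.n_atoms
        checked = []
        for k, f in enumerate(self.frames):
            f = np.asarray(f, dtype=float)
            if f.shape != (n, 3):
                raise TrajectoryError(
                    f"frame {k}: shape {f.shape} does not match topology ({n} atoms)"
                )
            checked.append(f)
        self.frames = checked
        if self.frame_times is not None:
            t = np.asarray(self.frame_times, dtype=float)
            if len(t) != len(self.frames):
                raise TrajectoryError("frame_times length does not match frame count")
            if len(t) > 1 and not np.all(np.diff(t) > 0):
                raise TrajectoryError("frame_times must be strictly increasing")
            self.frame_times = t

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def frame_structure(self, k: int) -> Structure:
        return self.topology.with_positions(self.frames[k])


# ---------------------------------------------------------------------------
# structure reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

_FORMATS = {"pdb", "mmcif"}


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in {".cif", ".mmcif"}:
        return "mmcif"
    return "pdb"


def _validate_pdb_records(path: Path) -> None:
    """Fail fast, naming the line, on ATOM/HETATM records whose fixed
    coordinate columns are not numeric (gemmi is permissive about these)."""
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM  ", "HETATM")):
                continue
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fld = line[lo:hi].strip()
                try:
                    float(fld)
                except ValueError:
                    raise StructureParseError(
                        f"{path}: line {lineno}: malformed coordinate field {fld!r}"
                    ) from None


def _gemmi_read(path: Path, format: str) -> gemmi.Structure:
    if format == "pdb":
        _validate_pdb_records(path)
    try:
        if format == "pdb":
            st = gemmi.read_pdb(str(path))
        else:
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    return st


_CIF_TAGS = [
    "group_PDB", "id", "type_symbol", "label_atom_id", "label_comp_id",
    "auth_asym_id", "auth_seq_id", "Cartn_x", "Cartn_y", "Cartn_z",
]


def _atoms_from_cif_loop(path: Path) -> list[Atom]:
    """Minimal mmCIF route: atoms straight from the atom_site loop.

    Used when gemmi cannot assemble a Structure from a stripped-down block
    (e.g. no entity records); label_* identifiers are accepted in place of
    missing auth_* ones."""
    try:
        block = gemmi.cif.read(str(path)).sole_block()
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"{path}: {exc}") from exc
    table = block.find("_atom_site.", _CIF_TAGS)
    if len(table) == 0:
        alt = list(_CIF_TAGS)
        alt[5], alt[6] = "label_asym_id", "label_seq_id"
        table = block.find("_atom_site.", alt)
    atoms: list[Atom] = []
    alt_col = block.find_loop("_atom_site.label_alt_id")
    altlocs = list(alt_col) if alt_col else None
    for k, row in enumerate(table):
        if altlocs is not None and altlocs[k] not in (".", "?", "A", ""):
            continue
        try:
            atoms.append(
                Atom(
                    serial=int(row[1]),
                    name=row[3],
                    element=row[2],
                    residue_name=row[4],
                    residue_index=int(row[6]),
                    chain_id=row[5],
                    position=np.array([float(row[7]), float(row[8]), float(row[9])]),
                )
            )
        except ValueError as exc:
            raise StructureParseError(f"{path}: atom_site row {k + 1}: {exc}") from exc
    return atoms


def _atoms_from_model(model: gemmi.Model, keep_hetatm: bool = True) -> list[Atom]:
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            for at in res:
                if at.altloc not in ("", "\0", "A"):
                    continue
                atoms.append(
                    Atom(
                        serial=at.serial,
                        name=at.name,
                        element=at.element.name,
                        residue_name=res.name,
                        residue_index=res.seqid.num,
                        chain_id=chain.name or "A",
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                    )
                )
    return atoms


def read_structure(path: str | Path, format: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    All ATOM/HETATM records of the first model are kept (altloc-filtered),
    chain order preserved.  ``format`` is inferred from the suffix when not
    given; passing an unknown format name raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or _infer_format(path)
    if fmt not in _FORMATS:
        raise ValueError(f"unknown structure format {fmt!r}; expected one of {sorted(_FORMATS)}")
    st = _gemmi_read(path, fmt)
    atoms = _atoms_from_model(st[0]) if len(st) else []
    if not atoms and fmt == "mmcif":
        atoms = _atoms_from_cif_loop(path)
    if not atoms:
        raise StructureParseError(f"{path}: no atom records parsed")
    return Structure(atoms)


def read_trajectory(
    path: str | Path,
    format: str | None = None,
    topology: Structure | None = None,
) -> Trajectory:
    """Read a multi-model PDB or multi-frame XYZ file as a trajectory.

    For multi-model PDB the topology comes from the first MODEL and every
    model must have the same atom count and ordering.  For XYZ, atoms carry
    element names only, so either a matching ``topology`` is supplied or a
    generic single-chain topology is synthesised (one residue per atom).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format or ("xyz" if path.suffix.lower() == ".xyz" else "pdb")
    if fmt in ("pdb", "mmcif", "multi-model pdb"):
        st = _gemmi_read(path, "pdb" if fmt != "mmcif" else "mmcif")
        if len(st) == 0:
            raise StructureParseError(f"{path}: no models found")
        top = Structure(_atoms_from_model(st[0]))
        frames = []
        for k, model in enumerate(st):
            atoms = _atoms_from_model(model)
            if len(atoms) != top.n_atoms:
                raise TrajectoryError(
                    f"{path}: model {k + 1} has {len(atoms)} atoms, expected {top.n_atoms}"
                )
            frames.append(np.vstack([a.position for a in atoms]))
        return Trajectory(top, frames)
    if fmt in ("xyz", "xyz-frames"):
        return _read_xyz_frames(path, topology)
    raise ValueError(f"unknown trajectory format {fmt!r}")


def _read_xyz_frames(path: Path, topology: Structure | None) -> Trajectory:
    import MDAnalysis as mda  # optional dependency, only for XYZ trajectories

    u = mda.Universe(str(path), format="XYZ")
    frames = [u.trajectory.ts.positions.astype(float).copy() for _ in u.trajectory]
    n = frames[0].shape[0]
    if topology is None:
        names = [str(nm) for nm in u.atoms.names]
        topology = Structure(
            [
                Atom(
                    serial=i + 1,
                    name=names[i],
                    element=names[i][:2].strip().capitalize(),
                    residue_name="UNK",
                    residue_index=i + 1,
                    chain_id="A",
                    position=frames[0][i],
                )
                for i in range(n)
            ]
        )
    return Trajectory(topology, frames)


def _to_gemmi(structures: Sequence[Structure]) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = "synucleo"
    for k, s in enumerate(structures):
        model = gemmi.Model(k + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in s.atoms:
            ch = chain_map.get(a.chain_id)
            if ch is None:
                ch = gemmi.Chain(a.chain_id)
                model.add_chain(ch)
                chain_map = {c.name: c for c in model}
                ch = chain_map[a.chain_id]
            if len(ch) == 0 or ch[len(ch) - 1].seqid.num != a.residue_index:
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_index, " ")
                ch.add_residue(res)
            res = ch[len(ch) - 1]
            at = gemmi.Atom()
            at.name = a.name
            at.element = gemmi.Element(a.element)
            at.serial = a.serial
            at.pos = gemmi.Position(*a.position)
            res.add_atom(at)
        st.add_model(model)
    st.setup_entities()
    return st


def write_structure(structure: Structure, path: str | Path) -> None:
    """Write a structure as a single-model PDB file."""
    _to_gemmi([structure]).write_pdb(str(path))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write a trajectory as a multi-model PDB file (MODEL/ENDMDL blocks)."""
    structures = [traj.frame_structure(k) for k in range(traj.n_frames)]
    _to_gemmi(structures).write_pdb(str(path))


# ---------------------------------------------------------------------------
# tabular I/O
# ---------------------------------------------------------------------------


def write_table(records: Iterable[dict], path: str | Path, format: str | None = None) -> None:
    """Write uniform keyed records as CSV, TSV or JSON.

    All records must share the same key set; an empty list yields a
    header-only file (CSV/TSV) or an empty JSON array.
    """
    records = list(records)
    path = Path(path)
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(path.suffix.lower(), "csv")
    if fmt not in {"csv", "tsv", "json"}:
        raise ValueError(f"unknown table format {fmt!r}")
    keys: list[str] | None = None
    for r in records:
        if keys is None:
            keys = list(r)
        elif list(r) != keys and set(r) != set(keys):
            raise ValueError("records do not share a uniform key set")
    if fmt == "json":
        path.write_text(json.dumps(records, indent=1, default=float) + "\n")
        return
    df = pd.DataFrame.from_records(records, columns=keys)
    df.to_csv(path, index=False, sep="," if fmt == "csv" else "\t", float_format="%.12g")


def read_table(path: str | Path, format: str | None = None) -> list[dict]:
    """Read back a table written by :func:`write_table`."""
    path = Path(path)
    fmt = format or {".csv": "csv", ".tsv": "tsv", ".json": "json"}.get(path.suffix.lower(), "csv")
    if fmt == "json":
        return json.loads(path.read_text())
    try:
        df = pd.read_csv(path, sep="," if fmt == "csv" else "\t")
    except pd.errors.EmptyDataError:
        return []
    return df.to_dict(orient="records")
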