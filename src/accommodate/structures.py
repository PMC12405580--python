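"""Read, select and write biomolecular coordinates.

The :class:`Structure` container is the unit of structural input for the whole
package: atoms carry (chain, residue number, residue name, atom name, element)
and 3-D coordinates in Angstrom.  Every observable addresses atoms through
(chain, residue number, atom name) triples -- residue numbering is taken
verbatim from the input file, because published measurements cite author
numbering (e.g. U4559 of the sarcin-ricin loop).

File parsing and writing goes through biotite; this module adds the
atom-addressing scheme, duplicate-key integrity checks and deterministic
altloc handling (highest occupancy, ties resolved to the first encountered).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import biotite.structure as bst
from biotite.structure.io.gro import GROFile
from biotite.structure.io.pdb import PDBFile

from .errors import FormatError, IntegrityError, ResolutionError


class AtomSpec(NamedTuple):
    """Address of a single atom: (chain id, residue number, atom name)."""

    chain: str
    res_id: int
    atom_name: str


@dataclass
class AtomSet:
    """An ordered set of atom indices into a specific Structure."""

    indices: np.ndarray

    def __post_init__(self):
        self.indices = np.asarray(self.indices, dtype=np.intp)
        if self.indices.ndim != 1:
            raise IntegrityError("AtomSet indices must be one-dimensional")
        if len(np.unique(self.indices)) != len(self.indices):
            raise IntegrityError("AtomSet indices must be unique")
        if len(self.indices) and self.indices.min() < 0:
            raise IntegrityError("AtomSet indices must be non-negative")

    def __len__(self) -> int:
        return len(self.indices)

    def __iter__(self):
        return iter(self.indices)


@dataclass
class Structure:
    """Atoms with naming metadata and coordinates in Angstrom."""

    chain: np.ndarray
    res_id: np.ndarray
    res_name: np.ndarray
    atom_name: np.ndarray
    element: np.ndarray
    coord: np.ndarray
    _index: dict | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.chain = np.asarray(self.chain, dtype="U4")
        self.res_id = np.asarray(self.res_id, dtype=np.int64)
        self.res_name = np.asarray(self.res_name, dtype="U5")
        self.atom_name = np.asarray(self.atom_name, dtype="U6")
        self.element = np.asarray(self.element, dtype="U2")
        self.coord = np.asarray(self.coord, dtype=float).reshape(-1, 3)
        n = len(self.coord)
        for arr, nm in [
            (self.chain, "chain"),
            (self.res_id, "res_id"),
            (self.res_name, "res_name"),
            (self.atom_name, "atom_name"),
            (self.element, "element"),
        ]:
            if len(arr) != n:
                raise IntegrityError(f"field {nm} has {len(arr)} entries for {n} atoms")
        if n and not np.all(np.isfinite(self.coord)):
            raise IntegrityError("coordinates must be finite")
        keys = list(zip(self.chain.tolist(), self.res_id.tolist(), self.atom_name.tolist()))
        if len(set(keys)) != n:
            seen, dup = set(), None
            for k in keys:
                if k in seen:
                    dup = k
                    break
                seen.add(k)
            raise IntegrityError(f"duplicate atom key {dup}")
        self._index = {k: i for i, k in enumerate(keys)}

    def __len__(self) -> int:
        return len(self.coord)

    @property
    def n_atoms(self) -> int:
        return len(self.coord)

    def index_of(self, spec: AtomSpec) -> int:
        """Index of the unique atom matching ``spec``."""
        key = (str(spec[0]), int(spec[1]), str(spec[2]))
        try:
            return self._index[key]
        except KeyError:
            raise ResolutionError(f"no atom matches {key}") from None

    def residues(self) -> list[tuple[str, int]]:
        """Unique (chain, residue number) pairs in order of appearance."""
        out, seen = [], set()
        for c, r in zip(self.chain.tolist(), self.res_id.tolist()):
            if (c, r) not in seen:
                seen.add((c, r))
                out.append((c, r))
        return out

    def with_coord(self, coord: np.ndarray) -> "Structure":
        """Copy of this structure with replaced coordinates."""
        return Structure(
            self.chain.copy(), self.res_id.copy(), self.res_name.copy(),
            self.atom_name.copy(), self.element.copy(),
            np.asarray(coord, dtype=float).copy(),
        )

    def heavy_mask(self) -> np.ndarray:
        return self.element != "H"


def to_atom_array(structure: Structure) -> bst.AtomArray:
    """Convert to a biotite AtomArray (coordinates stay in Angstrom)."""
    arr = bst.AtomArray(len(structure))
    arr.coord = np.asarray(structure.coord, dtype=np.float32)
    arr.chain_id = structure.chain.astype("U4")
    arr.res_id = structure.res_id.astype(int)
    arr.res_name = structure.res_name.astype("U5")
    arr.atom_name = structure.atom_name.astype("U6")
    arr.element = structure.element.astype("U2")
    arr.hetero = np.zeros(len(structure), dtype=bool)
    return arr


def from_atom_array(arr: bst.AtomArray) -> Structure:
    chain = np.array([c if c else "A" for c in arr.chain_id], dtype="U4")
    element = np.array(
        [e if e else _guess_element(n) for e, n in zip(arr.element, arr.atom_name)],
        dtype="U2",
    )
    return Structure(
        chain, np.asarray(arr.res_id, dtype=np.int64),
        np.asarray(arr.res_name, dtype="U5"), np.asarray(arr.atom_name, dtype="U6"),
        element, np.asarray(arr.coord, dtype=float),
    )


def _guess_element(atom_name: str) -> str:
    for ch in atom_name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def _infer_format(path: str, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("pdb", "gro"):
            raise FormatError(f"unsupported format {fmt!r} (expected 'pdb' or 'gro')")
        return fmt
    ext = os.path.splitext(path)[1].lower().lstrip(".")
    if ext in ("pdb", "gro"):
        return ext
    raise FormatError(f"cannot infer format from path {path!r}; pass format=")


def _locate_bad_line(path: str, fmt: str) -> int | None:
    """Best-effort scan for the first malformed line, for error messages."""
    try:
        lines = open(path).read().splitlines()
    except OSError:
        return None
    if fmt == "pdb":
        for no, line in enumerate(lines, start=1):
            if line.startswith(("ATOM", "HETATM")):
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                    int(line[22:26])
                except (ValueError, IndexError):
                    return no
    else:  # gro: header, count, atoms..., box
        if len(lines) < 2:
            return len(lines) or 1
        try:
            natoms = int(lines[1].strip())
        except ValueError:
            return 2
        for no in range(3, min(3 + natoms, len(lines) + 1)):
            line = lines[no - 1]
            try:
                int(line[0:5]); float(line[20:28]); float(line[28:36]); float(line[36:44])
            except (ValueError, IndexError):
                return no
    return None


def _chains_from_res_ids(res_ids: np.ndarray) -> np.ndarray:
    letters = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    chain_no = 0
    out = np.empty(len(res_ids), dtype="U4")
    for k, r in enumerate(res_ids):
        if k > 0 and r < res_ids[k - 1]:
            chain_no += 1
        out[k] = letters[chain_no % 26] * (chain_no // 26 + 1)
    return out


def _is_empty_file(path: str, fmt: str) -> bool:
    lines = open(path).read().splitlines()
    if fmt == "pdb":
        return not any(l.startswith(("ATOM", "HETATM")) for l in lines)
    return len(lines) >= 2 and lines[1].strip() == "0"


def read_structure(path: str, format: str | None = None) -> Structure:
    """Read a PDB or GRO file into a :class:`Structure`.

    PDB altloc policy: the highest-occupancy conformer is kept; on ties the
    first encountered wins.  GRO coordinates (nm) are converted to Angstrom
    (exactly x10).  Hydrogens are retained if present.
    """
    fmt = _infer_format(path, format)
    if _is_empty_file(path, fmt):
        return Structure(np.zeros(0, "U4"), np.zeros(0, np.int64),
                         np.zeros(0, "U5"), np.zeros(0, "U6"),
                         np.zeros(0, "U2"), np.zeros((0, 3)))
    try:
        if fmt == "pdb":
            pdb = PDBFile.read(path)
            arr = pdb.get_structure(model=1, altloc="occupancy")
        else:
            gro = GROFile.read(path)
            arr = gro.get_structure(model=1)
            if all(c == "" for c in arr.chain_id):
                # GRO stores no chain ids; start a new chain wherever the
                # residue numbering restarts so atom keys stay unique
                arr.chain_id = _chains_from_res_ids(arr.res_id)
    except FileNotFoundError:
        raise
    except Exception as exc:
        bad = _locate_bad_line(path, fmt)
        where = f" at line {bad}" if bad is not None else ""
        raise FormatError(f"cannot parse {path} as {fmt}{where}: {exc}") from exc
    try:
        return from_atom_array(arr)
    except IntegrityError as exc:
        raise IntegrityError(f"{path}: {exc}") from exc


def write_structure(structure: Structure, path: str, format: str | None = None) -> None:
    """Write a Structure as PDB or GRO (Angstrom -> nm for GRO, exactly /10)."""
    fmt = _infer_format(path, format)
    if len(structure) == 0:
        with open(path, "w") as fh:
            fh.write("END\n" if fmt == "pdb"
                     else "empty\n0\n   0.0   0.0   0.0\n")
        return
    arr = to_atom_array(structure)
    try:
        if fmt == "pdb":
            f = PDBFile()
            f.set_structure(arr)
            f.write(path)
        else:
            f = GROFile()
            f.set_structure(arr)
            f.write(path)
    except OSError as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc


def select_atoms(structure: Structure, specs: Sequence[AtomSpec | tuple]) -> AtomSet:
    """Resolve specs to an :class:`AtomSet` preserving the order of ``specs``.

    Each spec must resolve to exactly one atom; the (chain, residue number,
    atom name) key is unique per Structure by construction, so a present key
    matches exactly once and an absent key raises a ResolutionError.
    """
    indices = [structure.index_of(AtomSpec(*s)) for s in specs]
    return AtomSet(np.array(indices, dtype=np.intp))
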