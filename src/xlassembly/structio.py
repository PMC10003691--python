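"""Structure parsing, writing, assembly replication and atom selection.

Multi-chain protein structures are read from PDB files (via gemmi) into a
lightweight in-memory model with author residue numbering.  Homo-oligomeric
assemblies (e.g. an E1 dimer or an E2 trimer) are built by replicating a
structure under proper rigid transforms; every downstream distance
computation runs on the flattened assembly coordinates.
"""
from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np

from .transforms import RigidTransform

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "Structure",
    "Assembly",
    "AssemblyCopy",
    "Selection",
    "FlatAtom",
    "StructureError",
    "EmptyStructureError",
    "FormatError",
    "SelectionParseError",
    "TopologyMismatchError",
    "read_structure",
    "write_structure",
    "build_assembly",
    "select_atoms",
    "read_transform_file",
    "write_transform_file",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}
_WATERS = {"HOH", "WAT", "DOD"}
BACKBONE_NAMES = {"N", "CA", "C", "O"}
_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


class StructureError(ValueError):
    """Base class for structure model violations."""


class EmptyStructureError(StructureError):
    """A file or model contained no usable ATOM records."""


class FormatError(StructureError):
    """A value cannot be represented in fixed-column PDB format."""


class SelectionParseError(ValueError):
    """A selection expression could not be parsed."""


class TopologyMismatchError(StructureError):
    """Models expected to share one topology differ."""


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    bfactor: float = 0.0
    is_hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.name}: non-finite coordinates")
        if not 0.0 <= self.occupancy <= 1.0:
            raise StructureError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.icode)

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def is_complete(self) -> bool:
        """Standard amino acids must carry a C-alpha to enter distance work."""
        return self.res_name not in STANDARD_AA or self.ca is not None


@dataclass
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)


class FlatAtom(NamedTuple):
    """One row of a flattened atom table (deterministic traversal order)."""

    index: int
    copy_id: str
    chain_label: str
    chain_id: str
    seq_num: int
    icode: str
    res_name: str
    atom_name: str
    element: str
    is_hetero: bool


@dataclass
class Structure:
    """One or more models (frames) sharing a chain/residue/atom layout.

    A single-model Structure is a static structure; a multi-model one is the
    canonical trajectory interchange (see :mod:`xlassembly.dynamics`).
    """

    models: list[list[Chain]]
    title: str = ""

    @property
    def n_models(self) -> int:
        return len(self.models)

    def chains(self, model_index: int = 0) -> list[Chain]:
        return self.models[model_index]

    def residues(self, model_index: int = 0) -> Iterable[Residue]:
        for chain in self.models[model_index]:
            yield from chain.residues

    def atoms(self, model_index: int = 0) -> Iterable[Atom]:
        for res in self.residues(model_index):
            yield from res.atoms

    def n_atoms(self, model_index: int = 0) -> int:
        return sum(1 for _ in self.atoms(model_index))

    def flat_atoms(self, model_index: int = 0) -> list[FlatAtom]:
        out: list[FlatAtom] = []
        i = 0
        for chain in self.models[model_index]:
            for res in chain.residues:
                for atom in res.atoms:
                    out.append(FlatAtom(i, "", chain.chain_id, chain.chain_id,
                                        res.seq_num, res.icode, res.res_name,
                                        atom.name, atom.element, atom.is_hetero))
                    i += 1
        return out

    def coords(self, model_index: int = 0) -> np.ndarray:
        pts = [a.coords for a in self.atoms(model_index)]
        if not pts:
            return np.zeros((0, 3))
        return np.array(pts, dtype=float)

    def topology_signature(self, model_index: int = 0) -> tuple:
        return tuple(
            (c.chain_id, tuple((r.seq_num, r.icode, r.res_name,
                                tuple(a.name for a in r.atoms)) for r in c.residues))
            for c in self.models[model_index]
        )

    def validate_shared_topology(self) -> None:
        """Require all models identical in topology (trajectory contract)."""
        if not self.models:
            raise EmptyStructureError("structure has no models")
        ref = self.topology_signature(0)
        for m in range(1, self.n_models):
            if self.topology_signature(m) != ref:
                raise TopologyMismatchError(f"model {m + 1} differs from model 1 in topology")


# ---------------------------------------------------------------------------
# PDB I/O


def _resolve_altlocs(atoms_by_name: dict[str, list]) -> list:
    """Keep one conformer per atom name: highest occupancy, ties -> label 'A'."""
    chosen = []
    for name, group in atoms_by_name.items():
        group.sort(key=lambda a: (-a[0], a[1]))
        chosen.append(group[0][2])
    return chosen


def read_structure(path, altloc_policy: str = "occupancy", include_hetero: bool = False) -> Structure:
    """Read a (possibly multi-model) PDB file.

    Altloc resolution keeps, per atom name, the conformer with the highest
    occupancy, breaking ties by altloc label ('A' preferred).  HETATM records
    are dropped unless *include_hetero*; waters are always dropped.
    """
    import gemmi

    if altloc_policy != "occupancy":
        raise ValueError(f"unknown altloc policy {altloc_policy!r}")
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, OSError) as exc:
        raise OSError(f"cannot read PDB file {path}: {exc}") from exc

    models: list[list[Chain]] = []
    n_atoms_total = 0
    for g_model in st:
        chains: list[Chain] = []
        for g_chain in g_model:
            chain = Chain(chain_id=g_chain.name.strip() or "A")
            for g_res in g_chain:
                is_het = g_res.het_flag == "H"
                if g_res.name in _WATERS:
                    continue
                if is_het and not include_hetero:
                    continue
                res = Residue(
                    chain_id=chain.chain_id,
                    seq_num=g_res.seqid.num,
                    icode=(g_res.seqid.icode or "").strip(),
                    res_name=g_res.name,
                )
                by_name: dict[str, list] = {}
                for g_atom in g_res:
                    altloc = g_atom.altloc if g_atom.altloc not in ("\x00", " ") else ""
                    atom = Atom(
                        serial=g_atom.serial,
                        name=g_atom.name,
                        element=g_atom.element.name.upper(),
                        coords=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                        occupancy=min(max(float(g_atom.occ), 0.0), 1.0),
                        bfactor=float(g_atom.b_iso),
                        is_hetero=is_het,
                    )
                    by_name.setdefault(g_atom.name, []).append((atom.occupancy, altloc or "A", atom))
                res.atoms = sorted(_resolve_altlocs(by_name), key=lambda a: a.serial)
                if res.atoms:
                    chain.residues.append(res)
                    n_atoms_total += len(res.atoms)
            if chain.residues:
                chains.append(chain)
        models.append(chains)

    if n_atoms_total == 0:
        raise EmptyStructureError(f"{path}: no ATOM records after filtering")
    return Structure(models=models, title=st.name or path.stem)


def _format_atom_name(name: str, element: str) -> str:
    if len(name) >= 4:
        return name[:4]
    if len(element) == 1:
        return f" {name:<3}"
    return f"{name:<4}"


def write_structure(s: Structure, path) -> None:
    """Write fixed-column PDB; multi-model structures get MODEL/ENDMDL blocks."""
    if not s.models or all(not chains for chains in s.models):
        raise EmptyStructureError("refusing to write a structure with no models/atoms")
    lines: list[str] = []
    if s.title:
        lines.append(f"TITLE     {s.title[:70]}")
    multi = s.n_models > 1
    for m, chains in enumerate(s.models, start=1):
        if multi:
            lines.append(f"MODEL     {m:>4d}")
        serial = 0
        for chain in chains:
            if len(chain.chain_id) != 1:
                raise FormatError(
                    f"chain id {chain.chain_id!r} is not a single character; "
                    "relabel (e.g. Assembly.to_structure) before writing PDB"
                )
            for res in chain.residues:
                for atom in res.atoms:
                    serial += 1
                    x, y, z = atom.coords
                    for v in (x, y, z):
                        if not -999.999 <= v <= 9999.999:
                            raise FormatError(f"coordinate {v:.3f} exceeds PDB field width")
                    rec = "HETATM" if atom.is_hetero else "ATOM  "
                    lines.append(
                        f"{rec}{serial % 100000:>5d} {_format_atom_name(atom.name, atom.element)}"
                        f" {res.res_name:>3} {chain.chain_id}{res.seq_num:>4d}{res.icode or ' ':1}"
                        f"   {x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{atom.bfactor:6.2f}"
                        f"          {atom.element[:2]:>2}"
                    )
            serial += 1
            lines.append(f"TER   {serial % 100000:>5d}      {chain.residues[-1].res_name:>3} "
                         f"{chain.chain_id}{chain.residues[-1].seq_num:>4d}")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Assemblies


@dataclass(frozen=True)
class AssemblyCopy:
    copy_id: str
    structure: Structure
    transform: RigidTransform


class Assembly:
    """A multi-copy assembly: replicated structures under rigid transforms.

    Flattened chains get unique labels ``<copy_id>.<chain_id>`` so that
    homo-oligomer copies stay distinguishable in cross-link mapping.
    """

    def __init__(self, copies: Sequence[AssemblyCopy]):
        if not copies:
            raise StructureError("assembly needs at least one copy")
        for c in copies:
            c.transform.require_proper()
        self.copies = list(copies)
        labels = [f"{c.copy_id}.{ch.chain_id}" for c in self.copies for ch in c.structure.chains(0)]
        if len(labels) != len(set(labels)):
            raise StructureError("flattened chain labels are not unique")
        self._flat: list[FlatAtom] | None = None
        self._coords: np.ndarray | None = None
        self._ca_index: dict[tuple[str, int, str], int] | None = None

    @classmethod
    def from_structure(cls, s: Structure, copy_id: str = "c0") -> "Assembly":
        return cls([AssemblyCopy(copy_id, s, RigidTransform.identity())])

    @property
    def chain_labels(self) -> list[str]:
        return [f"{c.copy_id}.{ch.chain_id}" for c in self.copies for ch in c.structure.chains(0)]

    def _build(self) -> None:
        flat: list[FlatAtom] = []
        pts: list[np.ndarray] = []
        ca: dict[tuple[str, int, str], int] = {}
        i = 0
        for c in self.copies:
            for chain in c.structure.chains(0):
                label = f"{c.copy_id}.{chain.chain_id}"
                for res in chain.residues:
                    for atom in res.atoms:
                        flat.append(FlatAtom(i, c.copy_id, label, chain.chain_id,
                                             res.seq_num, res.icode, res.res_name,
                                             atom.name, atom.element, atom.is_hetero))
                        pts.append(atom.coords)
                        if atom.name == "CA":
                            ca[(label, res.seq_num, res.icode)] = i
                        i += 1
        coords = np.array(pts, dtype=float) if pts else np.zeros((0, 3))
        # apply per-copy transforms blockwise
        out = np.empty_like(coords)
        start = 0
        for c in self.copies:
            n = c.structure.n_atoms(0)
            out[start:start + n] = c.transform.apply(coords[start:start + n])
            start += n
        self._flat, self._coords, self._ca_index = flat, out, ca

    def flat_atoms(self) -> list[FlatAtom]:
        if self._flat is None:
            self._build()
        return self._flat

    def coords(self) -> np.ndarray:
        if self._coords is None:
            self._build()
        return self._coords

    @property
    def n_atoms(self) -> int:
        return len(self.flat_atoms())

    def ca_coord(self, chain_label: str, seq_num: int, icode: str = "") -> np.ndarray | None:
        if self._ca_index is None:
            self._build()
        idx = self._ca_index.get((chain_label, seq_num, icode))
        return None if idx is None else self.coords()[idx]

    def transformed(self, t: RigidTransform) -> "Assembly":
        """Compose *t* onto every copy (rigidly move the whole assembly)."""
        t.require_proper()
        return Assembly([AssemblyCopy(c.copy_id, c.structure, t.compose(c.transform))
                         for c in self.copies])

    def relabeled(self, prefix: str) -> "Assembly":
        return Assembly([AssemblyCopy(f"{prefix}{c.copy_id}", c.structure, c.transform)
                         for c in self.copies])

    @staticmethod
    def merge(*assemblies: "Assembly") -> "Assembly":
        copies: list[AssemblyCopy] = []
        for a in assemblies:
            copies.extend(a.copies)
        return Assembly(copies)

    def to_structure(self, title: str = "") -> Structure:
        """Flatten to a single-model Structure with fresh 1-char chain ids."""
        chains: list[Chain] = []
        k = 0
        for c in self.copies:
            for chain in c.structure.chains(0):
                if k >= len(_CHAIN_ALPHABET):
                    raise FormatError("too many chains for single-character PDB chain ids")
                new = Chain(chain_id=_CHAIN_ALPHABET[k])
                for res in chain.residues:
                    new_res = Residue(new.chain_id, res.seq_num, res.icode, res.res_name)
                    for atom in res.atoms:
                        new_res.atoms.append(Atom(atom.serial, atom.name, atom.element,
                                                  c.transform.apply(atom.coords),
                                                  atom.occupancy, atom.bfactor, atom.is_hetero))
                    new.residues.append(new_res)
                chains.append(new)
                k += 1
        return Structure(models=[chains], title=title)


def build_assembly(s: Structure, transforms: Sequence[RigidTransform],
                   copy_ids: Sequence[str] | None = None) -> Assembly:
    """Replicate *s* (model 1) under each proper rigid transform."""
    if not transforms:
        raise StructureError("need at least one transform")
    if copy_ids is None:
        copy_ids = [f"c{i}" for i in range(len(transforms))]
    if len(copy_ids) != len(transforms):
        raise StructureError("copy_ids and transforms length mismatch")
    return Assembly([AssemblyCopy(cid, s, t.require_proper())
                     for cid, t in zip(copy_ids, transforms)])


# ---------------------------------------------------------------------------
# Selections


@dataclass(frozen=True)
class Selection:
    """Predicate over (chain, residue range, atom names, element class).

    ``element_class``: ``all`` | ``heavy`` (no hydrogens) | ``ca`` | ``backbone``.
    Chain ids match either the flattened label (``c0.A``) or the bare chain id.
    """

    chain_ids: frozenset[str] | None = None
    seq_range: tuple[int, int] | None = None
    atom_names: frozenset[str] | None = None
    element_class: str = "all"

    def __post_init__(self):
        if self.element_class not in ("all", "heavy", "ca", "backbone"):
            raise SelectionParseError(f"unknown element class {self.element_class!r}")
        if self.chain_ids is not None:
            object.__setattr__(self, "chain_ids", frozenset(self.chain_ids))
        if self.atom_names is not None:
            object.__setattr__(self, "atom_names", frozenset(self.atom_names))

    @classmethod
    def parse(cls, expr: str) -> "Selection":
        """Parse e.g. ``"chain A; resi 78-133; name CA"`` or ``"class heavy"``."""
        kw: dict = {}
        for clause in expr.split(";"):
            clause = clause.strip()
            if not clause:
                continue
            parts = clause.split(None, 1)
            if len(parts) != 2:
                raise SelectionParseError(f"malformed clause {clause!r}")
            key, val = parts[0].lower(), parts[1].strip()
            if key == "chain":
                kw["chain_ids"] = frozenset(v.strip() for v in val.split(","))
            elif key == "resi":
                try:
                    if "-" in val:
                        lo, hi = val.split("-")
                        kw["seq_range"] = (int(lo), int(hi))
                    else:
                        kw["seq_range"] = (int(val), int(val))
                except ValueError as exc:
                    raise SelectionParseError(f"bad residue range {val!r}") from exc
            elif key == "name":
                kw["atom_names"] = frozenset(v.strip().upper() for v in val.split(","))
            elif key == "class":
                kw["element_class"] = val.lower()
            else:
                raise SelectionParseError(f"unknown selection keyword {key!r}")
        return cls(**kw)

    def matches(self, fa: FlatAtom) -> bool:
        if self.chain_ids is not None and fa.chain_label not in self.chain_ids \
                and fa.chain_id not in self.chain_ids:
            return False
        if self.seq_range is not None and not self.seq_range[0] <= fa.seq_num <= self.seq_range[1]:
            return False
        if self.atom_names is not None and fa.atom_name not in self.atom_names:
            return False
        ec = self.element_class
        if ec == "heavy" and fa.element == "H":
            return False
        if ec == "ca" and (fa.atom_name != "CA" or fa.is_hetero):
            return False
        if ec == "backbone" and fa.atom_name not in BACKBONE_NAMES:
            return False
        return True


def select_atoms(target, sel: Selection | str | None) -> np.ndarray:
    """Atom indices matching *sel* on an Assembly or Structure, flat order.

    The order is the deterministic flattened traversal (copy, chain, residue,
    atom); ``None`` selects everything.
    """
    if isinstance(sel, str):
        sel = Selection.parse(sel)
    flat = target.flat_atoms()
    if sel is None:
        return np.arange(len(flat), dtype=int)
    return np.array([fa.index for fa in flat if sel.matches(fa)], dtype=int)


# ---------------------------------------------------------------------------
# Transform files (one row = copy_id + 12 numbers)


def write_transform_file(transforms: dict[str, RigidTransform] | Sequence[tuple[str, RigidTransform]],
                         path) -> None:
    items = transforms.items() if isinstance(transforms, dict) else transforms
    lines = []
    for cid, t in items:
        nums = " ".join(f"{v:.17g}" for v in t.to_flat())
        lines.append(f"{cid} {nums}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_transform_file(path) -> list[tuple[str, RigidTransform]]:
    out = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 13:
            raise FormatError(f"{path}:{ln}: expected copy_id + 12 numbers, got {len(parts)} fields")
        out.append((parts[0], RigidTransform.from_flat([float(v) for v in parts[1:]])))
    return out
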