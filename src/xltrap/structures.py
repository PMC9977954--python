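"""Structure and ensemble handling for crosslink-guided modelling.

Coordinates are in Å throughout; residues are addressed by author (PDB)
numbering with insertion codes kept as part of the residue key.  Crosslink
distances are measured between *anchor atoms*: the Cβ of each residue, or
Cα for glycine, which has no Cβ.

Parsing is delegated to :mod:`gemmi`; only the first model of a file is
retained for a single :class:`Structure`, while multi-model files can be
loaded as a :class:`TrajectoryEnsemble`.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ResidueRef",
    "Structure",
    "TrajectoryEnsemble",
    "StructureError",
    "parse_structure",
    "parse_ensemble",
    "anchor_coordinate",
    "pair_distances",
    "superpose",
    "combine_structures",
]


class StructureError(ValueError):
    """Raised for parse failures, unresolvable residues or missing atoms."""


@dataclass(frozen=True)
class ResidueRef:
    """A residue addressed by chain id and author residue number.

    ``icode`` is the PDB insertion code ('' when absent); ``name`` is an
    optional expected 3-letter residue name, checked on lookup when given.
    """

    chain: str
    number: int
    icode: str = ""
    name: str | None = None

    def __post_init__(self) -> None:
        if not self.chain:
            raise ValueError("chain id must be non-empty")
        if not isinstance(self.number, (int, np.integer)):
            raise TypeError("residue number must be an integer")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, int(self.number), self.icode)

    def __str__(self) -> str:
        nm = f"({self.name})" if self.name else ""
        return f"{self.chain}:{self.number}{self.icode}{nm}"


@dataclass
class Residue:
    chain: str
    number: int
    icode: str
    name: str
    # atom name -> row index into the owning Structure's coordinate table
    atoms: dict[str, int] = field(default_factory=dict)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain, self.number, self.icode)


class Structure:
    """An atomic model: ordered residues plus a flat coordinate table.

    After altloc resolution at most one atom per (residue, atom name) is
    kept.  ``coords`` is an (n_atoms, 3) float64 array in Å.
    """

    def __init__(
        self,
        residues: list[Residue],
        atom_names: list[str],
        elements: list[str],
        coords: np.ndarray,
    ) -> None:
        coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        if len(atom_names) != len(coords) or len(elements) != len(coords):
            raise ValueError("atom table length mismatch")
        if coords.size and not np.isfinite(coords).all():
            raise StructureError("non-finite coordinates")
        self.residues = residues
        self.atom_names = list(atom_names)
        self.elements = list(elements)
        self.coords = coords
        self._index: dict[tuple[str, int, str], Residue] = {}
        for r in residues:
            if r.key in self._index:
                raise StructureError(f"duplicate residue {r.key}")
            self._index[r.key] = r

    # -- lookup ---------------------------------------------------------

    @property
    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain, None)
        return list(seen)

    def __len__(self) -> int:
        return len(self.residues)

    def residue(self, ref: ResidueRef) -> Residue:
        try:
            res = self._index[ref.key]
        except KeyError:
            raise StructureError(f"residue {ref} not found") from None
        if ref.name is not None and res.name != ref.name:
            raise StructureError(
                f"residue {ref} is {res.name}, expected {ref.name}"
            )
        return res

    def atom_coordinate(self, ref: ResidueRef, atom_name: str) -> np.ndarray:
        res = self.residue(ref)
        try:
            return self.coords[res.atoms[atom_name]]
        except KeyError:
            raise StructureError(f"atom {atom_name} absent in {ref}") from None

    def ca_coordinates(self, chain: str | None = None) -> np.ndarray:
        """Cα coordinates in residue order, optionally for one chain."""
        rows = [
            r.atoms["CA"]
            for r in self.residues
            if "CA" in r.atoms and (chain is None or r.chain == chain)
        ]
        return self.coords[rows]

    def residue_heavy_rows(self, ref: ResidueRef) -> list[int]:
        res = self.residue(ref)
        return [
            i for name, i in res.atoms.items() if self.elements[i] != "H"
        ]

    # -- transforms -----------------------------------------------------

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with coordinates mapped to ``R x + t``."""
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        new = Structure.__new__(Structure)
        new.residues = self.residues
        new.atom_names = self.atom_names
        new.elements = self.elements
        new.coords = self.coords @ R.T + t
        new._index = self._index
        return new

    def with_coords(self, coords: np.ndarray) -> "Structure":
        new = Structure.__new__(Structure)
        new.residues = self.residues
        new.atom_names = self.atom_names
        new.elements = self.elements
        new.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        new._index = self._index
        return new

    # -- output ---------------------------------------------------------

    def to_gemmi(self) -> gemmi.Structure:
        st = gemmi.Structure()
        st.add_model(_model_from(self, self.coords))
        st.setup_entities()
        return st

    def to_pdb_string(self) -> str:
        return self.to_gemmi().make_pdb_string()

    def write_pdb(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_pdb_string())


def _model_from(struct: Structure, coords: np.ndarray, name: str = "1") -> gemmi.Model:
    model = gemmi.Model(name)
    chain_obj: gemmi.Chain | None = None
    for res in struct.residues:
        if chain_obj is None or chain_obj.name != res.chain:
            chain_obj = gemmi.Chain(res.chain)
            model.add_chain(chain_obj)
            chain_obj = model[-1]
        g_res = gemmi.Residue()
        g_res.name = res.name
        g_res.seqid = gemmi.SeqId(res.number, res.icode or " ")
        for atom_name, row in res.atoms.items():
            a = gemmi.Atom()
            a.name = atom_name
            a.element = gemmi.Element(struct.elements[row])
            x, y, z = coords[row]
            a.pos = gemmi.Position(x, y, z)
            a.occ = 1.0
            g_res.add_atom(a)
        chain_obj.add_residue(g_res)
    return model


@dataclass
class TrajectoryEnsemble:
    """Ordered coordinate frames sharing one atom topology.

    ``topology`` carries residue/atom bookkeeping; ``frames`` is an
    (n_frames, n_atoms, 3) array.  Optional ``times`` are free-unit stamps.
    """

    topology: Structure
    frames: np.ndarray
    times: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.topology.coords):
            raise ValueError("frame atom count does not match topology")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.frames[i])

    def to_pdb_string(self) -> str:
        st = gemmi.Structure()
        for i in range(self.n_frames):
            st.add_model(_model_from(self.topology, self.frames[i], name=str(i + 1)))
        st.setup_entities()
        return st.make_pdb_string()

    def write_pdb(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_pdb_string())


# ---------------------------------------------------------------------------
# parsing


def _read_gemmi(text: str, fmt: str) -> gemmi.Structure:
    if not text.strip():
        raise StructureError("empty structure file")
    fmt = fmt.lower()
    try:
        if fmt == "pdb":
            return gemmi.read_pdb_string(text)
        if fmt in ("mmcif", "cif"):
            doc = gemmi.cif.read_string(text)
            return gemmi.make_structure_from_block(doc.sole_block())
    except (RuntimeError, ValueError) as exc:
        raise StructureError(f"malformed {fmt} input: {exc}") from exc
    raise ValueError(f"unknown format {fmt!r}; expected 'pdb' or 'mmcif'")


def _structure_from_model(model: gemmi.Model, drop_hydrogens: bool) -> Structure:
    residues: list[Residue] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords: list[tuple[float, float, float]] = []
    for chain in model:
        for g_res in chain:
            icode = g_res.seqid.icode.strip()
            res = Residue(chain.name, g_res.seqid.num, icode, g_res.name)
            # altloc resolution: keep highest occupancy, ties alphabetically
            best: dict[str, gemmi.Atom] = {}
            for atom in g_res:
                if drop_hydrogens and atom.element.name == "H":
                    continue
                prev = best.get(atom.name)
                if prev is None:
                    best[atom.name] = atom
                    continue
                if atom.occ > prev.occ or (
                    atom.occ == prev.occ and atom.altloc < prev.altloc
                ):
                    best[atom.name] = atom
            for name, atom in best.items():
                res.atoms[name] = len(coords)
                atom_names.append(name)
                elements.append(atom.element.name)
                coords.append((atom.pos.x, atom.pos.y, atom.pos.z))
            residues.append(res)
    if not residues:
        raise StructureError("no residues in model")
    return Structure(residues, atom_names, elements, np.array(coords, dtype=float))


def parse_structure(text: str, format: str = "pdb", drop_hydrogens: bool = True) -> Structure:
    """Parse structure-file content; only the first model is retained.

    Alternative locations are resolved to the highest-occupancy atom
    (ties broken alphabetically by altloc id).
    """
    st = _read_gemmi(text, format)
    if len(st) == 0:
        raise StructureError("structure contains no models")
    return _structure_from_model(st[0], drop_hydrogens)


def parse_ensemble(text: str, format: str = "pdb", drop_hydrogens: bool = True) -> TrajectoryEnsemble:
    """Parse a multi-model file as an ordered ensemble of frames.

    All models must share the first model's atom topology.
    """
    st = _read_gemmi(text, format)
    if len(st) == 0:
        raise StructureError("structure contains no models")
    topo = _structure_from_model(st[0], drop_hydrogens)
    frames = [topo.coords]
    for k in range(1, len(st)):
        frame = _structure_from_model(st[k], drop_hydrogens)
        if frame.atom_names != topo.atom_names or len(frame.residues) != len(topo.residues):
            raise StructureError(f"model {k + 1} topology differs from model 1")
        frames.append(frame.coords)
    return TrajectoryEnsemble(topo, np.stack(frames))


def load_structure(path: str, drop_hydrogens: bool = True) -> Structure:
    fmt = "mmcif" if str(path).endswith((".cif", ".mmcif")) else "pdb"
    with open(path) as fh:
        return parse_structure(fh.read(), fmt, drop_hydrogens)


def load_ensemble(path: str, drop_hydrogens: bool = True) -> TrajectoryEnsemble:
    fmt = "mmcif" if str(path).endswith((".cif", ".mmcif")) else "pdb"
    with open(path) as fh:
        return parse_ensemble(fh.read(), fmt, drop_hydrogens)


# ---------------------------------------------------------------------------
# anchors and distances


def anchor_coordinate(
    structure: Structure, ref: ResidueRef, fallback_calpha: bool = False
) -> np.ndarray:
    """Cβ position of a residue; Cα for glycine.

    For a non-glycine residue lacking a Cβ the default is a hard error;
    with ``fallback_calpha`` the Cα is used and a warning logged.
    """
    res = structure.residue(ref)
    if res.name == "GLY":
        anchor = "CA"
    elif "CB" in res.atoms:
        anchor = "CB"
    elif fallback_calpha:
        logger.warning("residue %s lacks CB; falling back to CA", ref)
        anchor = "CA"
    else:
        raise StructureError(f"residue {ref} ({res.name}) has no CB anchor")
    try:
        return structure.coords[res.atoms[anchor]]
    except KeyError:
        raise StructureError(f"residue {ref} lacks anchor atom {anchor}") from None


def pair_distances(
    structure: Structure,
    pairs: Sequence[tuple[ResidueRef, ResidueRef]],
    fallback_calpha: bool = False,
) -> np.ndarray:
    """Euclidean anchor–anchor distance (Å) per pair, order-preserving."""
    out = np.empty(len(pairs))
    for i, (a, b) in enumerate(pairs):
        try:
            pa = anchor_coordinate(structure, a, fallback_calpha)
            pb = anchor_coordinate(structure, b, fallback_calpha)
        except StructureError as exc:
            raise StructureError(f"pair ({a}, {b}): {exc}") from exc
        out[i] = float(np.linalg.norm(pa - pb))
    return out


# ---------------------------------------------------------------------------
# superposition


def superpose(
    mobile: np.ndarray, reference: np.ndarray
) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(R, t, rmsd)`` with ``R`` a proper rotation (det +1) such
    that ``R @ x + t`` best fits the reference (Kabsch).  Requires at
    least 3 points with non-collinear spread in both sets.
    """
    mob = np.asarray(mobile, dtype=float).reshape(-1, 3)
    ref = np.asarray(reference, dtype=float).reshape(-1, 3)
    if mob.shape != ref.shape:
        raise ValueError("point sets must have equal shapes")
    n = len(mob)
    if n < 3:
        raise StructureError("superposition needs at least 3 points")
    mob_c = mob - mob.mean(axis=0)
    ref_c = ref - ref.mean(axis=0)
    for pts in (mob_c, ref_c):
        sv = np.linalg.svd(pts, compute_uv=False)
        if sv[1] <= 1e-9 * max(sv[0], 1.0):
            raise StructureError("degenerate (collinear) point spread")
    H = mob_c.T @ ref_c
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ref.mean(axis=0) - R @ mob.mean(axis=0)
    fitted = mob @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    return R, t, rmsd


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD without fitting."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def combine_structures(*parts: Structure) -> Structure:
    """Concatenate structures (e.g. receptor + arrestin) into one model.

    Chain ids must not collide between parts.
    """
    residues: list[Residue] = []
    atom_names: list[str] = []
    elements: list[str] = []
    coords_list = []
    offset = 0
    seen_chains: set[str] = set()
    for part in parts:
        if seen_chains & set(part.chains):
            raise StructureError("chain id collision while combining structures")
        seen_chains |= set(part.chains)
        for res in part.residues:
            new = Residue(res.chain, res.number, res.icode, res.name)
            new.atoms = {name: row + offset for name, row in res.atoms.items()}
            residues.append(new)
        atom_names.extend(part.atom_names)
        elements.extend(part.elements)
        coords_list.append(part.coords)
        offset += len(part.coords)
    return Structure(residues, atom_names, elements, np.vstack(coords_list))
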