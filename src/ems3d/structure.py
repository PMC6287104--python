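"""Molecular structures: atoms with charges and radii, PQR/PDB I/O,
parameter assignment and rigid-body superposition.

A :class:`Molecule` is the solver's source term and surface definition: an
ordered list of atoms, each carrying Cartesian coordinates (Angstrom), a
partial charge (elementary charges) and a van der Waals radius (Angstrom).
PQR files carry charges and radii directly; PDB files carry coordinates
only, and charges/radii are filled in from a packaged PARSE-like residue
parameter table (:func:`assign_parameters`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np


class StructureError(ValueError):
    """Malformed structure input or invalid structural operation."""


@dataclass
class Atom:
    """One atom: name, element, position (A), charge (e), vdW radius (A)."""

    name: str
    element: str
    position: np.ndarray
    charge: float = 0.0
    radius: float = 0.0
    residue_index: int = 0
    chain_id: str = ""
    residue_name: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise StructureError(f"atom {self.name!r}: position must be a finite 3-vector")
        if self.radius < 0:
            raise StructureError(f"atom {self.name!r}: negative radius {self.radius}")


@dataclass
class Molecule:
    """An ordered collection of atoms with a text label."""

    label: str
    atoms: list[Atom]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise StructureError(f"molecule {self.label!r} has no atoms")

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coordinates(self) -> np.ndarray:
        """(n, 3) coordinate array in Angstrom."""
        return np.array([a.position for a in self.atoms], dtype=float)

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms], dtype=float)

    @property
    def radii(self) -> np.ndarray:
        return np.array([a.radius for a in self.atoms], dtype=float)

    @property
    def total_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def geometric_center(self) -> np.ndarray:
        return self.coordinates.mean(axis=0)


@dataclass
class RigidTransform:
    """Proper rigid-body transform y = R x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        if self.rotation.shape != (3, 3) or self.translation.shape != (3,):
            raise StructureError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(self.rotation @ self.rotation.T, np.eye(3), atol=1e-8):
            raise StructureError("rotation matrix is not orthonormal")
        if abs(np.linalg.det(self.rotation) - 1.0) > 1e-9:
            raise StructureError("rotation matrix determinant is not +1")

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, dtype=float) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Transform equivalent to applying ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


def transform_molecule(molecule: Molecule, transform: RigidTransform) -> Molecule:
    """Return a copy of ``molecule`` with transformed coordinates."""
    atoms = [replace(a, position=transform.apply(a.position)) for a in molecule.atoms]
    return Molecule(molecule.label, atoms, dict(molecule.meta))


# ---------------------------------------------------------------------------
# PQR / PDB input and output


def read_pqr(path: str | Path) -> Molecule:
    """Read a whitespace-delimited PQR file.

    Each ATOM/HETATM record carries, after the coordinates, the partial
    charge (e) and radius (A) in the last two columns.  Chain identifiers
    are optional (both the 10- and 11-field dialects are accepted).
    """
    path = Path(path)
    atoms: list[Atom] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.startswith(("ATOM", "HETATM")):
                continue
            fields = line.split()
            if len(fields) not in (10, 11):
                raise StructureError(
                    f"{path.name}:{lineno}: expected 10 or 11 fields in PQR record, "
                    f"got {len(fields)}"
                )
            has_chain = len(fields) == 11
            try:
                name = fields[2]
                resname = fields[3]
                chain = fields[4] if has_chain else ""
                resseq = int(fields[5 if has_chain else 4])
                x, y, z, q, r = (float(v) for v in fields[-5:])
            except ValueError as exc:
                raise StructureError(f"{path.name}:{lineno}: malformed PQR record: {exc}") from exc
            atoms.append(
                Atom(
                    name=name,
                    element=_guess_element(name),
                    position=np.array([x, y, z]),
                    charge=q,
                    radius=r,
                    residue_index=resseq,
                    chain_id=chain,
                    residue_name=resname,
                )
            )
    if not atoms:
        raise StructureError(f"{path.name}: no ATOM/HETATM records found")
    return Molecule(path.stem, atoms)


def write_pqr(molecule: Molecule, path: str | Path) -> None:
    """Write ``molecule`` in the whitespace-delimited PQR dialect."""
    with open(path, "w") as fh:
        for i, a in enumerate(molecule.atoms, start=1):
            chain = a.chain_id if a.chain_id else ""
            fields = [
                "ATOM", f"{i:d}", a.name, a.residue_name or "UNK",
            ]
            if chain:
                fields.append(chain)
            fields += [
                f"{a.residue_index:d}",
                f"{a.position[0]:.4f}", f"{a.position[1]:.4f}", f"{a.position[2]:.4f}",
                f"{a.charge:.4f}", f"{a.radius:.4f}",
            ]
            fh.write(" ".join(fields) + "\n")


def read_pdb(path: str | Path) -> Molecule:
    """Read coordinates from a PDB file (gemmi); charges/radii left at zero.

    Use :func:`assign_parameters` afterwards to fill charges and radii.
    """
    import gemmi

    path = Path(path)
    st = gemmi.read_structure(str(path))
    atoms: list[Atom] = []
    if len(st) == 0:
        raise StructureError(f"{path.name}: no models")
    model = st[0]
    for chain in model:
        for residue in chain:
            for at in residue:
                atoms.append(
                    Atom(
                        name=at.name,
                        element=at.element.name,
                        position=np.array([at.pos.x, at.pos.y, at.pos.z]),
                        residue_index=residue.seqid.num,
                        chain_id=chain.name,
                        residue_name=residue.name,
                    )
                )
    if not atoms:
        raise StructureError(f"{path.name}: no atoms")
    return Molecule(path.stem, atoms)


# ---------------------------------------------------------------------------
# Parameter assignment

#: element -> vdW radius fallback (A); PARSE-style values
_ELEMENT_RADII = {"H": 1.0, "C": 1.7, "N": 1.5, "O": 1.4, "S": 1.85, "P": 1.9}
_DEFAULT_RADIUS = 1.7


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].capitalize() in ("Cl", "Br", "Fe", "Zn", "Mg", "Na"):
        return stripped[:2].capitalize()
    return stripped[0].upper()


def load_parameter_table() -> dict[tuple[str, str], tuple[float, float]]:
    """Load the packaged PARSE-like (residue, atom) -> (charge, radius) table."""
    table: dict[tuple[str, str], tuple[float, float]] = {}
    ref = importlib.resources.files("ems3d.data").joinpath("parse_params.csv")
    with ref.open() as fh:
        header = fh.readline()
        assert header.startswith("residue")
        for line in fh:
            res, atom, charge, radius = line.strip().split(",")
            table[(res, atom)] = (float(charge), float(radius))
    return table


def assign_parameters(
    molecule: Molecule,
    table: Mapping[tuple[str, str], tuple[float, float]] | None = None,
    allow_fallback: bool = True,
) -> Molecule:
    """Fill atom charges and radii from a (residue, atom) parameter table.

    Atoms without a table entry receive charge 0 and an element-based radius
    when ``allow_fallback`` is true; their names are recorded in
    ``molecule.meta["unmatched_atoms"]``.  With ``allow_fallback=False`` any
    unmatched atom raises, naming the offending atoms.
    """
    if table is None:
        table = load_parameter_table()
    atoms: list[Atom] = []
    unmatched: list[str] = []
    for a in molecule.atoms:
        key = (a.residue_name.upper(), a.name.upper())
        if key in table:
            charge, radius = table[key]
        else:
            unmatched.append(f"{a.residue_name}/{a.name}")
            charge = 0.0
            radius = _ELEMENT_RADII.get(a.element.capitalize(), _DEFAULT_RADIUS)
        atoms.append(replace(a, charge=charge, radius=radius))
    if unmatched and not allow_fallback:
        raise StructureError(
            "no parameter entry for atoms: " + ", ".join(sorted(set(unmatched)))
        )
    out = Molecule(molecule.label, atoms, dict(molecule.meta))
    out.meta["unmatched_atoms"] = unmatched
    return out


# ---------------------------------------------------------------------------
# Superposition


def _default_pairs(mobile: Molecule, reference: Molecule) -> list[tuple[int, int]]:
    """Pair C-alpha atoms by (chain, residue index); fall back to index pairing."""
    mob = {
        (a.chain_id, a.residue_index): i
        for i, a in enumerate(mobile.atoms)
        if a.name.upper() == "CA" and a.element.upper() == "C"
    }
    pairs = [
        (mob[(a.chain_id, a.residue_index)], j)
        for j, a in enumerate(reference.atoms)
        if a.name.upper() == "CA"
        and a.element.upper() == "C"
        and (a.chain_id, a.residue_index) in mob
    ]
    if len(pairs) >= 3:
        return pairs
    if len(mobile) == len(reference):
        return [(i, i) for i in range(len(mobile))]
    raise StructureError(
        "cannot derive an atom correspondence (need shared C-alpha atoms or equal "
        "atom counts); pass explicit pairs"
    )


def kabsch_superpose(
    mobile: Molecule,
    reference: Molecule,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> RigidTransform:
    """Least-squares optimal rigid transform taking ``mobile`` onto ``reference``.

    ``pairs`` lists (mobile_index, reference_index) atom correspondences;
    when omitted, C-alpha atoms are matched by residue index (equal-length
    molecules fall back to index pairing).  Requires at least three
    non-collinear pairs.
    """
    if pairs is None:
        pairs = _default_pairs(mobile, reference)
    if len(pairs) < 3:
        raise StructureError(f"need at least 3 atom pairs for superposition, got {len(pairs)}")
    mob_idx, ref_idx = zip(*pairs)
    p = mobile.coordinates[list(mob_idx)]
    q = reference.coordinates[list(ref_idx)]
    p_c = p - p.mean(axis=0)
    q_c = q - q.mean(axis=0)
    span = max(np.linalg.norm(p_c, axis=1).max(), 1.0)
    if np.linalg.matrix_rank(p_c, tol=1e-6 * span) < 2:
        raise StructureError("superposition pairs are collinear")
    h = p_c.T @ q_c
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = q.mean(axis=0) - rot @ p.mean(axis=0)
    return RigidTransform(rot, trans)


def superposition_rmsd(
    mobile: Molecule,
    reference: Molecule,
    transform: RigidTransform,
    pairs: Sequence[tuple[int, int]] | None = None,
) -> float:
    """RMSD over paired atoms after applying ``transform`` to ``mobile``."""
    if pairs is None:
        pairs = _default_pairs(mobile, reference)
    mob_idx, ref_idx = zip(*pairs)
    moved = transform.apply(mobile.coordinates[list(mob_idx)])
    diff = moved - reference.coordinates[list(ref_idx)]
    return float(np.sqrt((diff**2).sum(axis=1).mean()))


def make_point_charge(
    q: float, radius: float, position: Iterable[float] = (0.0, 0.0, 0.0), label: str = "ion"
) -> Molecule:
    """A one-atom molecule: a spherical ion of charge ``q`` (e) and vdW ``radius`` (A)."""
    if radius <= 0:
        raise StructureError("point-charge radius must be positive")
    atom = Atom(
        name="Q", element="X", position=np.asarray(list(position), dtype=float),
        charge=q, radius=radius, residue_index=1, residue_name="ION",
    )
    return Molecule(label, [atom])
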