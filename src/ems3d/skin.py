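"""Molecular-skin extraction and Hodgkin-index comparison of potentials.

Potentials are compared in a shell ("skin") of lattice nodes lying at a
distance sigma to sigma+delta above the molecule's van der Waals surface:
node p belongs to the skin iff  sigma <= d(p) < sigma + delta  with
d(p) = min_i (|p - x_i| - r_i).  Over the intersection of two molecules'
skins (both grids on one common frame), similarity is measured by the
Hodgkin index

    SI = 2 sum(a b) / (sum a^2 + sum b^2)   in [-1, 1]

and reported as the electrostatic similarity distance, the monotone map of
SI onto [0, 2] with the conventional anchor points: ESD = 1 - SI, so 0
means electrostatic identity (SI = 1), 2 anticorrelation of equal
magnitude (SI = -1) and 1 no apparent correlation (SI = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pbgrid import GridGeometry, PotentialGrid, SolverConfig, min_surface_distance, solve_lpb
from .structure import Molecule, kabsch_superpose, transform_molecule


class SkinError(ValueError):
    """Empty or incompatible skin/grid comparison."""


@dataclass
class SkinParams:
    """Skin geometry: stand-off ``sigma`` and thickness ``delta`` (Angstrom)."""

    sigma: float = 3.0
    delta: float = 4.0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise SkinError("sigma must be >= 0")
        if self.delta <= 0:
            raise SkinError("delta must be > 0")


@dataclass
class SkinMask:
    """Boolean membership flags on a lattice (same geometry as the potential)."""

    origin: tuple[float, float, float]
    spacing: float
    members: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.members = np.asarray(self.members, dtype=bool)
        if self.members.ndim != 3:
            raise SkinError("mask must be a 3-D boolean array")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.origin), self.spacing, self.members.shape)

    @property
    def n_points(self) -> int:
        return int(self.members.sum())

    def intersect(self, other: "SkinMask") -> "SkinMask":
        if not self.geometry.same_as(other.geometry):
            raise SkinError("cannot intersect masks on different grid geometries")
        return SkinMask(self.origin, self.spacing, self.members & other.members)


@dataclass
class SimilarityResult:
    """Hodgkin index and ESD for one pair of fields over one skin."""

    si: float
    esd: float
    n_points: int


def compute_skin(molecule: Molecule, geometry: GridGeometry, params: SkinParams) -> SkinMask:
    """Skin mask of ``molecule`` on ``geometry``: sigma <= d(p) < sigma + delta."""
    d = min_surface_distance(geometry, molecule)
    members = (d >= params.sigma) & (d < params.sigma + params.delta)
    if not members.any():
        raise SkinError(
            f"empty skin for {molecule.label!r} (sigma={params.sigma}, delta={params.delta}); "
            "grid may not cover the shell"
        )
    return SkinMask(tuple(geometry.origin), geometry.spacing, members)


def hodgkin_index(
    grid_a: PotentialGrid, grid_b: PotentialGrid, mask: SkinMask
) -> SimilarityResult:
    """Hodgkin similarity of two potentials over the masked nodes.

    Both grids and the mask must share one geometry.  Raises if both fields
    are identically zero on the mask (the index is undefined there, and a
    silent default would hide solver failures).
    """
    geom = grid_a.geometry
    if not geom.same_as(grid_b.geometry):
        raise SkinError("potential grids have different geometries")
    if not geom.same_as(mask.geometry):
        raise SkinError("mask geometry does not match the potential grids")
    if mask.n_points < 1:
        raise SkinError("mask has no member nodes")
    a = grid_a.values[mask.members]
    b = grid_b.values[mask.members]
    denom = float(a @ a + b @ b)
    if denom == 0.0:
        raise SkinError("both fields are identically zero on the skin; Hodgkin index undefined")
    si = 2.0 * float(a @ b) / denom
    return SimilarityResult(si=si, esd=1.0 - si, n_points=int(a.size))


def compare_pair(
    mol_a: Molecule,
    grid_a: PotentialGrid,
    mol_b: Molecule,
    grid_b: PotentialGrid,
    params: SkinParams | None = None,
) -> SimilarityResult:
    """ESD between two molecules' potentials over the intersection of their skins.

    Both grids must already live on one common frame (the structures are
    superposed before solving; see :func:`compare_molecules`).  The
    comparison region is the boolean AND of the two molecules' own skins.
    """
    if params is None:
        params = SkinParams()
    geom = grid_a.geometry
    if not geom.same_as(grid_b.geometry):
        raise SkinError("grids are not on a common frame; superpose structures before solving")
    skin = compute_skin(mol_a, geom, params).intersect(compute_skin(mol_b, geom, params))
    if skin.n_points == 0:
        raise SkinError(
            f"empty skin intersection between {mol_a.label!r} and {mol_b.label!r}"
        )
    return hodgkin_index(grid_a, grid_b, skin)


def compare_molecules(
    mol_a: Molecule,
    mol_b: Molecule,
    config: SolverConfig | None = None,
    params: SkinParams | None = None,
    pairs=None,
) -> SimilarityResult:
    """Superpose ``mol_b`` onto ``mol_a``, solve both potentials on one shared
    grid, and return their skin-intersection similarity.

    ``pairs`` is forwarded to :func:`ems3d.structure.kabsch_superpose`.
    """
    if config is None:
        config = SolverConfig()
    transform = kabsch_superpose(mol_b, mol_a, pairs=pairs)
    mol_b_moved = transform_molecule(mol_b, transform)
    center = (mol_a.geometric_center + mol_b_moved.geometric_center) / 2.0
    geometry = GridGeometry.centered(center, config.grid_points_per_side, config.spacing)
    grid_a = solve_lpb(mol_a, config, geometry)
    grid_b = solve_lpb(mol_b_moved, config, geometry)
    return compare_pair(mol_a, grid_a, mol_b_moved, grid_b, params)
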