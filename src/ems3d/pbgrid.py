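"""Finite-difference linearized Poisson-Boltzmann solver on a cubic lattice.

The electrostatic potential u (dimensionless, kT/e) of a molecule immersed
in a univalent ionic solution satisfies the linearized PB equation

    div( eps(x) grad u ) - eps_s * kappa^2 * a(x) * u = -4 pi l0 sum_i q_i delta(x - x_i)

with eps(x) the piecewise dielectric (eps_protein inside the union of atom
van der Waals spheres, eps_solvent outside), a(x) the ion-accessibility
indicator (zero inside atom spheres inflated by the probe radius), kappa
the inverse Debye length of the solvent and l0 = e^2/(4 pi eps0 kT) the
vacuum Coulomb scale length in Angstrom.

Discretization is the standard flux-conserving 7-point stencil: face
dielectrics are harmonic means of the two adjacent node values, point
charges are spread onto the 8 surrounding nodes with trilinear weights, and
Dirichlet boundary values are the superposition of per-atom Debye-Hueckel
screened-Coulomb spheres.  The linear system is solved with red-black
successive over-relaxation to a relative infinity-norm residual tolerance.

Grids are read and written in the OpenDX scalar-grid dialect used by APBS.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .constants import coulomb_scale_length, debye_kappa


class GridError(ValueError):
    """Invalid grid geometry or malformed grid file."""


class ConvergenceError(RuntimeError):
    """The iterative solver failed to reach the residual tolerance."""


@dataclass(frozen=True)
class GridGeometry:
    """Regular cubic lattice: origin (A), uniform spacing (A), node counts."""

    origin: tuple[float, float, float]
    spacing: float
    dims: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridError("grid spacing must be positive")
        if any(d < 1 for d in self.dims):
            raise GridError("grid dims must all be >= 1")

    @classmethod
    def centered(cls, center: np.ndarray, n: int, spacing: float) -> "GridGeometry":
        center = np.asarray(center, dtype=float)
        half = (n - 1) * spacing / 2.0
        origin = tuple(float(c - half) for c in center)
        return cls(origin, float(spacing), (n, n, n))

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[k] + self.spacing * np.arange(self.dims[k]) for k in range(3)
        )

    def extent(self) -> np.ndarray:
        """(2, 3) array of [min corner; max corner] node coordinates."""
        lo = np.array(self.origin)
        hi = lo + self.spacing * (np.array(self.dims) - 1)
        return np.vstack([lo, hi])

    def node_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ax, ay, az = self.axes()
        return ax[:, None, None], ay[None, :, None], az[None, None, :]

    def same_as(self, other: "GridGeometry", tol: float = 1e-9) -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass
class SolverConfig:
    """Solver parameters.

    Defaults are the production configuration for protein-scale work:
    a 353^3 cubic grid at 0.33 A spacing, 0.15 M univalent salt, protein
    dielectric 2, solvent dielectric 78, temperature 310 K and a 1.4 A
    ion-exclusion probe.  Desk-scale studies use much smaller grids.
    """

    grid_points_per_side: int = 353
    spacing: float = 0.33
    ionic_strength: float = 0.15
    eps_protein: float = 2.0
    eps_solvent: float = 78.0
    temperature: float = 310.0
    probe_radius: float = 1.4
    convergence_tol: float = 1e-6
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise GridError("spacing must be positive")
        if self.grid_points_per_side < 9:
            raise GridError("grid_points_per_side must be >= 9")
        if self.eps_protein < 1 or self.eps_solvent < 1:
            raise GridError("dielectric constants must be >= 1")
        if self.ionic_strength < 0:
            raise GridError("ionic strength must be >= 0")
        if self.temperature <= 0:
            raise GridError("temperature must be positive")

    @property
    def kappa(self) -> float:
        """Inverse Debye length of the solvent (A^-1)."""
        return debye_kappa(self.ionic_strength, self.temperature, self.eps_solvent)


@dataclass
class PotentialGrid:
    """Scalar electrostatic potential on a regular lattice, in kT/e."""

    origin: tuple[float, float, float]
    spacing: float
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise GridError("potential values must be a 3-D array")
        if not np.all(np.isfinite(self.values)):
            raise GridError("potential contains non-finite values")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(tuple(self.origin), self.spacing, self.values.shape)

    def sample(self, point: np.ndarray) -> float:
        """Trilinear interpolation of the potential at a Cartesian point."""
        f = (np.asarray(point, dtype=float) - np.array(self.origin)) / self.spacing
        i0 = np.floor(f).astype(int)
        if np.any(i0 < 0) or np.any(i0 + 1 > np.array(self.dims) - 1):
            raise GridError(f"point {point} outside grid")
        w = f - i0
        out = 0.0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = (
                        (w[0] if dx else 1 - w[0])
                        * (w[1] if dy else 1 - w[1])
                        * (w[2] if dz else 1 - w[2])
                    )
                    out += wt * self.values[i0[0] + dx, i0[1] + dy, i0[2] + dz]
        return float(out)


# ---------------------------------------------------------------------------
# Region maps


def build_region_maps(
    molecule, config: SolverConfig, geometry: GridGeometry
) -> tuple[np.ndarray, np.ndarray]:
    """Dielectric and ion-accessibility maps on the lattice.

    The dielectric is ``eps_protein`` at nodes strictly inside the union of
    atom van der Waals spheres and ``eps_solvent`` elsewhere.  Ion
    accessibility is 0 (screening switched off) at nodes inside atom spheres
    inflated by the probe radius, 1 outside.
    """
    eps = np.full(geometry.dims, config.eps_solvent, dtype=float)
    ion = np.ones(geometry.dims, dtype=float)
    ax, ay, az = geometry.axes()
    h = geometry.spacing
    for center, radius in zip(molecule.coordinates, molecule.radii):
        for cutoff, target, value in (
            (radius, eps, config.eps_protein),
            (radius + config.probe_radius, ion, 0.0),
        ):
            if cutoff <= 0:
                continue
            sl = []
            ok = True
            for k, axis in enumerate((ax, ay, az)):
                lo = int(np.searchsorted(axis, center[k] - cutoff))
                hi = int(np.searchsorted(axis, center[k] + cutoff, side="right"))
                if lo >= hi:
                    ok = False
                    break
                sl.append(slice(lo, hi))
            if not ok:
                continue
            xs = ax[sl[0]][:, None, None] - center[0]
            ys = ay[sl[1]][None, :, None] - center[1]
            zs = az[sl[2]][None, None, :] - center[2]
            inside = xs**2 + ys**2 + zs**2 < cutoff**2
            target[tuple(sl)][inside] = value
    # unused h kept out; geometry spacing only needed for the searchsorted pads
    del h
    return eps, ion


def min_surface_distance(geometry: GridGeometry, molecule) -> np.ndarray:
    """Signed distance from each node to the molecule's van der Waals surface.

    d(p) = min over atoms of (|p - x_i| - r_i); negative inside the surface.
    """
    xs, ys, zs = geometry.node_coordinates()
    dist = np.full(geometry.dims, np.inf)
    for center, radius in zip(molecule.coordinates, molecule.radii):
        d = np.sqrt((xs - center[0]) ** 2 + (ys - center[1]) ** 2 + (zs - center[2]) ** 2)
        np.minimum(dist, d - radius, out=dist)
    return dist


# ---------------------------------------------------------------------------
# Solver


def _boundary_condition(
    u: np.ndarray, geometry: GridGeometry, molecule, config: SolverConfig
) -> None:
    """Fill the 6 faces of ``u`` with superposed Debye-Hueckel sphere potentials.

    Each atom contributes q * l0 / (eps_s * d) * exp(-kappa (d - r)) / (1 + kappa r),
    the screened Coulomb potential outside a sphere of radius r.
    """
    l0 = coulomb_scale_length(config.temperature)
    kappa = config.kappa
    ax, ay, az = geometry.axes()
    nx, ny, nz = geometry.dims
    faces = [
        (np.index_exp[0, :, :], np.meshgrid(ax[:1], ay, az, indexing="ij")),
        (np.index_exp[-1, :, :], np.meshgrid(ax[-1:], ay, az, indexing="ij")),
        (np.index_exp[:, 0, :], np.meshgrid(ax, ay[:1], az, indexing="ij")),
        (np.index_exp[:, -1, :], np.meshgrid(ax, ay[-1:], az, indexing="ij")),
        (np.index_exp[:, :, 0], np.meshgrid(ax, ay, az[:1], indexing="ij")),
        (np.index_exp[:, :, -1], np.meshgrid(ax, ay, az[-1:], indexing="ij")),
    ]
    coords = molecule.coordinates
    charges = molecule.charges
    radii = molecule.radii
    for idx, (gx, gy, gz) in faces:
        phi = np.zeros(gx.shape)
        for (cx, cy, cz), q, r in zip(coords, charges, radii):
            if q == 0.0:
                continue
            d = np.sqrt((gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2)
            d = np.maximum(d, 1e-6)
            phi += q * l0 / (config.eps_solvent * d) * np.exp(-kappa * (d - r)) / (1.0 + kappa * r)
        u[idx] = phi.reshape(u[idx].shape)


def _spread_charges(geometry: GridGeometry, molecule) -> np.ndarray:
    """Trilinear deposition of point charges onto lattice nodes (units: e)."""
    qgrid = np.zeros(geometry.dims)
    origin = np.array(geometry.origin)
    h = geometry.spacing
    for center, q in zip(molecule.coordinates, molecule.charges):
        if q == 0.0:
            continue
        f = (center - origin) / h
        i0 = np.floor(f).astype(int)
        if np.any(i0 < 0) or np.any(i0 + 1 > np.array(geometry.dims) - 1):
            raise GridError("charge lies outside the grid")
        w = f - i0
        for dx in (0, 1):
            for dy in (0, 1):
                for dz in (0, 1):
                    wt = (
                        (w[0] if dx else 1 - w[0])
                        * (w[1] if dy else 1 - w[1])
                        * (w[2] if dz else 1 - w[2])
                    )
                    qgrid[i0[0] + dx, i0[1] + dy, i0[2] + dz] += q * wt
    return qgrid


def solve_lpb(
    molecule,
    config: SolverConfig | None = None,
    geometry: GridGeometry | None = None,
) -> PotentialGrid:
    """Solve the linearized PB equation for ``molecule`` on a cubic lattice.

    The grid is centered on the molecule's geometric center unless an
    explicit ``geometry`` is supplied (used to put two superposed molecules
    on one shared frame).  The molecule must fit inside the grid with at
    least 10 A of margin between every atom sphere and every face.

    Returns the potential in kT/e at ``config.temperature``.  Raises
    :class:`ConvergenceError` if the relative infinity-norm residual does
    not reach ``config.convergence_tol`` within ``config.max_iterations``
    red-black SOR sweeps.
    """
    if config is None:
        config = SolverConfig()
    if geometry is None:
        geometry = GridGeometry.centered(
            molecule.geometric_center, config.grid_points_per_side, config.spacing
        )
    lo, hi = geometry.extent()
    coords = molecule.coordinates
    radii = molecule.radii
    margin = min(
        float((coords - radii[:, None] - lo).min()),
        float((hi - coords - radii[:, None]).min()),
    )
    if margin < 10.0:
        raise GridError(
            f"molecule too large for grid: only {margin:.2f} A margin to the "
            "nearest face (>= 10 A required)"
        )

    eps, ion = build_region_maps(molecule, config, geometry)
    h = geometry.spacing
    l0 = coulomb_scale_length(config.temperature)
    kappa2_term = config.eps_solvent * config.kappa**2 * ion  # A^-2

    u = np.zeros(geometry.dims)
    _boundary_condition(u, geometry, molecule, config)

    qgrid = _spread_charges(geometry, molecule)
    # RHS of the h^2-scaled stencil equation
    rhs = 4.0 * math.pi * l0 * qgrid[1:-1, 1:-1, 1:-1] / h

    # harmonic-mean face dielectrics
    ex = 2.0 * eps[:-1] * eps[1:] / (eps[:-1] + eps[1:])
    ey = 2.0 * eps[:, :-1] * eps[:, 1:] / (eps[:, :-1] + eps[:, 1:])
    ez = 2.0 * eps[:, :, :-1] * eps[:, :, 1:] / (eps[:, :, :-1] + eps[:, :, 1:])
    cxm = ex[:-1, 1:-1, 1:-1]
    cxp = ex[1:, 1:-1, 1:-1]
    cym = ey[1:-1, :-1, 1:-1]
    cyp = ey[1:-1, 1:, 1:-1]
    czm = ez[1:-1, 1:-1, :-1]
    czp = ez[1:-1, 1:-1, 1:]
    diag = cxm + cxp + cym + cyp + czm + czp + kappa2_term[1:-1, 1:-1, 1:-1] * h * h

    nx, ny, nz = geometry.dims
    parity = (
        np.arange(1, nx - 1)[:, None, None]
        + np.arange(1, ny - 1)[None, :, None]
        + np.arange(1, nz - 1)[None, None, :]
    ) % 2
    red = (parity == 0).astype(float)
    black = 1.0 - red

    omega = 2.0 / (1.0 + math.sin(math.pi / min(geometry.dims)))
    rhs_scale = float(np.abs(rhs).max())

    def neighbor_sum() -> np.ndarray:
        return (
            cxm * u[:-2, 1:-1, 1:-1]
            + cxp * u[2:, 1:-1, 1:-1]
            + cym * u[1:-1, :-2, 1:-1]
            + cyp * u[1:-1, 2:, 1:-1]
            + czm * u[1:-1, 1:-1, :-2]
            + czp * u[1:-1, 1:-1, 2:]
        )

    ui = u[1:-1, 1:-1, 1:-1]
    residual = math.inf
    for sweep in range(1, config.max_iterations + 1):
        for color in (red, black):
            gs = (neighbor_sum() + rhs) / diag
            ui += omega * color * (gs - ui)
        if sweep % 10 == 0 or sweep == config.max_iterations:
            res = neighbor_sum() + rhs - diag * ui
            residual = float(np.abs(res).max())
            if rhs_scale > 0:
                residual /= rhs_scale
            if residual <= config.convergence_tol:
                break
    else:
        raise ConvergenceError(
            f"LPB solver did not converge in {config.max_iterations} sweeps "
            f"(final relative residual {residual:.3e})"
        )
    return PotentialGrid(tuple(geometry.origin), h, u)


# ---------------------------------------------------------------------------
# OpenDX scalar-grid I/O (APBS dialect)


def write_dx(grid: PotentialGrid, path: str | Path, comment: str = "") -> None:
    """Write a potential grid as an OpenDX regular scalar grid (APBS dialect)."""
    nx, ny, nz = grid.dims
    h = grid.spacing
    vals = grid.values.ravel(order="C")  # z fastest, as APBS writes
    with open(path, "w") as fh:
        if comment:
            fh.write(f"# {comment}\n")
        fh.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
        fh.write("origin {:.6e} {:.6e} {:.6e}\n".format(*grid.origin))
        fh.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
        fh.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
        fh.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
        fh.write(
            f"object 3 class array type double rank 0 items {vals.size} data follows\n"
        )
        for i in range(0, vals.size, 3):
            fh.write(" ".join(f"{v:.6e}" for v in vals[i : i + 3]) + "\n")
        fh.write('attribute "dep" string "positions"\n')
        fh.write('object "regular positions regular connections" class field\n')
        fh.write('component "positions" value 1\n')
        fh.write('component "connections" value 2\n')
        fh.write('component "data" value 3\n')


def read_dx(path: str | Path) -> PotentialGrid:
    """Read an OpenDX regular scalar grid (APBS dialect)."""
    path = Path(path)
    dims: tuple[int, int, int] | None = None
    conn_dims: tuple[int, int, int] | None = None
    origin: tuple[float, float, float] | None = None
    deltas: list[list[float]] = []
    n_items: int | None = None
    values: list[float] = []
    reading = False
    with open(path) as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#"):
                continue
            if reading:
                if s.startswith(("attribute", "object", "component")):
                    reading = False
                else:
                    values.extend(float(tok) for tok in s.split())
                    continue
            if s.startswith("object 1 class gridpositions counts"):
                dims = tuple(int(v) for v in s.split()[-3:])  # type: ignore[assignment]
            elif s.startswith("origin"):
                origin = tuple(float(v) for v in s.split()[1:4])  # type: ignore[assignment]
            elif s.startswith("delta"):
                deltas.append([float(v) for v in s.split()[1:4]])
            elif s.startswith("object 2 class gridconnections counts"):
                conn_dims = tuple(int(v) for v in s.split()[-3:])  # type: ignore[assignment]
            elif "class array" in s and "data follows" in s:
                n_items = int(s.split("items")[1].split()[0])
                reading = True
    if dims is None or origin is None or len(deltas) != 3:
        raise GridError(f"{path.name}: missing gridpositions/origin/delta records")
    if conn_dims is not None and conn_dims != dims:
        raise GridError(f"{path.name}: gridconnections counts {conn_dims} != {dims}")
    delta = np.array(deltas)
    diag = np.diag(delta).copy()
    if not np.allclose(delta, np.diag(diag)) or not np.allclose(diag, diag[0]):
        raise GridError(f"{path.name}: grid is not regular with uniform cubic spacing")
    n_expected = dims[0] * dims[1] * dims[2]
    if n_items is not None and n_items != n_expected:
        raise GridError(f"{path.name}: item count {n_items} != product of dims {n_expected}")
    if len(values) != n_expected:
        raise GridError(f"{path.name}: read {len(values)} values, expected {n_expected}")
    arr = np.array(values).reshape(dims, order="C")
    return PotentialGrid(origin, float(diag[0]), arr)
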