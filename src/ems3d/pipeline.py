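"""End-to-end pipeline: solve -> skin-compare -> matrix -> cluster, with a
run manifest for reproducibility.

A :class:`RunConfig` is a flat key=value file mirroring the solver and skin
parameter names; unknown keys are rejected so typos fail loudly.  Artifacts
are write-once per run directory: a run refuses to overwrite an existing
manifest.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

from . import __version__
from .matrix import cluster_order, pairwise_esd, to_newick
from .pbgrid import GridGeometry, SolverConfig, solve_lpb, write_dx
from .skin import SkinParams
from .structure import kabsch_superpose, read_pqr, transform_molecule


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Flat run configuration: solver + skin parameters, inputs, seed."""

    pqr: list[str]
    grid_points_per_side: int = 353
    spacing: float = 0.33
    ionic_strength: float = 0.15
    eps_protein: float = 2.0
    eps_solvent: float = 78.0
    temperature: float = 310.0
    probe_radius: float = 1.4
    convergence_tol: float = 1e-6
    max_iterations: int = 20000
    sigma: float = 3.0
    delta: float = 4.0
    seed: int = 0
    verbosity: int = 1

    def solver_config(self) -> SolverConfig:
        keys = {f.name for f in fields(SolverConfig)}
        return SolverConfig(**{k: v for k, v in asdict(self).items() if k in keys})

    def skin_params(self) -> SkinParams:
        return SkinParams(self.sigma, self.delta)


def parse_config_file(path: str | Path, pqr: list[str] | None = None) -> RunConfig:
    """Parse a flat ``key = value`` (or ``key: value``) configuration file."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        for sep in ("=", ":"):
            if sep in s:
                key, _, value = s.partition(sep)
                raw[key.strip()] = value.strip()
                break
        else:
            raise PipelineError(f"{path}:{lineno}: expected 'key = value', got {s!r}")
    known = {f.name: f.type for f in fields(RunConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise PipelineError(f"unknown configuration keys: {', '.join(sorted(unknown))}")
    kwargs: dict = {}
    for key, value in raw.items():
        if key == "pqr":
            kwargs[key] = [p.strip() for p in value.split(",") if p.strip()]
        elif key in ("grid_points_per_side", "max_iterations", "seed", "verbosity"):
            kwargs[key] = int(value)
        else:
            kwargs[key] = float(value)
    if pqr is not None:
        kwargs["pqr"] = list(pqr)
    kwargs.setdefault("pqr", [])
    return RunConfig(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, out_dir: str | Path) -> Path:
    """Run solve -> compare -> matrix -> cluster and write artifacts.

    All molecules are superposed onto the first and solved on one shared
    grid.  Writes per-molecule DX grids, the ESD matrix CSV, the dendrogram
    Newick, the leaf order, and a manifest (parameters, input checksums,
    package version).  Deterministic for fixed inputs and seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    if manifest_path.exists():
        raise PipelineError(f"run directory {out} already holds a manifest; refusing to overwrite")
    if len(config.pqr) < 2:
        raise PipelineError("stage read: need at least 2 PQR inputs")

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name} failed: {exc}") from exc
        return wrap

    molecules = []
    for p in config.pqr:
        if not Path(p).exists():
            raise PipelineError(f"stage read failed: PQR file not found: {p}")
        molecules.append(stage("read")(read_pqr, p))

    reference = molecules[0]
    aligned = [reference]
    for mol in molecules[1:]:
        t = stage("superpose")(kabsch_superpose, mol, reference)
        aligned.append(transform_molecule(mol, t))

    solver = config.solver_config()
    geometry = GridGeometry.centered(
        reference.geometric_center, solver.grid_points_per_side, solver.spacing
    )
    panel = []
    for mol in aligned:
        grid = stage("solve")(solve_lpb, mol, solver, geometry)
        write_dx(grid, out / f"{mol.label}.dx", comment=f"LPB potential of {mol.label} (kT/e)")
        panel.append((mol, grid))

    esd = stage("matrix")(pairwise_esd, panel, config.skin_params())
    esd.to_csv(out / "esd.csv")
    clustering = stage("cluster")(cluster_order, esd)
    (out / "order.txt").write_text("\n".join(clustering.ordered_labels) + "\n")
    (out / "dendrogram.nwk").write_text(to_newick(esd, clustering) + "\n")

    manifest = {
        "package": "ems3d",
        "version": __version__,
        "parameters": asdict(config),
        "inputs": {p: _sha256(Path(p)) for p in config.pqr},
        "outputs": sorted(
            f.name for f in out.iterdir() if f.name != "manifest.json"
        ),
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return out
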