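"""All-versus-all ESD matrices, complete-linkage clustering and export.

Pairwise electrostatic similarity distances over an allele panel are
compiled into a symmetric, hollow distance matrix, ordered by
complete-linkage hierarchical clustering so that electrostatically similar
alleles sit in contiguous blocks, and exported as CSV / Newick / heat map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .pbgrid import PotentialGrid
from .skin import SkinParams, compare_pair
from .structure import Molecule


class MatrixError(ValueError):
    """Invalid distance matrix or failed panel comparison."""


@dataclass
class EsdMatrix:
    """Symmetric hollow matrix of pairwise ESDs with allele labels."""

    labels: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MatrixError("matrix shape does not match label count")
        if np.isnan(self.values).any():
            raise MatrixError("ESD matrix contains NaN")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise MatrixError("ESD matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise MatrixError("ESD matrix diagonal is not zero")
        if self.values.min() < -1e-9 or self.values.max() > 2.0 + 1e-9:
            raise MatrixError("ESD values outside [0, 2]")

    def lookup(self, a: str, b: str) -> float:
        try:
            i, j = self.labels.index(a), self.labels.index(b)
        except ValueError as exc:
            raise KeyError(f"no ESD entry for pair ({a}, {b})") from exc
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EsdMatrix":
        df = pd.read_csv(path, index_col=0)
        if list(df.index) != list(df.columns):
            raise MatrixError("CSV matrix row and column labels differ")
        return cls(list(df.index), df.to_numpy(dtype=float))


def pairwise_esd(
    panel: Sequence[tuple[Molecule, PotentialGrid]],
    params: SkinParams | None = None,
) -> EsdMatrix:
    """All-versus-all ESD matrix over a panel of solved molecules.

    Every pair is compared once (n(n-1)/2 comparisons) and mirrored.  All
    grids must live on one common frame.  A failing pair aborts the run,
    naming the pair.
    """
    if len(panel) < 2:
        raise MatrixError("panel needs at least 2 members")
    labels = [mol.label for mol, _ in panel]
    n = len(panel)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            mol_a, grid_a = panel[i]
            mol_b, grid_b = panel[j]
            try:
                res = compare_pair(mol_a, grid_a, mol_b, grid_b, params)
            except Exception as exc:
                raise MatrixError(
                    f"pair comparison failed for ({labels[i]}, {labels[j]}): {exc}"
                ) from exc
            values[i, j] = values[j, i] = res.esd
    return EsdMatrix(labels, values)


@dataclass
class ClusterResult:
    """Complete-linkage merge tree over an ESD matrix."""

    linkage: np.ndarray
    leaf_order: list[int]
    ordered_labels: list[str]

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def cluster_order(matrix: EsdMatrix) -> ClusterResult:
    """Complete-linkage hierarchical clustering of an ESD matrix.

    Returns the merge tree (scipy linkage encoding, heights non-decreasing)
    and the dendrogram leaf order used to reorder the heat map.
    """
    condensed = squareform(matrix.values, checks=False)
    z = hierarchy.linkage(condensed, method="complete")
    order = [int(i) for i in hierarchy.leaves_list(z)]
    return ClusterResult(z, order, [matrix.labels[i] for i in order])


def reorder(matrix: EsdMatrix, result: ClusterResult) -> EsdMatrix:
    """Matrix permuted into dendrogram leaf order (cluster blocks contiguous)."""
    idx = np.array(result.leaf_order)
    return EsdMatrix(list(result.ordered_labels), matrix.values[np.ix_(idx, idx)])


def to_newick(matrix: EsdMatrix, result: ClusterResult | None = None) -> str:
    """Newick string for the complete-linkage dendrogram.

    Branch lengths are differences of merge heights, so root-to-leaf path
    length equals the final merge height.
    """
    if result is None:
        result = cluster_order(matrix)
    tree = hierarchy.to_tree(result.linkage)

    def walk(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            return f"{matrix.labels[node.id]}:{parent_height:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    body = walk(tree, tree.dist)
    # strip the root's zero-length suffix
    return body.rsplit(":", 1)[0] + ";"


def plot_heatmap(
    matrix: EsdMatrix, path: str | Path, result: ClusterResult | None = None
) -> None:
    """Symmetric ESD heat map in dendrogram order (optional PNG artifact)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if result is None:
        result = cluster_order(matrix)
    ordered = reorder(matrix, result)
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(ordered.values, cmap="viridis", vmin=0.0, vmax=2.0)
    ax.set_xticks(range(len(ordered.labels)))
    ax.set_yticks(range(len(ordered.labels)))
    ax.set_xticklabels(ordered.labels, rotation=90, fontsize=7)
    ax.set_yticklabels(ordered.labels, fontsize=7)
    fig.colorbar(im, ax=ax, label="ESD")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
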