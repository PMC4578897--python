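"""Chemical-space embedding of lipid structure sets.

A set of n molecules with pairwise structural distances defines an
(n-1)-dimensional space: molecule i's descriptor vector is simply its row
of the distance matrix (the distances to every member of the set).  PCA on
these row vectors — not classical metric MDS on squared distances — gives
low-dimensional coordinates in which structurally related lipids cluster.
A reference map embeds the union of several lipidomes in one shared space
so the lipidomes become directly comparable point sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .lipid_model import Lipidome, render_species
from .metrics import DistanceMatrix, pairwise_matrix

__all__ = [
    "ChemSpace",
    "ReferenceMap",
    "embed",
    "euclidean_in_plane",
    "build_reference_map",
    "plot_chemspace",
]

_DEGENERATE_VARIANCE = 1e-24


@dataclass
class ChemSpace:
    """Per-molecule coordinates from PCA of a distance matrix.

    ``coords`` is n x k (arbitrary units); ``explained`` holds the variance
    fractions of *all* components (non-increasing, summing to 1 for a
    non-degenerate matrix), of which the first k back the coordinates.
    """

    labels: list[str]
    coords: np.ndarray
    explained: np.ndarray
    source_metric: str = ""

    def row(self, label: str) -> np.ndarray:
        return self.coords[self.labels.index(label)]


def embed(dm: DistanceMatrix, k: int = 2) -> ChemSpace:
    """PCA-embed a distance matrix's rows into k components.

    Rows are column-centered and projected onto the leading principal
    axes.  Each axis's sign is fixed so its largest-magnitude loading is
    positive, making the embedding fully deterministic.  A degenerate
    matrix (all rows identical) yields all-zero coordinates and explained
    fractions.
    """
    n = len(dm.labels)
    if not 1 <= k <= max(n - 1, 1):
        raise ValueError(f"k={k} out of range [1, {n - 1}]")
    X = np.asarray(dm.values, dtype=float)
    centered = X - X.mean(axis=0)
    if float((centered**2).sum()) < _DEGENERATE_VARIANCE:
        return ChemSpace(list(dm.labels), np.zeros((n, k)), np.zeros(n), dm.metric_name)
    pca = PCA(n_components=min(n, X.shape[1]), svd_solver="full")
    scores = pca.fit_transform(centered)
    # deterministic sign: largest-|loading| of each axis made positive
    for c in range(pca.components_.shape[0]):
        load = pca.components_[c]
        if load[np.argmax(np.abs(load))] < 0:
            pca.components_[c] = -load
            scores[:, c] = -scores[:, c]
    explained = np.asarray(pca.explained_variance_ratio_, dtype=float)
    return ChemSpace(list(dm.labels), scores[:, :k], explained, dm.metric_name)


def euclidean_in_plane(
    cs: ChemSpace, ref: str, dims: tuple[int, ...] = (0, 1)
) -> list[tuple[str, float]]:
    """Euclidean distances from ``ref`` to every molecule in a component
    subspace (0-based component indices, default the PC1-PC2 plane)."""
    if ref not in cs.labels:
        raise KeyError(f"unknown label {ref!r}")
    dims = tuple(dims)
    if any(d < 0 or d >= cs.coords.shape[1] for d in dims):
        raise ValueError(f"dims {dims} outside available components")
    origin = cs.row(ref)[list(dims)]
    out = []
    for lab, row in zip(cs.labels, cs.coords):
        out.append((lab, float(np.linalg.norm(row[list(dims)] - origin))))
    return out


@dataclass
class ReferenceMap:
    """A shared chemical space over the union of several lipidomes.

    ``membership`` maps each lipidome name to a boolean mask over the map
    points; points are unique structures (deduplicated by rendered
    SMILES).  ``smiles`` aligns with ``space.labels``.
    """

    space: ChemSpace
    smiles: list[str]
    membership: dict[str, np.ndarray]
    distance_matrix: DistanceMatrix = field(repr=False, default=None)

    def coords_for(self, smiles: str) -> np.ndarray:
        try:
            return self.space.coords[self.smiles.index(smiles)]
        except ValueError:
            raise KeyError(f"structure not on the reference map: {smiles!r}") from None


def build_reference_map(
    lipidomes: list[Lipidome], metric: str = "levenshtein", k: int | None = 2
) -> ReferenceMap:
    """Embed the deduplicated union of several lipidomes.

    Identity is by rendered SMILES: a species shared between lipidomes
    occupies one map point flagged in each lipidome's membership mask.
    """
    if not lipidomes:
        raise ValueError("need at least one lipidome")
    union: dict[str, str] = {}  # smiles -> label (first-seen species id)
    for lp in lipidomes:
        for entry in lp.entries:
            s = render_species(entry.species)
            union.setdefault(s, entry.species.id)
    if not union:
        raise ValueError("empty union of lipidomes")
    smiles = list(union)
    labels = [union[s] for s in smiles]
    dm = pairwise_matrix(list(zip(labels, smiles)), metric)
    full = max(len(smiles) - 1, 1)  # k=None: keep the full-rank embedding
    space = embed(dm, k=full if k is None else min(k, full))
    membership = {}
    for lp in lipidomes:
        own = {render_species(e.species) for e in lp.entries}
        membership[lp.name] = np.array([s in own for s in smiles])
    return ReferenceMap(space, smiles, membership, dm)


def plot_chemspace(
    cs: ChemSpace,
    path: str,
    membership: dict[str, np.ndarray] | None = None,
    annotate: bool = False,
) -> None:
    """Scatter the first two components to SVG/PNG (needs matplotlib).

    With ``membership`` masks (from a reference map), each lipidome's
    points are drawn as a separate series.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if cs.coords.shape[1] < 2:
        raise ValueError("need at least 2 components to plot")
    fig, ax = plt.subplots(figsize=(5, 4))
    if membership:
        for name, mask in membership.items():
            ax.scatter(cs.coords[mask, 0], cs.coords[mask, 1], s=18, label=name, alpha=0.7)
        ax.legend(frameon=False, fontsize=8)
    else:
        ax.scatter(cs.coords[:, 0], cs.coords[:, 1], s=18)
    if annotate:
        for lab, (x, y) in zip(cs.labels, cs.coords[:, :2]):
            ax.annotate(lab, (x, y), fontsize=7, xytext=(2, 2), textcoords="offset points")
    ax.set_xlabel(f"PC1 ({100 * cs.explained[0]:.1f}%)")
    ax.set_ylabel(f"PC2 ({100 * cs.explained[1]:.1f}%)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
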