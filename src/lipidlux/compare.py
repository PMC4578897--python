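"""Lipidome-set comparison: alternative similarity measures, complete-
linkage clustering, and an abundance-perturbation error model with branch
support counting.

Besides the structural LUX score, two conventional measures are provided:
the percentage of common lipids (Jaccard overlap of structure sets) and a
Pearson-correlation distance over abundance profiles.  Dendrogram
robustness is assessed by repeatedly perturbing every abundance with
Gaussian noise, dropping species that fall below a detection threshold,
reclustering, and counting how often each branch of the reference tree
recurs — the analogue of bootstrap support for lipidome trees.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr

from .lipid_model import (
    LipidModelError,
    Lipidome,
    LipidomeEntry,
    render_species,
)
from .lux import lux_matrix
from .metrics import DistanceMatrix

__all__ = [
    "ErrorModelParams",
    "TreeNode",
    "Dendrogram",
    "common_lipid_similarity",
    "common_lipid_distance",
    "abundance_distance",
    "complete_linkage",
    "perturb_lipidome",
    "metric_matrix",
    "branch_support",
    "PARAMETER_SETS",
]


# published perturbation parameter sets (mol%) for yeast-scale abundances
PARAMETER_SETS = {
    1: {"t_detect": 0.003, "s": 0.001},
    2: {"t_detect": 0.003, "s": 0.002},
    3: {"t_detect": 0.006, "s": 0.004},
}


@dataclass(frozen=True)
class ErrorModelParams:
    """Detection threshold and perturbation width of the error model.

    ``t_detect`` (mol%): species whose perturbed abundance does not exceed
    it are treated as undetected and removed.  ``s`` (mol%): standard
    deviation of the zero-mean Gaussian added to every abundance.  Both
    act on raw mol% values; no renormalization is applied.
    """

    t_detect: float = 0.003
    s: float = 0.001
    iterations: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.t_detect < 0 or self.s < 0:
            raise ValueError("t_detect and s must be >= 0")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


# -- pairwise lipidome measures ---------------------------------------------

def common_lipid_similarity(a: Lipidome, b: Lipidome) -> float:
    """Percentage of common lipids: 100 * |A & B| / |A | B|, identity by
    rendered SMILES."""
    sa, sb = set(a.smiles()), set(b.smiles())
    if not sa or not sb:
        raise ValueError("empty lipidome")
    return 100.0 * len(sa & sb) / len(sa | sb)


def common_lipid_distance(a: Lipidome, b: Lipidome) -> float:
    return 100.0 - common_lipid_similarity(a, b)


def abundance_distance(a: Lipidome, b: Lipidome) -> float:
    """1 - Pearson correlation of mol% profiles over the union of
    structures (a species absent from one lipidome counts as 0 mol%)."""
    xa, xb = a.abundance_by_smiles(), b.abundance_by_smiles()
    union = sorted(xa.keys() | xb.keys())
    if len(xa.keys() & xb.keys()) < 2:
        raise ValueError("need at least 2 shared species for a correlation")
    va = np.array([xa.get(s, 0.0) for s in union])
    vb = np.array([xb.get(s, 0.0) for s in union])
    if np.ptp(va) == 0 or np.ptp(vb) == 0:
        raise ValueError("zero-variance abundance vector")
    r = pearsonr(va, vb).statistic
    return float(1.0 - r)


# -- dendrograms -------------------------------------------------------------

@dataclass
class TreeNode:
    height: float = 0.0
    label: str | None = None
    children: tuple["TreeNode", "TreeNode"] | None = None
    support: int | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        return self.children[0].leaves() | self.children[1].leaves()


@dataclass
class Dendrogram:
    """Binary merge tree over lipidome labels with merge heights."""

    root: TreeNode
    labels: list[str] = field(default_factory=list)

    def clades(self, nontrivial: bool = True) -> list[frozenset[str]]:
        """Leaf sets of internal nodes; ``nontrivial`` drops the root set.

        A binary tree over m leaves yields m - 2 nontrivial clades.
        """
        out = []

        def walk(node: TreeNode, is_root: bool):
            if node.is_leaf:
                return
            if not (nontrivial and is_root):
                out.append(node.leaves())
            walk(node.children[0], False)
            walk(node.children[1], False)

        walk(self.root, True)
        return out

    def newick(self, support: bool = False) -> str:
        def fmt(x: float) -> str:
            return f"{x:.6g}"

        def walk(node: TreeNode) -> str:
            if node.is_leaf:
                return node.label
            l, r = node.children
            body = f"({walk(l)}:{fmt(node.height - l.height)},{walk(r)}:{fmt(node.height - r.height)})"
            if support and node.support is not None:
                body += str(node.support)
            return body

        return walk(self.root) + ";"


def complete_linkage(
    data: DistanceMatrix | np.ndarray,
    labels: list[str] | None = None,
    input_mode: str = "rows",
) -> Dendrogram:
    """Agglomerative clustering with maximum inter-cluster distance.

    ``input_mode="rows"`` (default) first takes Euclidean distances
    between the rows of the supplied score matrix or feature table — the
    dist()+hclust idiom — while ``"direct"`` uses the matrix itself as the
    dissimilarity.  Merges with tied distances break deterministically by
    the lexicographically smallest pair of cluster label sets.
    """
    if isinstance(data, DistanceMatrix):
        labels = list(data.labels)
        X = np.asarray(data.values, dtype=float)
    else:
        X = np.asarray(data, dtype=float)
        if labels is None:
            labels = [str(i) for i in range(X.shape[0])]
    if input_mode == "rows":
        D = squareform(pdist(X, metric="euclidean"))
    elif input_mode == "direct":
        if X.ndim != 2 or X.shape[0] != X.shape[1]:
            raise ValueError("direct mode needs a square dissimilarity matrix")
        D = X.copy()
    else:
        raise ValueError(f"unknown input_mode {input_mode!r}")
    n = len(labels)
    if n < 2:
        raise ValueError("need at least 2 items")

    nodes = {i: TreeNode(0.0, label=labels[i]) for i in range(n)}
    members: dict[int, tuple[int, ...]] = {i: (i,) for i in range(n)}

    def label_key(cid: int) -> tuple[str, ...]:
        return tuple(sorted(labels[i] for i in members[cid]))

    dist: dict[tuple[int, int], float] = {
        (i, j): float(D[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    next_id = n
    while len(nodes) > 1:
        best_key = min(
            dist,
            key=lambda k: (dist[k], tuple(sorted((label_key(k[0]), label_key(k[1]))))),
        )
        h = dist[best_key]
        i, j = best_key
        a, b = sorted((nodes[i], nodes[j]), key=lambda t: sorted(t.leaves()))
        merged = TreeNode(h, children=(a, b))
        del nodes[i], nodes[j]
        new_members = tuple(sorted(members.pop(i) + members.pop(j)))
        for key in [k for k in dist if i in k or j in k]:
            del dist[key]
        for other in nodes:
            pair = (min(other, next_id), max(other, next_id))
            dist[pair] = max(
                float(D[x, y]) for x in new_members for y in members[other]
            )
        nodes[next_id] = merged
        members[next_id] = new_members
        next_id += 1
    return Dendrogram(next(iter(nodes.values())), labels)


# -- error model -------------------------------------------------------------

def perturb_lipidome(
    lp: Lipidome, params: ErrorModelParams, rng: np.random.Generator
) -> Lipidome:
    """One error-model draw: x' = x + N(0, s) per species (stable id
    order); a species is retained, at abundance x', iff x' > t_detect."""
    order = sorted(range(len(lp.entries)), key=lambda i: lp.entries[i].species.id)
    perturbed: dict[int, float] = {}
    for i in order:  # draws in stable id order, for reproducibility
        x = lp.entries[i].abundance
        perturbed[i] = x + (rng.normal(0.0, params.s) if params.s > 0 else 0.0)
    entries = [
        LipidomeEntry(e.species, perturbed[i])
        for i, e in enumerate(lp.entries)
        if perturbed[i] > params.t_detect
    ]
    if not entries:
        raise LipidModelError(f"error model removed every species of {lp.name!r}")
    return Lipidome(lp.name, entries)


def metric_matrix(
    lipidomes: list[Lipidome],
    metric: str = "lux",
    space: str = "full",
    structures=None,
) -> DistanceMatrix:
    """Pairwise lipidome dissimilarities under the chosen measure."""
    names = [lp.name for lp in lipidomes]
    if metric == "lux":
        return lux_matrix(lipidomes, space=space, structures=structures)
    if metric == "common":
        fn = lambda a, b: common_lipid_distance(a, b) / 100.0
    elif metric == "abundance":
        fn = lambda a, b: abundance_distance(a, b) / 2.0
    else:
        raise ValueError(f"unknown lipidome metric {metric!r}")
    n = len(lipidomes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(lipidomes[i], lipidomes[j])
    return DistanceMatrix(names, values, metric)


def branch_support(
    lipidomes: list[Lipidome],
    metric: str = "lux",
    params: ErrorModelParams | None = None,
    space: str = "full",
    input_mode: str = "rows",
) -> Dendrogram:
    """Reference dendrogram with per-branch recurrence counts.

    The reference tree is clustered from the unperturbed lipidomes.  Each
    iteration perturbs every lipidome with the error model, recomputes the
    pairwise metric and the tree, and records which reference clades
    recur; each internal node's support is that count over all
    iterations.
    """
    if len(lipidomes) < 3:
        raise ValueError("branch support needs at least 3 lipidomes")
    params = params or ErrorModelParams()
    structures = None
    if metric == "lux":
        # the error model only removes structures, so one structure-level
        # distance matrix over the unperturbed union serves every iteration
        from .lux import StructureSpace, _build_space

        structures = _build_space(lipidomes, space, None)
    ref = complete_linkage(
        metric_matrix(lipidomes, metric, space, structures), input_mode=input_mode
    )
    counts = {clade: 0 for clade in ref.clades(nontrivial=False)}
    rng = np.random.default_rng(params.seed)
    for _ in range(params.iterations):
        perturbed = [perturb_lipidome(lp, params, rng) for lp in lipidomes]
        tree = complete_linkage(
            metric_matrix(perturbed, metric, space, structures), input_mode=input_mode
        )
        seen = set(tree.clades(nontrivial=False))
        for clade in counts:
            if clade in seen:
                counts[clade] += 1

    def annotate(node: TreeNode):
        if node.is_leaf:
            return
        node.support = counts[node.leaves()]
        annotate(node.children[0])
        annotate(node.children[1])

    annotate(ref.root)
    return ref
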