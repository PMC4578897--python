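"""The LUX lipidome homology score.

A lipidome is treated as a set of structures.  The directed distance from
lipidome A to B is the average, over every lipid in A, of the distance to
the most similar lipid in B — a modified (average-directed) Hausdorff
distance.  Species present in both lipidomes contribute zeros to that
average.  The symmetric homology score is the larger of the two directed
averages: zero exactly for identical structure sets, growing as the
repertoires diverge.

Distances between structures are either Levenshtein distances on the
rendered SMILES (``space="full"``) or Euclidean distances between
reference-map coordinates (``space="2d"``/``"3d"``/``"kd"``), with species
identity always decided by exact SMILES equality.  A
:class:`StructureSpace` precomputes all structure-level distances once, so
that repeated lipidome comparisons (clustering, the error model) are cheap
lookups.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chemspace import ReferenceMap, build_reference_map
from .lipid_model import Lipidome
from .metrics import DistanceMatrix, levenshtein_distance

__all__ = ["LUXResult", "StructureSpace", "directed_distance", "lux_score", "lux_matrix"]

_SPACE_DIMS = {"2d": 2, "3d": 3, "kd": None}


@dataclass(frozen=True)
class LUXResult:
    """Directed average shortest distances and their maximum."""

    d_ab: float
    d_ba: float
    space: str = "full"

    @property
    def score(self) -> float:
        return max(self.d_ab, self.d_ba)


def directed_distance(a: list[str], b: list[str], dist) -> float:
    """Mean over x in ``a`` of the smallest ``dist(x, y)`` over y in ``b``.

    ``a`` and ``b`` are structure keys (rendered SMILES); ``dist`` is a
    pairwise lookup.  Keys occurring in both sets contribute zero, which
    is deliberate: shared species anchor the average.
    """
    if not a or not b:
        raise ValueError("directed distance needs two non-empty lipidomes")
    bset = set(b)
    total = 0.0
    for x in a:
        if x in bset:
            continue  # identical structure: minimum is 0
        total += min(dist(x, y) for y in b)
    return total / len(a)


class StructureSpace:
    """Distance lookup over a fixed universe of structures.

    Holds an index from SMILES to row and the full pairwise matrix, either
    Levenshtein over the strings or Euclidean over reference-map
    coordinates truncated to ``dims`` components.
    """

    def __init__(self, smiles: list[str], matrix: np.ndarray, space: str = "full"):
        self.smiles = list(smiles)
        self.index = {s: i for i, s in enumerate(self.smiles)}
        self.matrix = np.asarray(matrix, dtype=float)
        self.space = space

    @classmethod
    def from_smiles(cls, smiles: list[str]) -> "StructureSpace":
        uniq = list(dict.fromkeys(smiles))
        n = len(uniq)
        m = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                m[i, j] = m[j, i] = levenshtein_distance(uniq[i], uniq[j])
        return cls(uniq, m, "full")

    @classmethod
    def from_reference_map(cls, ref_map: ReferenceMap, space: str) -> "StructureSpace":
        dims = _SPACE_DIMS[space] or ref_map.space.coords.shape[1]
        if ref_map.space.coords.shape[1] < dims:
            raise ValueError(
                f"reference map has {ref_map.space.coords.shape[1]} components, need {dims}"
            )
        X = ref_map.space.coords[:, :dims]
        diff = X[:, None, :] - X[None, :, :]
        return cls(ref_map.smiles, np.sqrt((diff**2).sum(axis=2)), space)

    def _rows(self, smiles: list[str]) -> np.ndarray:
        try:
            return np.array([self.index[s] for s in smiles])
        except KeyError as exc:
            raise KeyError(f"structure not in this space: {exc.args[0]!r}") from None

    def distance(self, x: str, y: str) -> float:
        return float(self.matrix[self.index[x], self.index[y]])

    def directed(self, a: list[str], b: list[str]) -> float:
        """Vectorized average shortest distance from set a to set b."""
        if not a or not b:
            raise ValueError("directed distance needs two non-empty lipidomes")
        sub = self.matrix[np.ix_(self._rows(a), self._rows(b))]
        return float(sub.min(axis=1).mean())


def _build_space(
    lipidomes: list[Lipidome], space: str, ref_map: ReferenceMap | None
) -> StructureSpace:
    if space == "full":
        smiles: list[str] = []
        for lp in lipidomes:
            smiles.extend(lp.smiles())
        return StructureSpace.from_smiles(smiles)
    if space not in _SPACE_DIMS:
        raise ValueError(f"unknown space {space!r}; choose full/2d/3d/kd")
    if ref_map is None:
        ref_map = build_reference_map(lipidomes, k=_SPACE_DIMS[space])
    return StructureSpace.from_reference_map(ref_map, space)


def lux_score(
    a: Lipidome,
    b: Lipidome,
    space: str = "full",
    ref_map: ReferenceMap | None = None,
    structures: StructureSpace | None = None,
) -> LUXResult:
    """Lipidome homology score: max of the two directed averages.

    ``space="full"`` compares rendered SMILES by Levenshtein distance;
    ``"2d"``/``"3d"``/``"kd"`` use Euclidean distance between coordinates
    on a reference map (supplied, or built over the union).  A shared
    species (identical SMILES) always contributes a zero distance.
    """
    ss = structures if structures is not None else _build_space([a, b], space, ref_map)
    sa, sb = a.smiles(), b.smiles()
    return LUXResult(ss.directed(sa, sb), ss.directed(sb, sa), ss.space)


def lux_matrix(
    lipidomes: list[Lipidome],
    space: str = "full",
    ref_map: ReferenceMap | None = None,
    structures: StructureSpace | None = None,
) -> DistanceMatrix:
    """Symmetric matrix of pairwise LUX scores over several lipidomes.

    All lipidomes share one structure universe (and, in a coordinate
    space, one reference map), so scores are mutually comparable.
    Coordinate-space scores are rescaled into [0, 1] by their maximum for
    the DistanceMatrix contract; relative structure (and hence
    clustering) is unaffected.
    """
    if len(lipidomes) < 2:
        raise ValueError("need at least 2 lipidomes")
    names = [lp.name for lp in lipidomes]
    if len(set(names)) != len(names):
        raise ValueError("lipidome names must be unique")
    ss = structures if structures is not None else _build_space(lipidomes, space, ref_map)
    n = len(lipidomes)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = lux_score(lipidomes[i], lipidomes[j], structures=ss)
            values[i, j] = values[j, i] = r.score
    if values.max() > 1.0:
        values = values / values.max()
    return DistanceMatrix(names, values, f"lux-{space}")
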