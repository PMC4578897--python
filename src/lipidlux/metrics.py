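"""Structural-similarity metrics over template SMILES strings.

Four metrics, all returning distances in [0, 1]:

* ``levenshtein`` — global unit-cost edit distance, normalized by the
  longer string.  The only tested metric that both distinguishes all
  positional isomers and stays symmetric, which is why it backs the
  chemical-space and lipidome-comparison layers.
* ``smith-waterman`` — local alignment similarity (match +1, mismatch -1,
  linear gap -1), converted to a distance; local alignment may trim
  distinguishing end features, which this package exposes on purpose.
* ``lingo`` — Tanimoto over the multiset of 4-character SMILES substrings
  (ring-closure digits collapsed to ``0``).
* ``fp2`` — Tanimoto over 1021-bit fingerprints of linear atom paths of
  1-7 atoms, an FP2-style path fingerprint computed on the parsed graph.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .lipid_model import MolecularGraph, parse_smiles

__all__ = [
    "DistanceMatrix",
    "levenshtein_raw",
    "levenshtein_distance",
    "smith_waterman_align",
    "smith_waterman_distance",
    "lingo_profile",
    "lingo_distance",
    "path_set",
    "path_fingerprint",
    "tanimoto_distance",
    "pairwise_matrix",
    "select_representative",
    "METRICS",
]

FINGERPRINT_BITS = 1021


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise distances in [0, 1]."""

    labels: list[str]
    values: np.ndarray
    metric_name: str = ""

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError(f"matrix shape {v.shape} does not match {n} labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(v) != 0):
            raise ValueError("distance matrix must have a zero diagonal")
        if v.min() < -1e-12 or v.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[self.labels.index(a), self.labels.index(b)])


# -- Levenshtein -------------------------------------------------------------

def levenshtein_raw(a: str, b: str) -> int:
    """Unit-cost edit distance (insert/delete/substitute), row-wise DP.

    The left-to-right insertion dependency within a row is resolved with a
    prefix-minimum scan: row[j] = j + min(row[0], min_k (t[k] - k)) where t
    holds the substitution/deletion candidates.
    """
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    bv = np.frombuffer(b.encode("utf-8"), dtype=np.uint8)
    idx = np.arange(1, len(bv) + 1)
    prev = np.arange(len(bv) + 1)
    for i, ca in enumerate(a.encode("utf-8"), start=1):
        t = np.minimum(prev[:-1] + (bv != ca), prev[1:] + 1)
        acc = np.minimum.accumulate(np.concatenate(([i], t - idx)))
        prev = np.concatenate(([i], acc[1:] + idx))
    return int(prev[-1])


def levenshtein_distance(a: str, b: str) -> float:
    """Edit distance normalized by the longer string; d("","") = 0."""
    m = max(len(a), len(b))
    if m == 0:
        return 0.0
    return levenshtein_raw(a, b) / m


# -- Smith-Waterman ----------------------------------------------------------

@dataclass
class LocalAlignment:
    score: int
    a_span: tuple[int, int]  # half-open [start, end) in a
    b_span: tuple[int, int]
    a_aligned: str = ""
    b_aligned: str = ""


def smith_waterman_align(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -1
) -> LocalAlignment:
    """Best local alignment under linear gap costs, with traceback."""
    if gap >= 0 or mismatch >= match:
        raise ValueError("expect gap < 0 and mismatch < match")
    n, m = len(a), len(b)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    if n and m:
        av = np.frombuffer(a.encode("utf-8"), dtype=np.uint8)
        bv = np.frombuffer(b.encode("utf-8"), dtype=np.uint8)
        sub = np.where(av[:, None] == bv[None, :], match, mismatch)
        idx = np.arange(1, m + 1)
        for i in range(1, n + 1):
            base = np.maximum(H[i - 1, :-1] + sub[i - 1], H[i - 1, 1:] + gap)
            np.maximum(base, 0, out=base)
            # left-gap dependency via prefix-max scan (valid for linear gaps)
            H[i, 1:] = np.maximum.accumulate(base - gap * idx) + gap * idx
    best = int(H.max())
    if best == 0:
        return LocalAlignment(0, (0, 0), (0, 0))
    i, j = map(int, np.unravel_index(int(H.argmax()), H.shape))
    end_i, end_j = i, j
    aa, bb = [], []
    while i > 0 and j > 0 and H[i, j] > 0:
        s = match if a[i - 1] == b[j - 1] else mismatch
        if H[i, j] == H[i - 1, j - 1] + s:
            aa.append(a[i - 1])
            bb.append(b[j - 1])
            i, j = i - 1, j - 1
        elif H[i, j] == H[i - 1, j] + gap:
            aa.append(a[i - 1])
            bb.append("-")
            i -= 1
        else:
            aa.append("-")
            bb.append(b[j - 1])
            j -= 1
    return LocalAlignment(
        best, (i, end_i), (j, end_j), "".join(reversed(aa)), "".join(reversed(bb))
    )


def smith_waterman_distance(
    a: str, b: str, match: int = 1, mismatch: int = -1, gap: int = -1
) -> float:
    """1 - S / max(|a|, |b|), with S the best local-alignment score."""
    m = max(len(a), len(b))
    if m == 0:
        return 0.0
    s = smith_waterman_align(a, b, match, mismatch, gap).score
    return 1.0 - s / m


# -- LINGO -------------------------------------------------------------------

_DIGITS = str.maketrans("123456789", "000000000")


def lingo_profile(s: str, q: int = 4) -> Counter:
    """Multiset of overlapping q-grams; ring-closure digits become '0'."""
    t = s.translate(_DIGITS)
    if len(t) <= q:
        return Counter([t])
    return Counter(t[i : i + q] for i in range(len(t) - q + 1))


def lingo_distance(a: str, b: str, q: int = 4, counts: bool = True) -> float:
    """1 - Tanimoto over q-gram profiles.

    ``counts=True`` uses the integral (multiset) Tanimoto
    sum(min)/sum(max); ``counts=False`` compares q-gram sets only.
    """
    pa, pb = lingo_profile(a, q), lingo_profile(b, q)
    if counts:
        keys = pa.keys() | pb.keys()
        lo = sum(min(pa[k], pb[k]) for k in keys)
        hi = sum(max(pa[k], pb[k]) for k in keys)
    else:
        lo = len(pa.keys() & pb.keys())
        hi = len(pa.keys() | pb.keys())
    if hi == 0:
        return 0.0
    return 1.0 - lo / hi


# -- path fingerprint --------------------------------------------------------

def path_set(g: MolecularGraph, max_atoms: int = 7) -> frozenset[str]:
    """Canonical strings of all simple linear paths of 1..max_atoms atoms.

    A path string interleaves element symbols with bond orders
    (e.g. ``C1C2O`` for C-C=O); each path is read in the direction giving
    the lexicographically smaller string.  Single-atom C/N/O paths are
    dropped, matching path-fingerprint practice of ignoring ubiquitous
    atoms.
    """
    adj = g.neighbors()
    out: set[str] = set()
    for start, elem in enumerate(g.atoms):
        if elem not in ("C", "N", "O"):
            out.add(elem)

    def extend(path: list[int], tokens: list[str]):
        if len(path) >= 2:
            s = "".join(tokens)
            out.add(min(s, s[::-1]))
        if len(path) == max_atoms:
            return
        last = path[-1]
        for j, order in adj[last]:
            if j in path_members:
                continue
            path_members.add(j)
            path.append(j)
            tokens.append(str(order))
            tokens.append(g.atoms[j])
            extend(path, tokens)
            tokens.pop()
            tokens.pop()
            path.pop()
            path_members.remove(j)

    for start in range(len(g.atoms)):
        path_members = {start}
        extend([start], [g.atoms[start]])
    return frozenset(out)


def _fnv1a(s: str) -> int:
    h = 0x811C9DC5
    for byte in s.encode("utf-8"):
        h ^= byte
        h = (h * 0x01000193) & 0xFFFFFFFF
    return h


def path_fingerprint(g: MolecularGraph, bits: int = FINGERPRINT_BITS) -> frozenset[int]:
    """Hash each canonical path into a fixed-width bit set (FNV-1a mod bits)."""
    return frozenset(_fnv1a(p) % bits for p in path_set(g))


def tanimoto_distance(fa: frozenset, fb: frozenset) -> float:
    """1 - |A&B|/|A|B|; two empty sets are identical by convention."""
    union = len(fa | fb)
    if union == 0:
        return 0.0
    return 1.0 - len(fa & fb) / union


# -- pairwise machinery ------------------------------------------------------

def _fp2_pairwise(smiles: list[str]) -> np.ndarray:
    fps = [path_fingerprint(parse_smiles(s)) for s in smiles]
    n = len(fps)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = tanimoto_distance(fps[i], fps[j])
    return d


METRICS = {
    "levenshtein": levenshtein_distance,
    "smith-waterman": smith_waterman_distance,
    "lingo": lingo_distance,
    "fp2": None,  # handled on graphs, see pairwise_matrix
}


def pairwise_matrix(
    labeled_smiles: list[tuple[str, str]], metric: str = "levenshtein", **kwargs
) -> DistanceMatrix:
    """Pairwise distance matrix over ``(label, smiles)`` records.

    Each unordered pair is computed once; the diagonal is zero by
    construction.
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {sorted(METRICS)}")
    if len(labeled_smiles) < 2:
        raise ValueError("need at least 2 molecules")
    labels = [lab for lab, _ in labeled_smiles]
    smiles = [s for _, s in labeled_smiles]
    if metric == "fp2":
        values = _fp2_pairwise(smiles)
    else:
        fn = METRICS[metric]
        n = len(smiles)
        values = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                values[i, j] = values[j, i] = fn(smiles[i], smiles[j], **kwargs)
    return DistanceMatrix(labels, values, metric)


def select_representative(smiles: list[str]) -> int:
    """Index of the isomer with the smallest mean Levenshtein distance.

    Ties break to the lowest index.  A singleton list returns 0.
    """
    if not smiles:
        raise ValueError("empty isomer list")
    if len(smiles) == 1:
        return 0
    n = len(smiles)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = levenshtein_distance(smiles[i], smiles[j])
    means = d.sum(axis=1) / (n - 1)
    # ties (within float noise of the minimum) break to the lowest index
    lo = means.min()
    return int(np.flatnonzero(means <= lo + 1e-9)[0])
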