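"""Built-in test systems: the ceramide hydroxyl scan, a phosphatidylinositol
chain-length series, and seeded synthetic lipidome pairs with controlled
structural overlap.

These generators make every pipeline stage testable without external
datasets.  The ceramide scan is the classic positional-isomer benchmark: 17
ceramides sharing one composition, differing only in where the fatty-acid
hydroxyl sits.  The PI series scans sn2 chain length and unsaturation on a
fixed 16:0 sn1 backbone.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .lipid_model import (
    ChainSpec,
    LipidModelError,
    Lipidome,
    LipidomeEntry,
    LipidSpecies,
    render_species,
    rendered,
)

__all__ = [
    "ceramide_scan",
    "pi_series",
    "SyntheticPairSpec",
    "synthetic_lipidome_pair",
]


def ceramide_scan() -> list[LipidSpecies]:
    """17 ceramide positional isomers: d16:0 base, 18:0 amide-linked fatty
    acid, hydroxyl at fatty-acid positions 2..18.  Ids are the hydroxyl
    position; all rendered strings share one length and composition."""
    base = ChainSpec(16, role="sphingoid")
    out = []
    for p in range(2, 19):
        fa = ChainSpec(18, hydroxyls=(p,), role="amide-acyl")
        out.append(rendered(LipidSpecies(id=str(p), lipid_class="CER", chains=(base, fa))))
    return out


def pi_series() -> list[LipidSpecies]:
    """16 phosphatidylinositols: sn1 fixed at 16:0; sn2 scans 10:0..19:0
    plus 14:1(9)..19:1(9)."""
    sn1 = ChainSpec(16, role="acyl")
    out = []
    for n in range(10, 20):
        sn2 = ChainSpec(n, role="acyl")
        out.append(rendered(LipidSpecies(id=f"{n}:0", lipid_class="PI", chains=(sn1, sn2))))
    for n in range(14, 20):
        sn2 = ChainSpec(n, double_bonds=(9,), role="acyl")
        out.append(rendered(LipidSpecies(id=f"{n}:1", lipid_class="PI", chains=(sn1, sn2))))
    return out


@dataclass(frozen=True)
class SyntheticPairSpec:
    """Recipe for a pair of random lipidomes sharing a set fraction of
    structures.  ``overlap`` must be realizable: round(overlap * count)
    shared structures."""

    count: int = 20
    overlap: float = 0.5
    classes: tuple[str, ...] = ("PC", "PE", "PI", "TAG", "CER")
    seed: int = 0

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")


def _random_species(rng: np.random.Generator, lipid_class: str, ident: str) -> LipidSpecies:
    from .lipid_model import TEMPLATE_REGISTRY

    slots = TEMPLATE_REGISTRY[lipid_class].slots
    chains = []
    for role in slots:
        n = int(rng.integers(12, 25))
        dbs: tuple[int, ...] = ()
        ohs: tuple[int, ...] = ()
        if role != "sphingoid":
            if rng.random() < 0.5:
                dbs = (int(rng.integers(2, n - 1)),)
            if role == "amide-acyl" and rng.random() < 0.5:
                ohs = (int(rng.integers(2, n + 1)),)
        chains.append(ChainSpec(n, double_bonds=dbs, hydroxyls=ohs, role=role))
    return rendered(LipidSpecies(id=ident, lipid_class=lipid_class, chains=tuple(chains)))


def _species_pool(rng: np.random.Generator, classes, size: int) -> list[LipidSpecies]:
    """Distinct-by-SMILES random species, round-robin over classes."""
    pool: list[LipidSpecies] = []
    seen: set[str] = set()
    tries = 0
    while len(pool) < size:
        tries += 1
        if tries > 100 * size:
            raise LipidModelError("could not draw enough distinct structures")
        cls = classes[len(pool) % len(classes)] if rng.random() < 0.5 else classes[
            int(rng.integers(len(classes)))
        ]
        sp = _random_species(rng, cls, ident=f"sp{len(pool)}")
        if sp.smiles not in seen:
            seen.add(sp.smiles)
            pool.append(sp)
    return pool


def synthetic_lipidome_pair(spec: SyntheticPairSpec) -> tuple[Lipidome, Lipidome]:
    """Two lipidomes of ``spec.count`` species sharing exactly
    ``round(overlap * count)`` structures; abundances uniform on (0, 10]
    mol%; fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    shared = round(spec.overlap * spec.count)
    pool = _species_pool(rng, spec.classes, 2 * spec.count - shared)
    shared_sp = pool[:shared]
    only_a = pool[shared : spec.count]
    only_b = pool[spec.count :]

    def build(name: str, species: list[LipidSpecies], tag: str) -> Lipidome:
        entries = []
        for k, sp in enumerate(species):
            x = float(10.0 * (1.0 - rng.random()))  # uniform on (0, 10]
            entries.append(
                LipidomeEntry(
                    LipidSpecies(f"{tag}{k}", sp.lipid_class, sp.chains, smiles=sp.smiles), x
                )
            )
        return Lipidome(name, entries)

    a = build("A", shared_sp + only_a, "a")
    b = build("B", shared_sp + only_b, "b")
    return a, b
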