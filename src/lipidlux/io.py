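"""Readers and writers: lipidome tables, SMILES files, distance matrices,
coordinates and Newick trees.

Lipidome tables are TSV with the header ``species_id  class  chains
abundance``.  The ``chains`` column uses shorthand: chains separated by
``/``, each ``C:D`` with optional ``;OH{p,...}`` and ``;db{d,...}``
modifiers, and a leading ``d`` marking a sphingoid base, e.g.
``d16:0/18:0;OH{2}``.  All writers are deterministic: stable ordering,
floats at 6 significant digits.
"""

from __future__ import annotations

import hashlib
import logging
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .chemspace import ChemSpace
from .compare import Dendrogram
from .lipid_model import (
    ChainSpec,
    LipidModelError,
    Lipidome,
    LipidomeEntry,
    LipidSpecies,
    TEMPLATE_REGISTRY,
    rendered,
)
from .metrics import DistanceMatrix

__all__ = [
    "TableParseError",
    "parse_chain_shorthand",
    "read_lipidome_table",
    "write_lipidome_table",
    "read_smiles_file",
    "write_smiles_file",
    "read_matrix",
    "write_matrix",
    "write_coords",
    "write_newick",
    "file_digest",
]

log = logging.getLogger("lipidlux")

TABLE_COLUMNS = ["species_id", "class", "chains", "abundance"]

_CHAIN_RE = re.compile(r"^(?P<sph>d)?(?P<c>\d+):(?P<d>\d+)(?P<mods>(?:;(?:OH|db)\{[\d,]*\})*)$")
_MOD_RE = re.compile(r";(?P<kind>OH|db)\{(?P<body>[\d,]*)\}")


class TableParseError(LipidModelError):
    """Malformed lipidome table; message carries line context."""


def parse_chain_shorthand(text: str, roles: tuple[str, ...]) -> tuple[ChainSpec, ...]:
    """Parse ``d16:0/18:0;OH{2}``-style shorthand into ChainSpecs.

    ``roles`` comes from the class template's slots; the leading ``d``
    marker must agree with a sphingoid slot.  The declared double-bond
    count must match the number of ``db{}`` positions.
    """
    parts = text.split("/") if text not in ("", "-") else []
    if len(parts) != len(roles):
        raise TableParseError(
            f"expected {len(roles)} chain(s) for this class, got {len(parts)} in {text!r}"
        )
    chains = []
    for ci, (part, role) in enumerate(zip(parts, roles), start=1):
        m = _CHAIN_RE.match(part)
        if m is None:
            raise TableParseError(f"malformed chain shorthand {part!r} (chain {ci})")
        is_sph = bool(m.group("sph"))
        if is_sph != (role == "sphingoid"):
            raise TableParseError(
                f"chain {ci} {part!r}: 'd' sphingoid marker does not match the "
                f"class slot role {role!r}"
            )
        carbons = int(m.group("c"))
        declared_db = int(m.group("d"))
        dbs: list[int] = []
        ohs: list[int] = []
        for mod in _MOD_RE.finditer(m.group("mods")):
            body = [int(x) for x in mod.group("body").split(",") if x]
            if not body:
                raise TableParseError(f"empty position set in chain {ci} {part!r}")
            (dbs if mod.group("kind") == "db" else ohs).extend(body)
        if declared_db != len(dbs):
            raise TableParseError(
                f"chain {ci} {part!r} declares {declared_db} double bond(s) but "
                f"lists {len(dbs)} position(s); add ;db{{...}}"
            )
        try:
            chains.append(
                ChainSpec(carbons, tuple(sorted(dbs)), tuple(sorted(ohs)), role=role)
            )
        except LipidModelError as exc:
            raise TableParseError(f"chain {ci} {part!r}: {exc}") from exc
    return tuple(chains)


def read_lipidome_table(path: str | Path, name: str | None = None) -> Lipidome:
    """Read a lipidome TSV; species with identical rendered SMILES are
    collapsed with summed abundance (logged as a warning)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableParseError(f"{path}: missing column(s) {missing}; header must be {TABLE_COLUMNS}")
    entries: list[LipidomeEntry] = []
    by_smiles: dict[str, int] = {}
    for line_no, row in enumerate(
        df[TABLE_COLUMNS].itertuples(index=False), start=2
    ):
        sid, cls, chains_text, abundance_text = (str(v).strip() for v in row)
        tmpl = TEMPLATE_REGISTRY.get(cls)
        if tmpl is None:
            raise TableParseError(f"{path}:{line_no}: unknown lipid class {cls!r}")
        try:
            chains = parse_chain_shorthand(chains_text, tmpl.slots)
            abundance = float(abundance_text)
            sp = rendered(LipidSpecies(id=sid, lipid_class=cls, chains=chains))
            entry = LipidomeEntry(sp, abundance)
        except (LipidModelError, ValueError) as exc:
            raise TableParseError(f"{path}:{line_no}: {exc}") from exc
        if sp.smiles in by_smiles:
            k = by_smiles[sp.smiles]
            prev = entries[k]
            log.warning(
                "%s:%d: %r renders the same structure as %r; abundances summed",
                path, line_no, sid, prev.species.id,
            )
            entries[k] = LipidomeEntry(prev.species, prev.abundance + abundance)
        else:
            by_smiles[sp.smiles] = len(entries)
            entries.append(entry)
    return Lipidome(name or path.stem, entries)


def write_lipidome_table(lp: Lipidome, path: str | Path) -> None:
    rows = [
        {
            "species_id": e.species.id,
            "class": e.species.lipid_class,
            "chains": "/".join(c.shorthand() for c in e.species.chains) or "-",
            "abundance": f"{e.abundance:.6g}",
        }
        for e in lp.entries
    ]
    pd.DataFrame(rows, columns=TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


# -- SMILES files ------------------------------------------------------------

def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read ``.smi`` records, one ``SMILES<TAB>id`` per line."""
    out = []
    for line_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        if "\t" not in line:
            raise TableParseError(f"{path}:{line_no}: expected 'SMILES<TAB>id'")
        smiles, label = line.split("\t", 1)
        if not smiles.strip():
            raise TableParseError(f"{path}:{line_no}: empty SMILES field")
        out.append((label.strip(), smiles.strip()))
    return out


def write_smiles_file(records: list[tuple[str, str]], path: str | Path) -> None:
    """Write ``(label, smiles)`` records as ``SMILES<TAB>id`` lines."""
    Path(path).write_text("".join(f"{s}\t{lab}\n" for lab, s in records))


# -- matrices, coordinates, trees -------------------------------------------

def write_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    """Full symmetric CSV with a label header row and column."""
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("matrix contains non-finite values")
    df = pd.DataFrame(dm.values, index=dm.labels, columns=dm.labels)
    df.to_csv(path, float_format="%.6g", index_label="label")


def read_matrix(path: str | Path, metric_name: str = "") -> DistanceMatrix:
    df = pd.read_csv(path, index_col=0)
    return DistanceMatrix(list(df.columns), df.to_numpy(dtype=float), metric_name)


def write_coords(cs: ChemSpace, path: str | Path, variance_path: str | Path | None = None) -> None:
    k = cs.coords.shape[1]
    df = pd.DataFrame(cs.coords, columns=[f"pc{i + 1}" for i in range(k)])
    df.insert(0, "label", cs.labels)
    df.to_csv(path, index=False, float_format="%.6g")
    if variance_path is not None:
        vf = pd.DataFrame(
            {"component": np.arange(1, len(cs.explained) + 1), "fraction": cs.explained}
        )
        vf.to_csv(variance_path, index=False, float_format="%.6g")


def write_newick(tree: Dendrogram, path: str | Path, support: bool = False) -> None:
    Path(path).write_text(tree.newick(support=support) + "\n")


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file's bytes, for provenance logging."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
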