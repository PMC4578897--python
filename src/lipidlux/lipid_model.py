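"""Domain model for lipid molecular species and template-based SMILES.

The central idea is that SMILES strings are only comparable by string
metrics if equivalent substructures are always written the same way.
Instead of canonicalizing arbitrary SMILES, every lipid class has a fixed
template with slots for hydrocarbon chains, and every chain is written with
a fixed direction and a fixed spelling for its features (hydroxyls as
``(O)`` branches, double bonds as ``=``).  Rendering the same species twice
therefore yields byte-identical strings, and a one-carbon shift of a
hydroxyl group changes the string by a predictable, local edit.

The module also carries a minimal SMILES parser producing a
:class:`MolecularGraph` (heavy atoms only, implicit hydrogens), which backs
the path-based fingerprint metric and the molecular-formula validity check
for templates.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field, replace

__all__ = [
    "ChainSpec",
    "LipidSpecies",
    "Lipidome",
    "LipidomeEntry",
    "MolecularGraph",
    "LipidModelError",
    "ChainValidationError",
    "SmilesParseError",
    "ValenceError",
    "TEMPLATE_REGISTRY",
    "render_chain",
    "render_species",
    "rendered",
    "sanitize_smiles",
    "simplify_terminal_branches",
    "parse_smiles",
    "molecular_formula",
    "formula_string",
    "enumerate_isomers",
]


class LipidModelError(ValueError):
    """Base class for domain validation errors."""


class ChainValidationError(LipidModelError):
    """A ChainSpec violates a structural constraint."""


class SmilesParseError(LipidModelError):
    """Malformed SMILES input; carries the offending position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (position {position})"
        super().__init__(message)


class ValenceError(LipidModelError):
    """A parsed graph implies a negative implicit-hydrogen count."""


ROLES = ("acyl", "sphingoid", "amide-acyl")


@dataclass(frozen=True)
class ChainSpec:
    """One hydrocarbon chain of a lipid.

    Positions are counted from the carbon attached to the head group or
    carbonyl (position 1).  A double bond at position ``d`` sits between
    carbons ``d`` and ``d+1``.  For acyl chains position 1 is the carbonyl
    carbon and cannot carry a hydroxyl; for sphingoid chains positions 1-3
    carry the template's own substituents (1-OH, 2-NH, 3-OH of the
    dihydroxy amino backbone), so extra hydroxyls start at position 4.
    """

    carbons: int
    double_bonds: tuple[int, ...] = ()
    hydroxyls: tuple[int, ...] = ()
    role: str = "acyl"

    def __post_init__(self):
        object.__setattr__(self, "double_bonds", tuple(self.double_bonds))
        object.__setattr__(self, "hydroxyls", tuple(self.hydroxyls))
        if self.role not in ROLES:
            raise ChainValidationError(f"unknown chain role {self.role!r}")
        if self.carbons < 2:
            raise ChainValidationError("a chain needs at least 2 carbons")
        for name, positions, lo, hi in (
            ("double bond", self.double_bonds, 2, self.carbons - 1),
            ("hydroxyl", self.hydroxyls, 2, self.carbons),
        ):
            if list(positions) != sorted(set(positions)):
                raise ChainValidationError(
                    f"{name} positions must be sorted and unique: {positions}"
                )
            for p in positions:
                if not lo <= p <= hi:
                    raise ChainValidationError(
                        f"{name} position {p} outside [{lo}, {self.carbons if name == 'hydroxyl' else self.carbons - 1}]"
                        f" for a {self.carbons}-carbon chain"
                    )
        if self.role == "sphingoid":
            bad = [p for p in self.hydroxyls if p < 4]
            if bad:
                raise ChainValidationError(
                    f"sphingoid positions 1-3 are fixed by the backbone; extra "
                    f"hydroxyls must sit at position >= 4, got {bad}"
                )
        db = set(self.double_bonds)
        for m in range(2, self.carbons + 1):
            # cumulated diene centred on a substituted carbon would need a
            # pentavalent carbon
            if m - 1 in db and m in db:
                if m in self.hydroxyls or (self.role == "sphingoid" and m <= 3):
                    raise ChainValidationError(
                        f"cumulated double bonds around substituted carbon {m}"
                    )

    def shorthand(self) -> str:
        s = f"{'d' if self.role == 'sphingoid' else ''}{self.carbons}:{len(self.double_bonds)}"
        if self.double_bonds:
            s += ";db{" + ",".join(map(str, self.double_bonds)) + "}"
        if self.hydroxyls:
            s += ";OH{" + ",".join(map(str, self.hydroxyls)) + "}"
        return s


def render_chain(chain: ChainSpec, style: str = "carbonyl-first") -> str:
    """Render an acyl chain as a SMILES fragment.

    ``carbonyl-first`` writes ``C(=O)`` then carbons 2..n; ``tail-only``
    writes carbons 2..n alone (the template supplies the carbonyl).  A
    ``(O)`` branch follows each hydroxyl-bearing carbon and ``=`` precedes
    carbon ``d+1`` for a double bond at ``d``.
    """
    if style not in ("carbonyl-first", "tail-only"):
        raise ValueError(f"unknown chain style {style!r}")
    if chain.role == "sphingoid":
        raise ChainValidationError("sphingoid chains render inside their class template")
    parts = ["C(=O)"] if style == "carbonyl-first" else []
    db = set(chain.double_bonds)
    oh = set(chain.hydroxyls)
    for i in range(2, chain.carbons + 1):
        if i - 1 in db:
            parts.append("=")
        parts.append("C")
        if i in oh:
            parts.append("(O)")
    return "".join(parts)


def _render_sphingoid(chain: ChainSpec, c1_branch: str) -> str:
    """Sphingoid backbone written from the methyl end down to carbon 2.

    Carbon 3 carries the backbone hydroxyl, carbon 2 the amino nitrogen
    (written after, joining the amide), and carbon 1 sits in a branch whose
    oxygen either stays a free hydroxyl (``c1_branch='O'``, ceramide) or
    carries a phosphodiester head group.
    """
    if chain.carbons < 4:
        raise ChainValidationError("a sphingoid base needs at least 4 carbons")
    db = set(chain.double_bonds)
    oh = set(chain.hydroxyls)
    parts = []
    for i in range(chain.carbons, 3, -1):
        parts.append("C")
        if i in oh:
            parts.append("(O)")
        if i - 1 in db:
            parts.append("=")
    # carbon 3 (backbone OH), then carbon 2 with the C1 branch
    parts.append("C(O)")
    if 2 in db:
        parts.append("=")
    parts.append(f"C(C{c1_branch})")
    return "".join(parts)


# -- class templates ---------------------------------------------------------

_GPL_HEADS = {
    "PC": "OCCN(C)(C)C",
    "PE": "OCCN",
    "PS": "OCC(N)C(=O)O",
    "PI": "OC1C(O)C(O)C(O)C(O)C1O",
    "PA": "O",
}

# phosphoinositol / mannosyl-phosphoinositol head groups attached to the
# sphingoid C1 oxygen of yeast sphingolipids
_IPC_HEAD = "OP(=O)(O)OC1C(O)C(O)C(O)C(O)C1O"
_MIPC_HEAD = "OP(=O)(O)OC1C(O)C(O)C(O)C(OC2OC(CO)C(O)C(O)C2O)C1O"
_MIP2C_HEAD = (
    "OP(=O)(O)OC1C(O)C(O)C(O)C(OC2OC(COP(=O)(O)OC3C(O)C(O)C(O)C(O)C3O)C(O)C(O)C2O)C1O"
)

# ergostane-type sterol skeleton (delta-5,7,22 triene, 24-methyl side
# chain); {O} is the 3-position oxygen: "(O)" free sterol, ester in CE
_STEROL_CORE = "CC(C=CC(C)C(C)C)C1CCC2C1(C)CCC3C2=CC=C4C3(C)CCC{O}C4"


def _render_cer_family(chains, head_branch: str) -> str:
    base, amide = chains
    return _render_sphingoid(base, head_branch) + "N" + render_chain(amide, "carbonyl-first")


def _render_gpl(chains, head: str) -> str:
    sn1, sn2 = (render_chain(c, "tail-only") for c in chains)
    return f"C(COC(=O){sn1})(OC(=O){sn2})COP(=O)(O){head}"


def _render_tag(chains) -> str:
    sn1, sn2, sn3 = (render_chain(c, "tail-only") for c in chains)
    return f"C(COC(=O){sn1})(OC(=O){sn2})COC(=O){sn3}"


def _render_dag(chains) -> str:
    sn1, sn2 = (render_chain(c, "tail-only") for c in chains)
    return f"C(COC(=O){sn1})(OC(=O){sn2})CO"


@dataclass(frozen=True)
class _Template:
    slots: tuple[str, ...]  # chain role per slot
    render: object  # callable(chains) -> str


TEMPLATE_REGISTRY: dict[str, _Template] = {
    "CER": _Template(("sphingoid", "amide-acyl"), lambda ch: _render_cer_family(ch, "O")),
    "IPC": _Template(("sphingoid", "amide-acyl"), lambda ch: _render_cer_family(ch, _IPC_HEAD)),
    "MIPC": _Template(("sphingoid", "amide-acyl"), lambda ch: _render_cer_family(ch, _MIPC_HEAD)),
    "MIP2C": _Template(("sphingoid", "amide-acyl"), lambda ch: _render_cer_family(ch, _MIP2C_HEAD)),
    "PC": _Template(("acyl", "acyl"), lambda ch: _render_gpl(ch, _GPL_HEADS["PC"])),
    "PE": _Template(("acyl", "acyl"), lambda ch: _render_gpl(ch, _GPL_HEADS["PE"])),
    "PS": _Template(("acyl", "acyl"), lambda ch: _render_gpl(ch, _GPL_HEADS["PS"])),
    "PI": _Template(("acyl", "acyl"), lambda ch: _render_gpl(ch, _GPL_HEADS["PI"])),
    "PA": _Template(("acyl", "acyl"), lambda ch: _render_gpl(ch, _GPL_HEADS["PA"])),
    "TAG": _Template(("acyl", "acyl", "acyl"), _render_tag),
    "DAG": _Template(("acyl", "acyl"), _render_dag),
    "CE": _Template(
        ("acyl",),
        lambda ch: _STEROL_CORE.format(O=f"(OC(=O){render_chain(ch[0], 'tail-only')})"),
    ),
    "STEROL": _Template((), lambda ch: _STEROL_CORE.format(O="(O)")),
}


@dataclass(frozen=True)
class LipidSpecies:
    """A lipid class plus its chains, renderable to one template SMILES."""

    id: str
    lipid_class: str
    chains: tuple[ChainSpec, ...] = ()
    smiles: str | None = field(default=None, compare=False)

    def __post_init__(self):
        object.__setattr__(self, "chains", tuple(self.chains))
        tmpl = TEMPLATE_REGISTRY.get(self.lipid_class)
        if tmpl is None:
            raise LipidModelError(f"unknown lipid class {self.lipid_class!r}")
        if len(self.chains) != len(tmpl.slots):
            raise LipidModelError(
                f"{self.lipid_class} takes {len(tmpl.slots)} chain(s), got {len(self.chains)}"
            )
        for slot_role, chain in zip(tmpl.slots, self.chains):
            if chain.role != slot_role:
                raise LipidModelError(
                    f"{self.lipid_class} slot expects role {slot_role!r}, got {chain.role!r}"
                )


def render_species(species: LipidSpecies) -> str:
    """Render a species to its deterministic template SMILES string."""
    if species.smiles is not None:
        return species.smiles
    tmpl = TEMPLATE_REGISTRY[species.lipid_class]
    return tmpl.render(species.chains)


def rendered(species: LipidSpecies) -> LipidSpecies:
    """Return a copy with the SMILES cache filled."""
    if species.smiles is not None:
        return species
    return replace(species, smiles=render_species(species))


# -- sanitization ------------------------------------------------------------

_BRACKET_RE = re.compile(r"\[(?P<body>[^\]]*)\]")
_BRACKET_BODY_RE = re.compile(
    r"^(?P<isotope>\d+)?(?P<elem>[A-Z][a-z]?)(?P<chiral>@{1,2})?(?P<hcount>H\d*)?(?P<charge>[+-]\d*|[+-]+)?$"
)


def _collapse_bracket(m: re.Match) -> str:
    body = _BRACKET_BODY_RE.match(m.group("body"))
    if body is None:
        return m.group(0)
    return body.group("elem")


def sanitize_smiles(s: str) -> str:
    """Strip chirality, cis/trans and charge decorations from a SMILES string.

    ``[N+]`` collapses to ``N``, ``[C@@H]`` to ``C``; bare ``/ \\ @`` marks
    are dropped.  Idempotent, and a no-op on already-clean strings.
    """
    if not s:
        raise ValueError("empty SMILES string")
    s = _BRACKET_RE.sub(_collapse_bracket, s)
    return s.translate({ord(c): None for c in "@/\\"})


def simplify_terminal_branches(s: str) -> str:
    """Elide redundant parentheses around trailing branches.

    A branch written last at its nesting level needs no parentheses:
    ``...CCC(O)`` and ``...CCCO`` encode the same molecule, and standard
    SMILES emitters write the latter.  The template renderer keeps the
    parentheses so that equivalent substructures stay byte-identical
    everywhere in a string; this helper produces the emitter-style form,
    which matters when comparing against substring-based similarity results
    computed on conventionally written SMILES.  Idempotent.
    """
    changed = True
    while changed:
        changed = False
        out = []
        i = 0
        while i < len(s):
            ch = s[i]
            if ch == "(":
                depth = 1
                j = i + 1
                while j < len(s) and depth:
                    if s[j] == "(":
                        depth += 1
                    elif s[j] == ")":
                        depth -= 1
                    j += 1
                if depth == 0 and (j == len(s) or s[j] == ")"):
                    out.append(s[i + 1 : j - 1])
                    i = j
                    changed = True
                    continue
            out.append(ch)
            i += 1
        s = "".join(out)
    return s


# -- minimal SMILES parser ---------------------------------------------------

@dataclass
class MolecularGraph:
    """Heavy-atom skeleton: element symbols plus bonds with integer orders."""

    atoms: list[str]
    bonds: list[tuple[int, int, int]]

    def neighbors(self) -> list[list[tuple[int, int]]]:
        adj: list[list[tuple[int, int]]] = [[] for _ in self.atoms]
        for i, j, order in self.bonds:
            adj[i].append((j, order))
            adj[j].append((i, order))
        return adj


_ELEMENTS = set("CNOPS")
_BOND_CHARS = {"=": 2, "#": 3}


def parse_smiles(s: str) -> MolecularGraph:
    """Parse a sanitized SMILES subset into a molecular graph.

    Supported: the C/N/O/P/S organic set written as bare symbols, branches
    ``( )``, bond orders ``=`` and ``#``, and single-digit ring closures.
    """
    atoms: list[str] = []
    bonds: list[tuple[int, int, int]] = []
    stack: list[int] = []
    prev: int | None = None
    pending_order = 1
    ring_open: dict[str, tuple[int, int]] = {}

    for pos, ch in enumerate(s):
        if ch in _ELEMENTS:
            idx = len(atoms)
            atoms.append(ch)
            if prev is not None:
                bonds.append((prev, idx, pending_order))
            pending_order = 1
            prev = idx
        elif ch in _BOND_CHARS:
            pending_order = _BOND_CHARS[ch]
        elif ch == "(":
            if prev is None:
                raise SmilesParseError("branch before any atom", pos)
            stack.append(prev)
        elif ch == ")":
            if not stack:
                raise SmilesParseError("unbalanced ')'", pos)
            prev = stack.pop()
        elif ch.isdigit():
            if prev is None:
                raise SmilesParseError("ring closure before any atom", pos)
            if ch in ring_open:
                other, order = ring_open.pop(ch)
                order = max(order, pending_order)
                if other == prev:
                    raise SmilesParseError("ring closure to the same atom", pos)
                bonds.append((other, prev, order))
                pending_order = 1
            else:
                ring_open[ch] = (prev, pending_order)
                pending_order = 1
        else:
            raise SmilesParseError(f"unsupported character {ch!r}", pos)

    if stack:
        raise SmilesParseError("unbalanced '('", len(s))
    if ring_open:
        digit = sorted(ring_open)[0]
        raise SmilesParseError(f"unmatched ring-closure digit {digit!r}", len(s))
    if not atoms:
        raise SmilesParseError("no atoms", 0)
    # connectivity check (templates always yield connected molecules)
    seen = {0}
    frontier = [0]
    adj = MolecularGraph(atoms, bonds).neighbors()
    while frontier:
        for j, _ in adj[frontier.pop()]:
            if j not in seen:
                seen.add(j)
                frontier.append(j)
    if len(seen) != len(atoms):
        raise SmilesParseError("disconnected structure", 0)
    return MolecularGraph(atoms, bonds)


_VALENCE = {"C": 4, "N": 3, "O": 2, "P": 5, "S": 2}


def molecular_formula(g: MolecularGraph) -> dict[str, int]:
    """Element counts with implicit hydrogens from standard valences.

    Phosphorus is taken pentavalent, as written in phosphate templates.
    A nitrogen with four bonds and no hydrogens is accepted (a
    charge-stripped quaternary ammonium, as sanitization leaves the
    choline head group); any other over-valent atom is an error.
    """
    counts: dict[str, int] = {}
    order_sum = [0] * len(g.atoms)
    for i, j, order in g.bonds:
        order_sum[i] += order
        order_sum[j] += order
    h = 0
    for idx, elem in enumerate(g.atoms):
        counts[elem] = counts.get(elem, 0) + 1
        implicit = _VALENCE[elem] - order_sum[idx]
        if implicit < 0:
            if elem == "N" and order_sum[idx] == 4:
                implicit = 0  # charge-stripped quaternary ammonium
            else:
                raise ValenceError(
                    f"atom {idx} ({elem}) has bond-order sum {order_sum[idx]} exceeding valence"
                )
        h += implicit
    if h:
        counts["H"] = h
    return counts


def formula_string(counts: dict[str, int]) -> str:
    """Hill-order formula string (C, H, then alphabetical)."""
    order = [e for e in ("C", "H") if e in counts]
    order += sorted(e for e in counts if e not in ("C", "H"))
    return "".join(f"{e}{counts[e] if counts[e] != 1 else ''}" for e in order)


# -- isomer enumeration ------------------------------------------------------

def enumerate_isomers(
    species: LipidSpecies,
    unresolved: list[tuple[int, str, list[int]]],
) -> list[LipidSpecies]:
    """Expand a species with unresolved feature positions into isomers.

    ``unresolved`` lists ``(chain_index, kind, allowed_positions)`` with
    kind ``"hydroxyl"`` or ``"double_bond"``; each entry places one feature
    at one allowed position.  The result is the Cartesian product over
    entries, in ascending position order, each isomer rendered.
    """
    if not unresolved:
        return [rendered(species)]
    for ci, kind, allowed in unresolved:
        if not allowed:
            raise LipidModelError("empty allowed position set")
        if kind not in ("hydroxyl", "double_bond"):
            raise LipidModelError(f"unknown feature kind {kind!r}")
        if not 0 <= ci < len(species.chains):
            raise LipidModelError(f"chain index {ci} out of range")
    choices = [sorted(allowed) for _, _, allowed in unresolved]
    out = []
    for combo in itertools.product(*choices):
        chains = list(species.chains)
        for (ci, kind, _), pos in zip(unresolved, combo):
            c = chains[ci]
            if kind == "hydroxyl":
                chains[ci] = replace(c, hydroxyls=tuple(sorted(c.hydroxyls + (pos,))))
            else:
                chains[ci] = replace(c, double_bonds=tuple(sorted(c.double_bonds + (pos,))))
        tag = "-".join(
            f"{'oh' if kind == 'hydroxyl' else 'db'}{pos}"
            for (_, kind, _), pos in zip(unresolved, combo)
        )
        out.append(
            rendered(
                LipidSpecies(
                    id=f"{species.id}|{tag}",
                    lipid_class=species.lipid_class,
                    chains=tuple(chains),
                )
            )
        )
    return out


# -- lipidomes ---------------------------------------------------------------

@dataclass(frozen=True)
class LipidomeEntry:
    """A species with its molar-percentage abundance."""

    species: LipidSpecies
    abundance: float

    def __post_init__(self):
        if not (self.abundance >= 0) or self.abundance != self.abundance:
            raise LipidModelError(f"abundance must be finite and >= 0, got {self.abundance}")


class Lipidome:
    """A named collection of lipid species with mol% abundances."""

    def __init__(self, name: str, entries: list[LipidomeEntry] | None = None):
        self.name = name
        self.entries: list[LipidomeEntry] = list(entries or [])
        ids = [e.species.id for e in self.entries]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise LipidModelError(f"duplicate species ids in lipidome {name!r}: {dup}")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def species(self) -> list[LipidSpecies]:
        return [e.species for e in self.entries]

    def smiles(self) -> list[str]:
        """Unique rendered SMILES, in first-appearance order."""
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(render_species(e.species), None)
        return list(seen)

    def abundance_by_smiles(self) -> dict[str, float]:
        out: dict[str, float] = {}
        for e in self.entries:
            s = render_species(e.species)
            out[s] = out.get(s, 0.0) + e.abundance
        return out
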