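"""Chain/template rendering, sanitization, parsing and formula checks."""

import pytest
from hypothesis import assume, given
from hypothesis import strategies as st

from lipidlux.lipid_model import (
    ChainSpec,
    ChainValidationError,
    LipidModelError,
    LipidSpecies,
    SmilesParseError,
    TEMPLATE_REGISTRY,
    ValenceError,
    enumerate_isomers,
    formula_string,
    molecular_formula,
    parse_smiles,
    render_chain,
    render_species,
    rendered,
    sanitize_smiles,
    simplify_terminal_branches,
)


class TestChainSpec:
    def test_positions_validated(self):
        with pytest.raises(ChainValidationError):
            ChainSpec(18, hydroxyls=(1,))  # carbonyl carbon cannot carry OH
        with pytest.raises(ChainValidationError):
            ChainSpec(18, hydroxyls=(19,))
        with pytest.raises(ChainValidationError):
            ChainSpec(18, double_bonds=(18,))  # max is carbons-1
        with pytest.raises(ChainValidationError):
            ChainSpec(18, double_bonds=(9, 9))
        with pytest.raises(ChainValidationError):
            ChainSpec(1)

    def test_sphingoid_backbone_positions_reserved(self):
        with pytest.raises(ChainValidationError):
            ChainSpec(18, hydroxyls=(3,), role="sphingoid")
        ChainSpec(18, hydroxyls=(4,), role="sphingoid")  # t-series OK


class TestRenderChain:
    @pytest.mark.parametrize(
        "chain, style, expected",
        [
            (ChainSpec(18, hydroxyls=(2,)), "carbonyl-first", "C(=O)C(O)CCCCCCCCCCCCCCCC"),
            (ChainSpec(4), "carbonyl-first", "C(=O)CCC"),
            (ChainSpec(18, double_bonds=(9,)), "carbonyl-first", "C(=O)CCCCCCCC=CCCCCCCCC"),
            (ChainSpec(4), "tail-only", "CCC"),
            (ChainSpec(2), "tail-only", "C"),
        ],
    )
    def test_examples(self, chain, style, expected):
        assert render_chain(chain, style) == expected

    def test_double_bond_sits_between_d_and_d_plus_1(self):
        # 18:1(9): carbons 2..9 written, then = before carbon 10
        frag = render_chain(ChainSpec(18, double_bonds=(9,)), "carbonyl-first")
        assert frag.index("=C", 5) == 5 + 8  # 8 chain carbons after "C(=O)"
        assert ChainValidationError  # imported; chemistry guards live in ChainSpec


class TestRenderSpecies:
    def test_ceramide_oh2(self):
        sp = LipidSpecies(
            "cer",
            "CER",
            (ChainSpec(16, role="sphingoid"), ChainSpec(18, hydroxyls=(2,), role="amide-acyl")),
        )
        s = render_species(sp)
        assert s == "CCCCCCCCCCCCCC(O)C(CO)NC(=O)C(O)CCCCCCCCCCCCCCCC"
        assert len(s) == 48

    def test_ceramide_oh18_moves_branch_to_end(self):
        sp = LipidSpecies(
            "cer",
            "CER",
            (ChainSpec(16, role="sphingoid"), ChainSpec(18, hydroxyls=(18,), role="amide-acyl")),
        )
        assert render_species(sp).endswith("C(O)")

    def test_tag_shortest(self):
        sp = LipidSpecies("tag", "TAG", tuple(ChainSpec(2) for _ in range(3)))
        assert render_species(sp) == "C(COC(=O)C)(OC(=O)C)COC(=O)C"

    def test_rendering_deterministic(self):
        sp = LipidSpecies("pc", "PC", (ChainSpec(16), ChainSpec(18, (9,))))
        assert render_species(sp) == render_species(sp)

    def test_slot_mismatch_rejected(self):
        with pytest.raises(LipidModelError):
            LipidSpecies("x", "CER", (ChainSpec(16), ChainSpec(18)))  # roles wrong
        with pytest.raises(LipidModelError):
            LipidSpecies("x", "TAG", (ChainSpec(16), ChainSpec(18)))
        with pytest.raises(LipidModelError):
            LipidSpecies("x", "NOPE", ())


class TestSanitize:
    @pytest.mark.parametrize(
        "raw, clean",
        [
            ("C[C@H](O)C", "CC(O)C"),
            ("CC/C=C\\CC", "CCC=CCC"),
            ("CC[N+](C)(C)C", "CCN(C)(C)C"),
            ("CCO", "CCO"),
            ("[O-]C", "OC"),
        ],
    )
    def test_examples(self, raw, clean):
        assert sanitize_smiles(raw) == clean

    @given(st.text(alphabet="CNOP()=@/\\[]+-H123", min_size=1, max_size=30))
    def test_idempotent(self, s):
        once = sanitize_smiles(s)
        assume(once)  # strings of pure decoration sanitize to nothing
        assert sanitize_smiles(once) == once


class TestSimplifyTerminalBranches:
    @pytest.mark.parametrize(
        "s, expected",
        [
            ("CCC(O)", "CCCO"),
            ("C(C(O))", "CCO"),
            ("C(A)(B)", "C(A)B"),
            ("C(O)C", "C(O)C"),  # interior branch kept
        ],
    )
    def test_examples(self, s, expected):
        assert simplify_terminal_branches(s) == expected

    def test_preserves_molecule(self):
        a = parse_smiles("CCC(O)")
        b = parse_smiles(simplify_terminal_branches("CCC(O)"))
        assert molecular_formula(a) == molecular_formula(b)


class TestParseSmiles:
    def test_linear(self):
        g = parse_smiles("CCO")
        assert g.atoms == ["C", "C", "O"]
        assert sorted((min(i, j), max(i, j), o) for i, j, o in g.bonds) == [
            (0, 1, 1),
            (1, 2, 1),
        ]

    def test_ring_closure_triangle(self):
        g = parse_smiles("C1CC1")
        assert len(g.atoms) == 3 and len(g.bonds) == 3
        assert all(o == 1 for *_, o in g.bonds)

    def test_double_bond_in_branch(self):
        g = parse_smiles("CC(=O)O")
        assert len(g.atoms) == 4
        orders = sorted(o for *_, o in g.bonds)
        assert orders == [1, 1, 2]

    @pytest.mark.parametrize("bad", ["CC(C", "CC)", "C1CC", "CCl", "C%11C", ""])
    def test_errors_name_position(self, bad):
        with pytest.raises((SmilesParseError, ValueError)):
            parse_smiles(bad)


class TestMolecularFormula:
    @pytest.mark.parametrize(
        "smiles, expected",
        [("C", "CH4"), ("CCO", "C2H6O"), ("CC(=O)O", "C2H4O2"), ("O=C=O", "CO2")],
    )
    def test_small_molecules(self, smiles, expected):
        assert formula_string(molecular_formula(parse_smiles(smiles))) == expected

    def test_ceramide_composition(self, ceramides):
        # C34 ceramide with one amide carbonyl: H = 2C + 1 for the acyclic
        # saturated backbone -> C34H69NO4
        f = molecular_formula(parse_smiles(ceramides[0].smiles))
        assert formula_string(f) == "C34H69NO4"

    def test_overvalent_carbon_rejected(self):
        with pytest.raises(ValenceError):
            molecular_formula(parse_smiles("C(=O)(=O)=O"))


# closed-form composition per class: heavy atoms added by the template
# beyond the chains, plus template rings and double bonds.  H then follows
# from valences: H = 4C + 3N + 2O + 5P - 2*(bonds), quaternary N adjusted.
_CLASS_CLOSED_FORM = {
    # extra C, extra O, N, P, rings, extra double bonds, quaternary N count
    "PC": (8, 8, 1, 1, 0, 3, 1),
    "PE": (5, 8, 1, 1, 0, 3, 0),
    "PS": (6, 10, 1, 1, 0, 4, 0),
    "PI": (9, 13, 0, 1, 1, 3, 0),
    "PA": (3, 8, 0, 1, 0, 3, 0),
    "TAG": (3, 6, 0, 0, 0, 3, 0),
    "DAG": (3, 5, 0, 0, 0, 2, 0),
    "CER": (0, 3, 1, 0, 0, 1, 0),
}


@st.composite
def _chain(draw, role="acyl"):
    n = draw(st.integers(min_value=4, max_value=26))
    dbs = draw(st.sets(st.integers(2, n - 1), max_size=3))
    lo = 4 if role == "sphingoid" else 2
    ohs = draw(st.sets(st.integers(lo, n), max_size=2))
    try:
        return ChainSpec(n, tuple(sorted(dbs)), tuple(sorted(ohs)), role=role)
    except ChainValidationError:  # cumulated diene at a substituted carbon
        assume(False)


@given(data=st.data(), cls=st.sampled_from(sorted(_CLASS_CLOSED_FORM)))
def test_render_parse_formula_round_trip(data, cls):
    """Rendered template SMILES parse back to the closed-form composition."""
    roles = TEMPLATE_REGISTRY[cls].slots
    chains = tuple(data.draw(_chain(role=r)) for r in roles)
    sp = LipidSpecies("x", cls, chains)
    f = molecular_formula(parse_smiles(render_species(sp)))
    xc, xo, n_n, n_p, rings, xdb, quat = _CLASS_CLOSED_FORM[cls]
    n_c = xc + sum(c.carbons for c in chains)
    n_o = xo + sum(len(c.hydroxyls) for c in chains)
    db = xdb + sum(len(c.double_bonds) for c in chains)
    heavy = n_c + n_o + n_n + n_p
    bonds = heavy - 1 + rings  # connected graph
    h = 4 * n_c + 3 * n_n + 2 * n_o + 5 * n_p + quat - 2 * (bonds + db)
    assert f.get("C", 0) == n_c
    assert f.get("O", 0) == n_o
    assert f.get("N", 0) == n_n
    assert f.get("P", 0) == n_p
    assert f.get("H", 0) == h


def test_rendered_formulas_match_rdkit():
    """Independent cross-check of parser + implicit-H rules against RDKit."""
    rdkit = pytest.importorskip("rdkit")
    from rdkit import Chem, RDLogger
    from rdkit.Chem.rdMolDescriptors import CalcMolFormula

    RDLogger.DisableLog("rdApp.*")
    cases = [
        LipidSpecies("a", "PC", (ChainSpec(16), ChainSpec(18, (9,)))),
        LipidSpecies("b", "PI", (ChainSpec(16), ChainSpec(18))),
        LipidSpecies("c", "TAG", (ChainSpec(16), ChainSpec(18), ChainSpec(18, (9,)))),
        LipidSpecies("d", "STEROL", ()),
        LipidSpecies("e", "CE", (ChainSpec(16),)),
        LipidSpecies(
            "f",
            "MIP2C",
            (ChainSpec(18, role="sphingoid", hydroxyls=(4,)), ChainSpec(26, role="amide-acyl")),
        ),
    ]
    for sp in cases:
        s = render_species(sp)
        mol = Chem.MolFromSmiles(s, sanitize=False)
        assert mol is not None
        mol.UpdatePropertyCache(strict=False)
        assert formula_string(molecular_formula(parse_smiles(s))) == CalcMolFormula(mol)


class TestEnumerateIsomers:
    def test_ceramide_hydroxyl_scan_has_17(self):
        sp = LipidSpecies(
            "cer", "CER", (ChainSpec(16, role="sphingoid"), ChainSpec(18, role="amide-acyl"))
        )
        isomers = enumerate_isomers(sp, [(1, "hydroxyl", list(range(2, 19)))])
        assert len(isomers) == 17
        assert len({i.smiles for i in isomers}) == 17

    def test_fully_specified_is_singleton(self):
        sp = LipidSpecies("pc", "PC", (ChainSpec(16), ChainSpec(18)))
        assert len(enumerate_isomers(sp, [])) == 1

    def test_product_count(self):
        sp = LipidSpecies(
            "cer", "CER", (ChainSpec(16, role="sphingoid"), ChainSpec(18, role="amide-acyl"))
        )
        isomers = enumerate_isomers(
            sp, [(1, "hydroxyl", [2, 3]), (1, "double_bond", [6, 9, 12])]
        )
        assert len(isomers) == 6
        assert [i.id for i in isomers] == [
            "cer|oh2-db6", "cer|oh2-db9", "cer|oh2-db12",
            "cer|oh3-db6", "cer|oh3-db9", "cer|oh3-db12",
        ]

    def test_empty_allowed_set_rejected(self):
        sp = LipidSpecies(
            "cer", "CER", (ChainSpec(16, role="sphingoid"), ChainSpec(18, role="amide-acyl"))
        )
        with pytest.raises(LipidModelError):
            enumerate_isomers(sp, [(1, "hydroxyl", [])])


def test_ceramide_scan_strings_equal_length_and_distinct(ceramide_smiles):
    assert len(ceramide_smiles) == 17
    assert {len(s) for s in ceramide_smiles} == {48}
    assert len(set(ceramide_smiles)) == 17
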