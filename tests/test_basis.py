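import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aotrunc.basis import (
    AOBasisSet,
    BasisError,
    BasisParseError,
    BasisShell,
    apply_truncation,
    count_functions,
    even_tempered_extend,
    expand,
    format_basis,
    load_basis,
    parse_basis_text,
    parse_composition,
)
from aotrunc.geometry import MolecularGeometry
from aotrunc.geometry import make_h2_dimer

H1 = MolecularGeometry(("H",), np.zeros((1, 3)), charge=1)


class TestParse:
    def test_single_shell(self):
        b = parse_basis_text("H S\n 1.0 1.0\n")
        assert b.composition("H") == "1s"
        assert len(expand(b, H1)) == 1

    def test_sp_composite_split(self):
        b = parse_basis_text("O SP\n 1.0 0.5 0.3\n 0.4 0.5 0.7\n")
        assert b.composition("O") == "1s1p"

    def test_unknown_letter(self):
        with pytest.raises(BasisParseError):
            parse_basis_text("H Q\n 1.0 1.0\n")

    def test_row_before_header(self):
        with pytest.raises(BasisParseError):
            parse_basis_text(" 1.0 1.0\nH S\n")

    def test_non_numeric_exponent(self):
        with pytest.raises(BasisParseError):
            parse_basis_text("H S\n one 1.0\n")

    def test_vendored_compositions(self):
        assert load_basis("6-31G").composition("H") == "2s"
        assert load_basis("6-31G**").composition("H") == "2s1p"
        assert load_basis("6-31++G").composition("H") == "3s"
        assert load_basis("6-31++G**").composition("H") == "3s1p"
        tz = load_basis("tz-synthetic")
        assert tz.composition("H") == "3s3p1d"
        assert tz.composition("O") == "6s4p3d1f"

    @pytest.mark.parametrize("name", ["6-31G", "6-31++G**", "tz-synthetic"])
    def test_write_parse_round_trip(self, name):
        b = load_basis(name)
        back = parse_basis_text(format_basis(b))
        assert set(back.element_shells) == set(b.element_shells)
        for el in b.element_shells:
            assert back.composition(el) == b.composition(el)
            for s1, s2 in zip(b.element_shells[el], back.element_shells[el]):
                assert s1.l == s2.l
                assert np.allclose(s1.exponents, s2.exponents, rtol=1e-12)
                assert np.allclose(s1.coefficients, s2.coefficients, rtol=1e-12)


class TestExpand:
    def test_single_h_631g(self):
        labels = expand(load_basis("6-31G"), H1)
        assert [f"{l.k}{l.m_name}" for l in labels] == ["1s", "2s"]

    def test_dimer_631ppgss_count(self):
        labels = expand(load_basis("6-31++G**"), make_h2_dimer())
        assert len(labels) == 24
        assert [l.mu for l in labels] == list(range(24))
        assert len(set(labels)) == 24

    def test_empty_geometry(self):
        g = MolecularGeometry((), np.zeros((0, 3)))
        assert expand(load_basis("6-31G"), g) == []

    def test_missing_element(self):
        b = parse_basis_text("H S\n 1.0 1.0\n")
        g = MolecularGeometry(("O",), np.zeros((1, 3)))
        with pytest.raises(BasisError):
            expand(b, g)


class TestCounting:
    @pytest.mark.parametrize(
        "comp,counts,expected",
        [
            ({"H": "3s3p1d", "O": "6s4p3d1f"}, {"H": 4, "O": 2}, 148),
            ({"H": "5s3p", "O": "8s6p3d"}, {"H": 4, "O": 2}, 138),
            ({"H": "1s"}, {"H": 1}, 1),
        ],
    )
    def test_spherical_counts(self, comp, counts, expected):
        assert count_functions(comp, counts) == expected

    def test_unknown_letter(self):
        with pytest.raises(BasisError):
            parse_composition("2q")

    @given(
        st.lists(
            st.tuples(st.integers(0, 4), st.integers(1, 5)),
            min_size=1, max_size=5,
        ),
        st.integers(1, 4),
    )
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_count_matches_expansion(self, shell_spec, n_atoms):
        """count_functions and expand agree on arbitrary shell structures."""
        shells = tuple(
            BasisShell("H", l, tuple(2.0 ** -k for k in range(n)), (1.0,) * n)
            for l, n in shell_spec
        )
        basis = AOBasisSet("rand", {"H": shells})
        geom = MolecularGeometry(
            ("H",) * n_atoms, np.arange(3 * n_atoms, dtype=float).reshape(-1, 3)
        )
        comp = basis.composition("H")
        assert len(expand(basis, geom)) == count_functions(
            {"H": comp}, {"H": n_atoms}
        )


class TestEvenTempered:
    def test_geometric_progression(self):
        assert even_tempered_extend((4.0, 2.0)) == pytest.approx(1.0)
        assert even_tempered_extend((9.0, 3.0, 1.0)) == pytest.approx(1.0 / 3.0)

    def test_requires_two_distinct(self):
        with pytest.raises(BasisError):
            even_tempered_extend((1.0,))
        with pytest.raises(BasisError):
            even_tempered_extend((1.0, 1.0))

    def test_double_extension_stays_geometric(self):
        exps = [7.3, 1.9]
        a1 = even_tempered_extend(exps)
        a2 = even_tempered_extend(exps + [a1])
        assert a2 / a1 == pytest.approx(a1 / exps[1], rel=1e-12)

    def test_synthetic_tz_channel_extension_compositions(self):
        """Extending every l-channel of a truncated triple-zeta-like pair
        (H 3s3p, O 6s4p2d) by one even-tempered diffuse function yields
        4s4p and 7s5p3d."""
        tz = load_basis("tz-synthetic")
        h = [s for s in tz.element_shells["H"] if s.l <= 1]
        o = [s for s in tz.element_shells["O"] if s.l <= 2]
        o = [s for s in o if not (s.l == 2 and s is o[-1])]  # drop 3rd d
        def extend_all(shells):
            out = list(shells)
            for l in sorted({s.l for s in shells}):
                exps = [a for s in shells if s.l == l for a in s.exponents]
                alpha = even_tempered_extend(sorted(exps)[:2][::-1])
                out.append(BasisShell(shells[0].element, l, (alpha,), (1.0,)))
            return out
        bh = AOBasisSet("x", {"H": tuple(extend_all(h))})
        bo = AOBasisSet("x", {"O": tuple(extend_all(o))})
        assert bh.composition("H") == "4s4p"
        assert bo.composition("O") == "7s5p3d"


class TestTruncation:
    def test_empty_deleted_is_identity(self):
        b = load_basis("6-31++G**")
        g = make_h2_dimer()
        out = apply_truncation(b, g, set(), level="function")
        assert [str(l) for l in expand(out, g)] == [str(l) for l in expand(b, g)]

    def test_whole_p_shells_reduce_to_unpolarized(self):
        b = load_basis("6-31++G**")
        g = make_h2_dimer()
        deleted = {l for l in expand(b, g) if l.l == 1}
        out = apply_truncation(b, g, deleted, level="shell")
        assert out.composition(next(iter(out.element_shells))) == "3s"
        ref = load_basis("6-31++G")
        assert [f"{l.k}{l.m_name}" for l in expand(out, g)] == [
            f"{l.k}{l.m_name}" for l in expand(ref, g)
        ]

    def test_partial_shell_at_shell_level_is_error(self):
        b = load_basis("6-31++G**")
        g = make_h2_dimer()
        pz = {l for l in expand(b, g) if l.m_name == "p_z"}
        with pytest.raises(BasisError):
            apply_truncation(b, g, pz, level="shell")

    def test_function_level_partial_shell(self):
        b = load_basis("6-31++G**")
        g = make_h2_dimer()
        pxy = {l for l in expand(b, g) if l.m_name in ("p_x", "p_y")}
        out = apply_truncation(b, g, pxy, level="function")
        labels = expand(out, g)
        assert len(labels) == 16
        assert all(l.m_name != "p_x" and l.m_name != "p_y" for l in labels)
        assert out.has_partial_shells()
        with pytest.raises(BasisError):
            format_basis(out)

    def test_idempotent(self):
        b = load_basis("6-31G**")
        g = make_h2_dimer()
        pxy = {l for l in expand(b, g) if l.m_name in ("p_x", "p_y")}
        once = apply_truncation(b, g, pxy, level="function")
        twice = apply_truncation(once, g, set(), level="function")
        assert [str(l) for l in expand(twice, g)] == [
            str(l) for l in expand(once, g)
        ]

    def test_asymmetric_deletion_gets_per_atom_keys(self):
        b = load_basis("6-31G**")
        g = make_h2_dimer()
        # delete the whole p shell of atom 0 only
        dele = {l for l in expand(b, g) if l.l == 1 and l.atom == 0}
        out = apply_truncation(b, g, dele, level="shell")
        assert out.atom_keys is not None
        labels = expand(out, g)
        assert len(labels) == 20 - 3
        per_atom = {a: sum(1 for l in labels if l.atom == a) for a in range(4)}
        assert per_atom == {0: 2, 1: 5, 2: 5, 3: 5}

    def test_deleting_everything_on_an_atom_is_error(self):
        b = load_basis("6-31G")
        g = make_h2_dimer()
        dele = {l for l in expand(b, g) if l.atom == 0}
        with pytest.raises(BasisError):
            apply_truncation(b, g, dele, level="shell")
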