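"""Fragment enumeration: backbone series, glycan Y/B stepping, oxonium ions."""

import numpy as np
import pytest

import glycoplot as gp
from glycoplot.chemistry import PROTON
from glycoplot.errors import ValidationError
from glycoplot.fragments import DissociationMethod

from conftest import (
    ORACLE_NH3,
    ORACLE_H,
    brute_force_B,
    brute_force_Y,
    comp_key,
    oracle_by_masses,
    random_tree,
)


class TestDissociationMethods:
    @pytest.mark.parametrize(
        "method,series",
        [
            (DissociationMethod.CID, {"b", "y"}),
            (DissociationMethod.HCD, {"b", "y"}),
            (DissociationMethod.ETD, {"c", "z"}),
            (DissociationMethod.ECD, {"c", "z"}),
            (DissociationMethod.ETHCD, {"b", "y", "c", "z"}),
            (DissociationMethod.ETCID, {"b", "y", "c", "z"}),
        ],
    )
    def test_series_map(self, method, series):
        assert set(method.ion_series) == series

    def test_glycan_ions_need_collisional_component(self):
        collisional = {m for m in DissociationMethod if m.collisional}
        assert collisional == {
            DissociationMethod.CID,
            DissociationMethod.HCD,
            DissociationMethod.ETHCD,
            DissociationMethod.ETCID,
        }


class TestPeptideFragments:
    def test_ion_count_unmodified_hcd(self):
        p = gp.Peptide("PEPTIDEK")
        ions = gp.peptide_fragments(p, DissociationMethod.HCD, max_charge=1)
        assert len(ions) == 2 * (len(p) - 1)

    def test_invalid_charge(self):
        with pytest.raises(ValidationError):
            gp.peptide_fragments(gp.Peptide("PEPTIDE"), DissociationMethod.HCD, 0)

    def test_by_complementarity(self):
        p = gp.Peptide("TPASDPHGDNLTYSVFYTK")
        total = gp.peptide_neutral_mass(p)
        ions = {
            (i.series, i.ordinal): i.neutral_mass
            for i in gp.peptide_fragments(p, DissociationMethod.HCD, 1)
        }
        n = len(p)
        for i in range(1, n):
            assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(total, abs=1e-9)

    def test_against_independent_oracle_phosphopeptide(self, phosphopeptide_s6):
        """Phosphopeptide with one site: site-bearing fragments carry +79.966
        and have -97.977 satellites; every mass agrees with a residue-sum oracle."""
        seq = phosphopeptide_s6.sequence
        n = len(seq)
        b_oracle, y_oracle = oracle_by_masses(seq, {6: 79.96633})
        ions = gp.peptide_fragments(phosphopeptide_s6, DissociationMethod.HCD, 1)
        base = {(i.series, i.ordinal): i for i in ions if i.neutral_loss is None}
        losses = {(i.series, i.ordinal): i for i in ions if i.neutral_loss is not None}
        for i in range(1, n):
            assert base[("b", i)].neutral_mass == pytest.approx(b_oracle[i], abs=1e-4)
            assert base[("y", n - i)].neutral_mass == pytest.approx(
                y_oracle[n - i], abs=1e-4
            )
        # loss satellites exactly where the phospho site is on the fragment
        assert set(losses) == {("b", i) for i in range(6, n)} | {
            ("y", j) for j in range(n - 5, n)
        }
        for ion in losses.values():
            assert ion.neutral_loss == pytest.approx(97.97690, abs=1e-4)
            assert ion.mz == pytest.approx(
                ion.neutral_mass - ion.neutral_loss + PROTON, abs=1e-9
            )
            assert "H3PO4" in ion.label

    def test_cz_complementarity_constant(self):
        """c_i + z_(n-i) = M + H (z-dot convention)."""
        p = gp.Peptide("GNAEGSSDEEGKLVIDEPAK")
        total = gp.peptide_neutral_mass(p)
        ions = {
            (i.series, i.ordinal): i.neutral_mass
            for i in gp.peptide_fragments(p, DissociationMethod.ETD, 1)
        }
        n = len(p)
        for i in range(1, n):
            assert ions[("c", i)] + ions[("z", n - i)] == pytest.approx(
                total + ORACLE_H, abs=1e-4
            )

    def test_ethcd_is_union_of_hcd_and_etd(self, biantennary_tree):
        p = gp.Peptide("TPASDPHGDNLTYSVFYTK")
        key = lambda ions: {(i.series, i.label, round(i.mz, 9)) for i in ions}
        hcd = key(gp.assemble_ions(p, DissociationMethod.HCD, 2, glycan_tree=biantennary_tree))
        etd = key(gp.assemble_ions(p, DissociationMethod.ETD, 2, glycan_tree=biantennary_tree))
        both = key(gp.assemble_ions(p, DissociationMethod.ETHCD, 2, glycan_tree=biantennary_tree))
        assert both == hcd | etd

    def test_mz_identity_all_ions(self, biantennary_tree):
        p = gp.Peptide("TPASDPHGDNLTYSVFYTK")
        ions = gp.assemble_ions(p, DissociationMethod.ETHCD, 3, glycan_tree=biantennary_tree)
        for ion in ions:
            loss = ion.neutral_loss or 0.0
            assert ion.mz == pytest.approx(
                (ion.neutral_mass - loss + ion.charge * PROTON) / ion.charge, abs=1e-6
            )


class TestGlycanY:
    def test_single_node(self):
        tree = gp.tree_from_nested(("NeuAc", []))
        comps = gp.enumerate_glycan_Y(tree)
        assert {comp_key(c) for c in comps} == {
            frozenset(), frozenset({("NeuAc", 1)}),
        }

    def test_linear_chain_prefixes(self):
        k = 5
        nested = ("Hex", [])
        for _ in range(k - 1):
            nested = ("Hex", [nested])
        tree = gp.tree_from_nested(nested)
        comps = gp.enumerate_glycan_Y(tree)
        assert len(comps) == k + 1  # prefixes incl. empty

    def test_biantennary_structure_matches_brute_force(self, biantennary_tree):
        stepping = {comp_key(c) for c in gp.enumerate_glycan_Y(biantennary_tree)}
        assert stepping == brute_force_Y(biantennary_tree)

    def test_bounds(self, biantennary_tree):
        comps = gp.enumerate_glycan_Y(biantennary_tree)
        assert biantennary_tree.depth + 1 <= len(comps) <= 2 ** len(biantennary_tree)


class TestGlycanB:
    def test_single_node(self):
        tree = gp.tree_from_nested(("Hex", []))
        assert {comp_key(c) for c in gp.enumerate_glycan_B(tree)} == {
            frozenset({("Hex", 1)})
        }

    def test_linear_chain_suffixes(self):
        nested = ("NeuAc", [])
        for sym in ("Hex", "HexNAc", "HexNAc"):
            nested = (sym, [nested])
        tree = gp.tree_from_nested(nested)
        assert len(gp.enumerate_glycan_B(tree)) == 4

    def test_biantennary_structure_matches_brute_force(self, biantennary_tree):
        reversed_stepping = {comp_key(c) for c in gp.enumerate_glycan_B(biantennary_tree)}
        assert reversed_stepping == brute_force_B(biantennary_tree)


class TestOracleEquivalenceRandomTrees:
    def test_fifty_random_trees(self):
        """Y = root-containing connected subtrees; B = per-node closures."""
        rng = np.random.default_rng(2024)
        for _ in range(50):
            tree = random_tree(rng, max_nodes=12)
            assert {comp_key(c) for c in gp.enumerate_glycan_Y(tree)} == brute_force_Y(tree)
            assert {comp_key(c) for c in gp.enumerate_glycan_B(tree)} == brute_force_B(tree)


class TestGlycopeptideYIons:
    def test_y0_is_bare_peptide(self, biantennary_tree):
        p = gp.Peptide("TPASDPHGDNLTYSVFYTK")
        ions = gp.glycopeptide_Y_ions(p, biantennary_tree, 1)
        y0 = next(i for i in ions if i.label == "Y0")
        assert y0.neutral_mass == pytest.approx(gp.peptide_neutral_mass(p), abs=1e-9)

    def test_full_glycan_additivity(self, biantennary_tree):
        p = gp.Peptide("TPASDPHGDNLTYSVFYTK")
        ions = gp.glycopeptide_Y_ions(p, biantennary_tree, 1)
        full = max(ions, key=lambda i: i.neutral_mass)
        expected = gp.peptide_neutral_mass(p) + gp.glycan_mass(biantennary_tree.composition())
        assert full.neutral_mass == pytest.approx(expected, abs=1e-9)

    def test_chimeric_glycan_pair_differs_by_about_1da(self):
        """Near-isobaric glycans Hex(4)HexNAc(5)Fuc(2) vs Hex(4)HexNAc(5)NeuAc(1): Y-full ions
        on the same peptide differ by ~1.02 Da."""
        p = gp.Peptide("TPASDPHGDNLTYSVFYTK")
        pep = gp.peptide_neutral_mass(p)
        a = pep + gp.glycan_mass(gp.parse_composition("Hex(4)HexNAc(5)Fuc(2)"))
        b = pep + gp.glycan_mass(gp.parse_composition("Hex(4)HexNAc(5)NeuAc(1)"))
        assert a - b == pytest.approx(1.02, abs=0.01)


class TestOxoniumIons:
    def test_neugc_diagnostic(self):
        ions = gp.oxonium_ions(gp.parse_composition("NeuGc(1)"))
        assert any(round(i.mz, 3) == 308.098 for i in ions)

    def test_empty_composition(self):
        assert gp.oxonium_ions(gp.parse_composition("")) == []

    def test_hexnac_ladder_without_sialic(self):
        ions = gp.oxonium_ions(gp.parse_composition("HexNAc(1)"))
        mzs = {round(i.mz, 3) for i in ions}
        assert {204.087, 186.076, 168.066, 138.055, 126.055} <= mzs
        assert not any(abs(i.mz - 292.103) < 0.01 for i in ions)

    def test_requires_all_members(self):
        ions = gp.oxonium_ions(gp.parse_composition("Hex(2)"))
        labels = {i.label for i in ions}
        assert "HexHexNAc" not in labels

    def test_config_extension(self, tmp_path):
        path = tmp_path / "oxonium.tsv"
        path.write_text("HexNAc2\t-\tHexNAc(2)\t-\n")
        table = gp.fragments.load_oxonium_config(path)
        ions = gp.oxonium_ions(gp.parse_composition("HexNAc(3)"), table=table)
        assert any(i.label == "HexNAc2" for i in ions)
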