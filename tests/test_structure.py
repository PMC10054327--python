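"""Structure parsing, neighbor shells, SPP aggregation, report parsers."""

import numpy as np
import pytest

from hypercys import synthetic
from hypercys.structure import (
    CysteineSite,
    PocketProfile,
    SHELL_RADII,
    aggregate_spp,
    find_cysteines,
    intrinsic_pka_fallback,
    neighbor_shells,
    parse_pdb,
    parse_pka_report,
    parse_pocket_report,
    pocket_membership,
    shell_members,
    write_pdb,
)

SINGLE_CYS_PDB = """\
ATOM      1  N   CYS A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  CYS A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   CYS A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   CYS A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  CYS A   1       2.000  -0.750  -1.200  1.00  0.00           C
ATOM      6  SG  CYS A   1       1.500  -2.500  -1.400  1.00  0.00           S
END
"""


class TestParsePDB:
    def test_single_residue_identity(self):
        s = parse_pdb(SINGLE_CYS_PDB)
        assert len(s.atoms) == 6
        assert s.chains == {"A": "C"}
        assert s.residue_numbers("A") == [1]

    def test_roundtrip_through_write(self, helix):
        structure, pdb_text = helix
        reparsed = parse_pdb(pdb_text)
        assert reparsed.chains == structure.chains
        assert len(reparsed.atoms) == len(structure.atoms)
        for a, b in zip(reparsed.atoms, structure.atoms):
            assert a.name == b.name and a.element == b.element
            np.testing.assert_allclose(a.position, b.position, atol=1e-3)

    def test_altloc_keeps_highest_occupancy(self):
        text = (
            "ATOM      1  CA ACYS A   1       0.000   0.000   0.000  0.60  0.00           C\n"
            "ATOM      2  CA BCYS A   1       5.000   0.000   0.000  0.40  0.00           C\n"
        )
        s = parse_pdb(text)
        assert len(s.atoms) == 1
        np.testing.assert_allclose(s.atoms[0].position, [0, 0, 0])

    def test_altloc_tie_breaks_alphabetically(self):
        text = (
            "ATOM      1  CA BCYS A   1       5.000   0.000   0.000  0.50  0.00           C\n"
            "ATOM      2  CA ACYS A   1       0.000   0.000   0.000  0.50  0.00           C\n"
        )
        s = parse_pdb(text)
        np.testing.assert_allclose(s.atoms[0].position, [0, 0, 0])

    def test_malformed_coordinates_name_line(self):
        bad = SINGLE_CYS_PDB.replace("1.458", "xx.xx")
        with pytest.raises(ValueError, match="line 2"):
            parse_pdb(bad)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError, match="no ATOM"):
            parse_pdb("HEADER only\n")

    def test_waters_and_hetatm_skipped_by_default(self):
        text = SINGLE_CYS_PDB.replace("END\n", "") + (
            "HETATM    7  O   HOH A 101       9.000   9.000   9.000  1.00  0.00           O\n"
            "HETATM    8 ZN    ZN A 102       8.000   8.000   8.000  1.00  0.00          ZN\n"
        )
        assert len(parse_pdb(text).atoms) == 6
        assert len(parse_pdb(text, include_hetero=True).atoms) == 7  # waters still out


class TestFindCysteines:
    def test_no_cysteines_gives_empty_list(self):
        s, _ = synthetic.make_helix_peptide("AGLVK", seed=0)
        assert find_cysteines(s) == []

    def test_positions_by_construction(self):
        s, _ = synthetic.make_helix_peptide("ACDCG", seed=0)
        sites = find_cysteines(s)
        assert [x.residue_number for x in sites] == [2, 4]
        assert all(x.chain == "A" for x in sites)
        assert all(x.sg_position is not None for x in sites)
        assert all(x.label == "unlabeled" and not x.in_pocket for x in sites)

    def test_missing_sg_reported_absent(self):
        text = "\n".join(
            line for line in SINGLE_CYS_PDB.splitlines() if " SG " not in line
        )
        sites = find_cysteines(parse_pdb(text))
        assert len(sites) == 1 and sites[0].sg_position is None


def brute_force_shells(structure, site, radii=SHELL_RADII):
    """O(n^2) oracle: min heavy-atom pair distance per residue."""
    cys = [a for a in structure.residue_atoms(site.chain, site.residue_number)
           if a.element != "H"]
    dmin = {}
    for atom in structure.polymer_atoms():
        if atom.element == "H":
            continue
        key = (atom.chain, atom.residue_number)
        if key == (site.chain, site.residue_number):
            continue
        for c in cys:
            d = float(np.linalg.norm(c.position - atom.position))
            if key not in dmin or d < dmin[key]:
                dmin[key] = d
    return {r: sorted(k for k, d in dmin.items() if d <= r) for r in radii}


class TestNeighborShells:
    def test_isolated_cysteine_has_empty_shells(self):
        s = parse_pdb(SINGLE_CYS_PDB)
        comp = neighbor_shells(s, find_cysteines(s)[0])
        assert all(comp.total(r) == 0 for r in SHELL_RADII)

    @pytest.mark.parametrize("seq", ["ACDCG", "MKACDEFGHIKLMNPQRSTVWYC", "CCC"])
    def test_membership_matches_brute_force_oracle(self, seq):
        s, _ = synthetic.make_helix_peptide(seq, seed=0)
        for site in find_cysteines(s):
            assert shell_members(s, site) == brute_force_shells(s, site)

    @pytest.mark.parametrize("seed", range(10))
    def test_partition_and_monotonicity_properties(self, seed):
        rng = np.random.default_rng(seed)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        seq = "C" + "".join(rng.choice(letters, size=12))
        s, _ = synthetic.make_helix_peptide(seq, seed=seed)
        comp = neighbor_shells(s, find_cysteines(s)[0])
        totals = [comp.total(r) for r in sorted(SHELL_RADII)]
        assert totals == sorted(totals)  # non-decreasing in radius
        for r in SHELL_RADII:
            assert comp.hydrophobic(r) + comp.polar(r) == comp.total(r)


class TestAggregateSPP:
    def test_empty_shells_give_zero_vector(self):
        site = CysteineSite(chain="A", residue_number=1)
        spp = aggregate_spp(
            site, {r: [] for r in SHELL_RADII},
            residue_sasa={("A", 1): 55.0}, pka={("A", 1): 9.0},
        )
        v = spp.as_array()
        assert v.shape == (18,)
        np.testing.assert_allclose(v[:16], 0.0)
        assert v[16] == 55.0 and v[17] == 9.0

    def test_simple_shell_arithmetic(self):
        site = CysteineSite(chain="A", residue_number=1)
        shells = {r: [("A", 2), ("A", 3)] for r in SHELL_RADII}
        spp = aggregate_spp(
            site, shells,
            residue_sasa={("A", 1): 10.0, ("A", 2): 20.0, ("A", 3): 30.0},
            pka={("A", 1): 9.0, ("A", 2): 4.0, ("A", 3): 6.0},
        )
        for r in SHELL_RADII:
            pka_total, pka_ave, sasa_total, sasa_ave = spp.shell_values[r]
            assert (pka_total, pka_ave) == (10.0, 5.0)
            assert (sasa_total, sasa_ave) == (50.0, 25.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_ave_times_count_equals_total(self, seed):
        rng = np.random.default_rng(seed)
        residues = [("A", i) for i in range(2, 30)]
        sasa = {k: float(rng.uniform(0, 100)) for k in residues}
        sasa[("A", 1)] = 12.0
        pka = {k: float(rng.uniform(3, 13)) for k in residues if rng.random() < 0.5}
        pka[("A", 1)] = 9.0
        shells = {
            r: [k for k in residues if rng.random() < 0.6] for r in SHELL_RADII
        }
        site = CysteineSite(chain="A", residue_number=1)
        spp = aggregate_spp(site, shells, sasa, pka)
        for r in SHELL_RADII:
            pka_total, pka_ave, sasa_total, sasa_ave = spp.shell_values[r]
            n_all = len(shells[r])
            n_pka = sum(1 for k in shells[r] if k in pka)
            assert sasa_ave * n_all == pytest.approx(sasa_total, rel=1e-9)
            assert pka_ave * n_pka == pytest.approx(pka_total, rel=1e-9)

    def test_missing_site_pka_errors_without_fallback(self):
        site = CysteineSite(chain="A", residue_number=1)
        with pytest.raises(ValueError, match="pKa"):
            aggregate_spp(site, {r: [] for r in SHELL_RADII},
                          residue_sasa={}, pka={})


class TestIntrinsicPkaFallback:
    def test_single_cysteine_lookup(self):
        s, _ = synthetic.make_helix_peptide("AGCGA", seed=0)
        out = intrinsic_pka_fallback(s)
        assert out == {("A", 3): 9.0}

    def test_no_ionizable_residues(self):
        s, _ = synthetic.make_helix_peptide("AGLVG", seed=0)
        assert intrinsic_pka_fallback(s) == {}

    def test_deterministic(self, helix):
        structure, _ = helix
        assert intrinsic_pka_fallback(structure) == intrinsic_pka_fallback(structure)


class TestReportParsers:
    def test_pka_summary_line(self):
        text = "stuff\nSUMMARY OF THIS PREDICTION\n   CYS  38 A     9.53      9.00\n"
        assert parse_pka_report(text) == {("A", 38): 9.53}

    def test_pka_requires_summary_section(self):
        with pytest.raises(ValueError, match="summary"):
            parse_pka_report("CYS 38 A 9.53\n")

    def test_pka_empty_summary(self):
        assert parse_pka_report("SUMMARY OF THIS PREDICTION\n") == {}

    def test_pka_duplicate_last_wins(self):
        text = (
            "SUMMARY OF THIS PREDICTION\n"
            "   CYS  38 A     9.53\n"
            "   CYS  38 A     8.11\n"
        )
        assert parse_pka_report(text) == {("A", 38): 8.11}

    def test_pka_skips_termini_and_ligands(self):
        text = (
            "SUMMARY OF THIS PREDICTION\n"
            "   N+    1 A     7.99\n"
            "   ASP  10 A     3.65\n"
        )
        assert parse_pka_report(text) == {("A", 10): 3.65}

    def test_pocket_report_two_pockets(self):
        text = (
            "Pocket 1 :\n\tDruggability Score : 0.70\n"
            "\tHydrophobicity score : 40.0\n\tPolarity score : 8.0\n"
            "\tResidues : A:1 A:2\n"
            "Pocket 2 :\n\tDruggability Score : 0.20\n"
            "\tHydrophobicity score : 10.0\n\tPolarity score : 3.0\n"
            "\tResidues : A:9\n"
        )
        pockets = parse_pocket_report(text)
        assert [p.pocket_id for p in pockets] == [1, 2]
        assert pockets[0].member_residues == {("A", 1), ("A", 2)}
        assert pockets[0].drug_score == 0.70

    def test_pocket_report_zero_pockets(self):
        assert parse_pocket_report("no pockets found\n") == []

    def test_pocket_missing_score_errors(self):
        text = "Pocket 3 :\n\tDruggability Score : 0.5\n\tResidues : A:1\n"
        with pytest.raises(ValueError, match="3"):
            parse_pocket_report(text)

    def test_pocket_without_residue_list_kept_empty(self):
        text = (
            "Pocket 1 :\n\tDruggability Score : 0.5\n"
            "\tHydrophobicity score : 1.0\n\tPolarity score : 1.0\n"
        )
        (p,) = parse_pocket_report(text)
        assert p.member_residues == set()


class TestPocketMembership:
    def _pocket(self, pid, members, drug):
        return PocketProfile(pocket_id=pid, member_residues=members,
                             drug_score=drug, hydrophobicity_score=0.0,
                             polarity_score=0.0)

    def test_site_outside_all_pockets(self):
        site = CysteineSite(chain="A", residue_number=5)
        assert pocket_membership(site, [self._pocket(1, {("A", 1)}, 0.5)]) is None
        assert site.in_pocket is False

    def test_site_in_single_pocket(self):
        site = CysteineSite(chain="A", residue_number=1)
        p = self._pocket(1, {("A", 1)}, 0.5)
        assert pocket_membership(site, [p]) is p
        assert site.in_pocket is True

    def test_overlapping_pockets_resolved_by_drug_score(self):
        site = CysteineSite(chain="A", residue_number=1)
        lo = self._pocket(1, {("A", 1)}, 0.3)
        hi = self._pocket(2, {("A", 1)}, 0.8)
        assert pocket_membership(site, [lo, hi]) is hi
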