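"""Structure parsing, mutation grammar, solvent accessibility, trajectories."""

import io
import math

import numpy as np
import pytest

from ddgdyn import fixtures
from ddgdyn.structure_io import (MAX_ASA, MultiMutation, MutationFormatError,
                                 PDBParseError, SiteNotFoundError,
                                 WildTypeMismatchError, locate_site,
                                 parse_multi, parse_mutation, parse_structure,
                                 relative_solvent_accessibility, rsa_class,
                                 write_pdb, write_trajectory)

MINIMAL_ALA = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000  -0.760   1.200  1.00  0.00           C
END
"""

ALTLOC = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA AALA A   1       1.458   0.000   0.000  0.60  0.00           C
ATOM      3  CA BALA A   1       9.999   0.000   0.000  0.40  0.00           C
ATOM      4  C   ALA A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      5  O   ALA A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      6  CB  ALA A   1       2.000  -0.760   1.200  1.00  0.00           C
END
"""


class TestParseStructure:
    def test_minimal_single_residue(self):
        s = parse_structure(MINIMAL_ALA)
        assert len(s.atoms) == 5
        assert s.chains == {"A"}
        assert s.atoms[0].residue_seq == 1

    def test_altloc_keeps_highest_occupancy(self):
        s = parse_structure(ALTLOC)
        cas = [a for a in s.atoms if a.name == "CA"]
        assert len(cas) == 1
        assert cas[0].coords[0] == pytest.approx(1.458)

    def test_multi_model_takes_first_by_default(self):
        body = MINIMAL_ALA.replace("END\n", "")
        shifted = body.replace("   0.000   0.000", "  50.000   0.000")
        text = ("MODEL        1\n" + body + "ENDMDL\n"
                "MODEL        2\n" + shifted + "ENDMDL\n"
                "MODEL        3\n" + shifted + "ENDMDL\nEND\n")
        s = parse_structure(text)
        assert len(s.atoms) == 5
        assert s.atoms[0].coords[0] == pytest.approx(0.0)
        s2 = parse_structure(text, model=1)
        assert s2.atoms[0].coords[0] == pytest.approx(50.0)

    def test_no_atom_records_is_parse_error(self):
        with pytest.raises(PDBParseError):
            parse_structure("HEADER    NOTHING\nEND\n")

    def test_water_excluded(self):
        text = MINIMAL_ALA.replace(
            "END\n",
            "HETATM    6  O   HOH A 100      10.000  10.000  10.000"
            "  1.00  0.00           O\nEND\n")
        s = parse_structure(text)
        assert all(a.residue_name != "HOH" for a in s.atoms)


class TestMutationGrammar:
    def test_parse_mutation(self):
        spec = parse_mutation("W43F", "A")
        assert (spec.chain, spec.wt, spec.position, spec.mut) == ("A", "W", 43, "F")

    @pytest.mark.parametrize("code", ["W43W", "X43F", "43F", "W43", "W4.3F"])
    def test_bad_codes_rejected(self, code):
        with pytest.raises(MutationFormatError):
            parse_mutation(code, "A")

    def test_parse_multi_two_sites(self):
        mm = parse_multi("A W43F,A T69S")
        assert len(mm) == 2
        assert mm.specs[1].position == 69

    def test_parse_multi_single(self):
        assert len(parse_multi("A W43F")) == 1

    def test_parse_multi_global_chain(self):
        mm = parse_multi("W43F,T69S", default_chain="B")
        assert {s.chain for s in mm} == {"B"}

    def test_four_sites_rejected_citing_limit(self):
        with pytest.raises(MutationFormatError, match="three"):
            parse_multi("A A5V,A A9V,A A12V,A A15V")

    def test_duplicate_sites_rejected(self):
        with pytest.raises(MutationFormatError):
            parse_multi("A W43F,A W43G")


class TestLocateSite:
    def test_found(self, helix12_ala):
        s, _ = helix12_ala
        res = locate_site(s, parse_mutation("L5V", "A"))
        assert res.name == "LEU" and res.residue_seq == 5

    def test_wildtype_mismatch_is_distinct(self, helix12_ala):
        s, _ = helix12_ala
        with pytest.raises(WildTypeMismatchError):
            locate_site(s, parse_mutation("G5V", "A"))

    def test_site_not_found(self, helix12_ala):
        s, _ = helix12_ala
        with pytest.raises(SiteNotFoundError):
            locate_site(s, parse_mutation("A99V", "A"))

    def test_total_over_all_residues_and_substitutions(self, helix20):
        """locate_site never crashes: returns handle or a defined error."""
        from ddgdyn.structure_io import STANDARD_AA1, MutationSpec
        s, _ = helix20
        for res in s.residues():
            for mut in sorted(STANDARD_AA1):
                for wt in ("A", res.one_letter):
                    if wt == mut:
                        continue
                    spec = MutationSpec(chain="A", wt=wt,
                                        position=res.residue_seq, mut=mut)
                    try:
                        handle = locate_site(s, spec)
                        assert handle.residue_seq == res.residue_seq
                    except (SiteNotFoundError, WildTypeMismatchError):
                        pass


class TestRSA:
    def test_isolated_residue_fully_exposed(self):
        s = parse_structure(MINIMAL_ALA)
        assert relative_solvent_accessibility(s, s.residues()[0]) >= 0.9

    def test_packed_cluster_buried(self):
        s, _ = fixtures.make_packed_cluster(7)
        assert relative_solvent_accessibility(s, s.residues()[0]) < 0.1

    def test_monotone_under_occlusion(self):
        values = []
        for shells in range(4):
            s, _ = fixtures.make_packed_cluster(shells)
            values.append(relative_solvent_accessibility(s, s.residues()[0]))
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_boundary_030_is_buried(self):
        assert rsa_class(0.30) == "buried"
        assert rsa_class(0.301) == "exposed"

    def test_against_independent_shrake_rupley(self, helix20):
        """Residue ASA agrees with Bio.PDB's Shrake-Rupley within 2%."""
        from Bio.PDB import PDBParser
        from Bio.PDB.SASA import ShrakeRupley
        s, text = helix20
        entity = PDBParser(QUIET=True).get_structure("h", io.StringIO(text))
        ShrakeRupley(probe_radius=1.4, n_points=960).compute(
            entity[0], level="R")
        oracle = [r.sasa for r in entity[0]["A"]]
        for i in (0, 7, 13, 19):
            res = s.residues()[i]
            mine = relative_solvent_accessibility(s, res) * MAX_ASA[res.name]
            assert mine == pytest.approx(oracle[i], rel=0.02)


class TestTrajectory:
    def test_zero_amplitude_frames_identical(self, helix12_ala):
        s, _ = helix12_ala
        disp = np.zeros((len(s.atoms), 3))
        disp[:, 0] = 1.0
        text = write_trajectory(s, disp, amplitude=0.0, n_frames=3)
        for m in range(3):
            frame = parse_structure(text, model=m)
            np.testing.assert_allclose(frame.coords, s.coords, atol=1e-3)

    def test_sine_sampling_closed_form(self):
        s = parse_structure(MINIMAL_ALA)
        disp = np.zeros((5, 3))
        disp[1, 0] = 1.0  # unit x-displacement on CA
        text = write_trajectory(s, disp, amplitude=1.0, n_frames=4)
        expected = [math.sin(math.pi / 2), math.sin(math.pi),
                    math.sin(3 * math.pi / 2), math.sin(2 * math.pi)]
        for k in range(4):
            frame = parse_structure(text, model=k)
            offset = frame.coords[1, 0] - s.coords[1, 0]
            assert offset == pytest.approx(expected[k], abs=1e-3)

    def test_round_trip_every_model(self, helix12_ala):
        s, _ = helix12_ala
        disp = np.ones((len(s.atoms), 3))
        text = write_trajectory(s, disp, amplitude=0.5, n_frames=3)
        for m in range(3):
            assert len(parse_structure(text, model=m).atoms) == len(s.atoms)

    def test_zero_frames_rejected(self, helix12_ala):
        s, _ = helix12_ala
        with pytest.raises(ValueError):
            write_trajectory(s, np.zeros((len(s.atoms), 3)), 1.0, 0)


def test_parse_write_parse_round_trip(helix20):
    s, _ = helix20
    text = write_pdb(s)
    s2 = parse_structure(text)
    assert len(s2.atoms) == len(s.atoms)
    assert [a.name for a in s2.atoms] == [a.name for a in s.atoms]
    np.testing.assert_allclose(s2.coords, s.coords, atol=1e-3)
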