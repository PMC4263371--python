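import math

import numpy as np
import pandas as pd
import pytest

from cloneseq.interface3d import (
    Atom,
    InterfaceAnnotation,
    StructureModel,
    classify_locus,
    interface_domains,
    interface_residues,
    sasa,
    sphere_points,
)

PROBE = 1.4
R_C = 1.7


def carbon(chain, res, x, y, z, name="CA"):
    return Atom(chain, res, "ALA", name, "C", (x, y, z), R_C)


def model(*atoms):
    return StructureModel(list(atoms))


def two_sphere_exposed_area(r, d):
    """Closed-form exposed area of one of two equal spheres of radius r
    whose centers are d apart: full sphere minus the buried cap."""
    h = r - d / 2.0  # height of the buried cap
    return 4 * math.pi * r**2 - 2 * math.pi * r * h


class TestSasa:
    def test_single_atom_analytic_sphere(self):
        m = model(carbon("A", 1, 0, 0, 0))
        area = sasa(m)[("A", 1)]
        exact = 4 * math.pi * (R_C + PROBE) ** 2  # ~120.76
        assert exact == pytest.approx(120.76, abs=0.01)
        assert area == pytest.approx(exact, rel=0.01)

    def test_distant_atoms_keep_full_sphere(self):
        m = model(carbon("A", 1, 0, 0, 0), carbon("A", 2, 50, 0, 0))
        areas = sasa(m)
        exact = 4 * math.pi * (R_C + PROBE) ** 2
        assert areas[("A", 1)] == pytest.approx(exact, rel=0.01)
        assert areas[("A", 2)] == pytest.approx(exact, rel=0.01)

    @pytest.mark.parametrize("d", [2.0, 3.0, 4.5, 5.5])
    def test_two_sphere_cap_oracle(self, d):
        m = model(carbon("A", 1, 0, 0, 0), carbon("A", 2, d, 0, 0))
        areas = sasa(m, n_points=2000)
        exact = two_sphere_exposed_area(R_C + PROBE, d)
        assert areas[("A", 1)] == pytest.approx(exact, rel=0.02)

    def test_translation_rotation_invariance(self):
        atoms = [carbon("A", i, *xyz) for i, xyz in enumerate(
            [(0, 0, 0), (2.5, 0.5, 0), (1.0, 2.0, 1.0)]
        )]
        base = sasa(model(*atoms))
        # rotate 90 degrees about z and translate
        moved = [
            Atom(a.chain_id, a.res_seq, a.res_name, a.name, a.element,
                 (-a.coord[1] + 7, a.coord[0] - 3, a.coord[2] + 11), a.radius)
            for a in atoms
        ]
        rotated = sasa(model(*moved))
        for key in base:
            assert rotated[key] == pytest.approx(base[key], rel=0.02)

    def test_quadrature_convergence(self):
        atoms = [carbon("A", i, *xyz) for i, xyz in enumerate(
            [(0, 0, 0), (2.5, 0.5, 0), (1.0, 2.0, 1.0), (0, 0, 3.1)]
        )]
        a1 = sasa(model(*atoms), n_points=960)
        a2 = sasa(model(*atoms), n_points=1920)
        for key in a1:
            assert a2[key] == pytest.approx(a1[key], rel=0.01)

    def test_empty_model_rejected(self):
        with pytest.raises(ValueError, match="no atoms"):
            sasa(model())

    def test_sphere_points_on_unit_sphere(self):
        pts = sphere_points(500)
        assert np.allclose(np.linalg.norm(pts, axis=1), 1.0)


class TestInterfaceResidues:
    def _toy_complex(self):
        # chain A: residues 1 (contacting) and 2 (far); chain B mirrors
        return model(
            carbon("A", 1, 0.0, 0, 0),
            carbon("A", 2, -20.0, 0, 0),
            carbon("B", 1, 4.0, 0, 0),
            carbon("B", 2, 24.0, 0, 0),
        )

    def test_contacting_residues_flagged(self):
        ann = interface_residues(self._toy_complex(), ("A", "B"))
        assert ann.interface_residues == {("A", 1), ("B", 1)}

    def test_distant_residue_zero_delta(self):
        ann = interface_residues(self._toy_complex(), ("A", "B"))
        assert ann.delta_asa[("A", 2)] == pytest.approx(0.0, abs=1e-6)

    def test_delta_nonnegative_up_to_quadrature(self):
        ann = interface_residues(self._toy_complex(), ("A", "B"))
        assert all(d >= -1e-6 for d in ann.delta_asa.values())

    def test_strict_inequality_at_cutoff(self):
        ann = interface_residues(self._toy_complex(), ("A", "B"))
        d = ann.delta_asa[("A", 1)]
        # with the cutoff set to the residue's own delta it is NOT flagged
        strict = interface_residues(
            self._toy_complex(), ("A", "B"), cutoff=d
        )
        assert ("A", 1) not in strict.interface_residues

    def test_missing_chain_errors(self):
        with pytest.raises(ValueError, match="missing"):
            interface_residues(self._toy_complex(), ("A", "Z"))


def _annotation(iface, chain_pair=("A", "B"), all_residues=None):
    residues = all_residues or iface
    delta = {r: (8.0 if r in iface else 0.0) for r in residues}
    return InterfaceAnnotation(
        chain_pair=chain_pair,
        asa_unbound={r: 100.0 for r in residues},
        asa_complex={r: 100.0 - delta[r] for r in residues},
        delta_asa=delta,
        interface_residues=set(iface),
    )


def _domains(rows):
    return pd.DataFrame(rows, columns=["chain", "domain_id", "start", "end"])


def _ddi(pairs):
    return pd.DataFrame(pairs, columns=["domain_id_a", "domain_id_b"])


class TestInterfaceDomains:
    def test_known_ddi_with_one_residue_each(self):
        ann = _annotation({("A", 5), ("B", 7)})
        doms = _domains([("A", "PF1", 1, 50), ("B", "PF2", 1, 50)])
        flagged = interface_domains(ann, doms, _ddi([("PF1", "PF2")]))
        assert len(flagged) == 1
        assert flagged[0]["criterion"] == 1

    def test_five_residues_each_without_ddi(self):
        iface = {("A", i) for i in range(1, 6)} | {("B", i) for i in range(1, 8)}
        ann = _annotation(iface)
        doms = _domains([("A", "D1", 1, 50), ("B", "D2", 1, 50)])
        flagged = interface_domains(ann, doms, None)
        assert len(flagged) == 1
        assert flagged[0]["criterion"] == 2
        assert flagged[0]["n_interface_a"] == 5
        assert flagged[0]["n_interface_b"] == 7

    def test_four_residues_each_not_flagged(self):
        iface = {("A", i) for i in range(1, 5)} | {("B", i) for i in range(1, 5)}
        ann = _annotation(iface)
        doms = _domains([("A", "D1", 1, 50), ("B", "D2", 1, 50)])
        assert interface_domains(ann, doms, None) == []

    def test_overlapping_domains_error(self):
        ann = _annotation({("A", 5), ("B", 7)})
        doms = _domains(
            [("A", "D1", 1, 30), ("A", "D1b", 25, 60), ("B", "D2", 1, 50)]
        )
        with pytest.raises(ValueError, match="overlap"):
            interface_domains(ann, doms, None)


class TestClassifyLocus:
    def _annotated(self):
        residues = {("A", i) for i in range(1, 101)}
        ann = _annotation({("A", 10)}, all_residues=residues)
        doms = _domains([("A", "D1", 1, 50), ("B", "D2", 1, 50)])
        # give chain B one interface residue so criterion 1 applies
        ann.interface_residues.add(("B", 3))
        ann.delta_asa[("B", 3)] = 8.0
        interface_domains(ann, doms, _ddi([("D1", "D2")]))
        return ann

    def test_interface_residue(self):
        assert classify_locus(("A", 10), self._annotated()) == "interface_residue"

    def test_interface_domain(self):
        assert classify_locus(("A", 30), self._annotated()) == "interface_domain"

    def test_away(self):
        assert classify_locus(("A", 80), self._annotated()) == "away"

    def test_unmapped(self):
        assert classify_locus(("A", 999), self._annotated()) == "unmapped"


class TestPdbReader:
    PDB = """\
HEADER    TOY
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  H   ALA A   1      12.000   6.000  -4.000  1.00  0.00           H
HETATM    4  O   HOH A 101       0.000   0.000   0.000  1.00  0.00           O
ATOM      5  CB  ALA B   2       8.062   8.017  -4.655  1.00  0.00           C
END
"""

    def test_reader_skips_hetatm_and_hydrogen(self, tmp_path):
        p = tmp_path / "toy.pdb"
        p.write_text(self.PDB)
        m = StructureModel.from_pdb(p)
        assert len(m.atoms) == 3
        assert m.chains == ["A", "B"]
        assert m.residues() == [("A", 1), ("B", 2)]
        assert {a.element for a in m.atoms} == {"N", "C"}
        assert m.atoms[0].radius == pytest.approx(1.55)
        assert m.atoms[1].coord == pytest.approx((11.639, 6.071, -5.147))
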