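"""Curation, torsion matching, dihedral measurement, histograms."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from rdkit import Chem

import torsionprofiles as tp
from torsionprofiles.extraction import CurationError, DihedralError


class TestCuration:
    def test_two_component_entry_splits_into_two_records(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("CCO.CCN"))
        records, report = tp.curate_molecule(mol, "pair")
        assert len(records) == 2
        assert report.n_components == 2
        assert {r.identifier for r in records} == {"pair.0", "pair.1"}

    def test_methane_dropped_for_missing_cc_bond(self):
        records, report = tp.curate_molecule(Chem.MolFromSmiles("C"), "methane")
        assert records == []
        assert report.dropped[0][1] == "no carbon-carbon bond"

    def test_ethane_gets_six_explicit_hydrogens(self):
        records, _ = tp.curate_molecule(Chem.MolFromSmiles("CC"), "ethane")
        assert len(records) == 1
        n_h = sum(1 for a in records[0].mol.GetAtoms() if a.GetAtomicNum() == 1)
        assert n_h == 6

    def test_disallowed_element_dropped_with_reason(self):
        records, report = tp.curate_molecule(Chem.MolFromSmiles("CC[Si](C)(C)C"), "silane")
        assert records == []
        assert "Si" in report.dropped[0][1]

    def test_unparsable_molblock_raises_with_entry_named(self):
        with pytest.raises(CurationError, match="badentry"):
            tp.curate_molecule("not a molblock", "badentry")

    def test_mixed_entry_keeps_only_valid_component(self):
        mol = Chem.AddHs(Chem.MolFromSmiles("CCO.O"))  # ethanol + water
        records, report = tp.curate_molecule(mol, "solvate")
        assert len(records) == 1
        assert len(report.dropped) == 1


class TestMatching:
    def test_butadiene_fails_cx3h0_requirement(self, library, toy_molecules):
        by_id = {rec.identifier: rec for rec, _ in toy_molecules}
        matches = tp.match_torsions(by_id["C=CC=C"], library)
        assert "diene_cc" not in {m.pattern_id for m in matches}

    def test_published_motifs_match_their_toys(self, library, toy_molecules):
        for rec, expected in toy_molecules:
            ids = {m.pattern_id for m in tp.match_torsions(rec, library)}
            if expected is not None:
                assert expected in ids
            else:
                assert not ids & {"diene_cc", "fbenzamide_cc", "arylether_co"}

    def test_first_match_wins_per_bond(self):
        # both patterns hit the same central C-C bond of butane; rank decides
        lib = tp.load_library([
            ("[CH3:1][CH2:2]!@;-[CH2:3][CH3:4]", "C-C", 1, "specific"),
            ("[C:1][C:2]!@;-[C:3][C:4]", "C-C", 5, "generic"),
        ])
        mol, _ = tp.curate_molecule(Chem.MolFromSmiles("CCCC"), "butane")
        matches = tp.match_torsions(mol[0], lib)
        central = [m for m in matches if m.pattern_id in ("specific", "generic")]
        assert {m.pattern_id for m in central} == {"specific"}

    def test_line_order_irrelevant_when_ranks_fixed(self, toy_molecules):
        recs = [
            ("[CH3:1][CH2:2]!@;-[CH2:3][CH3:4]", "C-C", 1, "specific"),
            ("[C:1][C:2]!@;-[C:3][C:4]", "C-C", 5, "generic"),
        ]
        mol, _ = tp.curate_molecule(Chem.MolFromSmiles("CCCC"), "butane")
        a = tp.match_torsions(mol[0], tp.load_library(recs))
        b = tp.match_torsions(mol[0], tp.load_library(recs[::-1]))
        assert {(m.pattern_id, m.central_bond, m.mappings) for m in a} == \
               {(m.pattern_id, m.central_bond, m.mappings) for m in b}

    def test_symmetric_motif_records_all_mappings(self):
        # 2,3-dimethylbutane: central bond matched 2x2x(2 directions) = 8 ways
        lib = tp.load_library([("[CH3:1][CH:2]!@;-[CH:3][CH3:4]", "C-C", 1, "iso")])
        mol, _ = tp.curate_molecule(Chem.MolFromSmiles("CC(C)C(C)C"), "dmb")
        matches = tp.match_torsions(mol[0], lib)
        assert len(matches) == 1
        assert len(matches[0].mappings) == 8
        bond = set(matches[0].central_bond)
        assert all(set(q[1:3]) == bond for q in matches[0].mappings)


class TestDihedral:
    @staticmethod
    def _frame(theta_deg: float) -> np.ndarray:
        """Four atoms with dihedral theta about the z-axis bond j-k."""
        t = np.radians(theta_deg)
        return np.array([
            [1.0, 0.0, 0.0],
            [0.0, 0.0, 0.0],
            [0.0, 0.0, 1.5],
            [np.cos(t), -np.sin(t), 1.5],  # sign chosen for the package convention
        ])

    def test_planar_cis_is_zero(self):
        assert tp.measure_dihedral(self._frame(0.0), (0, 1, 2, 3)) == pytest.approx(0.0, abs=1e-9)

    def test_planar_trans_is_180(self):
        assert tp.measure_dihedral(self._frame(180.0), (0, 1, 2, 3)) == pytest.approx(180.0)

    @pytest.mark.parametrize("theta", [10.0, 97.3, 181.0, 350.0])
    def test_reversed_quadruple_same_angle(self, theta):
        coords = self._frame(theta)
        fwd = tp.measure_dihedral(coords, (0, 1, 2, 3))
        rev = tp.measure_dihedral(coords, (3, 2, 1, 0))
        assert fwd == pytest.approx(rev, abs=1e-9)

    @pytest.mark.parametrize("theta", [10.0, 120.0, 250.0])
    def test_mirror_coordinates_give_360_minus_theta(self, theta):
        coords = self._frame(theta)
        fwd = tp.measure_dihedral(coords, (0, 1, 2, 3))
        mirrored = tp.measure_dihedral(-coords, (0, 1, 2, 3))  # inversion = improper op
        assert mirrored == pytest.approx((360.0 - fwd) % 360.0, abs=1e-9)

    def test_collinear_atoms_raise(self):
        coords = np.array([[0, 0, -1.0], [0, 0, 0], [0, 0, 1.0], [0, 1.0, 2.0]])
        with pytest.raises(DihedralError):
            tp.measure_dihedral(coords, (0, 1, 2, 3))


class TestPruning:
    @staticmethod
    def _ensemble(energies, environment="vacuum"):
        mol, _ = tp.curate_molecule(Chem.MolFromSmiles("CC"), "ethane")
        coords = np.zeros((mol[0].mol.GetNumAtoms(), 3))
        return tp.ConformerEnsemble(mol[0], [(coords, e) for e in energies], environment)

    def test_cutoff_25_retains_low_energy_conformers(self):
        pruned = tp.prune_by_energy(self._ensemble([0.0, 10.0, 30.0]), 25.0)
        assert [e for _, e in pruned.conformers] == [0.0, 10.0]

    def test_cutoff_zero_keeps_only_minimum(self):
        pruned = tp.prune_by_energy(self._ensemble([5.0, 3.0, 3.0, 40.0]), 0.0)
        assert [e for _, e in pruned.conformers] == [3.0, 3.0]

    @given(st.lists(st.floats(0, 100), min_size=1, max_size=20),
           st.floats(0, 50), st.floats(0, 50))
    def test_nested_in_cutoff(self, energies, c1, c2):
        lo, hi = sorted([c1, c2])
        ens = self._ensemble(energies)
        kept_lo = {e for _, e in tp.prune_by_energy(ens, lo).conformers}
        kept_hi = {e for _, e in tp.prune_by_energy(ens, hi).conformers}
        assert kept_lo <= kept_hi

    def test_crystal_ensemble_bypasses_pruning(self):
        mol, _ = tp.curate_molecule(Chem.MolFromSmiles("CC"), "ethane")
        coords = np.zeros((mol[0].mol.GetNumAtoms(), 3))
        ens = tp.ConformerEnsemble(mol[0], [(coords, None)], "crystal")
        assert tp.prune_by_energy(ens, 0.0) is ens

    def test_empty_ensemble_rejected(self):
        mol, _ = tp.curate_molecule(Chem.MolFromSmiles("CC"), "ethane")
        with pytest.raises(ValueError):
            tp.ConformerEnsemble(mol[0], [], "vacuum")


class TestAugmentAndAccumulate:
    def test_ten_degrees_augments_to_350(self):
        assert tp.augment_mirror([10.0]) == [10.0, 350.0]

    def test_fixed_points(self):
        assert tp.augment_mirror([180.0]) == [180.0, 180.0]
        assert tp.augment_mirror([0.0]) == [0.0, 0.0]

    @given(st.lists(st.floats(0, 359.999), max_size=50))
    def test_augment_doubles_and_is_mirror_closed(self, angles):
        out = tp.augment_mirror(angles)
        assert len(out) == 2 * len(angles)
        # consecutive entries are mirror pairs: theta + mirror == 0 (mod 360)
        pair_sums = (np.array(out[0::2]) + np.array(out[1::2])) % 360.0
        assert np.allclose(np.minimum(pair_sums, 360.0 - pair_sums), 0.0, atol=1e-9)

    def test_counts_land_in_one_degree_bins(self):
        hist = tp.accumulate([10.0, 350.0], n_bins=360)
        assert hist.counts[10] == 1 and hist.counts[350] == 1
        assert hist.n_samples == 2

    def test_empty_angle_list(self):
        hist = tp.accumulate([], n_bins=36)
        assert hist.n_samples == 0 and not hist.counts.any()

    def test_uniform_angles_fill_bins_binomially(self):
        rng = np.random.default_rng(1234)
        hist = tp.accumulate(rng.uniform(0, 360, 10_000), n_bins=36)
        assert hist.n_samples == 10_000
        # each bin is Binomial(10000, 1/36): mean ~278, sd ~16.4
        assert np.all(np.abs(hist.counts - 10_000 / 36) < 6 * 16.5)

    def test_out_of_range_angles_wrapped_with_warning(self):
        with pytest.warns(UserWarning, match="wrapped"):
            hist = tp.accumulate([-10.0, 370.0], n_bins=360)
        assert hist.counts[350] == 1 and hist.counts[10] == 1

    def test_bad_bin_count_rejected(self):
        with pytest.raises(ValueError):
            tp.accumulate([1.0], n_bins=7)

    @given(st.lists(st.integers(0, 35999), min_size=1, max_size=100),
           st.sampled_from([36, 60, 120, 360]))
    def test_augmented_histogram_exactly_mirror_symmetric(self, ticks, n_bins):
        # angles strictly inside bins (never exactly on an edge, where the
        # half-open binning convention breaks the k <-> n-1-k pairing)
        angles = [t * 0.01 + 0.005 for t in ticks]
        hist = tp.accumulate(tp.augment_mirror(angles), n_bins=n_bins)
        assert np.array_equal(hist.counts, hist.counts[::-1])


class TestEnsembleExtraction:
    def test_mirror_image_coordinates_give_identical_histograms(self, library, embedded_diene):
        coords = np.array(embedded_diene.mol.GetConformer().GetPositions())
        ens = tp.ConformerEnsemble(embedded_diene, [(coords, 0.0)], "vacuum")
        mirrored = tp.ConformerEnsemble(embedded_diene, [(-coords, 0.0)], "vacuum")
        h1 = tp.extract_ensemble(ens, library)
        h2 = tp.extract_ensemble(mirrored, library)
        assert h1.keys() == h2.keys() and len(h1) > 0
        for pid in h1:
            assert np.array_equal(h1[pid].counts, h2[pid].counts)

    def test_sample_count_contract(self, library, embedded_diene):
        coords = np.array(embedded_diene.mol.GetConformer().GetPositions())
        confs = [(coords, 0.0), (coords, 5.0), (coords, 10.0)]
        ens = tp.ConformerEnsemble(embedded_diene, confs, "vacuum")
        hists = tp.extract_ensemble(ens, library, cutoff_kjmol=25.0)
        n_mappings: dict[str, int] = {}
        for m in tp.match_torsions(embedded_diene, library):
            n_mappings[m.pattern_id] = n_mappings.get(m.pattern_id, 0) + len(m.mappings)
        for pid, hist in hists.items():
            assert hist.n_samples == 3 * n_mappings[pid] * 2


class TestSdfRoundTrip:
    def test_read_back_toy_sdf(self, tmp_path):
        path = tmp_path / "toys.sdf"
        n = tp.make_toy_sdf(str(path), seed=7, n_confs=3)
        ensembles = tp.read_sdf_ensembles(path, environment="vacuum")
        assert sum(len(e.conformers) for e in ensembles) == n
        assert all(np.isfinite(e) for ens in ensembles for _, e in ens.conformers)
        assert {e.environment for e in ensembles} == {"vacuum"}
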