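import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import pdist

from biososs import (
    Conformer,
    Ensemble,
    EulerAngles,
    NoFeasibleLabelingError,
    PDBFormatError,
    enumerate_label_sites,
    generate_synthetic_ensemble,
    load_pdb,
    load_labeled_ensemble,
    orientation_ensemble,
    place_aunp,
    rotate,
    save_labeled_ensemble,
    select_label_pairs,
)
from biososs.structures import ATTACHMENT_RADIUS


def make_conformer(names, elements, positions, residues=None):
    n = len(names)
    return Conformer(
        elements=np.array(elements),
        positions=np.array(positions, dtype=float),
        residue_index=np.array(residues if residues is not None else [1] * n),
        atom_names=np.array(names),
    )


class TestSyntheticEnsemble:
    def test_70_residues_give_2255_atoms(self):
        ens = generate_synthetic_ensemble(n_residues=70, n_snapshots=1, seed=0)
        assert ens[0].n_atoms == 2255

    def test_zero_fluctuation_gives_identical_snapshots(self):
        ens = generate_synthetic_ensemble(
            n_residues=8, n_snapshots=5, fluctuation_amplitude=0.0, seed=0
        )
        for c in ens.conformers[1:]:
            np.testing.assert_array_equal(c.positions, ens[0].positions)

    def test_seed_determinism_and_variation(self):
        a = generate_synthetic_ensemble(n_residues=8, n_snapshots=2, seed=7)
        b = generate_synthetic_ensemble(n_residues=8, n_snapshots=2, seed=7)
        c = generate_synthetic_ensemble(n_residues=8, n_snapshots=2, seed=8)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.positions, cb.positions)
        assert np.abs(a[0].positions - c[0].positions).max() > 0.0

    def test_intersite_distances_fluctuate(self, tiny_ensemble):
        c0 = tiny_ensemble[0]
        i = c0.atom_index(2, "O1P")
        j = c0.atom_index(9, "O2P")
        d = [np.linalg.norm(c.positions[i] - c.positions[j]) for c in tiny_ensemble]
        assert np.std(d) > 0.0

    def test_no_duplicate_coordinates(self, rigid_conformer):
        assert pdist(rigid_conformer.positions).min() > 0.0

    def test_invalid_residue_count(self):
        with pytest.raises(ValueError):
            generate_synthetic_ensemble(n_residues=1, n_snapshots=1)


class TestRotation:
    def test_identity_rotation_is_noop(self, rigid_conformer):
        out = rotate(rigid_conformer, EulerAngles(0.0, 0.0, 0.0))
        np.testing.assert_allclose(out.positions, rigid_conformer.positions, atol=1e-12)

    def test_quarter_turn_about_z(self):
        # two atoms so the centroid sits at the origin
        conf = make_conformer(
            ["A1", "A2"], ["C", "C"], [[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]]
        )
        out = rotate(conf, EulerAngles(math.pi / 2, 0.0, 0.0))
        np.testing.assert_allclose(out.positions[0], [0.0, 1.0, 0.0], atol=1e-12)

    @settings(derandomize=True, max_examples=20, deadline=None)
    @given(
        st.tuples(
            st.floats(0, 2 * math.pi),
            st.floats(0, math.pi),
            st.floats(0, 2 * math.pi),
        )
    )
    def test_pairwise_distances_preserved(self, angles):
        """Rigid rotations preserve the full all-pairs distance matrix."""
        conformer = generate_synthetic_ensemble(
            n_residues=4, n_snapshots=1, seed=11
        )[0]
        out = rotate(conformer, EulerAngles(*angles))
        np.testing.assert_allclose(
            pdist(out.positions), pdist(conformer.positions), rtol=1e-9
        )


class TestOrientationEnsemble:
    def test_count_and_topology(self, rigid_conformer):
        ens = orientation_ensemble(rigid_conformer, n_orient=30, seed=0)
        assert len(ens) == 30
        assert all(c.n_atoms == rigid_conformer.n_atoms for c in ens)
        assert ens.source == "pdb_multi_orientation"

    def test_single_orientation_is_rigid(self, rigid_conformer):
        ens = orientation_ensemble(rigid_conformer, n_orient=1, seed=3)
        np.testing.assert_allclose(
            pdist(ens[0].positions), pdist(rigid_conformer.positions), rtol=1e-9
        )

    def test_different_seeds_differ(self, rigid_conformer):
        a = orientation_ensemble(rigid_conformer, 2, seed=0)
        b = orientation_ensemble(rigid_conformer, 2, seed=1)
        assert np.abs(a[0].positions - b[0].positions).max() > 0.0


class TestLabelSites:
    def test_two_sites_per_phosphate(self):
        ens = generate_synthetic_ensemble(n_residues=70, n_snapshots=1, seed=0)
        sites = enumerate_label_sites(ens[0], "rna")
        # 70 nucleotide phosphates, two free oxygens each
        assert len(sites) == 140

    def test_op1_alias_accepted(self):
        conf = make_conformer(
            ["P", "OP1"], ["P", "O"], [[0, 0, 0], [1.5, 0, 0]]
        )
        assert (1, "OP1") in enumerate_label_sites(conf, "rna")

    def test_protein_kind_on_rna_names_is_empty(self, rigid_conformer):
        assert enumerate_label_sites(rigid_conformer, "protein") == []

    def test_protein_carbonyl_oxygens(self):
        conf = make_conformer(
            ["C", "O", "CA"], ["C", "O", "C"], [[0, 0, 0], [1.23, 0, 0], [0, 1.5, 0]]
        )
        assert enumerate_label_sites(conf, "protein") == [(1, "O")]


class TestPlaceAunp:
    def test_collinear_placement(self):
        conf = make_conformer(
            ["P", "O1P"], ["P", "O"], [[0, 0, 0], [1.5, 0, 0]]
        )
        center = place_aunp(conf, (1, "O1P"), radius=9.0)
        np.testing.assert_allclose(center, [10.5, 0.0, 0.0], atol=1e-12)

    def test_forced_clash_rejection(self):
        conf = make_conformer(
            ["P", "O1P", "C"],
            ["P", "O", "C"],
            [[0, 0, 0], [1.5, 0, 0], [10.5, 0, 2.0]],
            residues=[1, 1, 2],
        )
        # third atom 2 A from the would-be center at (10.5, 0, 0)
        assert place_aunp(conf, (1, "O1P"), radius=9.0, clash_margin=0.5) is None

    def test_agrees_with_bruteforce_clash_scan(self, rng):
        """Acceptance flag equals an exhaustive all-atom distance check."""
        ens = generate_synthetic_ensemble(n_residues=10, n_snapshots=1, seed=5)
        conf = ens[0]
        radius, margin = 9.0, 0.5
        for site in enumerate_label_sites(conf, "rna")[::3]:
            center = place_aunp(conf, site, radius, clash_margin=margin)
            idx = conf.atom_index(*site)
            o = conf.positions[idx]
            # independent O(N) scan implementing the documented rule:
            # heavy atoms only, attachment neighborhood exempt
            clash = False
            partner = None
            best = np.inf
            for k in range(conf.n_atoms):
                if k == idx or conf.elements[k] in ("H", "O"):
                    continue
                if conf.residue_index[k] != conf.residue_index[idx]:
                    continue
                dist = np.linalg.norm(conf.positions[k] - o)
                if dist < best:
                    best, partner = dist, k
            u = (o - conf.positions[partner]) / np.linalg.norm(
                o - conf.positions[partner]
            )
            expected_center = o + radius * u
            for k in range(conf.n_atoms):
                if k == idx or conf.elements[k] == "H":
                    continue
                if np.linalg.norm(conf.positions[k] - o) <= ATTACHMENT_RADIUS:
                    continue
                if np.linalg.norm(conf.positions[k] - expected_center) < radius + margin:
                    clash = True
            if clash:
                assert center is None
            else:
                np.testing.assert_allclose(center, expected_center, atol=1e-9)


class TestSelectLabelPairs:
    def test_min_separation_rule_excludes_close_pairs(self):
        """r_AuNP must exceed 2.4 R in every conformer."""
        ens = generate_synthetic_ensemble(n_residues=12, n_snapshots=2, seed=2)
        pairs = select_label_pairs(
            ens, radius=9.0, n_pairs_min=1, n_pairs_max=6, min_spread=5.0, seed=0
        )
        for p in pairs:
            assert np.all(p.r_aunp > 2.4 * 9.0)

    def test_mean_spread_rule(self):
        ens = generate_synthetic_ensemble(n_residues=30, n_snapshots=2, seed=2)
        pairs = select_label_pairs(
            ens, radius=6.0, n_pairs_min=1, n_pairs_max=6, min_spread=10.0, seed=0
        )
        means = sorted(float(p.r_aunp.mean()) for p in pairs)
        assert all(b - a >= 10.0 for a, b in zip(means, means[1:]))

    def test_infeasible_radius_raises_with_constraint(self):
        # a 12-residue chain is too small for 2.4 * 20 A = 48 A separations
        ens = generate_synthetic_ensemble(n_residues=6, n_snapshots=1, seed=2)
        with pytest.raises(NoFeasibleLabelingError, match="2.4R"):
            select_label_pairs(ens, radius=20.0, n_pairs_min=2, seed=0)

    def test_deterministic_given_seed(self):
        ens = generate_synthetic_ensemble(n_residues=20, n_snapshots=2, seed=2)
        a = select_label_pairs(ens, radius=6.0, n_pairs_min=1, seed=5)
        b = select_label_pairs(ens, radius=6.0, n_pairs_min=1, seed=5)
        assert [(p.site_a, p.site_b) for p in a] == [(p.site_a, p.site_b) for p in b]

    def test_all_conformer_feasibility_via_bruteforce(self):
        """Selected pairs pass an exhaustive per-conformer placement check."""
        ens = generate_synthetic_ensemble(n_residues=10, n_snapshots=3, seed=9)
        pairs = select_label_pairs(
            ens, radius=6.0, n_pairs_min=1, n_pairs_max=3, min_spread=5.0, seed=1
        )
        for p in pairs:
            for ci, conf in enumerate(ens):
                ia = conf.atom_index(*p.site_a)
                ib = conf.atom_index(*p.site_b)
                ca = place_aunp(
                    conf, p.site_a, p.radius, clash_margin=0.5, exclude_indices=(ib,)
                )
                cb = place_aunp(
                    conf, p.site_b, p.radius, clash_margin=0.5, exclude_indices=(ia,)
                )
                assert ca is not None and cb is not None
                np.testing.assert_allclose(ca, p.centers[ci, 0], atol=1e-9)
                np.testing.assert_allclose(cb, p.centers[ci, 1], atol=1e-9)


def _pdb_line(serial, name, res, resseq, x, y, z, element):
    return (
        f"ATOM  {serial:5d} {name:<4s}{res:>4s} A{resseq:4d}    "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          {element:>2s}"
    )


PDB_MINIMAL = "\n".join(
    [
        _pdb_line(1, "P", "A", 1, 0.0, 0.0, 0.0, "P"),
        _pdb_line(2, "O1P", "A", 1, 1.5, 0.0, 0.0, "O"),
        _pdb_line(3, "AU1", "AUN", 2, 5.0, 5.0, 5.0, "AU"),
        "END",
        "",
    ]
)


class TestPdbIO:
    def test_minimal_atoms_echoed(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_MINIMAL)
        conf = load_pdb(path)
        assert conf.n_atoms == 3
        np.testing.assert_allclose(conf.positions[1], [1.5, 0.0, 0.0])
        assert conf.elements[0] == "P"

    def test_au_element_column_normalized(self, tmp_path):
        path = tmp_path / "mini.pdb"
        path.write_text(PDB_MINIMAL)
        conf = load_pdb(path)
        assert conf.elements[2] == "AU"

    def test_empty_file_raises_format_error(self, tmp_path):
        path = tmp_path / "empty.pdb"
        path.write_text("REMARK nothing here\nEND\n")
        with pytest.raises(PDBFormatError):
            load_pdb(path)


class TestArchive:
    def test_roundtrip(self, tmp_path):
        ens = generate_synthetic_ensemble(n_residues=10, n_snapshots=2, seed=3)
        pairs = select_label_pairs(
            ens, radius=6.0, n_pairs_min=1, n_pairs_max=2, min_spread=5.0, seed=0
        )
        path = tmp_path / "arc.npz"
        save_labeled_ensemble(path, ens, pairs, metadata={"note": "test"})
        ens2, pairs2, meta = load_labeled_ensemble(path)
        assert len(ens2) == len(ens)
        np.testing.assert_array_equal(ens2[0].positions, ens[0].positions)
        assert meta == {"note": "test"}
        assert [(p.site_a, p.site_b) for p in pairs2] == [
            (p.site_a, p.site_b) for p in pairs
        ]
        np.testing.assert_allclose(pairs2[0].centers, pairs[0].centers)


class TestEnsembleInvariants:
    def test_mismatched_topology_rejected(self, rigid_conformer):
        small = make_conformer(["P"], ["P"], [[0, 0, 0]])
        with pytest.raises(ValueError):
            Ensemble(conformers=[rigid_conformer, small])
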