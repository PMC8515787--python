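import numpy as np
import pytest

from trajtree import synthfix
from trajtree.invrep import (
    DistanceMatrix,
    FeatureLabel,
    backmap_coordinates,
    default_group_order,
    distance_matrix,
    feature_labels,
    flatten,
    index_invariant_matrix,
    place_dummy_atoms,
    resolve_feature_atoms,
    select_reference_atom,
    unsort,
)
from trajtree.trajio import Frame

from conftest import random_frame


def kabsch_rmsd(a, b):
    """Independent optimal-superposition oracle (SVD Kabsch).

    Distance-matrix embeddings are defined only up to rotation *and*
    reflection, so the mirror image of ``b`` is tried as well.
    """

    def _rmsd(a, b, allow_reflection):
        a = a - a.mean(axis=0)
        b = b - b.mean(axis=0)
        u, _, vt = np.linalg.svd(a.T @ b)
        d = 1.0 if allow_reflection else np.sign(np.linalg.det(u @ vt))
        rot = u @ np.diag([1.0, 1.0, d]) @ vt
        return float(np.sqrt(np.mean(np.sum((a - b @ rot.T) ** 2, axis=1))))

    return min(_rmsd(a, b, False), _rmsd(a, b * np.array([1.0, 1.0, -1.0]), False))


class TestDistanceMatrix:
    def test_single_atom(self):
        d = distance_matrix(Frame(elements=("C",), coords=np.zeros((1, 3))))
        assert np.array_equal(d.values, [[0.0]])

    def test_three_four_five(self):
        fr = Frame(elements=("C", "O"), coords=np.array([[0, 0, 0], [3.0, 4.0, 0]]))
        assert distance_matrix(fr).values[0, 1] == pytest.approx(5.0)

    def test_matches_pairwise_brute_force(self, rng):
        fr = random_frame(rng, n_atoms=12)
        d = distance_matrix(fr).values
        for i in range(12):
            for j in range(12):
                assert d[i, j] == pytest.approx(
                    np.linalg.norm(fr.coords[i] - fr.coords[j]), abs=1e-12
                )
        assert np.array_equal(d, d.T) and np.all(np.diag(d) == 0)


class TestReferenceAtom:
    def test_unique_element_rule(self):
        fr = synthfix.template_cluster(6)
        assert select_reference_atom(fr, "C") == 0

    def test_ambiguous_or_missing_rule_raises(self):
        water = Frame(
            elements=("O", "H", "H"),
            coords=np.array([[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0]]),
        )
        with pytest.raises(ValueError, match="explicit"):
            select_reference_atom(water, "C")
        with pytest.raises(ValueError, match="explicit"):
            select_reference_atom(water, "H")

    def test_explicit_index(self):
        fr = synthfix.template_cluster(4)
        assert select_reference_atom(fr, 7) == 7


# collinear C(0) - O(1 Å) - O(2 Å) - H(3 Å): small enough to sort by hand
_COLLINEAR = Frame(
    elements=("C", "O", "O", "H"),
    coords=np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0], [3.0, 0, 0]]),
)
_COLLINEAR_EXPECTED = np.array(
    [
        [0.0, 1.0, 2.0, 3.0],  # C: self, O@1, O@2, H
        [1.0, 0.0, 1.0, 2.0],  # O@1: C, self, O@2, H
        [2.0, 0.0, 1.0, 1.0],  # O@2: C, self, O@1, H
        [3.0, 1.0, 2.0, 0.0],  # H: C, O@2, O@1, self
    ]
)


class TestInvariantMatrix:
    def test_hand_sorted_collinear_case(self):
        inv = index_invariant_matrix(distance_matrix(_COLLINEAR), 0, ("C", "O", "H"))
        np.testing.assert_array_equal(inv.values, _COLLINEAR_EXPECTED)
        np.testing.assert_array_equal(inv.row_order, [0, 1, 2, 3])

    def test_single_atom(self):
        inv = index_invariant_matrix(
            distance_matrix(Frame(elements=("C",), coords=np.zeros((1, 3)))), 0
        )
        assert np.array_equal(inv.values, [[0.0]])
        vec, labels = flatten(inv)
        assert len(vec) == 1 and str(labels[0]) == "C0-C0'"

    def test_missing_element_in_group_order(self):
        with pytest.raises(ValueError, match="missing"):
            index_invariant_matrix(distance_matrix(_COLLINEAR), 0, ("C", "O"))

    def test_rows_sorted_within_element_groups(self, rng):
        fr = random_frame(rng, n_atoms=15)
        ref = 0
        inv = index_invariant_matrix(distance_matrix(fr), ref)
        dref = distance_matrix(fr).values[ref]
        for el in inv.element_group_order:
            group = [a for a in inv.row_order if fr.elements[a] == el]
            dists = [dref[a] for a in group]
            assert dists == sorted(dists)

    def test_each_row_self_entry_is_zero_at_own_group_rank_zero(self, rng):
        fr = random_frame(rng, n_atoms=10)
        inv = index_invariant_matrix(distance_matrix(fr), 0)
        labels = feature_labels(fr.elements, inv.element_group_order)
        for i in range(10):
            row_el = fr.elements[inv.row_order[i]]
            js = [
                j for j, lab in enumerate(labels[i])
                if lab.col_element == row_el and lab.col_rank == 0
            ]
            assert len(js) == 1 and inv.values[i, js[0]] == 0.0

    def test_label_grid_layout_for_isolated_acid(self):
        # C + 2 O + 2 H with group order C, O, H: rows C0, O0, O1, H0, H1
        labels = feature_labels(("C", "O", "O", "H", "H"), ("C", "O", "H"))
        assert [row[0].row_label() for row in labels] == ["C0", "O0", "O1", "H0", "H1"]
        assert str(labels[1][4]) == "O0-H1'"

    def test_feature_label_parse_round_trip(self):
        for text in ("O2-H5'", "C0-C0'", "H9-H11'"):
            assert str(FeatureLabel.parse(text)) == text
        with pytest.raises(ValueError):
            FeatureLabel.parse("O2H5")

    def test_default_group_order_puts_reference_first(self):
        fr = synthfix.template_cluster(4)
        assert default_group_order(fr.elements, 0) == ("C", "O", "H")

    @pytest.mark.parametrize("n_waters, expected", [(6, 529), (4, 289)])
    def test_flattened_length_is_m_squared(self, n_waters, expected):
        fr = synthfix.template_cluster(n_waters)
        inv = index_invariant_matrix(distance_matrix(fr), 0)
        vec, labels = flatten(inv)
        assert len(vec) == len(labels) == expected


class TestInvariance:
    def test_rigid_motion_and_permutation_invariance(self, rng):
        """The flattened representation is identical under rotation,
        translation and relabeling of the input atoms."""
        fr = random_frame(rng, n_atoms=14, elements=("O", "H"))
        fr = Frame(elements=("C",) + fr.elements[1:], coords=fr.coords)
        ref_vec, _ = flatten(index_invariant_matrix(distance_matrix(fr), 0))
        for _ in range(20):
            q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
            moved = Frame(fr.elements, fr.coords @ q.T + rng.uniform(-20, 20, 3))
            vec, _ = flatten(index_invariant_matrix(distance_matrix(moved), 0))
            assert np.max(np.abs(vec - ref_vec)) <= 1e-9
        for _ in range(20):
            perm = rng.permutation(14)
            shuffled = Frame(
                tuple(fr.elements[p] for p in perm), fr.coords[perm]
            )
            new_ref = int(np.flatnonzero(perm == 0)[0])
            vec, _ = flatten(
                index_invariant_matrix(distance_matrix(shuffled), new_ref)
            )
            assert np.array_equal(vec, ref_vec)  # permutation is exact


class TestUnsort:
    def test_round_trip_is_exact_up_to_recorded_permutation(self, rng):
        fr = random_frame(rng, n_atoms=11)
        d = distance_matrix(fr)
        inv = index_invariant_matrix(d, 0)
        rec = unsort(inv)
        # the reconstruction is the original matrix re-indexed by row_order
        expected = d.values[np.ix_(inv.row_order, inv.row_order)]
        assert np.array_equal(rec.values, expected)
        assert rec.elements == tuple(fr.elements[a] for a in inv.row_order)

    def test_collinear_case(self):
        d = distance_matrix(_COLLINEAR)
        rec = unsort(index_invariant_matrix(d, 0, ("C", "O", "H")))
        assert np.array_equal(rec.values, d.values)  # already in sorted order

    def test_single_atom(self):
        d = distance_matrix(Frame(elements=("C",), coords=np.zeros((1, 3))))
        assert np.array_equal(unsort(index_invariant_matrix(d, 0)).values, [[0.0]])

    def test_corrupted_permutation_raises(self, rng):
        inv = index_invariant_matrix(distance_matrix(random_frame(rng, 5)), 0)
        inv.col_order[2] = 0
        with pytest.raises(ValueError, match="permutation"):
            unsort(inv)


class TestBackmap:
    def test_two_points(self):
        d = DistanceMatrix(values=np.array([[0, 2.5], [2.5, 0]]), elements=("O", "O"))
        coords = backmap_coordinates(d)
        assert np.linalg.norm(coords[0] - coords[1]) == pytest.approx(2.5, abs=1e-10)

    @pytest.mark.parametrize("m", [10, 25, 50])
    def test_random_point_sets_reconstruct_to_machine_precision(self, rng, m):
        pts = rng.uniform(-8, 8, size=(m, 3))
        fr = Frame(elements=("C",) * m, coords=pts)
        coords = backmap_coordinates(distance_matrix(fr))
        assert kabsch_rmsd(pts, coords) < 1e-8

    def test_gram_matrix_has_at_most_three_significant_eigenvalues(self, rng):
        pts = rng.uniform(-5, 5, size=(20, 3))
        d2 = distance_matrix(Frame(elements=("C",) * 20, coords=pts)).values ** 2
        j = np.eye(20) - np.full((20, 20), 1 / 20)
        evals = np.linalg.eigvalsh(-0.5 * j @ d2 @ j)
        assert np.sum(evals > 1e-9 * evals.max()) <= 3

    def test_agrees_with_independent_pcoa(self, rng):
        """Cross-check against scikit-bio's principal-coordinates
        analysis on the same distance matrix."""
        skbio = pytest.importorskip("skbio")
        pts = rng.uniform(-4, 4, size=(8, 3))
        d = distance_matrix(Frame(elements=("C",) * 8, coords=pts))
        ours = backmap_coordinates(d)
        theirs = skbio.stats.ordination.pcoa(
            skbio.DistanceMatrix(d.values), number_of_dimensions=3
        ).samples.to_numpy()
        # axes carry an arbitrary sign, so compare realized geometries
        from scipy.spatial.distance import pdist

        np.testing.assert_allclose(pdist(ours), pdist(theirs), atol=1e-8)

    def test_asymmetric_input_rejected(self):
        with pytest.raises(ValueError):
            backmap_coordinates(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestDummyAtoms:
    def _dimer(self):
        coords = np.array(
            [[0, 0, 0], [0.96, 0, 0], [-0.24, 0.93, 0],
             [2.8, 0, 0], [3.2, 0.8, 0], [3.2, -0.8, 0]]
        )
        return Frame(elements=("O", "H", "H", "O", "H", "H"), coords=coords)

    def test_markers_coincide_with_resolved_atoms(self):
        fr = self._dimer()
        inv = index_invariant_matrix(distance_matrix(fr), 0)
        label = FeatureLabel("O", 0, "H", 0)
        a, b = resolve_feature_atoms(label, inv)
        marked = place_dummy_atoms(fr, [label], inv)
        assert marked.elements[-2:] == ("X", "X")
        np.testing.assert_array_equal(marked.coords[-2], fr.coords[a])
        np.testing.assert_array_equal(marked.coords[-1], fr.coords[b])

    def test_empty_node_list_returns_frame_unchanged(self):
        fr = self._dimer()
        inv = index_invariant_matrix(distance_matrix(fr), 0)
        assert place_dummy_atoms(fr, [], inv) is fr

    def test_unresolvable_rank_raises(self):
        fr = self._dimer()
        inv = index_invariant_matrix(distance_matrix(fr), 0)
        with pytest.raises(ValueError, match="not resolvable"):
            place_dummy_atoms(fr, [FeatureLabel("O", 9, "H", 0)], inv)

    def test_markers_survive_xyz_round_trip(self, tmp_path):
        from trajtree.trajio import read_xyz, write_xyz

        fr = self._dimer()
        inv = index_invariant_matrix(distance_matrix(fr), 0)
        marked = place_dummy_atoms(fr, [FeatureLabel("O", 1, "O", 1)], inv)
        write_xyz([marked], tmp_path / "m.xyz")
        (back,) = read_xyz(tmp_path / "m.xyz")
        assert back.elements.count("X") == 2
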