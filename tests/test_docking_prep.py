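"""Box geometry, keyword-file override semantics, and chemical matching."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from probedock import (DockParams, EmptyInputError, ParseError,
                       PharmacophorePoint, build_match_table, compute_box,
                       evaluate_match, finalize_dock_input, points_to_spheres,
                       read_match_table, write_box_pdb, write_grid_input,
                       write_match_files)
from probedock.pharmacophore import FEATURE_LABELS

from conftest import random_points


def brute_force_match(points, sphere_set, table, overlap):
    """Independent oracle: nested all-pairs loop."""
    for p in points:
        for s in sphere_set.all_spheres:
            if np.linalg.norm(p.center - s.center) <= overlap:
                if not table.compatible(p.label, sphere_set.label_of(s)):
                    return False
    return True


class TestComputeBox:
    def test_default_margin_five(self):
        box = compute_box(np.array([[0.0, 0.0, 0.0]]), margin=5.0)
        np.testing.assert_allclose(box.min_corner, [-5, -5, -5])
        np.testing.assert_allclose(box.max_corner, [5, 5, 5])
        np.testing.assert_allclose(box.dimensions, [10, 10, 10])

    def test_benchmark_margin_ten(self):
        box = compute_box(np.array([[0.0, 0, 0], [2.0, 0, 0]]), margin=10.0)
        np.testing.assert_allclose(box.min_corner, [-10, -10, -10])
        np.testing.assert_allclose(box.max_corner, [12, 10, 10])

    def test_zero_margin_is_exact_bounding_box(self):
        rng = np.random.default_rng(1)
        centers = rng.uniform(-8, 8, (20, 3))
        box = compute_box(centers, margin=0.0)
        np.testing.assert_allclose(box.min_corner, centers.min(axis=0))
        np.testing.assert_allclose(box.max_corner, centers.max(axis=0))

    def test_negative_margin_rejected(self):
        with pytest.raises(ValueError):
            compute_box(np.zeros((1, 3)), margin=-1.0)

    def test_empty_set_rejected(self):
        with pytest.raises(EmptyInputError):
            compute_box(np.zeros((0, 3)))

    def test_containment_and_margin_edge_law(self):
        rng = np.random.default_rng(6)
        centers = rng.uniform(-15, 15, (30, 3))
        big = compute_box(centers, margin=7.0)
        assert big.contains(centers).all()
        delta = 2.5
        small = compute_box(centers, margin=7.0 - delta)
        np.testing.assert_allclose(big.dimensions - small.dimensions,
                                   2 * delta * np.ones(3))


class TestBoxPdb:
    def test_corner_records_match_corners(self):
        box = compute_box(np.array([[0.5, 0.5, 0.5]]), margin=0.5)
        text = write_box_pdb(box)
        recs = [l for l in text.splitlines() if l.startswith("HETATM")]
        assert len(recs) == 8
        got = sorted(tuple(float(l[c:c + 8]) for c in (30, 38, 46)) for l in recs)
        want = sorted(map(tuple, box.corners))
        np.testing.assert_allclose(got, want, atol=5e-4)

    def test_degenerate_box_valid(self):
        box = compute_box(np.array([[1.0, 2.0, 3.0]]), margin=0.0)
        recs = [l for l in write_box_pdb(box).splitlines() if l.startswith("HETATM")]
        assert len(recs) == 8

    def test_remark_dimensions(self):
        box = compute_box(np.array([[0.0, 0, 0], [4.0, 2.0, 6.0]]), margin=1.0)
        (dim_line,) = [l for l in write_box_pdb(box).splitlines()
                       if "DIMENSIONS" in l]
        vals = [float(v) for v in dim_line.split()[-3:]]
        np.testing.assert_allclose(vals, box.dimensions, atol=5e-4)


class TestGridInput:
    def test_paths_appear_exactly_once(self):
        text = write_grid_input("out/box.pdb", "rec.mol2")
        assert text.count("out/box.pdb") == 1
        assert text.count("rec.mol2") == 1

    def test_deterministic(self):
        assert write_grid_input("b.pdb", "r.mol2") == write_grid_input("b.pdb", "r.mol2")

    def test_override_replaces_default(self):
        text = write_grid_input("b.pdb", "r.mol2", overrides={"grid_spacing": "0.4"})
        params = DockParams.from_text(text)
        assert params.get("grid_spacing") == "0.4"


class TestFinalizeDockInput:
    CUSTOM = ("# user file\n"
              "foo bar\n"
              "chemical_matching              no\n"
              "my_unknown_keyword      7\n")

    def test_toggle_preserves_every_other_line(self):
        out = finalize_dock_input(self.CUSTOM, {"chemical_matching": "yes"})
        got = out.to_text().splitlines()
        want = self.CUSTOM.splitlines()
        assert len(got) == len(want)
        for g, w in zip(got, want):
            if w.startswith("chemical_matching"):
                assert g == "chemical_matching              yes"
            else:
                assert g == w

    def test_no_custom_uses_defaults_plus_managed(self):
        out = finalize_dock_input(None, {"chemical_matching": "yes",
                                         "ligand_atom_file": "lig.mol2"})
        assert out.get("chemical_matching") == "yes"
        assert out.get("ligand_atom_file") == "lig.mol2"
        assert out.get("conformer_search_type") == "flex"

    def test_unknown_keyword_preserved_verbatim(self):
        out = finalize_dock_input(self.CUSTOM, {"chemical_matching": "yes"})
        assert "my_unknown_keyword      7" in out.to_text().splitlines()

    def test_idempotent(self):
        managed = {"chemical_matching": "yes", "receptor_site_file": "s.sph"}
        once = finalize_dock_input(self.CUSTOM, managed).to_text()
        twice = finalize_dock_input(once, managed).to_text()
        assert once == twice

    def test_duplicate_keyword_in_custom_rejected(self):
        with pytest.raises(ParseError, match="line 2"):
            finalize_dock_input("a 1\na 2\n", {})


class TestMatchTable:
    def test_identity_default_with_null(self):
        t = build_match_table(["donor", "acceptor"])
        assert t.labels == ("acceptor", "donor", "null")
        assert t.compatible("donor", "donor")
        assert not t.compatible("donor", "acceptor")
        assert t.compatible("donor", "null") and t.compatible("null", "acceptor")

    def test_single_label_all_true(self):
        t = build_match_table(["aromatic"])
        assert t.compatibility.all()

    def test_duplicates_deduplicated(self):
        t = build_match_table(["donor", "donor", "donor"])
        assert t.labels == ("donor", "null")

    def test_table_file_round_trip(self):
        t = build_match_table(["donor", "acceptor", "hydrophobic"])
        _, table_text = write_match_files(t)
        back = read_match_table(table_text)
        assert back.labels == t.labels
        assert np.array_equal(back.compatibility, t.compatibility)

    @given(st.lists(st.sampled_from([l for l in FEATURE_LABELS if l != "null"]),
                    min_size=1, max_size=6))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_null_compatibility(self, labels):
        t = build_match_table(labels)
        assert np.array_equal(t.compatibility, t.compatibility.T)
        assert np.all(np.diag(t.compatibility))
        k = t.labels.index("null")
        assert t.compatibility[k].all() and t.compatibility[:, k].all()


class TestEvaluateMatch:
    def _sphere_set(self, label, center):
        pt = PharmacophorePoint(label, np.asarray(center, dtype=float),
                                source_atoms=(0,))
        return points_to_spheres([pt])

    def test_incompatible_overlap_unfavourable(self):
        table = build_match_table(["donor", "acceptor"])
        pt = PharmacophorePoint("donor", np.zeros(3), source_atoms=(0,))
        ss = self._sphere_set("acceptor", [0.5, 0.0, 0.0])
        assert evaluate_match([pt], ss, table, overlap=1.0) is False

    def test_same_label_overlap_favourable(self):
        table = build_match_table(["donor", "acceptor"])
        pt = PharmacophorePoint("donor", np.zeros(3), source_atoms=(0,))
        assert evaluate_match([pt], self._sphere_set("donor", [0.5, 0, 0]),
                              table, overlap=1.0) is True

    def test_no_overlap_vacuously_favourable(self):
        table = build_match_table(["donor", "acceptor"])
        pt = PharmacophorePoint("donor", np.zeros(3), source_atoms=(0,))
        assert evaluate_match([pt], self._sphere_set("acceptor", [9, 9, 9]),
                              table, overlap=1.0) is True

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = ("donor", "acceptor", "hydrophobic", "aromatic")
        table = build_match_table(list(labels))
        lig = random_points(rng, int(rng.integers(1, 8)), labels)
        sph = points_to_spheres(random_points(rng, int(rng.integers(1, 15)), labels))
        overlap = float(rng.uniform(0.5, 25.0))
        assert evaluate_match(lig, sph, table, overlap) == \
            brute_force_match(lig, sph, table, overlap)
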