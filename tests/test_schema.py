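"""Landmark schema structure, normalization geometry, and file round-trips."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mabeauty as mb
from mabeauty.errors import (DegeneracyError, InsufficientPointsError,
                             LandmarkParseError, SchemaMismatchError)
from mabeauty.schema import fit_line_tls, mirror_landmarks, symmetrize
from conftest import apply_similarity, random_similarity


class TestSchemaStructure:
    def test_point_count_and_indices(self, schema):
        assert schema.n_points == 72
        assert [p.index for p in schema.points] == list(range(72))

    def test_bilateral_pairs_disjoint_and_distinct(self, schema):
        seen = set()
        for left, right in schema.bilateral_pairs:
            assert left != right
            assert left not in seen and right not in seen
            seen.update((left, right))

    def test_midline_disjoint_from_pairs(self, schema):
        paired = {i for p in schema.bilateral_pairs for i in p}
        assert not paired & set(schema.midline_indices)

    def test_every_point_is_paired_or_midline(self, schema):
        paired = {i for p in schema.bilateral_pairs for i in p}
        assert paired | set(schema.midline_indices) == set(range(72))

    def test_region_census(self, schema):
        census = {r: len(schema.region_indices(r)) for r in
                  ("contour", "brow", "eye", "nose", "mouth",
                   "zygomatic", "orbital", "chin")}
        assert census == {"contour": 17, "brow": 10, "eye": 12, "nose": 9,
                          "mouth": 12, "zygomatic": 6, "orbital": 4, "chin": 2}

    def test_thirds_boundaries_are_midline_points(self, schema):
        assert set(schema.thirds_boundaries) <= set(schema.midline_indices)

    def test_schema_yaml_round_trip(self, schema, tmp_path):
        path = tmp_path / "schema.yaml"
        schema.to_yaml(path)
        again = mb.LandmarkSchema.from_yaml(path)
        assert again == schema

    def test_duplicate_pair_index_rejected(self, schema):
        bad = schema.bilateral_pairs[:-1] + ((1, 10),)  # 1 already paired
        with pytest.raises(SchemaMismatchError):
            mb.LandmarkSchema(points=schema.points, bilateral_pairs=bad,
                              midline_indices=schema.midline_indices,
                              thirds_boundaries=schema.thirds_boundaries)


class TestMeanShape:
    def test_mean_shape_is_mirror_symmetric(self, schema, mean_face):
        line = mb.midline(mean_face, schema)
        reflected = line.reflect(mean_face.coords)
        for left, right in schema.bilateral_pairs:
            np.testing.assert_allclose(reflected[right], mean_face.coords[left],
                                       atol=1e-9)

    def test_bilateral_pair_midpoints_on_midline(self, schema, mean_face):
        line = mb.midline(mean_face, schema)
        for left, right in schema.bilateral_pairs:
            mid = 0.5 * (mean_face.coords[left] + mean_face.coords[right])
            assert line.distance(mid) < 1e-9


class TestMidline:
    def test_vertical_points_give_vertical_line(self):
        pts = np.array([[0.0, 0.0], [0.0, 1.0], [0.0, 5.0]])
        line = fit_line_tls(pts)
        assert abs(line.direction[0]) < 1e-12
        assert line.distance(np.array([3.0, 2.0])) == pytest.approx(3.0)

    def test_matches_eigendecomposition_oracle_on_noisy_points(self):
        rng = np.random.default_rng(5)
        pts = np.array([[0.1, 0.0], [-0.05, 1.0], [0.02, 2.0]])
        line = fit_line_tls(pts)
        # oracle: smallest-eigenvector normal of the scatter matrix
        c = pts - pts.mean(axis=0)
        evals, evecs = np.linalg.eigh(c.T @ c)
        normal = evecs[:, np.argmin(evals)]
        assert abs(abs(line.direction @ normal)) < 1e-12
        del rng

    def test_too_few_points(self):
        with pytest.raises(InsufficientPointsError):
            fit_line_tls(np.array([[1.0, 2.0]]))

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegeneracyError):
            fit_line_tls(np.zeros((3, 2)))


class TestNormalize:
    def test_postconditions(self, schema, mean_face):
        out = mb.normalize(mean_face, schema)
        a, b = schema.ocular_indices
        assert np.linalg.norm(out.coords[a] - out.coords[b]) == pytest.approx(1.0)
        np.testing.assert_allclose(out.coords.mean(axis=0), 0.0, atol=1e-12)
        line = mb.midline(out, schema)
        assert abs(line.direction[0]) < 1e-9  # vertical midline

    def test_idempotent(self, schema, mean_face):
        once = mb.normalize(mean_face, schema)
        twice = mb.normalize(once, schema)
        np.testing.assert_allclose(twice.coords, once.coords, atol=1e-9)

    def test_rotated_and_scaled_input_maps_to_same_output(self, schema, mean_face):
        theta = np.radians(30)
        R = 3.0 * np.array([[np.cos(theta), -np.sin(theta)],
                            [np.sin(theta), np.cos(theta)]])
        moved = mb.LandmarkSet(mean_face.coords @ R.T + [11.0, -4.0])
        np.testing.assert_allclose(mb.normalize(moved, schema).coords,
                                   mb.normalize(mean_face, schema).coords,
                                   atol=1e-6)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_similarity_invariance_property(self, seed, schema, small_cohort):
        rng = np.random.default_rng(seed)
        face = small_cohort.faces[int(rng.integers(len(small_cohort.faces)))]
        R, t = random_similarity(rng)
        moved = mb.LandmarkSet(apply_similarity(face.coords, R, t))
        np.testing.assert_allclose(mb.normalize(moved, schema).coords,
                                   mb.normalize(face, schema).coords,
                                   atol=1e-6)

    def test_degenerate_input(self, schema):
        with pytest.raises(DegeneracyError):
            mb.normalize(mb.LandmarkSet(np.ones((72, 2))), schema)


class TestMirrorAndSymmetrize:
    def test_mirror_is_identity_on_symmetric_face(self, schema, mean_face):
        mirrored = mirror_landmarks(mean_face, schema)
        np.testing.assert_allclose(mirrored.coords, mean_face.coords, atol=1e-9)

    def test_symmetrize_produces_mirror_symmetric_face(self, schema, small_cohort):
        face = small_cohort.faces[0]
        sym = mb.LandmarkSet(symmetrize(face.coords, schema))
        line = mb.midline(sym, schema)
        reflected = line.reflect(sym.coords)
        for left, right in schema.bilateral_pairs:
            np.testing.assert_allclose(reflected[right], sym.coords[left], atol=1e-8)


class TestLandmarkIO:
    def test_csv_round_trip_multiple_faces(self, tmp_path, small_cohort):
        path = tmp_path / "faces.csv"
        faces = small_cohort.faces[:5]
        mb.save_landmarks(faces, path)
        loaded = mb.load_landmarks(path)
        assert len(loaded) == 5
        for orig, got in zip(faces, loaded):
            np.testing.assert_allclose(got.coords, orig.coords, rtol=1e-9)
            assert got.source_id == orig.source_id

    def test_json_round_trip(self, tmp_path, mean_face):
        path = tmp_path / "face.json"
        mb.save_landmarks(mean_face, path)
        (got,) = mb.load_landmarks(path)
        np.testing.assert_allclose(got.coords, mean_face.coords, rtol=1e-9)

    def test_pts_round_trip_exact(self, tmp_path, small_cohort):
        path = tmp_path / "face.pts"
        face = small_cohort.faces[3]
        mb.save_landmarks(face, path)
        (got,) = mb.load_landmarks(path)
        np.testing.assert_allclose(got.coords, face.coords, rtol=1e-9)

    def test_wrong_point_count_names_record(self, tmp_path):
        header = "id," + ",".join(f"x{i},y{i}" for i in range(71))
        row = "bad_face," + ",".join(["1.0"] * 142)
        path = tmp_path / "short.csv"
        path.write_text(header + "\n" + row + "\n")
        with pytest.raises(SchemaMismatchError):
            mb.load_landmarks(path)

    def test_non_numeric_coordinate_reports_line(self, tmp_path):
        header = "id," + ",".join(f"x{i},y{i}" for i in range(72))
        good = "f0," + ",".join(["1.0"] * 144)
        bad = "f1," + ",".join(["1.0"] * 143 + ["oops"])
        path = tmp_path / "bad.csv"
        path.write_text("\n".join([header, good, bad]) + "\n")
        with pytest.raises(LandmarkParseError) as err:
            mb.load_landmarks(path)
        assert err.value.line == 3

    def test_pts_declared_count_mismatch(self, tmp_path):
        body = "\n".join("1.0 2.0" for _ in range(71))
        path = tmp_path / "short.pts"
        path.write_text(f"version: 1\nn_points: 72\n{{\n{body}\n}}\n")
        with pytest.raises(SchemaMismatchError):
            mb.load_landmarks(path)
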