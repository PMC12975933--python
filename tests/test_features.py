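"""Feature registry composition, MA primitives, and extraction invariances."""

import json
from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mabeauty as mb
from mabeauty.errors import DegeneracyError
from mabeauty.features import (ANGLE_TRIPLES, N_CLASSICAL, N_FEATURES, N_MA,
                               angle_deg, ma_feature_block)
from mabeauty.schema import Line, symmetrize
from conftest import apply_similarity, random_similarity

GOLDEN = Path(__file__).parent / "data" / "mean_shape_features.json"


class TestRegistry:
    def test_census(self, registry):
        assert len(registry.entries) == N_FEATURES == 135
        cats = [e.category for e in registry.entries]
        assert cats.count("ma") == N_MA == 20
        assert sum(c in ("distance", "ratio", "angle") for c in cats) == N_CLASSICAL == 115

    def test_ma_block_is_the_tail(self, registry):
        assert registry.ma_indices == tuple(range(115, 135))

    def test_names_unique(self, registry):
        assert len(set(registry.names)) == 135

    def test_yaml_round_trip(self, registry, tmp_path):
        path = tmp_path / "registry.yaml"
        registry.to_yaml(path)
        assert mb.FeatureRegistry.from_yaml(path) == registry

    def test_reference_ranges_only_on_ma_rows(self, registry):
        for e in registry.entries:
            if e.reference_range is not None:
                assert e.category == "ma"


class TestAsymmetryIndex:
    def test_mirrored_face_scores_zero(self, schema, mean_face):
        line = mb.midline(mean_face, schema)
        value = mb.asymmetry_index(mean_face, schema.bilateral_pairs, line)
        assert value == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_hand_computation(self, schema, mean_face):
        # L=(-1,0), R=(1.2,0) about the line x=0: |1.2-1| / 1.2
        coords = mean_face.coords.copy()
        coords[60] = (-1.0, 0.0)
        coords[61] = (1.2, 0.0)
        lm = mb.LandmarkSet(coords)
        line = Line(point=np.array([0.0, 0.0]), direction=np.array([0.0, 1.0]))
        value = mb.asymmetry_index(lm, [(60, 61)], line)
        assert value == pytest.approx(0.2 / 1.2)

    def test_translation_invariance(self, schema, small_cohort):
        face = small_cohort.faces[1]
        line = mb.midline(face, schema)
        a0 = mb.asymmetry_index(face, schema.bilateral_pairs, line)
        moved = mb.LandmarkSet(face.coords + np.array([37.0, -12.0]))
        line2 = mb.midline(moved, schema)
        a1 = mb.asymmetry_index(moved, schema.bilateral_pairs, line2)
        assert a1 == pytest.approx(a0, rel=1e-9)

    def test_literal_reading_nonzero_on_symmetric_face(self, schema, mean_face):
        line = mb.midline(mean_face, schema)
        literal = mb.asymmetry_index(mean_face, schema.bilateral_pairs, line,
                                     literal=True)
        assert literal > 1.0  # pair separation dominates

    def test_pair_on_midline_degenerate(self, schema, mean_face):
        coords = mean_face.coords.copy()
        coords[60] = coords[61] = (128.0, 130.0)  # both on x=128 midline
        line = Line(point=np.array([128.0, 0.0]), direction=np.array([0.0, 1.0]))
        with pytest.raises(DegeneracyError):
            mb.asymmetry_index(mb.LandmarkSet(coords), [(60, 61)], line)


class TestNasolabialAngle:
    def test_quarter_turn_case(self):
        assert mb.nasolabial_angle((0, 0), (0, 1), (1, 1)) == pytest.approx(45.0)

    def test_collinear_rays_give_zero(self):
        assert mb.nasolabial_angle((0, 0), (1, 2), (2, 4)) == pytest.approx(0.0)

    def test_swap_symmetry(self):
        sn, ls, c = (0.3, -0.2), (0.9, 1.4), (-0.5, 0.8)
        assert mb.nasolabial_angle(sn, ls, c) == pytest.approx(
            mb.nasolabial_angle(sn, c, ls))

    def test_vertical_ray_no_singularity(self):
        # naive ratio-arctan diverges for a vertical ray; atan2 does not
        assert mb.nasolabial_angle((0, 0), (0, -3), (2, 0)) == pytest.approx(90.0)

    def test_coincident_points_degenerate(self):
        with pytest.raises(DegeneracyError):
            mb.nasolabial_angle((1, 1), (1, 1), (0, 0))


class TestThirdsProportion:
    def test_equal_thirds_give_one(self, schema, mean_face):
        coords = mean_face.coords.copy()
        t, g, s, m = schema.thirds_boundaries
        coords[g, 1] = coords[t, 1] + 50.0
        coords[s, 1] = coords[t, 1] + 100.0
        coords[m, 1] = coords[t, 1] + 150.0
        assert mb.thirds_proportion(mb.LandmarkSet(coords), schema) == pytest.approx(1.0)

    def test_hand_computed_heights(self, schema, mean_face):
        coords = mean_face.coords.copy()
        t, g, s, m = schema.thirds_boundaries
        coords[g, 1] = coords[t, 1] + 50.0
        coords[s, 1] = coords[g, 1] + 60.0
        coords[m, 1] = coords[s, 1] + 40.0
        assert mb.thirds_proportion(mb.LandmarkSet(coords), schema) == pytest.approx(
            1.5, rel=1e-9)

    def test_scale_invariance(self, schema, small_cohort):
        face = small_cohort.faces[2]
        p0 = mb.thirds_proportion(face, schema)
        p1 = mb.thirds_proportion(mb.LandmarkSet(face.coords * 4.2), schema)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestMABlock:
    def test_symmetry_rows_zero_on_mirrored_face(self, schema, mean_face):
        block = ma_feature_block(mb.normalize(mean_face, schema), schema)
        np.testing.assert_allclose(block[[14, 15, 16]], 0.0, atol=1e-9)

    def test_golden_ratio_construction(self, schema, mean_face):
        # rescale widths so bizygomatic / face height is exactly 1/1.618
        coords = mean_face.coords.copy()
        height = np.linalg.norm(coords[0] - coords[70])
        width = np.linalg.norm(coords[60] - coords[61])
        target = height / 1.618
        coords[:, 0] = 128.0 + (coords[:, 0] - 128.0) * (target / width)
        block = ma_feature_block(mb.normalize(mb.LandmarkSet(coords), schema), schema)
        assert block[0] == pytest.approx(1 / 1.618, rel=1e-6)

    def test_equal_alar_half_widths_give_unit_ratio(self, schema, mean_face):
        block = ma_feature_block(mb.normalize(mean_face, schema), schema)
        assert block[6] == pytest.approx(1.0, abs=1e-9)

    def test_symmetry_row_monotone_in_zygion_displacement(self, schema, mean_face):
        values = []
        for shift in (0.0, 2.0, 5.0, 9.0, 14.0):
            coords = mean_face.coords.copy()
            coords[60, 0] -= shift  # push left zygion laterally
            block = ma_feature_block(mb.normalize(mb.LandmarkSet(coords), schema),
                                     schema)
            values.append(block[14])
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_jaw_and_nasofrontal_angles_in_plausible_degrees(self, schema, mean_face):
        block = ma_feature_block(mb.normalize(mean_face, schema), schema)
        assert 90.0 < block[12] < 160.0    # jaw angle
        assert 100.0 < block[7] <= 180.0   # frontal-projection nasofrontal


class TestExtraction:
    def test_length_and_order(self, registry, mean_face):
        fv = mb.extract_features(mean_face)
        assert fv.values.shape == (135,)
        assert [e.category for e in registry.entries[:115]].count("ma") == 0
        assert all(e.category == "ma" for e in registry.entries[115:])

    def test_matches_frozen_golden_vector(self, mean_face):
        golden = json.loads(GOLDEN.read_text())
        fv = mb.extract_features(mean_face)
        np.testing.assert_allclose(fv.values, np.array(golden["values"]),
                                   rtol=1e-9, atol=1e-9)

    def test_ratio_rows_strictly_positive_and_angles_interior(self, registry,
                                                              small_cohort):
        X = small_cohort.features
        for e in registry.entries:
            if e.category == "ratio":
                assert np.all(X[:, e.index] > 0)
            elif e.category == "angle":
                assert np.all((X[:, e.index] > 0) & (X[:, e.index] < 360))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_similarity_invariance_of_all_features(self, seed, small_cohort):
        rng = np.random.default_rng(seed)
        face = small_cohort.faces[int(rng.integers(len(small_cohort.faces)))]
        R, t = random_similarity(rng)
        moved = mb.LandmarkSet(apply_similarity(face.coords, R, t))
        np.testing.assert_allclose(mb.extract_features(moved).values,
                                   mb.extract_features(face).values,
                                   rtol=1e-6, atol=1e-6)

    def test_symmetrized_face_has_zero_symmetry_rows(self, schema, small_cohort):
        face = small_cohort.faces[4]
        sym = mb.LandmarkSet(symmetrize(face.coords, schema))
        fv = mb.extract_features(sym)
        np.testing.assert_allclose(fv.values[[129, 130, 131]], 0.0, atol=1e-7)

    def test_angles_agree_with_law_of_cosines_oracle(self, small_cohort):
        face = mb.normalize(small_cohort.faces[5])
        P = face.coords
        fv = mb.extract_features(face)
        for k, (_, a, v, b) in enumerate(ANGLE_TRIPLES):
            la = np.linalg.norm(P[a] - P[v])
            lb = np.linalg.norm(P[b] - P[v])
            lc = np.linalg.norm(P[a] - P[b])
            oracle = np.degrees(np.arccos(
                np.clip((la**2 + lb**2 - lc**2) / (2 * la * lb), -1, 1)))
            assert fv.values[90 + k] == pytest.approx(oracle, abs=1e-9)

    def test_degenerate_face_raises_with_feature_context(self, mean_face):
        coords = mean_face.coords.copy()
        coords[30] = coords[27]  # collapse an eye width
        with pytest.raises(DegeneracyError):
            mb.extract_features(mb.LandmarkSet(coords))


def test_angle_deg_rejects_coincident_vertex():
    with pytest.raises(DegeneracyError):
        angle_deg(np.zeros(2), np.zeros(2), np.ones(2))
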