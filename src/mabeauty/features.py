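"""135-dimensional medical-aesthetic facial feature extraction.

The vector concatenates 115 classical geometric descriptors (52 normalized
inter-landmark distances, 38 ratios of those distances, 25 angles at
anatomical vertices) with a 20-entry medical-aesthetic (MA) block that
operationalizes clinical assessment rows: overall proportions (golden-ratio
width/height, facial thirds, five-eye rule), eye measurements (fissure
aspect, intercanthal spacing, ptosis proxy), nasal indices (alar symmetry,
nasofrontal angle, bridge deviation), lip indices, jawline angles and widths,
bilateral symmetry displacements, and local coordination ratios.

All features are computed on normalized landmarks (see
:func:`mabeauty.schema.normalize`): distances are in inter-ocular units,
ratios dimensionless, angles in degrees.  Every entry is therefore invariant
to similarity transforms of the raw input.

The exact catalog composition is versioned in the :class:`FeatureRegistry`
and serializable to YAML so the mapping of each entry to landmark indices is
inspectable and replaceable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import DegeneracyError
from .schema import LandmarkSchema, LandmarkSet, Line, default_schema, midline, normalize

N_FEATURES = 135
N_CLASSICAL = 115
N_MA = 20

# --------------------------------------------------------------------------
# classical catalog: 52 distances as landmark index pairs
# --------------------------------------------------------------------------
DISTANCE_PAIRS: tuple[tuple[str, int, int], ...] = (
    ("eye_width_l", 27, 30),
    ("eye_width_r", 33, 36),
    ("eye_opening_outer_l", 28, 32),
    ("eye_opening_inner_l", 29, 31),
    ("eye_opening_outer_r", 35, 37),
    ("eye_opening_inner_r", 34, 38),
    ("intercanthal", 30, 33),
    ("outercanthal", 27, 36),
    ("brow_length_l", 17, 21),
    ("brow_length_r", 22, 26),
    ("brow_eye_gap_l", 19, 28),
    ("brow_eye_gap_r", 24, 35),
    ("interbrow", 21, 22),
    ("glabella_nasion", 39, 40),
    ("nasal_dorsum", 40, 41),
    ("nose_length", 40, 43),
    ("nose_width", 46, 47),
    ("alar_base_width", 44, 45),
    ("tip_subnasale", 41, 43),
    ("philtrum_length", 43, 50),
    ("mouth_width", 48, 52),
    ("upper_lip_height", 50, 57),
    ("lower_lip_height", 57, 53),
    ("lip_height", 50, 53),
    ("lip_menton", 53, 70),
    ("stomion_menton", 57, 70),
    ("upper_third", 0, 39),
    ("middle_third", 39, 43),
    ("lower_third", 43, 70),
    ("face_height", 0, 70),
    ("bizygomatic_width", 60, 61),
    ("malar_width", 62, 63),
    ("arch_width", 64, 65),
    ("bigonial_width", 6, 14),
    ("temple_width", 1, 9),
    ("chin_width", 8, 16),
    ("menton_pogonion", 70, 71),
    ("subnasale_stomion", 43, 57),
    ("endocanthion_tip_l", 30, 41),
    ("endocanthion_tip_r", 33, 41),
    ("eye_mouth_l", 27, 48),
    ("eye_mouth_r", 36, 52),
    ("browpeak_separation", 19, 24),
    ("orbital_height_l", 66, 68),
    ("orbital_height_r", 67, 69),
    ("zygion_menton_l", 60, 70),
    ("zygion_menton_r", 61, 70),
    ("nasion_menton", 40, 70),
    ("trichion_subnasale", 0, 43),
    ("cheilion_menton_l", 48, 70),
    ("cheilion_menton_r", 52, 70),
    ("glabella_menton", 39, 70),
)

# 38 ratios as (numerator, denominator) indices into DISTANCE_PAIRS
RATIO_PAIRS: tuple[tuple[int, int], ...] = (
    (0, 6), (1, 6), (0, 7), (1, 7), (6, 7),
    (2, 0), (4, 1), (3, 0), (5, 1),
    (8, 9), (0, 1),
    (16, 30), (20, 30), (16, 20), (21, 22), (19, 28),
    (26, 27), (27, 28), (26, 28),
    (30, 29), (33, 30), (35, 33), (34, 30), (31, 30),
    (12, 6), (15, 29), (23, 28), (24, 28), (18, 15), (17, 16), (13, 15),
    (10, 11), (43, 44), (38, 39), (40, 41), (45, 46), (49, 50), (37, 28),
)

# 25 angles as (endpoint_a, vertex, endpoint_b) landmark triples
ANGLE_TRIPLES: tuple[tuple[str, int, int, int], ...] = (
    ("nasofrontal_pt", 39, 40, 41),
    ("nasal_tip", 40, 41, 43),
    ("alar_base_spread", 44, 41, 45),
    ("alare_spread", 46, 43, 47),
    ("jaw_l", 3, 6, 70),
    ("jaw_r", 11, 14, 70),
    ("brow_arch_l", 17, 19, 21),
    ("brow_arch_r", 26, 24, 22),
    ("canthal_outer_l", 28, 27, 32),
    ("canthal_outer_r", 35, 36, 37),
    ("canthal_inner_l", 29, 30, 31),
    ("canthal_inner_r", 34, 33, 38),
    ("mouth_corner_l", 50, 48, 53),
    ("mouth_corner_r", 50, 52, 53),
    ("chin_apex", 8, 70, 16),
    ("cupid_bow", 48, 50, 52),
    ("lower_lip_arc", 48, 53, 52),
    ("zygion_nasion_spread", 60, 40, 61),
    ("exocanthion_glabella", 27, 39, 36),
    ("gonial_spread", 6, 70, 14),
    ("endocanthion_nasion", 30, 40, 33),
    ("browpeak_glabella", 19, 39, 24),
    ("cheilion_tip_spread", 48, 41, 52),
    ("zygion_menton_spread", 60, 70, 61),
    ("browouter_trichion", 17, 0, 26),
)

MA_ROWS: tuple[tuple[str, tuple[int, ...]], ...] = (
    ("ma_width_height_ratio", (60, 61, 0, 70)),
    ("ma_thirds_proportion", (0, 39, 43, 70)),
    ("ma_five_eye_ratio", (27, 30, 33, 36, 60, 61)),
    ("ma_fissure_aspect", (27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38)),
    ("ma_intercanthal_ratio", (30, 33, 60, 61)),
    ("ma_ptosis_index", (27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 37, 38)),
    ("ma_alar_width_ratio", (46, 47)),
    ("ma_nasofrontal_angle", (39, 40, 41)),
    ("ma_nasal_bridge_deviation", (40, 41, 42)),
    ("ma_lip_width_ratio", (48, 52, 46, 47)),
    ("ma_philtrum_length_ratio", (43, 50, 70)),
    ("ma_lip_thickness_ratio", (50, 57, 53)),
    ("ma_jaw_angle", (3, 6, 70, 11, 14)),
    ("ma_chin_width_ratio", (8, 16, 6, 14)),
    ("ma_zygomatic_symmetry", (60, 61, 62, 63, 64, 65)),
    ("ma_brow_peak_symmetry", (19, 24)),
    ("ma_mouth_corner_offset", (48, 52)),
    ("ma_zygomatic_chin_ratio", (60, 61, 8, 16)),
    ("ma_eye_nose_ratio", (27, 30, 33, 36, 46, 47)),
    ("ma_frontotemporal_ratio", (1, 9, 60, 61)),
)

# Clinical reference ranges (target, half-width) for reporting only; never
# used in feature computation.  Angle rows in degrees, others dimensionless.
MA_REFERENCE_RANGES: dict[str, tuple[float, float, str]] = {
    "ma_width_height_ratio": (0.588, 0.649, "ratio"),      # golden ratio +-5%
    "ma_thirds_proportion": (1.0, 1.2, "ratio"),
    "ma_five_eye_ratio": (0.92, 1.08, "ratio"),
    "ma_fissure_aspect": (2.5, 3.5, "ratio"),
    "ma_intercanthal_ratio": (0.95, 1.05, "ratio"),
    "ma_ptosis_index": (0.0, 0.25, "fraction"),
    "ma_alar_width_ratio": (0.9, 1.1, "ratio"),
    "ma_nasofrontal_angle": (120.0, 135.0, "degrees"),
    "ma_nasal_bridge_deviation": (0.0, 0.012, "iod_units"),
    "ma_lip_width_ratio": (1.275, 1.725, "ratio"),
    "ma_philtrum_length_ratio": (0.28, 0.39, "ratio"),
    "ma_lip_thickness_ratio": (0.53, 0.72, "ratio"),
    "ma_jaw_angle": (110.0, 130.0, "degrees"),
    "ma_chin_width_ratio": (0.6, 0.73, "ratio"),
    "ma_zygomatic_symmetry": (0.0, 0.012, "iod_units"),
    "ma_brow_peak_symmetry": (0.0, 0.017, "iod_units"),
    "ma_mouth_corner_offset": (0.0, 0.012, "iod_units"),
    "ma_zygomatic_chin_ratio": (1.14, 1.26, "ratio"),
    "ma_eye_nose_ratio": (0.9, 1.1, "ratio"),
    "ma_frontotemporal_ratio": (0.855, 0.945, "ratio"),
}


@dataclass(frozen=True)
class FeatureDef:
    index: int
    name: str
    category: str  # distance | ratio | angle | ma
    formula_id: str
    landmark_indices: tuple[int, ...]
    reference_range: tuple[float, float, str] | None = None


@dataclass(frozen=True)
class FeatureRegistry:
    """Ordered description of every entry of the 135-dim feature vector."""

    entries: tuple[FeatureDef, ...]
    version: str = "ma135-1"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.entries) != N_FEATURES:
            raise ValueError(f"registry must have {N_FEATURES} entries, got {len(self.entries)}")
        cats = [e.category for e in self.entries]
        n_ma = cats.count("ma")
        n_classical = sum(c in ("distance", "ratio", "angle") for c in cats)
        if n_ma != N_MA or n_classical != N_CLASSICAL:
            raise ValueError(
                f"registry must hold {N_CLASSICAL} classical + {N_MA} ma entries, "
                f"got {n_classical} + {n_ma}"
            )
        for i, e in enumerate(self.entries):
            if e.index != i:
                raise ValueError("registry entries out of order")

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    @property
    def ma_indices(self) -> tuple[int, ...]:
        """Indices of the 20 MA rows — the GA's protected prior set."""
        return tuple(e.index for e in self.entries if e.category == "ma")

    @property
    def classical_indices(self) -> tuple[int, ...]:
        return tuple(e.index for e in self.entries if e.category != "ma")

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "version": self.version,
            "entries": [
                {
                    "index": e.index,
                    "name": e.name,
                    "category": e.category,
                    "formula": e.formula_id,
                    "landmarks": list(e.landmark_indices),
                    **({"reference_range": list(e.reference_range)}
                       if e.reference_range else {}),
                }
                for e in self.entries
            ],
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureRegistry":
        data = yaml.safe_load(Path(path).read_text())
        entries = tuple(
            FeatureDef(
                index=int(e["index"]),
                name=str(e["name"]),
                category=str(e["category"]),
                formula_id=str(e["formula"]),
                landmark_indices=tuple(int(i) for i in e["landmarks"]),
                reference_range=(tuple(e["reference_range"])
                                 if "reference_range" in e else None),
            )
            for e in data["entries"]
        )
        return cls(entries=entries, version=str(data.get("version", "ma135-1")))


@lru_cache(maxsize=1)
def default_registry() -> FeatureRegistry:
    entries: list[FeatureDef] = []
    idx = 0
    for name, i, j in DISTANCE_PAIRS:
        entries.append(FeatureDef(idx, f"dist_{name}", "distance", f"dist:{i},{j}", (i, j)))
        idx += 1
    dist_names = [name for name, _, _ in DISTANCE_PAIRS]
    for a, b in RATIO_PAIRS:
        ia, ja = DISTANCE_PAIRS[a][1:]
        ib, jb = DISTANCE_PAIRS[b][1:]
        entries.append(FeatureDef(
            idx, f"ratio_{dist_names[a]}_over_{dist_names[b]}", "ratio",
            f"ratio:{a},{b}", (ia, ja, ib, jb)))
        idx += 1
    for name, a, v, b in ANGLE_TRIPLES:
        entries.append(FeatureDef(idx, f"angle_{name}", "angle", f"angle:{a},{v},{b}",
                                  (a, v, b)))
        idx += 1
    for row, (name, lms) in enumerate(MA_ROWS, start=1):
        entries.append(FeatureDef(idx, name, "ma", f"ma:{row:02d}", lms,
                                  MA_REFERENCE_RANGES.get(name)))
        idx += 1
    return FeatureRegistry(entries=tuple(entries))


@dataclass
class FeatureVector:
    """One face's ordered 135 measurements plus its identifier."""

    values: np.ndarray
    face_id: str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_FEATURES,):
            raise ValueError(f"feature vector must have length {N_FEATURES}")
        if not np.all(np.isfinite(self.values)):
            raise DegeneracyError(f"face {self.face_id!r}: non-finite feature values")


# --------------------------------------------------------------------------
# geometric primitives
# --------------------------------------------------------------------------

def angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    """Interior angle at `vertex` between rays to `a` and `b`, in degrees."""
    u = np.asarray(a, float) - vertex
    v = np.asarray(b, float) - vertex
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu <= 1e-12 or nv <= 1e-12:
        raise DegeneracyError("angle undefined: ray endpoint coincides with vertex")
    c = np.clip(u @ v / (nu * nv), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def nasolabial_angle(sn: np.ndarray, ls: np.ndarray, c: np.ndarray) -> float:
    """Nasolabial angle at the subnasale, degrees.

    Difference of the full-quadrant (atan2) polar angles of the rays
    subnasale->labiale superius and subnasale->columella, wrapped to
    (-180, 180] and reported as an absolute angle.  Using atan2 rather than
    the ratio arctangent avoids the +-90-degree singularities of the naive
    form for vertical rays.
    """
    sn = np.asarray(sn, float)
    v1 = np.asarray(ls, float) - sn
    v2 = np.asarray(c, float) - sn
    if np.linalg.norm(v1) <= 1e-12 or np.linalg.norm(v2) <= 1e-12:
        raise DegeneracyError("nasolabial angle undefined for coincident points")
    diff = np.degrees(np.arctan2(v1[1], v1[0]) - np.arctan2(v2[1], v2[0]))
    diff = (diff + 180.0) % 360.0 - 180.0
    if diff == -180.0:
        diff = 180.0
    return float(abs(diff))


def asymmetry_index(lm: LandmarkSet,
                    pairs: Sequence[tuple[int, int]],
                    line: Line,
                    literal: bool = False) -> float:
    """Zygomatic/bilateral asymmetry index.

    For each bilateral pair (L, R) the numerator is the distance between L
    and the mirror image of R across the facial midline, and the denominator
    is the larger of the two point-to-midline distances; the index is the
    mean of these quotients.  Zero iff every pair is exactly mirror
    symmetric.  With ``literal=True`` the numerator is the direct Euclidean
    distance d(L, R) instead (a reading under which even perfectly symmetric
    faces score the pair separation); the mirrored form is the default
    because clinical symmetry rows treat a symmetric face as zero-difference.
    """
    if len(pairs) == 0:
        raise DegeneracyError("asymmetry index needs at least one bilateral pair")
    total = 0.0
    for left, right in pairs:
        pl, pr = lm.coords[left], lm.coords[right]
        dl, dr = float(line.distance(pl)), float(line.distance(pr))
        denom = max(dl, dr)
        if denom <= 1e-12:
            raise DegeneracyError(
                f"pair ({left},{right}) lies on the midline; asymmetry quotient undefined"
            )
        num = np.linalg.norm(pl - pr) if literal else np.linalg.norm(pl - line.reflect(pr))
        total += float(num) / denom
    return total / len(pairs)


def thirds_proportion(lm: LandmarkSet, schema: LandmarkSchema | None = None) -> float:
    """Max/min ratio of the three facial-third heights (>= 1).

    Heights are projections of trichion-glabella, glabella-subnasale and
    subnasale-menton onto the midline direction, so residual head roll does
    not inflate them.
    """
    schema = schema or default_schema()
    line = midline(lm, schema)
    t, g, s, m = (lm.coords[i] for i in schema.thirds_boundaries)
    u = line.direction
    heights = np.array([abs((g - t) @ u), abs((s - g) @ u), abs((m - s) @ u)])
    if np.any(heights <= 1e-12):
        raise DegeneracyError("a facial third has non-positive height")
    return float(heights.max() / heights.min())


# --------------------------------------------------------------------------
# extraction
# --------------------------------------------------------------------------

@lru_cache(maxsize=4)
def _compiled(registry: FeatureRegistry):
    """Precompute index arrays so extraction is a handful of vector ops."""
    d_i = np.array([i for _, i, j in DISTANCE_PAIRS])
    d_j = np.array([j for _, i, j in DISTANCE_PAIRS])
    r_num = np.array([a for a, b in RATIO_PAIRS])
    r_den = np.array([b for a, b in RATIO_PAIRS])
    a_a = np.array([a for _, a, v, b in ANGLE_TRIPLES])
    a_v = np.array([v for _, a, v, b in ANGLE_TRIPLES])
    a_b = np.array([b for _, a, v, b in ANGLE_TRIPLES])
    return d_i, d_j, r_num, r_den, a_a, a_v, a_b


def _eye_geometry(P: np.ndarray):
    """(width, opening height) per eye from the 6-point eye rings."""
    wl = np.linalg.norm(P[27] - P[30])
    wr = np.linalg.norm(P[33] - P[36])
    hl = np.linalg.norm(0.5 * (P[28] + P[29]) - 0.5 * (P[31] + P[32]))
    hr = np.linalg.norm(0.5 * (P[34] + P[35]) - 0.5 * (P[37] + P[38]))
    return wl, wr, hl, hr


def ma_feature_block(lm: LandmarkSet, schema: LandmarkSchema | None = None) -> np.ndarray:
    """The 20 MA measurements (Table-style clinical rows), registry order."""
    schema = schema or default_schema()
    P = lm.coords
    line = midline(lm, schema)

    def d(i, j):
        return float(np.linalg.norm(P[i] - P[j]))

    bizygo = d(60, 61)
    face_h = d(0, 70)
    if bizygo <= 1e-12 or face_h <= 1e-12:
        raise DegeneracyError("zero facial width or height")
    wl, wr, hl, hr = _eye_geometry(P)
    eye_w = 0.5 * (wl + wr)
    eye_h = 0.5 * (hl + hr)
    if min(wl, wr, hl, hr) <= 1e-12:
        raise DegeneracyError("degenerate eye geometry")

    # ptosis proxy: upper-lid encroachment on a nominal iris of diameter w/3
    def ptosis(w, h):
        return float(np.clip(1.0 - h / (w / 3.0), 0.0, 1.0))

    def mirror_gap(left, right):
        return float(np.linalg.norm(P[left] - line.reflect(P[right])))

    nose_w = d(46, 47)
    chin_w = d(8, 16)
    bigonial = d(6, 14)
    if min(nose_w, chin_w, bigonial) <= 1e-12:
        raise DegeneracyError("degenerate nose/jaw geometry")
    alar_l = float(line.distance(P[46]))
    alar_r = float(line.distance(P[47]))
    if min(alar_l, alar_r) <= 1e-12:
        raise DegeneracyError("alare landmarks lie on the midline")

    values = np.array([
        bizygo / face_h,                                     # 1 width/height
        thirds_proportion(lm, schema),                       # 2 thirds
        eye_w / (bizygo / 5.0),                              # 3 five-eye
        eye_w / eye_h,                                       # 4 fissure aspect
        d(30, 33) / (bizygo / 5.0),                          # 5 intercanthal
        0.5 * (ptosis(wl, hl) + ptosis(wr, hr)),             # 6 ptosis index
        alar_l / alar_r,                                     # 7 alar width ratio
        angle_deg(P[39], P[40], P[41]),                      # 8 nasofrontal angle
        float(np.mean(line.distance(P[[40, 41, 42]]))),      # 9 bridge deviation
        d(48, 52) / nose_w,                                  # 10 lip width ratio
        d(43, 50) / d(43, 70),                               # 11 philtrum ratio
        d(50, 57) / d(57, 53),                               # 12 lip thickness
        0.5 * (angle_deg(P[3], P[6], P[70])
               + angle_deg(P[11], P[14], P[70])),            # 13 jaw angle
        chin_w / bigonial,                                   # 14 chin width ratio
        float(np.mean([mirror_gap(60, 61), mirror_gap(62, 63),
                       mirror_gap(64, 65)])),                # 15 zygomatic symmetry
        mirror_gap(19, 24),                                  # 16 brow peak symmetry
        mirror_gap(48, 52),                                  # 17 mouth corner offset
        bizygo / chin_w,                                     # 18 zygomatic-chin
        eye_w / nose_w,                                      # 19 eye-nose ratio
        d(1, 9) / bizygo,                                    # 20 frontotemporal
    ])
    return values


def extract_features(lm: LandmarkSet,
                     schema: LandmarkSchema | None = None,
                     registry: FeatureRegistry | None = None,
                     prenormalized: bool = False) -> FeatureVector:
    """Compute the full 135-dim vector for one face.

    Entries 0-114 are the classical catalog (distances, ratios, angles);
    entries 115-134 the MA block.  The landmark set is normalized first
    unless ``prenormalized=True``.
    """
    schema = schema or default_schema()
    registry = registry or default_registry()
    if not prenormalized or lm.frame != "normalized":
        lm = normalize(lm, schema)
    P = lm.coords
    d_i, d_j, r_num, r_den, a_a, a_v, a_b = _compiled(registry)

    diffs = P[d_i] - P[d_j]
    dists = np.sqrt(np.einsum("ij,ij->i", diffs, diffs))
    if np.any(dists <= 1e-12):
        bad = int(np.argmin(dists))
        raise DegeneracyError(
            f"feature {bad} ({registry.entries[bad].name}): coincident landmarks"
        )
    ratios = dists[r_num] / dists[r_den]

    u = P[a_a] - P[a_v]
    v = P[a_b] - P[a_v]
    nu = np.sqrt(np.einsum("ij,ij->i", u, u))
    nv = np.sqrt(np.einsum("ij,ij->i", v, v))
    if np.any(nu <= 1e-12) or np.any(nv <= 1e-12):
        bad = len(DISTANCE_PAIRS) + len(RATIO_PAIRS) + int(
            np.argmin(np.minimum(nu, nv)))
        raise DegeneracyError(
            f"feature {bad} ({registry.entries[bad].name}): angle vertex degenerate"
        )
    cosang = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
    angles = np.degrees(np.arccos(cosang))

    ma = ma_feature_block(lm, schema)
    values = np.concatenate([dists, ratios, angles, ma])
    return FeatureVector(values, face_id=lm.source_id)


def extract_feature_table(faces: Sequence[LandmarkSet],
                          schema: LandmarkSchema | None = None,
                          registry: FeatureRegistry | None = None) -> np.ndarray:
    """Stack feature vectors for many faces into an (n_faces, 135) array."""
    return np.array([extract_features(f, schema, registry).values for f in faces])
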