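"""72-point medical-aesthetic facial landmark schema, geometry, and landmark file I/O.

The schema names every landmark anatomically, declares which points form
bilateral (left/right) pairs, which lie on the facial midline, and which four
midline points bound the classical facial thirds (trichion, glabella,
subnasale, menton).  Coordinates follow the image convention: x increases
rightward, y increases downward, indices are 0-based.

All downstream measurement code operates on *normalized* landmarks: similarity
aligned so the midline is vertical, the inter-ocular (outer-canthal) distance
is 1, and the centroid sits at the origin.  Normalization preserves every
angle and ratio, so features computed afterwards are invariant to rotation,
isotropic scaling and translation of the raw input.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    DegeneracyError,
    InsufficientPointsError,
    LandmarkParseError,
    SchemaMismatchError,
)

N_POINTS = 72

REGIONS = ("contour", "brow", "eye", "nose", "mouth", "zygomatic", "orbital", "chin")

# (name, region); index = position in this tuple.  Left/right refer to image
# left (smaller x) / image right (larger x) on an upright frontal face.
POINT_TABLE: tuple[tuple[str, str], ...] = (
    ("trichion", "contour"),            # 0
    ("forehead_contour_l", "contour"),  # 1
    ("temple_l", "contour"),            # 2
    ("upper_cheek_l", "contour"),       # 3
    ("mid_cheek_l", "contour"),         # 4
    ("lower_cheek_l", "contour"),       # 5
    ("gonion_l", "contour"),            # 6
    ("jawline_l", "contour"),           # 7
    ("chin_lateral_l", "contour"),      # 8
    ("forehead_contour_r", "contour"),  # 9
    ("temple_r", "contour"),            # 10
    ("upper_cheek_r", "contour"),       # 11
    ("mid_cheek_r", "contour"),         # 12
    ("lower_cheek_r", "contour"),       # 13
    ("gonion_r", "contour"),            # 14
    ("jawline_r", "contour"),           # 15
    ("chin_lateral_r", "contour"),      # 16
    ("brow_outer_l", "brow"),           # 17
    ("brow_midouter_l", "brow"),        # 18
    ("brow_peak_l", "brow"),            # 19
    ("brow_midinner_l", "brow"),        # 20
    ("brow_inner_l", "brow"),           # 21
    ("brow_inner_r", "brow"),           # 22
    ("brow_midinner_r", "brow"),        # 23
    ("brow_peak_r", "brow"),            # 24
    ("brow_midouter_r", "brow"),        # 25
    ("brow_outer_r", "brow"),           # 26
    ("exocanthion_l", "eye"),           # 27
    ("upper_lid_outer_l", "eye"),       # 28
    ("upper_lid_inner_l", "eye"),       # 29
    ("endocanthion_l", "eye"),          # 30
    ("lower_lid_inner_l", "eye"),       # 31
    ("lower_lid_outer_l", "eye"),       # 32
    ("endocanthion_r", "eye"),          # 33
    ("upper_lid_inner_r", "eye"),       # 34
    ("upper_lid_outer_r", "eye"),       # 35
    ("exocanthion_r", "eye"),           # 36
    ("lower_lid_outer_r", "eye"),       # 37
    ("lower_lid_inner_r", "eye"),       # 38
    ("glabella", "nose"),               # 39
    ("nasion", "nose"),                 # 40
    ("pronasale", "nose"),              # 41
    ("columella", "nose"),              # 42
    ("subnasale", "nose"),              # 43
    ("alar_base_l", "nose"),            # 44
    ("alar_base_r", "nose"),            # 45
    ("alare_l", "nose"),                # 46
    ("alare_r", "nose"),                # 47
    ("cheilion_l", "mouth"),            # 48
    ("crista_philtri_l", "mouth"),      # 49
    ("labiale_superius", "mouth"),      # 50
    ("crista_philtri_r", "mouth"),      # 51
    ("cheilion_r", "mouth"),            # 52
    ("labiale_inferius", "mouth"),      # 53
    ("lower_vermilion_l", "mouth"),     # 54
    ("lower_vermilion_r", "mouth"),     # 55
    ("philtrum_mid", "mouth"),          # 56
    ("stomion", "mouth"),               # 57
    ("lower_lip_lateral_l", "mouth"),   # 58
    ("lower_lip_lateral_r", "mouth"),   # 59
    ("zygion_l", "zygomatic"),          # 60
    ("zygion_r", "zygomatic"),          # 61
    ("malar_l", "zygomatic"),           # 62
    ("malar_r", "zygomatic"),           # 63
    ("zygomatic_arch_l", "zygomatic"),  # 64
    ("zygomatic_arch_r", "zygomatic"),  # 65
    ("supraorbital_l", "orbital"),      # 66
    ("supraorbital_r", "orbital"),      # 67
    ("infraorbital_l", "orbital"),      # 68
    ("infraorbital_r", "orbital"),      # 69
    ("menton", "chin"),                 # 70
    ("pogonion", "chin"),               # 71
)

BILATERAL_PAIRS: tuple[tuple[int, int], ...] = (
    (1, 9), (2, 10), (3, 11), (4, 12), (5, 13), (6, 14), (7, 15), (8, 16),
    (17, 26), (18, 25), (19, 24), (20, 23), (21, 22),
    (27, 36), (28, 35), (29, 34), (30, 33), (31, 38), (32, 37),
    (44, 45), (46, 47),
    (48, 52), (49, 51), (54, 55), (58, 59),
    (60, 61), (62, 63), (64, 65),
    (66, 67), (68, 69),
)

MIDLINE_INDICES: tuple[int, ...] = (0, 39, 40, 41, 42, 43, 50, 53, 56, 57, 70, 71)

# trichion, glabella, subnasale, menton
THIRDS_BOUNDARIES: tuple[int, int, int, int] = (0, 39, 43, 70)

# outer eye corners used for scale normalization
OCULAR_INDICES: tuple[int, int] = (27, 36)

# Mean frontal face in a nominal 256x256 image frame (x, y), symmetric about
# x = 128 by construction.  Left-side and midline points are authored; right
# side is mirrored programmatically below.
_MEAN_LEFT_AND_MID: dict[int, tuple[float, float]] = {
    0: (128, 28),
    1: (58, 60), 2: (54, 90), 3: (52, 120), 4: (54, 150),
    5: (60, 175), 6: (70, 196), 7: (86, 212), 8: (106, 222),
    17: (78, 100), 18: (88, 96), 19: (98, 94), 20: (108, 96), 21: (116, 99),
    27: (84, 118), 28: (91, 114), 29: (101, 114),
    30: (113, 118), 31: (101, 122), 32: (91, 122),
    39: (128, 92), 40: (128, 104), 41: (128, 146), 42: (128, 152),
    43: (128, 158), 44: (112, 152), 46: (109, 146),
    48: (104, 185), 49: (120, 180), 50: (128, 179),
    53: (128, 196), 54: (116, 193), 56: (128, 168), 57: (128, 186),
    58: (110, 190),
    60: (56, 132), 62: (76, 142), 64: (64, 124),
    66: (98, 104), 68: (98, 130),
    70: (128, 228), 71: (128, 218),
}

_MIRROR_X = 128.0


@dataclass(frozen=True)
class SchemaPoint:
    index: int
    name: str
    region: str


@dataclass(frozen=True)
class LandmarkSchema:
    """Named landmark registry with pairing, midline and thirds structure."""

    points: tuple[SchemaPoint, ...]
    bilateral_pairs: tuple[tuple[int, int], ...]
    midline_indices: tuple[int, ...]
    thirds_boundaries: tuple[int, int, int, int]
    ocular_indices: tuple[int, int] = OCULAR_INDICES
    version: str = "ma72-1"

    def __post_init__(self):
        self.validate()

    @property
    def n_points(self) -> int:
        return len(self.points)

    def index_of(self, name: str) -> int:
        try:
            return self._name_index()[name]
        except KeyError:
            raise KeyError(f"unknown landmark name: {name!r}") from None

    def _name_index(self) -> dict[str, int]:
        # frozen dataclass: cache on the instance dict via object.__setattr__
        cached = self.__dict__.get("_names")
        if cached is None:
            cached = {p.name: p.index for p in self.points}
            object.__setattr__(self, "_names", cached)
        return cached

    def region_indices(self, region: str) -> list[int]:
        return [p.index for p in self.points if p.region == region]

    def validate(self) -> None:
        idx = [p.index for p in self.points]
        if idx != list(range(len(self.points))):
            raise SchemaMismatchError("point indices must be unique and contiguous from 0")
        if len(self.points) != N_POINTS:
            raise SchemaMismatchError(
                f"schema must declare exactly {N_POINTS} points, got {len(self.points)}"
            )
        seen: set[int] = set()
        for left, right in self.bilateral_pairs:
            if left == right:
                raise SchemaMismatchError(f"bilateral pair ({left},{right}) is degenerate")
            for i in (left, right):
                if i in seen:
                    raise SchemaMismatchError(f"index {i} appears in two bilateral pairs")
                seen.add(i)
        if seen & set(self.midline_indices):
            raise SchemaMismatchError("midline indices overlap bilateral pairs")
        if len(self.thirds_boundaries) != 4:
            raise SchemaMismatchError("thirds_boundaries must list 4 indices")

    # -- serialization ------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = {
            "version": self.version,
            "points": [[p.index, p.name, p.region] for p in self.points],
            "bilateral_pairs": [list(p) for p in self.bilateral_pairs],
            "midline": list(self.midline_indices),
            "thirds": list(self.thirds_boundaries),
            "ocular": list(self.ocular_indices),
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "LandmarkSchema":
        data = yaml.safe_load(Path(path).read_text())
        return cls(
            points=tuple(SchemaPoint(int(i), str(n), str(r)) for i, n, r in data["points"]),
            bilateral_pairs=tuple((int(a), int(b)) for a, b in data["bilateral_pairs"]),
            midline_indices=tuple(int(i) for i in data["midline"]),
            thirds_boundaries=tuple(int(i) for i in data["thirds"]),
            ocular_indices=tuple(int(i) for i in data.get("ocular", OCULAR_INDICES)),
            version=str(data.get("version", "ma72-1")),
        )


@dataclass
class LandmarkSet:
    """One face's 72 2D landmark coordinates (pixels unless frame='normalized')."""

    coords: np.ndarray
    frame: str = "image"
    source_id: str | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (N_POINTS, 2):
            raise SchemaMismatchError(
                f"landmark set {self.source_id!r}: expected shape ({N_POINTS}, 2), "
                f"got {self.coords.shape}"
            )
        if not np.all(np.isfinite(self.coords)):
            raise SchemaMismatchError(
                f"landmark set {self.source_id!r}: non-finite coordinates"
            )

    def copy(self) -> "LandmarkSet":
        return LandmarkSet(self.coords.copy(), self.frame, self.source_id)


@dataclass(frozen=True)
class Line:
    """A 2D line given by a point on it and a unit direction vector."""

    point: np.ndarray
    direction: np.ndarray

    def distance(self, p: np.ndarray) -> np.ndarray:
        """Unsigned point-to-line distance; p may be (2,) or (n, 2)."""
        p = np.asarray(p, dtype=float)
        v = p - self.point
        # perpendicular component magnitude
        n = np.array([-self.direction[1], self.direction[0]])
        return np.abs(v @ n)

    def reflect(self, p: np.ndarray) -> np.ndarray:
        """Mirror p (shape (2,) or (n,2)) across the line."""
        p = np.asarray(p, dtype=float)
        v = p - self.point
        proj = np.outer(v @ self.direction, self.direction) if v.ndim == 2 else (
            (v @ self.direction) * self.direction
        )
        return self.point + 2.0 * proj - v


@lru_cache(maxsize=1)
def default_schema() -> LandmarkSchema:
    """The frozen 72-point medical-aesthetic registry shipped with the package."""
    points = tuple(
        SchemaPoint(i, name, region) for i, (name, region) in enumerate(POINT_TABLE)
    )
    return LandmarkSchema(
        points=points,
        bilateral_pairs=BILATERAL_PAIRS,
        midline_indices=MIDLINE_INDICES,
        thirds_boundaries=THIRDS_BOUNDARIES,
    )


def mean_shape() -> np.ndarray:
    """Symmetric mean frontal face, (72, 2) float array in a 256x256 frame."""
    coords = np.zeros((N_POINTS, 2))
    for i, xy in _MEAN_LEFT_AND_MID.items():
        coords[i] = xy
    for left, right in BILATERAL_PAIRS:
        coords[right] = (2 * _MIRROR_X - coords[left, 0], coords[left, 1])
    return coords


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def midline(lm: LandmarkSet, schema: LandmarkSchema | None = None) -> Line:
    """Total-least-squares facial midline through the schema's midline landmarks.

    The direction is the principal axis of the midline points' scatter; for
    collinear points this is exact.  Robust to residual head roll, unlike
    taking the image's vertical axis.
    """
    schema = schema or default_schema()
    pts = lm.coords[list(schema.midline_indices)]
    return fit_line_tls(pts)


def fit_line_tls(pts: np.ndarray) -> Line:
    """Orthogonal (total) least-squares line through >= 2 points."""
    pts = np.asarray(pts, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InsufficientPointsError("need at least 2 points to fit a line")
    center = pts.mean(axis=0)
    d = pts - center
    cov = d.T @ d
    if np.allclose(cov, 0.0):
        raise DegeneracyError("cannot fit a line through coincident points")
    evals, evecs = np.linalg.eigh(cov)
    direction = evecs[:, np.argmax(evals)]
    direction = direction / np.linalg.norm(direction)
    return Line(point=center, direction=direction)


def interocular_distance(lm: LandmarkSet, schema: LandmarkSchema | None = None) -> float:
    schema = schema or default_schema()
    a, b = schema.ocular_indices
    return float(np.linalg.norm(lm.coords[a] - lm.coords[b]))


def normalize(lm: LandmarkSet, schema: LandmarkSchema | None = None) -> LandmarkSet:
    """Similarity-align a landmark set to the canonical frame.

    After normalization the total-least-squares midline is vertical (chin
    below glabella), the inter-ocular distance equals 1, and the centroid is
    the origin.  Angles and ratios are preserved, so the map is idempotent
    and invariant to any similarity transform of the input.
    """
    schema = schema or default_schema()
    coords = np.asarray(lm.coords, dtype=float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    if np.allclose(centered, 0.0):
        raise DegeneracyError("all landmarks coincide; cannot normalize")

    line = fit_line_tls(centered[list(schema.midline_indices)])
    ux, uy = line.direction
    # rotation taking the midline direction to (0, 1)
    rot = np.array([[uy, -ux], [ux, uy]])
    rotated = centered @ rot.T
    # resolve the 180-degree ambiguity: menton (chin) below glabella
    _, glabella_i, _, menton_i = schema.thirds_boundaries
    if rotated[menton_i, 1] < rotated[glabella_i, 1]:
        rotated = -rotated

    a, b = schema.ocular_indices
    iod = np.linalg.norm(rotated[a] - rotated[b])
    if iod <= 1e-12:
        raise DegeneracyError("outer eye corners coincide; inter-ocular distance is 0")
    scaled = rotated / iod
    scaled -= scaled.mean(axis=0)
    return LandmarkSet(scaled, frame="normalized", source_id=lm.source_id)


def mirror_landmarks(lm: LandmarkSet, schema: LandmarkSchema | None = None) -> LandmarkSet:
    """Reflect a face across its own midline and swap left/right point labels.

    For a perfectly symmetric face this is the identity (up to tolerance).
    """
    schema = schema or default_schema()
    line = midline(lm, schema)
    reflected = line.reflect(lm.coords)
    out = reflected.copy()
    for left, right in schema.bilateral_pairs:
        out[left], out[right] = reflected[right].copy(), reflected[left].copy()
    return LandmarkSet(out, frame=lm.frame, source_id=lm.source_id)


def symmetrize(coords: np.ndarray, schema: LandmarkSchema | None = None) -> np.ndarray:
    """Project coordinates onto exact bilateral symmetry about the TLS midline."""
    schema = schema or default_schema()
    lm = LandmarkSet(np.asarray(coords, dtype=float))
    line = midline(lm, schema)
    out = lm.coords.copy()
    reflected = line.reflect(lm.coords)
    for left, right in schema.bilateral_pairs:
        mean_left = 0.5 * (lm.coords[left] + reflected[right])
        out[left] = mean_left
        out[right] = line.reflect(mean_left)
    # snap midline points onto the line
    for i in schema.midline_indices:
        out[i] = 0.5 * (lm.coords[i] + reflected[i])
    return out


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

FORMATS = ("csv", "json", "pts")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ValueError(f"unknown landmark format {fmt!r}; expected one of {FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in FORMATS:
        return suffix
    raise ValueError(f"cannot infer landmark format from {path.name!r}; pass format=")


def load_landmarks(path: str | Path, format: str | None = None) -> list[LandmarkSet]:
    """Read landmark sets from CSV, JSON, or pts files.

    CSV: header ``id,x0,y0,...,x71,y71``, one face per row.
    JSON: a list (or single object) of ``{"id": ..., "points": [[x, y], ...]}``.
    pts: the common ``version: 1 / n_points: N / { ... }`` dialect, one face.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        return _load_csv(path)
    if fmt == "json":
        return _load_json(path)
    return _load_pts(path)


def save_landmarks(sets: Sequence[LandmarkSet] | LandmarkSet,
                   path: str | Path, format: str | None = None) -> None:
    if isinstance(sets, LandmarkSet):
        sets = [sets]
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "csv":
        header = "id," + ",".join(f"x{i},y{i}" for i in range(N_POINTS))
        lines = [header]
        for k, lm in enumerate(sets):
            sid = lm.source_id if lm.source_id is not None else str(k)
            lines.append(sid + "," + ",".join(f"{v:.10g}" for v in lm.coords.ravel()))
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "json":
        records = [
            {"id": lm.source_id if lm.source_id is not None else str(k),
             "frame": lm.frame,
             "points": [[float(x), float(y)] for x, y in lm.coords]}
            for k, lm in enumerate(sets)
        ]
        path.write_text(json.dumps(records, indent=1))
    else:
        if len(sets) != 1:
            raise ValueError("pts format stores exactly one face per file")
        lm = sets[0]
        body = "\n".join(f"{x:.10g} {y:.10g}" for x, y in lm.coords)
        path.write_text(f"version: 1\nn_points: {N_POINTS}\n{{\n{body}\n}}\n")


def _check_count(n: int, record: str) -> None:
    if n != N_POINTS:
        raise SchemaMismatchError(
            f"record {record!r}: expected {N_POINTS} points, got {n}"
        )


def _load_csv(path: Path) -> list[LandmarkSet]:
    out: list[LandmarkSet] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.lower().lstrip().startswith("id"):
            raise LandmarkParseError(f"{path.name}: missing 'id,...' header", line=1)
        n_cols = len(header.strip().split(","))
        _check_count((n_cols - 1) // 2, f"{path.name}:header")
        for lineno, raw in enumerate(fh, start=2):
            if not raw.strip():
                continue
            parts = raw.strip().split(",")
            sid = parts[0]
            _check_count((len(parts) - 1) // 2, sid)
            try:
                vals = np.array([float(v) for v in parts[1:]])
            except ValueError as exc:
                raise LandmarkParseError(
                    f"{path.name}: non-numeric coordinate ({exc})", line=lineno
                ) from None
            out.append(LandmarkSet(vals.reshape(-1, 2), source_id=sid))
    return out


def _load_json(path: Path) -> list[LandmarkSet]:
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise LandmarkParseError(f"{path.name}: invalid JSON ({exc.msg})",
                                 line=exc.lineno) from None
    if isinstance(data, dict):
        data = [data]
    out = []
    for k, rec in enumerate(data):
        sid = str(rec.get("id", k))
        pts = rec.get("points")
        if pts is None:
            raise SchemaMismatchError(f"record {sid!r}: missing 'points' key")
        _check_count(len(pts), sid)
        out.append(LandmarkSet(np.asarray(pts, dtype=float), source_id=sid,
                               frame=str(rec.get("frame", "image"))))
    return out


def _load_pts(path: Path) -> list[LandmarkSet]:
    lines = path.read_text().splitlines()
    coords: list[list[float]] = []
    declared = None
    in_body = False
    for lineno, raw in enumerate(lines, start=1):
        s = raw.strip()
        if not s:
            continue
        low = s.lower()
        if low.startswith("version"):
            continue
        if low.startswith("n_points"):
            try:
                declared = int(s.split(":")[1])
            except (IndexError, ValueError):
                raise LandmarkParseError(f"{path.name}: bad n_points", line=lineno) from None
            continue
        if s == "{":
            in_body = True
            continue
        if s == "}":
            in_body = False
            continue
        if in_body:
            parts = s.split()
            if len(parts) != 2:
                raise LandmarkParseError(f"{path.name}: expected 'x y'", line=lineno)
            try:
                coords.append([float(parts[0]), float(parts[1])])
            except ValueError:
                raise LandmarkParseError(
                    f"{path.name}: non-numeric coordinate", line=lineno
                ) from None
    if declared is not None and declared != len(coords):
        raise SchemaMismatchError(
            f"record {path.name!r}: header declares {declared} points, found {len(coords)}"
        )
    _check_count(len(coords), path.name)
    return [LandmarkSet(np.asarray(coords), source_id=path.stem)]
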