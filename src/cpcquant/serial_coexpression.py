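"""Co-expression counting across adjacent serial sections.

Serial sections of one block carry near-identical anatomy but different
markers; a cell expressing every marker appears at nearly the same physical
position in each section. The procedure: rigidly register the sections,
choose a representative field of fixed area by maximal tissue coverage,
then link centroids across sections by a mutual greedy nearest-neighbor
chain and report the matched count normalized per mm^2.

Point coordinates are (x, y) in microns, x = column * mpp, y = row * mpp.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from skimage.registration import phase_cross_correlation
from skimage.transform import rotate as _rotate_image

from .errors import NoTissueError, ParameterError
from .tissue_detection import TissueMask

DEFAULT_MATCH_RADIUS_UM = 15.0
DEFAULT_FIELD_AREA_MM2 = 4.0


@dataclass(frozen=True)
class CellSet:
    """Marker-positive cell centroids of one section, in microns."""

    section_id: str
    marker: str
    centroids: np.ndarray  # (N, 2) of (x, y) um

    def __post_init__(self) -> None:
        pts = np.asarray(self.centroids, dtype=float).reshape(-1, 2)
        if not np.all(np.isfinite(pts)):
            raise ParameterError("cell centroids must be finite")
        if not self.marker:
            raise ParameterError("marker must be nonempty")
        object.__setattr__(self, "centroids", pts)


@dataclass(frozen=True)
class RigidTransform:
    """p' = R(rotation_deg) @ p + translation_um, rotation about the origin."""

    rotation_deg: float = 0.0
    translation_um: tuple[float, float] = (0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        th = np.radians(self.rotation_deg)
        return np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])

    def apply(self, points_um) -> np.ndarray:
        pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
        return pts @ self.matrix.T + np.asarray(self.translation_um)

    def inverse(self) -> "RigidTransform":
        r_inv = self.matrix.T
        t = -r_inv @ np.asarray(self.translation_um)
        return RigidTransform(-self.rotation_deg, (float(t[0]), float(t[1])))

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self after other: (self . other)(p) = self(other(p))."""
        t = self.matrix @ np.asarray(other.translation_um) + np.asarray(
            self.translation_um
        )
        return RigidTransform(
            self.rotation_deg + other.rotation_deg, (float(t[0]), float(t[1]))
        )

    @classmethod
    def about_point(cls, rotation_deg: float, center_um, shift_um=(0.0, 0.0)):
        """Rotation about ``center_um`` followed by ``shift_um``."""
        c = np.asarray(center_um, dtype=float)
        th = np.radians(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        t = c + np.asarray(shift_um, dtype=float) - rot @ c
        return cls(rotation_deg, (float(t[0]), float(t[1])))


@dataclass(frozen=True)
class Field:
    """Axis-aligned square analysis window, origin at its top-left corner."""

    origin_um: tuple[float, float]
    width_um: float
    height_um: float

    @property
    def area_mm2(self) -> float:
        return self.width_um * self.height_um * 1e-6

    def contains(self, points_um: np.ndarray) -> np.ndarray:
        pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
        ox, oy = self.origin_um
        return (
            (pts[:, 0] >= ox)
            & (pts[:, 0] <= ox + self.width_um)
            & (pts[:, 1] >= oy)
            & (pts[:, 1] <= oy + self.height_um)
        )


@dataclass(frozen=True)
class CoexpressionResult:
    matched_count: int
    field_area_mm2: float
    markers: tuple[str, ...]

    @property
    def density_per_mm2(self) -> float:
        return self.matched_count / self.field_area_mm2


def register_rigid(
    reference: TissueMask,
    moving: TissueMask,
    *,
    rotation_range_deg: float = 10.0,
    rotation_step_deg: float = 0.5,
) -> RigidTransform:
    """Estimate the rigid map from ``moving`` coordinates into ``reference``.

    Exhaustive rotation grid about the moving mask's centroid; at each angle
    the translation comes from phase correlation, and candidates are scored
    by mask overlap. The identity is always a candidate, so the returned
    transform never scores below no alignment at all.
    """
    if reference.tissue_area_px == 0 or moving.tissue_area_px == 0:
        raise NoTissueError("registration requires two nonempty masks")
    if reference.shape != moving.shape:
        raise ParameterError("masks must share a shape for registration")
    ref = reference.mask.astype(float)
    mov = moving.mask.astype(float)
    mpp = moving.mpp
    cr, cc = np.argwhere(moving.mask).mean(axis=0)  # centroid (row, col)

    best = (int((reference.mask & moving.mask).sum()), 0.0, (0.0, 0.0))
    angles = np.arange(-rotation_range_deg, rotation_range_deg + 1e-9, rotation_step_deg)
    for angle in angles:
        # skimage rotates CCW in (x, up-y) display terms == CW in (x, y-down)
        # math terms; passing -angle makes +angle mean R(angle) on (x, y).
        rotated = _rotate_image(mov, -angle, center=(cc, cr), order=0, preserve_range=True)
        shift, _, _ = phase_cross_correlation(
            ref, rotated, upsample_factor=10, normalization=None
        )
        drow, dcol = float(shift[0]), float(shift[1])
        shifted = np.roll(
            np.roll(rotated > 0.5, int(round(drow)), axis=0), int(round(dcol)), axis=1
        )
        score = int((reference.mask & shifted).sum())
        if score > best[0]:
            best = (score, float(angle), (dcol * mpp, drow * mpp))
    _, angle, shift_um = best
    return RigidTransform.about_point(angle, (cc * mpp, cr * mpp), shift_um)


def select_field(
    tissue: TissueMask, field_area_mm2: float = DEFAULT_FIELD_AREA_MM2
) -> Field:
    """Square window of the requested area with maximal tissue coverage.

    Ties resolve to the smallest (row, col) origin, which is what row-major
    argmax over the window-sum image yields.
    """
    if field_area_mm2 <= 0:
        raise ParameterError("field_area_mm2 must be > 0")
    side_px = int(round(np.sqrt(field_area_mm2 * 1e6) / tissue.mpp))
    h, w = tissue.shape
    if side_px < 1 or side_px > h or side_px > w:
        raise ParameterError(
            f"field side {side_px} px does not fit the {h}x{w} image"
        )
    ii = np.pad(np.cumsum(np.cumsum(tissue.mask, axis=0), axis=1), ((1, 0), (1, 0)))
    s = side_px
    cover = ii[s:, s:] - ii[:-s, s:] - ii[s:, :-s] + ii[:-s, :-s]
    row, col = np.unravel_index(np.argmax(cover), cover.shape)
    side_um = side_px * tissue.mpp
    return Field(
        origin_um=(col * tissue.mpp, row * tissue.mpp),
        width_um=side_um,
        height_um=side_um,
    )


def match_and_count(
    cellsets: list[CellSet],
    transforms: list[RigidTransform | None] | None,
    field: Field,
    match_radius_um: float = DEFAULT_MATCH_RADIUS_UM,
) -> CoexpressionResult:
    """Count cells present in every marker's section within the field.

    All non-reference sets are mapped into the reference frame, clipped to
    the field, then chained: a counted cell is one centroid per set with all
    pairwise distances <= ``match_radius_um``. Chains are accepted greedily
    by total intra-chain distance and each centroid is used at most once.
    """
    k = len(cellsets)
    if k < 2:
        raise ParameterError("co-expression needs at least 2 cell sets")
    if match_radius_um <= 0:
        raise ParameterError("match_radius_um must be > 0")
    if transforms is None:
        transforms = [None] * (k - 1)
    if len(transforms) != k - 1:
        raise ParameterError("need one transform per non-reference cell set")

    mapped: list[np.ndarray] = [cellsets[0].centroids]
    for cs, tr in zip(cellsets[1:], transforms):
        mapped.append(cs.centroids if tr is None else tr.apply(cs.centroids))
    clipped = [pts[field.contains(pts)] for pts in mapped]

    candidates: list[tuple[float, tuple[int, ...]]] = []
    trees = [cKDTree(pts) if len(pts) else None for pts in clipped]
    for i0 in range(len(clipped[0])):
        p0 = clipped[0][i0]
        neighbor_lists = []
        ok = True
        for j in range(1, k):
            if trees[j] is None:
                ok = False
                break
            idx = trees[j].query_ball_point(p0, match_radius_um)
            if not idx:
                ok = False
                break
            neighbor_lists.append(sorted(idx))
        if not ok:
            continue
        for combo in itertools.product(*neighbor_lists):
            pts = [p0] + [clipped[j + 1][c] for j, c in enumerate(combo)]
            dists = [
                float(np.hypot(*(pts[a] - pts[b])))
                for a in range(k)
                for b in range(a + 1, k)
            ]
            if max(dists) <= match_radius_um:
                candidates.append((sum(dists), (i0, *combo)))

    candidates.sort(key=lambda c: (c[0], c[1]))
    used: list[set[int]] = [set() for _ in range(k)]
    count = 0
    for _, chain in candidates:
        if any(chain[j] in used[j] for j in range(k)):
            continue
        for j in range(k):
            used[j].add(chain[j])
        count += 1
    return CoexpressionResult(
        matched_count=count,
        field_area_mm2=field.area_mm2,
        markers=tuple(cs.marker for cs in cellsets),
    )


def group_coexpression_summary(
    densities_by_group: dict[str, list[float]],
) -> dict[str, dict[str, float]]:
    """Per-group n, mean, and sample (n-1) standard deviation; n=1 -> sd 0."""
    out: dict[str, dict[str, float]] = {}
    for group, values in densities_by_group.items():
        vals = np.asarray(list(values), dtype=float)
        if vals.size == 0:
            raise ParameterError(f"group {group!r} has no observations")
        sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
        out[group] = {"n": int(vals.size), "mean": float(vals.mean()), "sd": sd}
    return out
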