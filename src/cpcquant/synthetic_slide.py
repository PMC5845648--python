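"""Synthetic slides, serial-section stacks, and cohorts with known truth.

Phantoms are deliberately geometric: a contiguous tissue region (disc or
ellipse) on a bright background, counterstain over all tissue, chromogen
discs for positive signals (isolated or clustered), an optional dark rim
just inside the tissue border emulating edge artifacts, and two-stain
Beer-Lambert mixing back to RGB:  I = (I0 + 1) * 10^(-M c) - 1.

Every generator is a pure function of its spec, including the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi

from .cohort_stats import CohortTable, inverse_logit
from .errors import ParameterError, PlacementError
from .serial_coexpression import CellSet, RigidTransform
from .stain_separation import RGBSlide, StainBasis


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, stain levels, and noise of one synthetic slide."""

    height_px: int = 1024
    width_px: int = 1024
    mpp: float = 0.5
    tissue_shape: str = "disc"  # "disc" | "ellipse"
    tissue_radius_um: float = 220.0
    ellipse_axes_um: tuple[float, float] = (220.0, 145.0)
    ellipse_angle_deg: float = 0.0
    tissue_center_um: tuple[float, float] | None = None  # (x, y); None = center
    n_single_signals: int = 20
    n_cluster_signals: int = 5
    cluster_size: int = 2
    signal_radius_um: float = 7.5
    cluster_spacing_factor: float = 1.8  # disc-center spacing within a cluster, in radii
    min_center_spacing_um: float = 48.0  # between placed entities
    placement_margin_um: float = 40.0  # keep-out from the tissue border
    chromogen_od_level: float = 0.8
    hematoxylin_od_level: float = 0.5
    background_intensity: tuple[float, float, float] = (245.0, 245.0, 245.0)
    noise_sd: float = 3.0
    edge_artifact_width_um: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height_px < 1 or self.width_px < 1:
            raise ParameterError("image dimensions must be positive")
        if self.mpp <= 0:
            raise ParameterError("mpp must be > 0")
        if self.n_single_signals < 0 or self.n_cluster_signals < 0:
            raise ParameterError("signal counts must be >= 0")
        if min(self.chromogen_od_level, self.hematoxylin_od_level) < 0:
            raise ParameterError("stain OD levels must be >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.cluster_size < 2:
            raise ParameterError("cluster_size must be >= 2")


@dataclass(frozen=True)
class GroundTruth:
    """Generator-recorded truth for one phantom."""

    tissue_mask: np.ndarray
    signal_mask: np.ndarray
    records: list[dict]  # {centroid_px, area_px, cluster_flag}
    true_signal_count: int
    true_relative_area: float
    background_intensity: tuple[float, float, float]
    continuous_pixels: np.ndarray = field(repr=False, default=None)
    # noise-free float intensities, for quantization-free round trips


def _tissue_mask(spec: PhantomSpec) -> np.ndarray:
    yy, xx = np.mgrid[: spec.height_px, : spec.width_px]
    x_um, y_um = xx * spec.mpp, yy * spec.mpp
    if spec.tissue_center_um is None:
        cx = spec.width_px * spec.mpp / 2.0
        cy = spec.height_px * spec.mpp / 2.0
    else:
        cx, cy = spec.tissue_center_um
    dx, dy = x_um - cx, y_um - cy
    if spec.tissue_shape == "disc":
        return dx**2 + dy**2 <= spec.tissue_radius_um**2
    if spec.tissue_shape == "ellipse":
        th = np.radians(spec.ellipse_angle_deg)
        u = dx * np.cos(th) + dy * np.sin(th)
        v = -dx * np.sin(th) + dy * np.cos(th)
        ax, ay = spec.ellipse_axes_um
        return (u / ax) ** 2 + (v / ay) ** 2 <= 1.0
    raise ParameterError(f"unknown tissue_shape {spec.tissue_shape!r}")


def _shrink(mask: np.ndarray, radius_px: int) -> np.ndarray:
    """Erosion by a Euclidean disc via the distance transform."""
    if radius_px <= 0 or not mask.any():
        return mask
    return ndi.distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1] > radius_px


def _place_centers(
    region: np.ndarray, n: int, min_spacing_px: float, rng: np.random.Generator
) -> np.ndarray:
    """Rejection-sample n centers inside ``region`` with pairwise spacing."""
    candidates = np.argwhere(region)
    if len(candidates) == 0 and n > 0:
        raise PlacementError("placement region is empty")
    placed: list[np.ndarray] = []
    tries = 0
    budget = max(1000, 2000 * n)
    while len(placed) < n:
        if tries >= budget:
            raise PlacementError(
                f"could not place {n} signals after {budget} attempts"
            )
        tries += 1
        cand = candidates[rng.integers(len(candidates))].astype(float)
        if not placed or np.min(
            np.hypot(*(np.asarray(placed) - cand).T)
        ) >= min_spacing_px:
            placed.append(cand)
    return np.array(placed).reshape(-1, 2)


def _paint_disc(mask: np.ndarray, center_rc: np.ndarray, radius_px: float) -> None:
    h, w = mask.shape
    r0 = max(0, int(center_rc[0] - radius_px - 1))
    r1 = min(h, int(center_rc[0] + radius_px + 2))
    c0 = max(0, int(center_rc[1] - radius_px - 1))
    c1 = min(w, int(center_rc[1] + radius_px + 2))
    yy, xx = np.mgrid[r0:r1, c0:c1]
    mask[r0:r1, c0:c1] |= (yy - center_rc[0]) ** 2 + (
        xx - center_rc[1]
    ) ** 2 <= radius_px**2


def render_rgb(
    hematoxylin: np.ndarray,
    chromogen: np.ndarray,
    background_intensity,
    basis: StainBasis | None = None,
) -> np.ndarray:
    """Beer-Lambert inverse of two concentration maps to float intensities."""
    if basis is None:
        basis = StainBasis.default()
    od = (
        hematoxylin[..., None] * basis.hematoxylin_od
        + chromogen[..., None] * basis.chromogen_od
    )
    i0 = np.asarray(background_intensity, dtype=float)
    return (i0 + 1.0) * 10.0 ** (-od) - 1.0


def generate_slide(spec: PhantomSpec) -> tuple[RGBSlide, GroundTruth]:
    """Render one phantom slide and its ground truth.

    Signal entities (isolated discs and disc clusters) are placed inside the
    tissue, away from the border by ``placement_margin_um`` and from each
    other by ``min_center_spacing_um``; a cluster's discs overlap so it forms
    one connected component and one counted signal.
    """
    rng = np.random.default_rng(spec.seed)
    tissue = _tissue_mask(spec)

    r_sig_px = spec.signal_radius_um / spec.mpp
    margin_px = int(np.ceil((spec.placement_margin_um + spec.signal_radius_um) / spec.mpp))
    region = _shrink(tissue, margin_px)
    n_entities = spec.n_single_signals + spec.n_cluster_signals
    centers = (
        _place_centers(region, n_entities, spec.min_center_spacing_um / spec.mpp, rng)
        if n_entities
        else np.empty((0, 2))
    )

    signal_mask = np.zeros_like(tissue, dtype=bool)
    records: list[dict] = []
    for idx, center in enumerate(centers):
        is_cluster = idx >= spec.n_single_signals
        entity = np.zeros_like(signal_mask)
        _paint_disc(entity, center, r_sig_px)
        if is_cluster:
            angle = rng.uniform(0, 2 * np.pi)
            step = spec.cluster_spacing_factor * r_sig_px
            for m in range(1, spec.cluster_size):
                offset = np.array([np.sin(angle), np.cos(angle)]) * step * m
                _paint_disc(entity, center + offset, r_sig_px)
        signal_mask |= entity
        records.append(
            {
                "centroid_px": tuple(np.argwhere(entity).mean(axis=0)),
                "area_px": int(entity.sum()),
                "cluster_flag": bool(is_cluster),
            }
        )

    edge_px = int(round(spec.edge_artifact_width_um / spec.mpp))
    artifact = np.zeros_like(tissue)
    if edge_px > 0 and tissue.any():
        artifact = tissue & ~_shrink(tissue, edge_px)

    hema = np.where(tissue, spec.hematoxylin_od_level, 0.0)
    chrom = np.where(signal_mask | artifact, spec.chromogen_od_level, 0.0)
    continuous = render_rgb(hema, chrom, spec.background_intensity)
    noisy = continuous
    if spec.noise_sd > 0:
        noisy = continuous + rng.normal(0.0, spec.noise_sd, continuous.shape)
    pixels = np.clip(np.rint(noisy), 0, 255).astype(np.uint8)

    tissue_px = int(tissue.sum())
    rel_area = float((signal_mask & tissue).sum() / tissue_px) if tissue_px else 0.0
    slide = RGBSlide(pixels=pixels, mpp=spec.mpp, slide_id=f"phantom-{spec.seed}")
    truth = GroundTruth(
        tissue_mask=tissue,
        signal_mask=signal_mask,
        records=records,
        true_signal_count=n_entities,
        true_relative_area=rel_area,
        background_intensity=spec.background_intensity,
        continuous_pixels=continuous,
    )
    return slide, truth


@dataclass(frozen=True)
class SerialStack:
    """A registered family of synthetic serial sections."""

    sections: list[tuple[RGBSlide, CellSet]]
    true_transforms: list[RigidTransform]  # section -> reference frame
    true_coexpressing_count: int
    true_centroids_um: np.ndarray  # shared cells, reference frame (x, y)


_STACK_MARKERS = ("CD90", "CD117", "CD105")


def generate_serial_stack(
    spec: PhantomSpec,
    n_sections: int = 2,
    transform_jitter: tuple[float, float] = (5.0, 30.0),
    marker_overlap_fraction: float = 1.0,
    position_jitter_um: float = 2.0,
    n_cells: int | None = None,
) -> SerialStack:
    """Serial sections of one block, each under a recorded rigid transform.

    ``transform_jitter`` is (max |rotation| deg, max |shift| um) drawn
    uniformly per section. A fraction ``marker_overlap_fraction`` of the
    cells appears in every section (with positional jitter); the rest are
    section-private. An elliptical tissue shape is forced so rotation is
    recoverable from the mask. Returns the transforms mapping each section
    into the reference (first-section) frame.
    """
    if n_sections < 2:
        raise ParameterError("a serial stack needs >= 2 sections")
    if not 0.0 <= marker_overlap_fraction <= 1.0:
        raise ParameterError("marker_overlap_fraction must lie in [0, 1]")
    if spec.tissue_shape == "disc":  # rotation of a disc is unobservable
        spec = replace(spec, tissue_shape="ellipse")
    rng = np.random.default_rng(spec.seed)
    n_cells = spec.n_single_signals if n_cells is None else n_cells

    base = replace(spec, n_single_signals=n_cells, n_cluster_signals=0)
    tissue0 = _tissue_mask(base)
    margin_px = int(np.ceil((spec.placement_margin_um + spec.signal_radius_um) / spec.mpp))
    region = _shrink(tissue0, margin_px)
    spacing_px = spec.min_center_spacing_um / spec.mpp

    n_shared = int(round(marker_overlap_fraction * n_cells))
    shared_rc = _place_centers(region, n_shared, spacing_px, rng)
    shared_um = shared_rc[:, ::-1] * spec.mpp  # (x, y)

    cx = spec.width_px * spec.mpp / 2.0
    cy = spec.height_px * spec.mpp / 2.0
    max_rot, max_shift = transform_jitter

    sections: list[tuple[RGBSlide, CellSet]] = []
    to_reference: list[RigidTransform] = []
    for k in range(n_sections):
        if k == 0:
            fwd = RigidTransform()  # reference
        else:
            fwd = RigidTransform.about_point(
                rng.uniform(-max_rot, max_rot),
                (cx, cy),
                (rng.uniform(-max_shift, max_shift), rng.uniform(-max_shift, max_shift)),
            )
        # private cells drawn fresh per section, in the base frame
        n_private = n_cells - n_shared
        private_rc = _place_centers(region, n_private, spacing_px, rng) if n_private else np.empty((0, 2))
        base_pts = np.vstack([shared_um, private_rc[:, ::-1] * spec.mpp])
        jitter = rng.normal(0.0, position_jitter_um, base_pts.shape) if position_jitter_um else 0.0
        pts_k = fwd.apply(base_pts + jitter)

        # rasterize this section: tissue via inverse transform, cells as discs
        inv = fwd.inverse()
        yy, xx = np.mgrid[: spec.height_px, : spec.width_px]
        grid_um = np.stack([xx.ravel() * spec.mpp, yy.ravel() * spec.mpp], axis=1)
        back = inv.apply(grid_um)
        back_cols = back[:, 0] / spec.mpp
        back_rows = back[:, 1] / spec.mpp
        inside = (
            (back_rows >= 0)
            & (back_rows <= spec.height_px - 1)
            & (back_cols >= 0)
            & (back_cols <= spec.width_px - 1)
        )
        tissue_k = np.zeros(spec.height_px * spec.width_px, dtype=bool)
        rr = np.clip(np.rint(back_rows[inside]).astype(int), 0, spec.height_px - 1)
        cc = np.clip(np.rint(back_cols[inside]).astype(int), 0, spec.width_px - 1)
        tissue_k[np.flatnonzero(inside)] = tissue0[rr, cc]
        tissue_k = tissue_k.reshape(spec.height_px, spec.width_px)

        signal_k = np.zeros_like(tissue_k)
        r_sig_px = spec.signal_radius_um / spec.mpp
        for x_um, y_um in pts_k:
            _paint_disc(signal_k, np.array([y_um / spec.mpp, x_um / spec.mpp]), r_sig_px)
        hema = np.where(tissue_k, spec.hematoxylin_od_level, 0.0)
        chrom = np.where(signal_k & tissue_k, spec.chromogen_od_level, 0.0)
        continuous = render_rgb(hema, chrom, spec.background_intensity)
        if spec.noise_sd > 0:
            continuous = continuous + rng.normal(0.0, spec.noise_sd, continuous.shape)
        pixels = np.clip(np.rint(continuous), 0, 255).astype(np.uint8)

        marker = _STACK_MARKERS[k % len(_STACK_MARKERS)]
        slide = RGBSlide(
            pixels=pixels, mpp=spec.mpp, slide_id=f"section-{k}", marker=marker
        )
        cells = CellSet(section_id=f"section-{k}", marker=marker, centroids=pts_k)
        sections.append((slide, cells))
        to_reference.append(inv)

    return SerialStack(
        sections=sections,
        true_transforms=to_reference,
        true_coexpressing_count=n_shared,
        true_centroids_um=shared_um,
    )


def generate_cohort(
    group_sizes: tuple[int, ...],
    baseline_logit_mean: float = -1.0,
    group_effects: tuple[float, ...] | None = None,
    within_sd: float = 1.3,
    seed: int = 0,
    metric_name: str = "synthetic_relative_area",
    group_labels: tuple[str, ...] | None = None,
) -> tuple[CohortTable, dict]:
    """Group-structured (0,1) cohort drawn on the logit scale.

    Values ~ Normal(baseline + effect_g, within_sd) mapped through the
    inverse logit, so effects are directly the quantity the downstream
    analysis tests.
    """
    import pandas as pd

    if any(n < 1 for n in group_sizes):
        raise ParameterError("every group needs at least 1 observation")
    if within_sd <= 0:
        raise ParameterError("within_sd must be > 0")
    k = len(group_sizes)
    if group_effects is None:
        group_effects = tuple(0.0 for _ in group_sizes)
    if len(group_effects) != k:
        raise ParameterError("one effect per group required")
    if group_labels is None:
        from .cohort_stats import GROUPS

        group_labels = GROUPS if k == len(GROUPS) else tuple(f"Group{i+1}" for i in range(k))
    if len(group_labels) != k:
        raise ParameterError("one label per group required")

    rng = np.random.default_rng(seed)
    rows = []
    pid = 0
    for label, size, effect in zip(group_labels, group_sizes, group_effects):
        draws = rng.normal(baseline_logit_mean + effect, within_sd, size)
        for v in draws:
            pid += 1
            rows.append(
                {
                    "patient_id": f"P{pid:03d}",
                    "group": label,
                    "biopsy_location": "synthetic",
                    "metric_name": metric_name,
                    "value": float(inverse_logit(v)),
                }
            )
    truth = {
        "baseline_logit_mean": baseline_logit_mean,
        "group_effects": dict(zip(group_labels, group_effects)),
        "within_sd": within_sd,
        "seed": seed,
    }
    return CohortTable(pd.DataFrame(rows)), truth
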