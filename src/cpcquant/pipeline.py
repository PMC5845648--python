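"""End-to-end orchestration: slide quantification and cohort analysis.

A single config object carries every tunable; precedence is CLI flag over
config file over built-in default. Reports embed a provenance block (config
hash, seed, version) so identical inputs yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .cohort_stats import CohortTable, StatsReport, analyze_cohort, load_cohort_fixture
from .errors import CPCQuantError, FormatError, NoTissueError, ParameterError
from .io import (
    read_slide,
    write_components_csv,
    write_mask,
    write_metrics_csv,
)
from .signal_quantification import (
    CONCAT_AREA_UM2,
    MIN_PEAK_SEPARATION_UM,
    MIN_SIGNAL_AREA_UM2,
    POSITIVITY_OD,
    SlideMetrics,
    detect_signals,
    slide_metrics,
    split_single_concatenated,
)
from .stain_separation import AEC_OD, HEMATOXYLIN_OD, StainBasis, separate_stains
from .tissue_detection import exclude_edge, segment_tissue

log = logging.getLogger("cpcquant")


@dataclass(frozen=True)
class PipelineConfig:
    mpp: float = 0.5
    hematoxylin_od: tuple[float, float, float] = HEMATOXYLIN_OD
    chromogen_od: tuple[float, float, float] = AEC_OD
    positivity_threshold: float = POSITIVITY_OD
    adaptive_threshold: bool = False
    min_signal_area_um2: float = MIN_SIGNAL_AREA_UM2
    concat_area_threshold_um2: float = CONCAT_AREA_UM2
    min_peak_separation_um: float = MIN_PEAK_SEPARATION_UM
    min_tissue_fragment_um2: float = 500.0
    edge_margin_um: float = 20.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mpp <= 0:
            raise ParameterError("mpp must be > 0")
        if not 0 < self.alpha < 1:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.edge_margin_um < 0:
            raise ParameterError("edge_margin_um must be >= 0")
        for name in (
            "positivity_threshold",
            "min_signal_area_um2",
            "concat_area_threshold_um2",
            "min_peak_separation_um",
            "min_tissue_fragment_um2",
        ):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "PipelineConfig":
        return dataclasses.replace(
            self, **{k: v for k, v in overrides.items() if v is not None}
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    @property
    def stain_basis(self) -> StainBasis:
        return StainBasis.from_stains(self.hematoxylin_od, self.chromogen_od)

    def provenance(self) -> dict:
        return {
            "software": "cpcquant",
            "version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "config": self.to_dict(),
        }


def _stage(name: str, slide_id: str):
    """Context manager tagging failures with the slide and pipeline stage."""
    import contextlib

    @contextlib.contextmanager
    def cm():
        t0 = time.perf_counter()
        try:
            yield
        except CPCQuantError as exc:
            exc.args = (f"[slide {slide_id!r}, stage {name}] {exc}",)
            raise
        finally:
            log.info("%s: stage %s took %.2fs", slide_id, name, time.perf_counter() - t0)

    return cm()


def quantify_slide(
    path_or_slide, config: PipelineConfig, out_dir: Path | None = None
) -> SlideMetrics:
    """stain separation -> tissue masking + edge exclusion -> signal metrics.

    Accepts an image path or an in-memory RGBSlide. When ``out_dir`` is given,
    writes the tissue mask (PNG + JSON), the per-component CSV, and a one-row
    metrics CSV.
    """
    from .stain_separation import RGBSlide

    if isinstance(path_or_slide, RGBSlide):
        slide = path_or_slide
    else:
        slide = read_slide(path_or_slide, mpp=config.mpp)

    with _stage("stain_separation", slide.slide_id):
        maps = separate_stains(slide, config.stain_basis)
    with _stage("tissue_detection", slide.slide_id):
        tissue = segment_tissue(
            slide, maps, min_tissue_fragment_um2=config.min_tissue_fragment_um2
        )
        tissue = exclude_edge(tissue, config.edge_margin_um)
        if tissue.tissue_area_px == 0:
            raise NoTissueError("no tissue remains after segmentation and edge exclusion")
    with _stage("signal_quantification", slide.slide_id):
        components = detect_signals(
            maps,
            tissue,
            threshold=config.positivity_threshold,
            min_signal_area_um2=config.min_signal_area_um2,
            adaptive=config.adaptive_threshold,
        )
        components = split_single_concatenated(
            components,
            maps,
            config.mpp,
            concat_area_threshold_um2=config.concat_area_threshold_um2,
            min_peak_separation_um=config.min_peak_separation_um,
        )
        metrics = slide_metrics(
            components, tissue, slide_id=slide.slide_id, marker=slide.marker
        )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        stem = slide.slide_id or "slide"
        write_mask(out_dir / f"{stem}_tissue.png", tissue, slide_id=stem,
                   margin_um=config.edge_margin_um)
        write_components_csv(out_dir / f"{stem}_components.csv", components)
        write_metrics_csv(out_dir / f"{stem}_metrics.csv", [metrics])
    return metrics


def run_cohort_analysis(
    source,
    metric_name: str,
    config: PipelineConfig,
    fixture: str | None = None,
) -> StatsReport:
    """Cohort statistics from a metrics CSV or the packaged fixture.

    ``fixture="table-fixture"`` (any non-empty value) selects the packaged
    23-patient table; otherwise ``source`` is a cohort CSV path.
    """
    if fixture:
        table = load_cohort_fixture()
    else:
        table = CohortTable.from_csv(source)
    if len(table.groups) < 2:
        raise FormatError("cohort analysis needs at least 2 groups")
    report = analyze_cohort(table, metric_name, alpha=config.alpha)
    return dataclasses.replace(report, provenance=config.provenance())


def write_report(report: StatsReport, out_dir: Path, stem: str = "stats") -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / f"{stem}.json").write_text(json.dumps(report.to_dict(), indent=2))
    (out_dir / f"{stem}.txt").write_text(report.to_text() + "\n")
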