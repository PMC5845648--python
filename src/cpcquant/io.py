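"""Readers and writers for the image and report formats the pipeline touches.

8-bit RGB TIFF and PNG in; masks as 0/255 PNG with a JSON sidecar, label
images as 16-bit PNG, per-slide metrics as CSV, and optional per-stain
concentration maps as 32-bit single-channel TIFF.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from .errors import FormatError
from .signal_quantification import SignalComponent, SlideMetrics
from .stain_separation import RGBSlide, StainMaps
from .tissue_detection import TissueMask

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_slide(path, mpp: float, slide_id: str = "", marker: str = "") -> RGBSlide:
    """Load an 8-bit RGB TIFF or PNG; alpha channels are dropped."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such image: {path}")
    try:
        if path.suffix.lower() in _TIFF_SUFFIXES:
            arr = tifffile.imread(path)
        else:
            arr = np.asarray(Image.open(path).convert("RGB"))
    except Exception as exc:  # noqa: BLE001 - wrap any decoder failure
        raise FormatError(f"cannot read {path}: {exc}") from exc
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise FormatError(f"{path} is not an RGB image (shape {arr.shape})")
    if arr.dtype != np.uint8:
        raise FormatError(f"{path} must be 8-bit per channel, got {arr.dtype}")
    return RGBSlide(
        pixels=arr, mpp=mpp, slide_id=slide_id or path.stem, marker=marker
    )


def write_slide(path, slide: RGBSlide) -> None:
    path = Path(path)
    px = np.asarray(slide.pixels)
    if px.dtype != np.uint8:
        px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(path, px)
    else:
        Image.fromarray(px).save(path)


def write_mask(path_png, tissue: TissueMask, slide_id: str = "",
               margin_um: float | None = None) -> None:
    """0/255 PNG plus a JSON sidecar with the area bookkeeping."""
    path_png = Path(path_png)
    Image.fromarray((tissue.mask * 255).astype(np.uint8)).save(path_png)
    sidecar = {
        "slide_id": slide_id,
        "tissue_area_px": tissue.tissue_area_px,
        "tissue_area_mm2": tissue.tissue_area_mm2,
        "margin_um": margin_um,
    }
    path_png.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))


def write_label_image(path_png, labels: np.ndarray) -> None:
    arr = np.asarray(labels)
    if arr.max() > np.iinfo(np.uint16).max:
        raise FormatError("more than 65535 labels do not fit a 16-bit PNG")
    Image.fromarray(arr.astype(np.uint16)).save(path_png)


def write_stain_maps(path_tiff, maps: StainMaps) -> None:
    """Debug output: stains stacked as 32-bit single-channel TIFF pages."""
    stack = np.stack(
        [maps.hematoxylin, maps.chromogen, maps.residual], axis=0
    ).astype(np.float32)
    tifffile.imwrite(path_tiff, stack)


def write_metrics_csv(path, metrics: list[SlideMetrics]) -> None:
    pd.DataFrame([m.to_row() for m in metrics]).to_csv(path, index=False)


def write_components_csv(path, components: list[SignalComponent]) -> None:
    rows = [
        {
            "component_id": c.component_id,
            "area_px": c.area_px,
            "centroid_row": c.centroid[0],
            "centroid_col": c.centroid[1],
            "mean_chromogen": c.mean_chromogen,
            "signal_class": c.signal_class,
        }
        for c in components
    ]
    pd.DataFrame(
        rows,
        columns=[
            "component_id",
            "area_px",
            "centroid_row",
            "centroid_col",
            "mean_chromogen",
            "signal_class",
        ],
    ).to_csv(path, index=False)


def read_cellsets_csv(path):
    """CSV {section_id, marker, x_um, y_um} -> list of CellSet, file order."""
    from .serial_coexpression import CellSet

    df = pd.read_csv(path)
    needed = {"section_id", "marker", "x_um", "y_um"}
    if not needed.issubset(df.columns):
        raise FormatError(f"cell CSV needs columns {sorted(needed)}")
    out = []
    for (sec, marker), sub in df.groupby(["section_id", "marker"], sort=False):
        out.append(
            CellSet(
                section_id=str(sec),
                marker=str(marker),
                centroids=sub[["x_um", "y_um"]].to_numpy(dtype=float),
            )
        )
    return out
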