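"""Raster I/O, intensity preprocessing and result export.

Images are handled as :class:`Image2D` — a float raster in ``[0, 1]`` with a
calibrated pixel size in micrometres.  Label rasters come in two flavours:
:class:`InstanceMap` (one positive integer per object) and
:class:`SemanticMask` (a four-way per-pixel partition into background, axon,
inner tongue and compact myelin).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

logger = logging.getLogger(__name__)

#: Semantic codes: the fixed encoding used across the package.
SEMANTIC_BACKGROUND = 0
SEMANTIC_AXON = 1
SEMANTIC_INNER_TONGUE = 2
SEMANTIC_MYELIN = 3

SEMANTIC_NAMES = {
    SEMANTIC_BACKGROUND: "background",
    SEMANTIC_AXON: "axon",
    SEMANTIC_INNER_TONGUE: "inner_tongue",
    SEMANTIC_MYELIN: "compact_myelin",
}


class ComponentKind(str, Enum):
    """The three object types segmented for every myelinated fibre."""

    INNER_REGION = "inner_region"
    FIBRE = "fibre"
    AXON = "axon"


@dataclass
class Image2D:
    """A single-channel 2-D image with physical pixel calibration.

    Parameters
    ----------
    pixels
        Float array, shape ``(height, width)``.  Normalised images live in
        ``[0, 1]``.
    pixel_size_um
        Edge length of one pixel in micrometres (isotropic).
    """

    pixels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError("Image2D requires a 2-D single-channel array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must have at least one pixel")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]


@dataclass
class SemanticMask:
    """Per-pixel class raster: 0 background, 1 axon, 2 inner tongue, 3 myelin."""

    labels: np.ndarray
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("SemanticMask requires a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("semantic labels must be integers")
        if self.labels.min(initial=0) < 0 or self.labels.max(initial=0) > 3:
            raise ValueError("semantic codes must lie in {0, 1, 2, 3}")


@dataclass
class InstanceMap:
    """Integer label raster for one component kind; 0 is background."""

    labels: np.ndarray
    component_kind: ComponentKind
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("InstanceMap requires a 2-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("instance labels must be integers")
        if self.labels.min(initial=0) < 0:
            raise ValueError("instance labels must be non-negative")
        self.component_kind = ComponentKind(self.component_kind)

    @property
    def object_labels(self) -> np.ndarray:
        """Sorted positive labels present in the raster."""
        labs = np.unique(self.labels)
        return labs[labs > 0]

    def region(self, label: int) -> np.ndarray:
        """Boolean mask of one object."""
        mask = self.labels == label
        if not mask.any():
            raise KeyError(f"label {label} absent from raster")
        return mask


@dataclass
class ProbabilityStack:
    """Per-pixel class probabilities for myelin / axoplasm / membrane-other.

    ``probabilities`` has shape ``(3, height, width)`` and sums to one along
    the channel axis.
    """

    probabilities: np.ndarray
    pixel_size_um: float
    channel_names: tuple = ("myelin", "axoplasm", "membrane")

    def __post_init__(self) -> None:
        self.probabilities = np.asarray(self.probabilities, dtype=np.float64)
        if self.probabilities.ndim != 3 or self.probabilities.shape[0] != len(
            self.channel_names
        ):
            raise ValueError(
                f"expected ({len(self.channel_names)}, H, W) probability array"
            )
        if np.any(self.probabilities < -1e-9) or np.any(self.probabilities > 1 + 1e-9):
            raise ValueError("probabilities must lie in [0, 1]")
        sums = self.probabilities.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("per-pixel probabilities must sum to 1")

    def channel(self, name: str) -> np.ndarray:
        return self.probabilities[self.channel_names.index(name)]

    @property
    def argmax_class(self) -> np.ndarray:
        """Index of the most probable class per pixel (ties: lower channel)."""
        return self.probabilities.argmax(axis=0)


# ---------------------------------------------------------------------------
# loading / preprocessing
# ---------------------------------------------------------------------------

_DTYPE_MAX = {np.uint8: 255.0, np.uint16: 65535.0}


def load_image(path, pixel_size_um: float) -> Image2D:
    """Read an 8/16-bit grayscale TIFF or PNG and scale to ``[0, 1]``.

    Integer intensities are divided by their dtype maximum (255 or 65535);
    float rasters already in ``[0, 1]`` pass through unchanged.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[-1] == 1:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected single-channel grayscale, got shape {arr.shape}"
        )
    if arr.dtype == np.uint8:
        pixels = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        pixels = arr.astype(np.float64) / 65535.0
    elif np.issubdtype(arr.dtype, np.floating):
        pixels = arr.astype(np.float64)
        if pixels.min() < -1e-9 or pixels.max() > 1 + 1e-9:
            raise ValueError(f"{path.name}: float image outside [0, 1]")
    else:
        raise ValueError(f"{path.name}: unsupported dtype {arr.dtype}")
    return Image2D(pixels=pixels, pixel_size_um=pixel_size_um)


def normalise_image(img: Image2D, saturated_fraction: float = 0.01) -> Image2D:
    """Contrast-stretch with a saturated-pixel budget split across both tails.

    With ``n`` pixels and ``k = floor(n * saturated_fraction / 2)``, the
    ``k``-th smallest and ``k``-th largest intensities become the clip bounds,
    so (for distinct values) exactly ``k`` pixels saturate to 0 and ``k`` to 1.
    A constant image maps to all zeros (with a warning) so batch runs proceed.
    """
    if not 0 <= saturated_fraction < 1:
        raise ValueError("saturated_fraction must lie in [0, 1)")
    flat = img.pixels.ravel()
    n = flat.size
    k = int(n * saturated_fraction / 2.0)
    if k > 0:
        part = np.partition(flat, [k - 1, n - k])
        lo, hi = part[k - 1], part[n - k]
    else:
        lo, hi = flat.min(), flat.max()
    if hi <= lo:
        logger.warning("constant image: normalisation returns zeros")
        return Image2D(np.zeros_like(img.pixels), img.pixel_size_um)
    out = np.clip((img.pixels - lo) / (hi - lo), 0.0, 1.0)
    return Image2D(out, img.pixel_size_um)


def downsample_image(img: Image2D, factor: int) -> Image2D:
    """Block-mean downsampling by an integer factor.

    Each output pixel averages a ``factor x factor`` block; the pixel size is
    multiplied by ``factor``.  Trailing rows/columns that do not fill a whole
    block are cropped (with a warning).
    """
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be an integer >= 1")
    factor = int(factor)
    if factor == 1:
        return Image2D(img.pixels.copy(), img.pixel_size_um)
    h, w = img.pixels.shape
    hc, wc = (h // factor) * factor, (w // factor) * factor
    pixels = img.pixels
    if (hc, wc) != (h, w):
        logger.warning("cropping %dx%d to %dx%d for factor %d", h, w, hc, wc, factor)
        pixels = pixels[:hc, :wc]
    out = pixels.reshape(hc // factor, factor, wc // factor, factor).mean(axis=(1, 3))
    return Image2D(out, img.pixel_size_um * factor)


# ---------------------------------------------------------------------------
# label-raster round trips
# ---------------------------------------------------------------------------


def write_instance_map(m: InstanceMap, path) -> None:
    """Write a label raster as 16-bit TIFF (errors if > 65535 labels)."""
    if m.labels.max(initial=0) > 65535:
        raise ValueError("more than 65535 labels cannot be stored as 16-bit")
    tifffile.imwrite(str(path), m.labels.astype(np.uint16))


def read_instance_map(path, component_kind, pixel_size_um: float) -> InstanceMap:
    labels = tifffile.imread(str(path)).astype(np.int64)
    return InstanceMap(labels, ComponentKind(component_kind), pixel_size_um)


def write_semantic_mask(m: SemanticMask, path) -> None:
    tifffile.imwrite(str(path), m.labels.astype(np.uint16))


def read_semantic_mask(path, pixel_size_um: float) -> SemanticMask:
    return SemanticMask(tifffile.imread(str(path)).astype(np.int64), pixel_size_um)


def _region_polygon(mask: np.ndarray):
    """Longest closed contour of a binary region in (x, y) pixel coordinates."""
    from skimage import measure

    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return []
    contour = max(contours, key=len)
    # find_contours yields (row, col); GeoJSON wants x=col, y=row (y down).
    return [[float(c), float(r)] for r, c in contour]


def export_outputs(
    instance_maps: dict,
    semantic: SemanticMask,
    table: pd.DataFrame,
    out_dir,
    stem: str = "image",
    formats=("tiff", "csv", "geojson", "overlay"),
) -> dict:
    """Write label masks, the semantic mask, the results table and QC output.

    ``instance_maps`` maps :class:`ComponentKind` to :class:`InstanceMap`.
    Returns a manifest of written files keyed by artefact name.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    shapes = {m.labels.shape for m in instance_maps.values()} | {semantic.labels.shape}
    if len(shapes) != 1:
        raise ValueError("all rasters must share dimensions")
    manifest = {}
    suffix = {
        ComponentKind.AXON: "axon",
        ComponentKind.INNER_REGION: "inner",
        ComponentKind.FIBRE: "fibre",
    }
    if "tiff" in formats:
        for kind, m in instance_maps.items():
            p = out_dir / f"{stem}_{suffix[ComponentKind(kind)]}.tif"
            write_instance_map(m, p)
            manifest[f"instances_{ComponentKind(kind).value}"] = p
        p = out_dir / f"{stem}_semantic.tif"
        write_semantic_mask(semantic, p)
        manifest["semantic"] = p
    if "csv" in formats:
        p = out_dir / "results.csv"
        table.to_csv(p, index=False)
        manifest["results"] = p
    if "geojson" in formats:
        features = []
        for kind, m in instance_maps.items():
            kind = ComponentKind(kind)
            fibre_ids = {}
            if "fibre_id" in table.columns:
                fibre_ids = {int(f): int(f) for f in table["fibre_id"]}
            for lab in m.object_labels:
                ring = _region_polygon(m.labels == lab)
                if not ring:
                    continue
                features.append(
                    {
                        "type": "Feature",
                        "geometry": {"type": "Polygon", "coordinates": [ring]},
                        "properties": {
                            "component_kind": kind.value,
                            "label": int(lab),
                            "fibre_id": fibre_ids.get(int(lab), int(lab)),
                        },
                    }
                )
        p = out_dir / f"{stem}_rois.geojson"
        p.write_text(json.dumps({"type": "FeatureCollection", "features": features}))
        manifest["geojson"] = p
    if "overlay" in formats:
        from skimage.color import label2rgb

        fibre_map = instance_maps.get(ComponentKind.FIBRE)
        base = semantic.labels if fibre_map is None else fibre_map.labels
        rgb = label2rgb(base, bg_label=0)
        p = out_dir / f"{stem}_overlay.png"
        iio.imwrite(p, (np.clip(rgb, 0, 1) * 255).astype(np.uint8))
        manifest["overlay"] = p
    return manifest
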