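"""Fibre hierarchy construction and per-fibre myelin morphometry.

The three candidate sets (inner regions, fibres, axons) are post-processed
into a consistent fibre -> inner region -> axon hierarchy:

1. inner and fibre regions are reduced to their largest connected component
   (axons may stay composite);
2. containment is enforced by clipping: inner := inner AND fibre,
   axon := axon AND inner — the innermost elements never overflow outward;
3. optionally, an entry lacking an axon duplicates its inner region as the
   axon (flagged), modelling a shrunken inner tongue;
4. axons attach to the inner region of maximal pixel overlap.

Morphometry follows the circle-equivalent convention: diameters are those of
circles with the measured areas, so the myelin g-ratio is
``sqrt(area_inner / area_fibre)`` and the axon g-ratio
``sqrt(area_axon / area_fibre)``.  Their difference (the tongue index) is 0
when the inner tongue is absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure

from .io import (
    SEMANTIC_AXON,
    SEMANTIC_INNER_TONGUE,
    SEMANTIC_MYELIN,
    ComponentKind,
    InstanceMap,
    SemanticMask,
)
from .stages import RoiCandidate, selected

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class FibreEntry:
    fibre_id: int
    fibre_mask: np.ndarray
    inner_mask: np.ndarray
    axon_mask: np.ndarray | None
    axon_duplicated: bool
    border_flag: bool


@dataclass
class FibreHierarchy:
    """Consistent per-fibre containment hierarchy; the unit of morphometry."""

    entries: list
    pixel_size_um: float
    shape: tuple

    def __post_init__(self):
        ids = [e.fibre_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("fibre ids must be unique")

    def instance_maps(self) -> dict:
        """Rasterise the hierarchy back into one InstanceMap per component."""
        out = {}
        for kind, attr in (
            (ComponentKind.FIBRE, "fibre_mask"),
            (ComponentKind.INNER_REGION, "inner_mask"),
            (ComponentKind.AXON, "axon_mask"),
        ):
            labels = np.zeros(self.shape, dtype=np.int64)
            for e in self.entries:
                mask = getattr(e, attr)
                if mask is not None:
                    labels[mask] = e.fibre_id
            out[kind] = InstanceMap(labels, kind, self.pixel_size_um)
        return out


def _largest_component(mask: np.ndarray) -> np.ndarray:
    lab, n = ndi.label(mask, structure=_EIGHT)
    if n <= 1:
        return mask
    counts = np.bincount(lab.ravel())
    counts[0] = 0
    return lab == counts.argmax()


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any())


def build_hierarchy(
    inner_candidates,
    fibres: InstanceMap,
    axon_candidates,
    duplicate_inner_as_axon: bool = True,
) -> FibreHierarchy:
    """Assemble the fibre -> inner -> axon hierarchy from one image's candidates."""
    shape = fibres.labels.shape
    inner_sel = selected(inner_candidates)
    axon_sel = selected(axon_candidates)

    entries = []
    inner_by_label = {}
    for fid in fibres.object_labels:
        fid = int(fid)
        fibre_mask = _largest_component(fibres.labels == fid)
        # inner region attached by maximal overlap with this fibre
        best, best_ov = None, 0
        for c in sorted(inner_sel, key=lambda c: c.label):
            ov = int((c.mask & fibre_mask).sum())
            if ov > best_ov:
                best, best_ov = c, ov
        if best is None:
            logger.warning("fibre %d has no inner region; dropped", fid)
            continue
        inner_mask = _largest_component(best.mask) & fibre_mask
        if not inner_mask.any():
            logger.warning("fibre %d: inner region empties under clipping; dropped", fid)
            continue
        entries.append(
            FibreEntry(fid, fibre_mask, inner_mask, None, False, _touches_border(fibre_mask))
        )
        inner_by_label[fid] = inner_mask

    # axon -> inner assignment by maximal pixel overlap (tie: lower fibre id)
    for c in sorted(axon_sel, key=lambda c: c.label):
        best_fid, best_ov = None, 0
        for e in entries:
            ov = int((c.mask & e.inner_mask).sum())
            if ov > best_ov or (ov == best_ov and ov > 0 and best_fid is not None and e.fibre_id < best_fid):
                best_fid, best_ov = e.fibre_id, ov
        if best_fid is None:
            continue
        entry = next(e for e in entries if e.fibre_id == best_fid)
        clipped = c.mask & entry.inner_mask
        if not clipped.any():
            logger.warning("axon %d empties under clipping; dropped", c.label)
            continue
        if entry.axon_mask is None or clipped.sum() > entry.axon_mask.sum():
            entry.axon_mask = clipped

    if duplicate_inner_as_axon:
        for e in entries:
            if e.axon_mask is None:
                e.axon_mask = e.inner_mask.copy()
                e.axon_duplicated = True

    return FibreHierarchy(entries, fibres.pixel_size_um, shape)


def circle_equivalent_diameter(area_um2: float) -> float:
    """Diameter of the circle with the given area: ``2 * sqrt(area / pi)``."""
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    return 2.0 * np.sqrt(area_um2 / np.pi)


def _eccentricity(mask: np.ndarray) -> float:
    props = measure.regionprops(mask.astype(np.uint8))
    return float(props[0].eccentricity) if props else 0.0


def measure_fibres(h: FibreHierarchy) -> pd.DataFrame:
    """Per-fibre areas, circle-equivalent diameters, g-ratios and shape.

    One row per fibre id.  Areas are pixel counts times ``pixel_size_um**2``;
    entries without an axon (duplication off) report NaN axon metrics.
    """
    px2 = h.pixel_size_um**2
    rows = []
    for e in h.entries:
        area_fibre = float(e.fibre_mask.sum()) * px2
        area_inner = float(e.inner_mask.sum()) * px2
        if area_fibre == 0:
            raise ValueError(f"fibre {e.fibre_id} has zero area")
        has_axon = e.axon_mask is not None
        area_axon = float(e.axon_mask.sum()) * px2 if has_axon else np.nan
        d_fibre = circle_equivalent_diameter(area_fibre)
        d_inner = circle_equivalent_diameter(area_inner)
        d_axon = circle_equivalent_diameter(area_axon) if has_axon else np.nan
        g_myelin = d_inner / d_fibre
        g_axon = d_axon / d_fibre if has_axon else np.nan
        rows.append(
            {
                "fibre_id": e.fibre_id,
                "area_axon_um2": area_axon,
                "area_inner_um2": area_inner,
                "area_fibre_um2": area_fibre,
                "area_inner_tongue_um2": area_inner - area_axon if has_axon else np.nan,
                "area_myelin_um2": area_fibre - area_inner,
                "d_axon_um": d_axon,
                "d_inner_um": d_inner,
                "d_fibre_um": d_fibre,
                "g_myelin": g_myelin,
                "g_axon": g_axon,
                "tongue_index": g_myelin - g_axon if has_axon else np.nan,
                "eccentricity_fibre": _eccentricity(e.fibre_mask),
                "axon_duplicated": e.axon_duplicated,
                "border_flag": e.border_flag,
            }
        )
    columns = [
        "fibre_id", "area_axon_um2", "area_inner_um2", "area_fibre_um2",
        "area_inner_tongue_um2", "area_myelin_um2", "d_axon_um", "d_inner_um",
        "d_fibre_um", "g_myelin", "g_axon", "tongue_index",
        "eccentricity_fibre", "axon_duplicated", "border_flag",
    ]
    return pd.DataFrame(rows, columns=columns)


def semantic_from_hierarchy(h: FibreHierarchy, shape=None) -> SemanticMask:
    """Partition each fibre into axon / inner tongue / compact myelin codes."""
    shape = shape or h.shape
    labels = np.zeros(shape, dtype=np.int64)
    for e in h.entries:
        labels[e.fibre_mask] = SEMANTIC_MYELIN
        labels[e.inner_mask] = SEMANTIC_INNER_TONGUE
        if e.axon_mask is not None:
            labels[e.axon_mask] = SEMANTIC_AXON
        else:
            labels[e.inner_mask] = SEMANTIC_INNER_TONGUE
    return SemanticMask(labels, h.pixel_size_um)
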