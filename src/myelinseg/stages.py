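"""The three-stage segmentation of myelinated fibre cross-sections.

Stage 1 detects inner regions (axon + inner tongue) as the holes of the
myelin mask; components that look like background (border-touching, out of
the size window, or with low mean axoplasm probability) are kept as
*rejected* candidates rather than dropped, so a batch curation file can
recover them.  Stage 2 expands the selected inner regions as seeds through
the myelin mask — a marker-controlled flooding with uniform cost, i.e. each
myelin pixel joins the geodesically nearest seed (8-connectivity, ties to
the lower label).  Stage 3 keeps classified axon objects that lie mostly
inside a single inner region; inner-tongue objects are retained as rejected
candidates, and objects outside myelinated fibres are eliminated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage as ndi
from shapely.geometry import Polygon
from skimage import morphology

from .classifiers import ObjectClass
from .io import ComponentKind, InstanceMap, ProbabilityStack

logger = logging.getLogger(__name__)

_EIGHT = np.ones((3, 3), dtype=int)
_SHIFTS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


class Stage(str, Enum):
    INNER_REGION = "inner_region"
    FIBRE = "fibre"
    AXON = "axon"


class CandidateState(str, Enum):
    SELECTED = "selected"
    REJECTED = "rejected"


@dataclass
class RoiCandidate:
    """One candidate region with its selection state."""

    label: int
    mask: np.ndarray
    stage: Stage
    state: CandidateState
    fibre_id: int | None = None
    predicted_class: ObjectClass | None = None

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if not self.mask.any():
            raise ValueError("candidate pixel set must be non-empty")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


def selected(candidates) -> list:
    return [c for c in candidates if c.state is CandidateState.SELECTED]


def candidates_to_map(
    candidates, kind: ComponentKind, shape, pixel_size_um: float
) -> InstanceMap:
    """Rasterise selected candidates into a label map (later labels overwrite)."""
    labels = np.zeros(shape, dtype=np.int64)
    for c in selected(candidates):
        labels[c.mask] = c.label
    return InstanceMap(labels, kind, pixel_size_um)


# ---------------------------------------------------------------------------
# Stage 1 — inner regions
# ---------------------------------------------------------------------------


def myelin_mask_from_probabilities(
    prob: ProbabilityStack, close_radius: int = 1
) -> np.ndarray:
    """Binarise myelin by per-pixel argmax, optionally closed to seal small gaps."""
    mask = prob.argmax_class == 0
    if close_radius > 0:
        mask = morphology.closing(mask, morphology.disk(close_radius))
    return mask


def stage1_inner_regions(
    prob: ProbabilityStack,
    min_area_px: int = 50,
    max_area_fraction: float = 0.05,
    axoplasm_gate: float = 0.4,
    close_radius: int = 1,
) -> list:
    """Detect inner-region candidates from the myelin probability channel.

    Every connected component of the inverted myelin mask becomes a
    candidate; it is *selected* iff it does not touch the image border, its
    area lies within ``[min_area_px, max_area_fraction * image area]`` and
    its mean axoplasm probability is at least ``axoplasm_gate``.  Nothing is
    silently dropped: failing components are kept as *rejected*.
    """
    myelin = myelin_mask_from_probabilities(prob, close_radius)
    inverted = ~myelin
    # holes are 4-connected (the topological dual of 8-connected myelin), so
    # a diagonally connected ring still seals its inner region
    lab, n = ndi.label(inverted)
    axo = prob.channel("axoplasm")
    h, w = lab.shape
    max_area = max_area_fraction * h * w
    out = []
    border = np.zeros_like(lab, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    border_labels = set(np.unique(lab[border])) - {0}
    counts = np.bincount(lab.ravel())
    sums = ndi.sum_labels(axo, lab, index=np.arange(1, n + 1))
    for l in range(1, n + 1):
        area = counts[l]
        mean_axo = sums[l - 1] / area
        ok = (
            l not in border_labels
            and min_area_px <= area <= max_area
            and mean_axo >= axoplasm_gate
        )
        out.append(
            RoiCandidate(
                label=l,
                mask=lab == l,
                stage=Stage.INNER_REGION,
                state=CandidateState.SELECTED if ok else CandidateState.REJECTED,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Stage 2 — fibre expansion
# ---------------------------------------------------------------------------


def geodesic_label_expansion(seeds: np.ndarray, domain: np.ndarray) -> np.ndarray:
    """Multi-source geodesic flooding over ``domain`` (uniform cost).

    Level-synchronous BFS with 8-connectivity: at each step every unlabelled
    domain pixel adjacent to the current frontier takes the minimum positive
    label among its frontier neighbours.  This assigns each reachable pixel
    to the seed with the smallest geodesic distance, ties going to the lower
    seed label.  Unreachable domain pixels stay 0.
    """
    labels = np.asarray(seeds, dtype=np.int64).copy()
    domain = np.asarray(domain, dtype=bool) | (labels > 0)
    big = np.iinfo(np.int64).max
    while True:
        frontier = np.where(labels > 0, labels, big)
        best = np.full_like(labels, big)
        for dr, dc in _SHIFTS:
            shifted = np.full_like(frontier, big)
            src = frontier[
                max(0, -dr) : frontier.shape[0] - max(0, dr),
                max(0, -dc) : frontier.shape[1] - max(0, dc),
            ]
            shifted[
                max(0, dr) : frontier.shape[0] - max(0, -dr),
                max(0, dc) : frontier.shape[1] - max(0, -dc),
            ] = src
            best = np.minimum(best, shifted)
        new = (labels == 0) & domain & (best < big)
        if not new.any():
            break
        labels[new] = best[new]
    return labels


def stage2_fibres(
    inner_candidates, myelin_mask: np.ndarray, pixel_size_um: float
) -> InstanceMap:
    """Expand selected inner regions through the myelin mask to get fibres.

    Each fibre is its seed inner region plus the myelin territory
    geodesically nearest to that seed.  Myelin unreachable from any seed
    stays background — so a missed inner region leaves its ring unclaimed or
    lets neighbouring seeds absorb adjacent myelin.
    """
    sel = selected(inner_candidates)
    shape = myelin_mask.shape
    seeds = np.zeros(shape, dtype=np.int64)
    for c in sel:
        seeds[c.mask] = c.label
    if not sel:
        return InstanceMap(seeds, ComponentKind.FIBRE, pixel_size_um)
    domain = np.asarray(myelin_mask, dtype=bool) & (seeds == 0)
    labels = geodesic_label_expansion(seeds, domain)
    return InstanceMap(labels, ComponentKind.FIBRE, pixel_size_um)


# ---------------------------------------------------------------------------
# Stage 3 — axon selection
# ---------------------------------------------------------------------------


def stage3_axons(
    candidates: InstanceMap,
    classified,  # DataFrame with columns label, predicted_class
    inner_map: InstanceMap,
    overlap_fraction: float = 0.5,
) -> list:
    """Select axon objects inside myelinated fibres.

    An object predicted as an axon is *selected* iff at least
    ``overlap_fraction`` of its area lies inside one single inner region; it
    is then assigned that region's fibre id.  Inner-tongue objects become
    *rejected* candidates (recoverable by curation).  Objects overlapping no
    inner region are eliminated.  If several axons land in one inner region
    only the largest stays selected.
    """
    class_by_label = {
        int(r["label"]): ObjectClass(r["predicted_class"])
        for _, r in classified.iterrows()
    }
    out = []
    by_fibre: dict = {}
    for lab in candidates.object_labels:
        mask = candidates.labels == lab
        cls = class_by_label.get(int(lab), ObjectClass.UNASSIGNED)
        overlap = inner_map.labels[mask]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            continue  # outside myelinated fibres: eliminated
        counts = np.bincount(overlap)
        best_inner = int(counts.argmax())
        frac = counts.max() / mask.sum()
        if cls is ObjectClass.INNER_TONGUE:
            out.append(
                RoiCandidate(lab, mask, Stage.AXON, CandidateState.REJECTED, best_inner)
            )
            continue
        if cls is ObjectClass.UNASSIGNED:
            continue  # unannotated object kinds: predictions ignored
        if frac >= overlap_fraction:
            c = RoiCandidate(lab, mask, Stage.AXON, CandidateState.SELECTED, best_inner)
            prev = by_fibre.get(best_inner)
            if prev is not None:
                loser = prev if prev.area_px < c.area_px else c
                winner = c if loser is prev else prev
                loser.state = CandidateState.REJECTED
                by_fibre[best_inner] = winner
                out.append(c)
            else:
                by_fibre[best_inner] = c
                out.append(c)
        # below the overlap gate: dropped entirely
    return out


# ---------------------------------------------------------------------------
# batch curation
# ---------------------------------------------------------------------------


@dataclass
class CurationOverride:
    """Batch replacement for interactive ROI editing.

    ``accept_labels`` / ``reject_labels`` toggle existing candidates;
    ``added_polygons`` are closed pixel-coordinate rings rasterised as new
    selected candidates.
    """

    accept_labels: tuple = ()
    reject_labels: tuple = ()
    added_polygons: tuple = ()

    def __post_init__(self):
        if set(self.accept_labels) & set(self.reject_labels):
            raise ValueError("accept and reject lists must be disjoint")

    @classmethod
    def from_json(cls, path, stage_key: str) -> "CurationOverride":
        data = json.loads(Path(path).read_text())
        entry = data.get(stage_key, {})
        return cls(
            accept_labels=tuple(entry.get("accept", ())),
            reject_labels=tuple(entry.get("reject", ())),
            added_polygons=tuple(tuple(map(tuple, p)) for p in entry.get("add", ())),
        )


def rasterise_polygon(vertices, shape) -> np.ndarray:
    """Even-odd fill of a closed polygon over pixel centres.

    ``vertices`` are (x, y) pixel coordinates with y increasing downward.
    Rejects polygons with fewer than three vertices or self-intersections.
    """
    verts = [(float(x), float(y)) for x, y in vertices]
    if len(verts) < 3:
        raise ValueError("polygon needs at least 3 vertices")
    if not Polygon(verts).is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    ring = verts + [verts[0]]
    codes = [MplPath.MOVETO] + [MplPath.LINETO] * (len(verts) - 1) + [MplPath.CLOSEPOLY]
    path = MplPath(ring, codes)
    h, w = shape
    cols, rows = np.meshgrid(np.arange(w), np.arange(h))
    pts = np.column_stack([cols.ravel().astype(float), rows.ravel().astype(float)])
    inside = path.contains_points(pts)
    return inside.reshape(h, w)


def apply_curation(candidates, override: CurationOverride, shape) -> list:
    """Toggle listed candidates and rasterise added polygons as new ROIs."""
    out = []
    known = set()
    for c in candidates:
        known.add(c.label)
        state = c.state
        if c.label in override.accept_labels:
            state = CandidateState.SELECTED
        elif c.label in override.reject_labels:
            state = CandidateState.REJECTED
        out.append(RoiCandidate(c.label, c.mask, c.stage, state, c.fibre_id, c.predicted_class))
    for lab in set(override.accept_labels) | set(override.reject_labels):
        if lab not in known:
            logger.warning("curation references unknown label %d", lab)
    next_label = max(known, default=0) + 1
    stage = candidates[0].stage if candidates else Stage.INNER_REGION
    for poly in override.added_polygons:
        mask = rasterise_polygon(poly, shape)
        if not mask.any():
            logger.warning("added polygon rasterises to an empty region; skipped")
            continue
        out.append(RoiCandidate(next_label, mask, stage, CandidateState.SELECTED))
        next_label += 1
    return out


# ---------------------------------------------------------------------------
# axon correction
# ---------------------------------------------------------------------------


class AxonCorrection(str, Enum):
    NONE = "none"
    FILL_HOLES = "fill_holes"
    CONVEX_HULL = "convex_hull"
    CLOSING = "closing_r"


def correct_axon(
    candidate: RoiCandidate,
    method: AxonCorrection | str = AxonCorrection.FILL_HOLES,
    closing_radius: int = 2,
) -> RoiCandidate:
    """Morphological repair of a predicted axon region (area never decreases)."""
    if candidate.stage is not Stage.AXON:
        raise ValueError("axon correction applies to stage-3 candidates only")
    method = AxonCorrection(method)
    mask = candidate.mask
    if method is AxonCorrection.NONE:
        fixed = mask
    elif method is AxonCorrection.FILL_HOLES:
        fixed = ndi.binary_fill_holes(mask)
    elif method is AxonCorrection.CONVEX_HULL:
        fixed = morphology.convex_hull_image(mask)
    elif method is AxonCorrection.CLOSING:
        fixed = morphology.closing(mask, morphology.disk(closing_radius)) | mask
    return RoiCandidate(
        candidate.label, fixed, candidate.stage, candidate.state,
        candidate.fibre_id, candidate.predicted_class,
    )
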