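"""TEM-like phantoms of myelinated-fibre cross-sections with exact truth.

Each myelinated fibre is a nest of three similar ellipses: the axon, the
inner region (axon scaled so that ``inner area = axon area / (1 - tongue
fraction)``, with the axon offset to internal tangency along the major axis
so the tongue is a simply connected crescent) and the fibre (inner region
scaled by ``1/g`` so that ``sqrt(inner/fibre) = g``, the target myelin
g-ratio).  Intensities emulate TEM contrast of corpus callosum tissue: a
dark compact-myelin ring, lighter axoplasm, an intermediate inner tongue, a
1-px darker membrane line at the axon boundary, occasional dark mitochondria
inside axons, and unmyelinated axons (painted, but absent from the ground
truth — they exercise the "only myelinated axons" gate).  The analytic
truth table records per-fibre areas and g-ratios from the generating
geometry, not from the rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import (
    SEMANTIC_AXON,
    SEMANTIC_INNER_TONGUE,
    SEMANTIC_MYELIN,
    ComponentKind,
    Image2D,
    InstanceMap,
    ProbabilityStack,
    SemanticMask,
)

DEFAULT_INTENSITIES = {
    "extracellular": 0.80,
    "axoplasm": 0.75,
    "tongue": 0.65,
    "membrane": 0.35,
    "myelin": 0.15,
    "mitochondria": 0.25,
}


@dataclass
class PhantomSpec:
    """Study conditions for one phantom image.

    Distribution parameters: ``axon_radius_px`` is lognormal ``(mu, sigma)``
    of the circle-equivalent axon radius, clipped to ``axon_radius_clip``;
    ``target_g_myelin`` is a truncated normal ``(mean, sd, lo, hi)``;
    ``tongue_fraction`` is beta ``(a, b)`` — the fraction of the inner-region
    area occupied by the tongue crescent (0 = shrunken tongue).
    """

    image_size_px: int = 512
    pixel_size_um: float = 8.4182e-3
    n_fibres: int = 30
    axon_radius_px: tuple = (2.30, 0.25)  # lognormal mu, sigma (median ~10 px)
    axon_radius_clip: tuple = (7.0, 26.0)
    target_g_myelin: tuple = (0.72, 0.07, 0.55, 0.85)
    tongue_fraction: tuple = (2.0, 8.0)
    p_unmyelinated: float = 0.2
    p_mitochondria: float = 0.3
    intensity_levels: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    noise_sd: float = 0.05
    blur_sigma_px: float = 0.7
    seed: int = 0

    def __post_init__(self):
        m, sd, lo, hi = self.target_g_myelin
        if not (0 < lo < hi < 1):
            raise ValueError("g-ratio bounds must satisfy 0 < lo < hi < 1")
        a, b = self.tongue_fraction
        if a <= 0 or b <= 0:
            raise ValueError("tongue_fraction beta parameters must be positive")
        for p in (self.p_unmyelinated, self.p_mitochondria):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        bad = [k for k, v in self.intensity_levels.items() if not 0 <= v <= 1]
        if bad:
            raise ValueError(f"intensity levels outside [0, 1]: {bad}")


@dataclass
class PhantomOutput:
    image: Image2D
    gt_axon: InstanceMap
    gt_inner: InstanceMap
    gt_fibre: InstanceMap
    gt_semantic: SemanticMask
    truth_table: pd.DataFrame
    ideal_probs: ProbabilityStack
    membrane_mask: np.ndarray
    mitochondria_mask: np.ndarray


def _ellipse_mask(shape, center, semi_axes, theta) -> np.ndarray:
    """Pixel-centre rasterisation of a rotated ellipse."""
    h, w = shape
    rr, cc = np.mgrid[0:h, 0:w]
    dy = rr - center[0]
    dx = cc - center[1]
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    a, b = semi_axes
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _truncated_normal(rng, mean, sd, lo, hi):
    while True:
        v = rng.normal(mean, sd)
        if lo <= v <= hi:
            return v


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate one phantom with exact instance/semantic ground truth."""
    rng = np.random.default_rng(spec.seed)
    n = spec.image_size_px
    shape = (n, n)
    levels = spec.intensity_levels

    image = np.full(shape, levels["extracellular"], dtype=np.float64)
    gt_axon = np.zeros(shape, dtype=np.int64)
    gt_inner = np.zeros(shape, dtype=np.int64)
    gt_fibre = np.zeros(shape, dtype=np.int64)
    membrane_mask = np.zeros(shape, dtype=bool)
    mito_mask = np.zeros(shape, dtype=bool)
    occupancy = np.zeros(shape, dtype=bool)

    rows = []
    fid = 0
    n_unmyelinated = rng.binomial(spec.n_fibres, spec.p_unmyelinated)

    def place(bound_radius, paint):
        """Rejection-sample a centre; paint on success, return True/False."""
        margin = bound_radius + 4.0
        if 2 * margin >= n:
            return False
        for _ in range(60):
            cy = rng.uniform(margin, n - margin)
            cx = rng.uniform(margin, n - margin)
            footprint = paint((cy, cx), dry_run=True)
            dilated = ndi.binary_dilation(footprint, iterations=3)
            if not (dilated & occupancy).any():
                paint((cy, cx), dry_run=False)
                occupancy[footprint] = True
                return True
        return False

    for _ in range(spec.n_fibres):
        r = float(np.clip(rng.lognormal(*spec.axon_radius_px), *spec.axon_radius_clip))
        q = rng.uniform(1.0, 2.0)  # axis ratio
        a, b = r * np.sqrt(q), r / np.sqrt(q)
        theta = rng.uniform(0, np.pi)
        g = _truncated_normal(rng, *spec.target_g_myelin)
        tf = float(rng.beta(*spec.tongue_fraction))
        s = 1.0 / np.sqrt(1.0 - tf)  # inner = axon scaled by s
        fa, fb = s * a / g, s * b / g  # fibre semi-axes
        delta = (s - 1.0) * a  # axon offset to tangency along major axis
        n_mito = int(rng.random() < spec.p_mitochondria) * rng.integers(1, 3)
        mito_params = [
            (rng.uniform(0.12, 0.2) * r, rng.uniform(0, np.pi), rng.uniform(0, 2 * np.pi),
             rng.uniform(0.2, 0.55))
            for _ in range(n_mito)
        ]

        def paint_fibre(center, dry_run):
            cy, cx = center
            off = (delta * np.sin(theta), delta * np.cos(theta))  # (dy, dx)
            fibre = _ellipse_mask(shape, (cy, cx), (fa, fb), theta)
            if dry_run:
                return fibre
            inner = _ellipse_mask(shape, (cy, cx), (s * a, s * b), theta)
            axon = _ellipse_mask(shape, (cy + off[0], cx + off[1]), (a, b), theta)
            axon &= inner
            boundary = axon & ~ndi.binary_erosion(axon)
            image[fibre] = levels["myelin"]
            image[inner] = levels["tongue"]
            image[axon] = levels["axoplasm"]
            image[boundary] = levels["membrane"]
            for mr, mth, mang, mrad in mito_params:
                mc = (cy + off[0] + mrad * b * np.sin(mang),
                      cx + off[1] + mrad * b * np.cos(mang))
                mito = _ellipse_mask(shape, mc, (mr * 1.4, mr), mth) & axon
                image[mito] = levels["mitochondria"]
                mito_mask[mito] = True
            nonlocal fid
            fibre_id = fid + 1
            gt_fibre[fibre] = fibre_id
            gt_inner[inner] = fibre_id
            gt_axon[axon] = fibre_id
            membrane_mask[boundary] = True
            area_axon = np.pi * a * b
            rows.append(
                {
                    "fibre_id": fibre_id,
                    "axon_area_px2": area_axon,
                    "inner_area_px2": area_axon * s**2,
                    "fibre_area_px2": area_axon * s**2 / g**2,
                    "tongue_area_px2": area_axon * (s**2 - 1.0),
                    "g_myelin": g,
                    "g_axon": g * np.sqrt(1.0 - tf),
                    "tongue_fraction": tf,
                    "axis_ratio": q,
                    "centre_row": cy,
                    "centre_col": cx,
                }
            )
            return fibre

        if place(max(fa, fb), paint_fibre):
            fid += 1

    for _ in range(n_unmyelinated):
        r = float(np.clip(rng.lognormal(*spec.axon_radius_px), *spec.axon_radius_clip))
        q = rng.uniform(1.0, 2.0)
        a, b = r * np.sqrt(q), r / np.sqrt(q)
        theta = rng.uniform(0, np.pi)

        def paint_unmyelinated(center, dry_run):
            axon = _ellipse_mask(shape, center, (a, b), theta)
            if dry_run:
                return axon
            boundary = axon & ~ndi.binary_erosion(axon)
            image[axon] = levels["axoplasm"]
            image[boundary] = levels["membrane"]
            membrane_mask[boundary] = True
            return axon

        place(max(a, b), paint_unmyelinated)

    semantic = np.zeros(shape, dtype=np.int64)
    semantic[gt_fibre > 0] = SEMANTIC_MYELIN
    semantic[gt_inner > 0] = SEMANTIC_INNER_TONGUE
    semantic[gt_axon > 0] = SEMANTIC_AXON
    gt_semantic = SemanticMask(semantic, spec.pixel_size_um)

    if spec.blur_sigma_px > 0:
        image = ndi.gaussian_filter(image, spec.blur_sigma_px)
    if spec.noise_sd > 0:
        image = image + rng.normal(0.0, spec.noise_sd, shape)
    image = np.clip(image, 0.0, 1.0)

    px2 = spec.pixel_size_um**2
    truth = pd.DataFrame(rows)
    if not truth.empty:
        for c in ("axon_area", "inner_area", "fibre_area", "tongue_area"):
            truth[f"{c}_um2"] = truth[f"{c}_px2"] * px2
    # softness 0.5 keeps the thinnest myelin rings argmax-dominant while
    # still exercising non-degenerate probabilities
    ideal = ideal_probabilities(gt_semantic, softness_sigma_px=0.5)
    return PhantomOutput(
        image=Image2D(image, spec.pixel_size_um),
        gt_axon=InstanceMap(gt_axon, ComponentKind.AXON, spec.pixel_size_um),
        gt_inner=InstanceMap(gt_inner, ComponentKind.INNER_REGION, spec.pixel_size_um),
        gt_fibre=InstanceMap(gt_fibre, ComponentKind.FIBRE, spec.pixel_size_um),
        gt_semantic=gt_semantic,
        truth_table=truth,
        ideal_probs=ideal,
        membrane_mask=membrane_mask,
        mitochondria_mask=mito_mask,
    )


def ideal_probabilities(
    semantic: SemanticMask, softness_sigma_px: float = 1.0
) -> ProbabilityStack:
    """Noise-free probability stack from a semantic mask.

    One-hot channels — myelin; axoplasm (axon + tongue); membrane/other
    (background plus the 1-px axon boundary, i.e. the pixels at the axon's
    class boundary) — optionally blurred and renormalised per pixel.
    """
    lab = semantic.labels
    myelin = lab == SEMANTIC_MYELIN
    axoplasm = (lab == SEMANTIC_AXON) | (lab == SEMANTIC_INNER_TONGUE)
    axon = lab == SEMANTIC_AXON
    boundary = axon & ~ndi.binary_erosion(axon)
    axoplasm = axoplasm & ~boundary
    other = ~(myelin | axoplasm)
    stack = np.stack([m.astype(np.float64) for m in (myelin, axoplasm, other)])
    if softness_sigma_px > 0:
        stack = np.stack([ndi.gaussian_filter(c, softness_sigma_px) for c in stack])
        stack /= stack.sum(axis=0, keepdims=True)
    return ProbabilityStack(stack, semantic.pixel_size_um)


def perturb_probabilities(
    probs: ProbabilityStack,
    flip_rate: float,
    blur_sigma_px: float = 1.0,
    seed: int = 0,
) -> ProbabilityStack:
    """Corrupt a stack by re-drawing the class of a fraction of pixels.

    At ``flip_rate`` of pixel positions the hard class assignment is replaced
    by a uniformly random class before softening; used to stress-test the
    staged pipeline's robustness to classifier noise.
    """
    if not 0 <= flip_rate < 0.5:
        raise ValueError("flip_rate must lie in [0, 0.5)")
    if flip_rate == 0 and blur_sigma_px == 0:
        return ProbabilityStack(probs.probabilities.copy(), probs.pixel_size_um)
    rng = np.random.default_rng(seed)
    hard = probs.argmax_class
    if flip_rate > 0:
        flips = rng.random(hard.shape) < flip_rate
        hard = np.where(flips, rng.integers(0, 3, hard.shape), hard)
    stack = np.stack([(hard == k).astype(np.float64) for k in range(3)])
    if blur_sigma_px > 0:
        stack = np.stack([ndi.gaussian_filter(c, blur_sigma_px) for c in stack])
        stack /= stack.sum(axis=0, keepdims=True)
    return ProbabilityStack(stack, probs.pixel_size_um)


# ---------------------------------------------------------------------------
# scribble helpers: sparse annotations sampled from the ground truth
# ---------------------------------------------------------------------------


def pixel_scribbles(phantom: PhantomOutput, n_per_class: int = 200, seed: int = 0):
    """Sparse 4-class pixel scribbles (1 myelin, 2 axoplasm, 3 membrane, 4 mito).

    Pixels are sampled from the phantom's true masks, mimicking a user's
    sparse brush strokes.  Raises if a class has no pixels to sample from.
    """
    rng = np.random.default_rng(seed)
    lab = phantom.gt_semantic.labels
    masks = {
        1: (lab == SEMANTIC_MYELIN) & ~phantom.membrane_mask,
        2: ((lab == SEMANTIC_AXON) | (lab == SEMANTIC_INNER_TONGUE))
        & ~phantom.membrane_mask
        & ~phantom.mitochondria_mask,
        3: phantom.membrane_mask,
        4: phantom.mitochondria_mask,
    }
    out = np.zeros(lab.shape, dtype=np.int64)
    for code, mask in masks.items():
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            raise ValueError(f"no pixels available for scribble class {code}")
        take = rng.choice(idx, size=min(n_per_class, idx.size), replace=False)
        out.ravel()[take] = code
    return out


def gt_object_candidates(phantom: PhantomOutput) -> InstanceMap:
    """Candidate map built from the true object shapes (axons + crescents).

    Gives the object classifier a training set containing both disk-like
    axons and crescent-shaped tongues, as an annotator would provide.
    """
    axon = phantom.gt_axon.labels
    inner = phantom.gt_inner.labels
    tongue = (inner > 0) & (axon == 0)
    t_lab, _ = ndi.label(tongue, structure=np.ones((3, 3), dtype=int))
    labels = axon.copy()
    offset = int(axon.max())
    labels[t_lab > 0] = t_lab[t_lab > 0] + offset
    return InstanceMap(labels, ComponentKind.AXON, phantom.gt_axon.pixel_size_um)


def object_scribbles(phantom: PhantomOutput):
    """Object-class raster (1 large axon, 2 small axon, 3 inner tongue).

    True axon regions are coded large/small by a median area split; tongue
    crescents (inner minus axon) are coded 3.
    """
    axon = phantom.gt_axon.labels
    inner = phantom.gt_inner.labels
    out = np.zeros(axon.shape, dtype=np.int64)
    labels = phantom.gt_axon.object_labels
    if len(labels) == 0:
        return out
    areas = {int(l): int((axon == l).sum()) for l in labels}
    median = float(np.median(list(areas.values())))
    for l, area in areas.items():
        out[axon == l] = 1 if area >= median else 2
    out[(inner > 0) & (axon == 0)] = 3
    return out
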