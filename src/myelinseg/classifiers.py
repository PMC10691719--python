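"""Autocontext pixel classification and object classification.

The pixel classifier is a two-pass random-forest cascade.  Stage A is trained
on four classes (compact myelin, axoplasm, membrane, mitochondria) from the
multiscale feature bank.  Stage B consumes the same features plus stage A's
probability channels (raw and Gaussian-smoothed at every scale) and merges
the mitochondria annotations into axoplasm, so the final output has three
channels whose per-pixel sum is one.  Merging mitochondria prevents holes in
the axon instances caused by electron-dense organelles.

Axoplasm instance candidates are extracted from the axoplasm probability
channel by Gaussian smoothing (sigma 2.0), thresholding at 0.6 and rejecting
components smaller than 10 pixels.  A second random forest then scores each
candidate as a large axon, a small axon or an inner tongue from shape and
intensity-distribution features (no location features).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import joblib
import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureConfig, pixel_feature_stack, smooth_probability_channels
from .io import ComponentKind, Image2D, InstanceMap, ProbabilityStack

MODEL_FORMAT_VERSION = "myelinseg-model-1"

#: scribble codes for pixel training rasters (0 = unlabelled)
PIXEL_CLASSES = {1: "compact_myelin", 2: "axoplasm", 3: "membrane", 4: "mitochondria"}
#: stage-B classes after merging mitochondria into axoplasm
STAGE_B_CLASSES = {1: "compact_myelin", 2: "axoplasm", 3: "membrane"}
#: scribble codes for object training rasters (0 = unlabelled)
OBJECT_CLASSES = {1: "axon_large", 2: "axon_small", 3: "inner_tongue"}


class ObjectClass(str, Enum):
    AXON_LARGE = "axon_large"
    AXON_SMALL = "axon_small"
    INNER_TONGUE = "inner_tongue"
    UNASSIGNED = "unassigned"

    @property
    def is_axon(self) -> bool:
        return self in (ObjectClass.AXON_LARGE, ObjectClass.AXON_SMALL)


def _make_forest(seed: int) -> RandomForestClassifier:
    # 100 trees, sqrt features per split, unlimited depth; single thread so
    # results are reproducible on any machine.
    return RandomForestClassifier(
        n_estimators=100,
        max_features="sqrt",
        random_state=seed,
        n_jobs=1,
        oob_score=True,
    )


@dataclass
class PixelModel:
    """Trained autocontext cascade (stage A: 4 classes, stage B: 3 classes)."""

    stage_a: RandomForestClassifier
    stage_b: RandomForestClassifier
    feature_config: FeatureConfig
    rng_seed: int

    def save(self, path) -> None:
        joblib.dump(
            {
                "format": MODEL_FORMAT_VERSION,
                "kind": "pixel",
                "stage_a": self.stage_a,
                "stage_b": self.stage_b,
                "feature_config": {
                    "scales_sigma": self.feature_config.scales_sigma,
                    "feature_families": sorted(self.feature_config.feature_families),
                },
                "pixel_classes": PIXEL_CLASSES,
                "stage_b_classes": STAGE_B_CLASSES,
                "rng_seed": self.rng_seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "PixelModel":
        bundle = joblib.load(path)
        if bundle.get("format") != MODEL_FORMAT_VERSION or bundle.get("kind") != "pixel":
            raise ValueError("not a pixel-model bundle of a supported version")
        cfg = FeatureConfig(
            scales_sigma=tuple(bundle["feature_config"]["scales_sigma"]),
            feature_families=frozenset(bundle["feature_config"]["feature_families"]),
        )
        return cls(bundle["stage_a"], bundle["stage_b"], cfg, bundle["rng_seed"])


def _stage_a_probabilities(model: RandomForestClassifier, stack: np.ndarray) -> np.ndarray:
    """Predict stage-A probabilities for every pixel, as (4, H, W)."""
    n, h, w = stack.shape
    flat = stack.reshape(n, -1).T
    probs = model.predict_proba(flat)
    # columns follow model.classes_; re-order to codes 1..4
    out = np.zeros((4, h * w), dtype=np.float64)
    for i, cls in enumerate(model.classes_):
        out[int(cls) - 1] = probs[:, i]
    return out.reshape(4, h, w)


def _stage_b_input(stack: np.ndarray, probs_a: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    extra = smooth_probability_channels(probs_a, cfg, stack.shape[1:])
    return np.concatenate([stack, extra.astype(np.float32)], axis=0)


def train_pixel_autocontext(
    images,
    scribbles,
    cfg: FeatureConfig | None = None,
    seed: int = 0,
) -> PixelModel:
    """Train the two-pass pixel classifier from sparse scribble rasters.

    ``scribbles`` are integer rasters aligned with ``images`` using codes
    1 compact myelin, 2 axoplasm, 3 membrane, 4 mitochondria (0 unlabelled).
    Stage A requires at least one labelled pixel per class.  Stage B is
    trained on the same scribbles with mitochondria relabelled to axoplasm,
    plus stage A's probability channels as autocontext input.
    """
    cfg = cfg or FeatureConfig()
    if len(images) != len(scribbles):
        raise ValueError("images and scribbles must align one-to-one")
    stacks, labels = [], []
    for img, scr in zip(images, scribbles):
        scr = np.asarray(scr)
        if scr.shape != img.pixels.shape:
            raise ValueError("scribble raster must match image dimensions")
        stacks.append(pixel_feature_stack(img, cfg))
        labels.append(scr)
    present = np.unique(np.concatenate([l[l > 0] for l in labels]))
    missing = [PIXEL_CLASSES[c] for c in PIXEL_CLASSES if c not in present]
    if missing:
        raise ValueError(f"missing scribble class(es): {', '.join(missing)}")

    def gather(stacks, labels, transform=None):
        xs, ys = [], []
        for stack, lab in zip(stacks, labels):
            mask = lab > 0
            x = stack[:, mask].T
            y = lab[mask]
            if transform is not None:
                y = transform(y)
            xs.append(x)
            ys.append(y)
        return np.concatenate(xs), np.concatenate(ys)

    xa, ya = gather(stacks, labels)
    stage_a = _make_forest(seed)
    stage_a.fit(xa, ya)

    stacks_b = []
    for img, stack in zip(images, stacks):
        probs_a = _stage_a_probabilities(stage_a, stack)
        stacks_b.append(_stage_b_input(stack, probs_a, cfg))
    merge = lambda y: np.where(y == 4, 2, y)  # mitochondria -> axoplasm
    xb, yb = gather(stacks_b, labels, merge)
    stage_b = _make_forest(seed + 1)
    stage_b.fit(xb, yb)
    return PixelModel(stage_a, stage_b, cfg, seed)


def predict_probabilities(model: PixelModel, img: Image2D) -> ProbabilityStack:
    """Apply the autocontext cascade; returns the 3-channel probability stack."""
    stack = pixel_feature_stack(img, model.feature_config)
    probs_a = _stage_a_probabilities(model.stage_a, stack)
    stack_b = _stage_b_input(stack, probs_a, model.feature_config)
    n, h, w = stack_b.shape
    flat = stack_b.reshape(n, -1).T
    probs = model.stage_b.predict_proba(flat)
    out = np.zeros((3, h * w), dtype=np.float64)
    for i, cls in enumerate(model.stage_b.classes_):
        out[int(cls) - 1] = probs[:, i]
    out /= out.sum(axis=0, keepdims=True)
    return ProbabilityStack(out.reshape(3, h, w), img.pixel_size_um)


# ---------------------------------------------------------------------------
# candidate extraction
# ---------------------------------------------------------------------------


def axoplasm_candidates(
    prob: ProbabilityStack,
    smooth_sigma: float = 2.0,
    threshold: float = 0.6,
    min_size_px: int = 10,
) -> InstanceMap:
    """Segment potential axon/tongue instances from the axoplasm channel.

    Smooth, binarise at ``>= threshold``, label 8-connected components and
    reject components smaller than ``min_size_px``.  Surviving labels are
    renumbered 1..n in raster-scan order of each component's first pixel.
    """
    chan = prob.channel("axoplasm")
    smoothed = ndi.gaussian_filter(chan, smooth_sigma) if smooth_sigma > 0 else chan
    binary = smoothed >= threshold
    lab, _ = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    flat = lab.ravel()
    labs, first = np.unique(flat, return_index=True)
    keep = labs > 0
    labs, first = labs[keep], first[keep]
    counts = np.bincount(flat)
    # renumber surviving components 1..n by raster-scan order of first pixel
    relabel = np.zeros(int(labs.max(initial=0)) + 1, dtype=lab.dtype)
    next_label = 1
    for l in labs[np.argsort(first)]:
        if counts[l] >= min_size_px:
            relabel[l] = next_label
            next_label += 1
    return InstanceMap(relabel[lab], ComponentKind.AXON, prob.pixel_size_um)


# ---------------------------------------------------------------------------
# object classification
# ---------------------------------------------------------------------------

_QUANTILES = (0.05, 0.25, 0.5, 0.75, 0.95)


def object_feature_table(candidates: InstanceMap, img: Image2D) -> pd.DataFrame:
    """Shape and intensity-distribution features per candidate object.

    Location features (centroids, bounding-box positions) are deliberately
    absent so classification is translation invariant.
    """
    if len(candidates.object_labels) == 0:
        raise ValueError("candidate map is empty")
    if candidates.labels.shape != img.pixels.shape:
        raise ValueError("candidate raster must match image dimensions")
    rows = []
    props = measure.regionprops(candidates.labels, intensity_image=img.pixels)
    for p in props:
        area = float(p.area)
        perim = float(p.perimeter) if p.perimeter > 0 else 1.0
        values = img.pixels[candidates.labels == p.label]
        hist, _ = np.histogram(values, bins=10, range=(0.0, 1.0))
        row = {
            "label": int(p.label),
            "area": area,
            "perimeter": float(p.perimeter),
            "circularity": 4.0 * np.pi * area / perim**2,
            "convex_area": float(p.area_convex),
            "solidity": float(p.solidity),
            "eccentricity": float(p.eccentricity),
            "equivalent_diameter": float(p.equivalent_diameter_area),
            "extent": float(p.extent),
            "intensity_mean": float(values.mean()),
            "intensity_sd": float(values.std()),
            "intensity_min": float(values.min()),
            "intensity_max": float(values.max()),
        }
        for q in _QUANTILES:
            row[f"intensity_q{int(q * 100):02d}"] = float(np.quantile(values, q))
        for i, h in enumerate(hist):
            row[f"intensity_hist{i}"] = float(h) / area
        rows.append(row)
    return pd.DataFrame(rows)


FEATURE_COLUMNS_EXCLUDED = ("label",)


@dataclass
class ObjectModel:
    """Random forest scoring candidates as axon (large/small) or inner tongue."""

    forest: RandomForestClassifier
    feature_columns: tuple
    rng_seed: int

    def save(self, path) -> None:
        joblib.dump(
            {
                "format": MODEL_FORMAT_VERSION,
                "kind": "object",
                "forest": self.forest,
                "feature_columns": list(self.feature_columns),
                "object_classes": OBJECT_CLASSES,
                "rng_seed": self.rng_seed,
            },
            path,
        )

    @classmethod
    def load(cls, path) -> "ObjectModel":
        bundle = joblib.load(path)
        if bundle.get("format") != MODEL_FORMAT_VERSION or bundle.get("kind") != "object":
            raise ValueError("not an object-model bundle of a supported version")
        return cls(bundle["forest"], tuple(bundle["feature_columns"]), bundle["rng_seed"])


def train_object_model(
    candidates: InstanceMap,
    img: Image2D,
    label_raster: np.ndarray,
    seed: int = 0,
) -> ObjectModel:
    """Train the object classifier from an object-scribble raster.

    Each candidate takes the majority positive code (1 large axon, 2 small
    axon, 3 inner tongue) among its pixels in ``label_raster``; candidates
    with no labelled pixel are excluded from training (their kind was not
    annotated, so their predictions are ignored downstream).
    """
    label_raster = np.asarray(label_raster)
    table = object_feature_table(candidates, img)
    ys = []
    for lab in table["label"]:
        codes = label_raster[candidates.labels == lab]
        codes = codes[codes > 0]
        ys.append(int(np.bincount(codes).argmax()) if codes.size else 0)
    table = table.assign(_class=ys)
    train = table[table["_class"] > 0]
    if train.empty:
        raise ValueError("no labelled candidates to train on")
    cols = tuple(c for c in table.columns if c not in ("label", "_class"))
    forest = _make_forest(seed)
    forest.fit(train[list(cols)].to_numpy(), train["_class"].to_numpy())
    return ObjectModel(forest, cols, seed)


def classify_objects(model: ObjectModel, features: pd.DataFrame) -> pd.DataFrame:
    """Assign an :class:`ObjectClass` to every candidate in the feature table.

    Returns the table with a ``predicted_class`` column appended.  An empty
    table yields an empty result.
    """
    if features.empty:
        out = features.copy()
        out["predicted_class"] = pd.Series(dtype=object)
        return out
    missing = [c for c in model.feature_columns if c not in features.columns]
    if missing:
        raise ValueError(f"feature schema mismatch; missing columns: {missing}")
    x = features[list(model.feature_columns)].to_numpy()
    codes = model.forest.predict(x)
    out = features.copy()
    out["predicted_class"] = [ObjectClass(OBJECT_CLASSES[int(c)]) for c in codes]
    return out
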