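"""End-to-end orchestration: probabilities -> stages 1-3 -> hierarchy -> table.

This is the library-level equivalent of the ``segment`` command: it wires
candidate extraction, the three segmentation stages, optional batch
curation, axon correction, hierarchy post-processing and morphometry into a
single call with one parameter object.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .classifiers import (
    ObjectModel,
    axoplasm_candidates,
    classify_objects,
    object_feature_table,
)
from .hierarchy import (
    FibreHierarchy,
    build_hierarchy,
    measure_fibres,
    semantic_from_hierarchy,
)
from .io import ComponentKind, Image2D, InstanceMap, ProbabilityStack, SemanticMask
from .stages import (
    AxonCorrection,
    CurationOverride,
    candidates_to_map,
    correct_axon,
    myelin_mask_from_probabilities,
    selected,
    stage1_inner_regions,
    stage2_fibres,
    stage3_axons,
)


@dataclass
class RunConfig:
    """All stage parameters with their workflow defaults.

    Values stated by the source workflow keep those defaults: candidate
    smoothing sigma 2.0, threshold 0.6, minimum object size 10 px, IoU
    thresholds 0.5-0.9 step 0.05, downsampling factor 4, 1% saturation.
    """

    saturated_fraction: float = 0.01
    downsample_factor: int = 4
    candidate_smooth_sigma: float = 2.0
    candidate_threshold: float = 0.6
    candidate_min_size_px: int = 10
    stage1_min_area_px: int = 50
    stage1_max_area_fraction: float = 0.05
    stage1_axoplasm_gate: float = 0.4
    stage1_close_radius: int = 1
    stage3_overlap_fraction: float = 0.5
    axon_correction: str = "fill_holes"
    duplicate_inner_as_axon: bool = True
    iou_thresholds: tuple = tuple(np.round(np.arange(0.5, 0.901, 0.05), 2))
    seed: int = 0

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        valid = set(cls.__dataclass_fields__)
        unknown = sorted(set(mapping) - valid)
        if unknown:
            raise ValueError(f"invalid config keys: {', '.join(unknown)}")
        return cls(**mapping)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["iou_thresholds"] = list(d["iou_thresholds"])
        return d


@dataclass
class SegmentationResult:
    hierarchy: FibreHierarchy
    table: pd.DataFrame
    semantic: SemanticMask
    instance_maps: dict
    stage1_candidates: list
    stage3_candidates: list


def segment_from_probabilities(
    prob: ProbabilityStack,
    object_model: ObjectModel,
    image: Image2D | None = None,
    config: RunConfig | None = None,
    curation: dict | None = None,
) -> SegmentationResult:
    """Run stages 1-3, post-processing and morphometry on one image.

    ``image`` supplies intensities for the object features; when omitted the
    axoplasm probability channel stands in.  ``curation`` optionally maps
    stage keys (``"stage1"``, ``"stage3"``) to :class:`CurationOverride`.
    """
    config = config or RunConfig()
    curation = curation or {}
    shape = prob.probabilities.shape[1:]
    if image is None:
        image = Image2D(prob.channel("axoplasm"), prob.pixel_size_um)

    inner = stage1_inner_regions(
        prob,
        min_area_px=config.stage1_min_area_px,
        max_area_fraction=config.stage1_max_area_fraction,
        axoplasm_gate=config.stage1_axoplasm_gate,
        close_radius=config.stage1_close_radius,
    )
    if "stage1" in curation:
        inner = apply_stage_curation(inner, curation["stage1"], shape)

    myelin = myelin_mask_from_probabilities(prob, config.stage1_close_radius)
    fibres = stage2_fibres(inner, myelin, prob.pixel_size_um)

    candidates = axoplasm_candidates(
        prob,
        smooth_sigma=config.candidate_smooth_sigma,
        threshold=config.candidate_threshold,
        min_size_px=config.candidate_min_size_px,
    )
    inner_map = candidates_to_map(
        inner, ComponentKind.INNER_REGION, shape, prob.pixel_size_um
    )
    if len(candidates.object_labels) > 0:
        feats = object_feature_table(candidates, image)
        classified = classify_objects(object_model, feats)
    else:
        classified = pd.DataFrame(columns=["label", "predicted_class"])
    axons = stage3_axons(
        candidates, classified, inner_map, config.stage3_overlap_fraction
    )
    if "stage3" in curation:
        axons = apply_stage_curation(axons, curation["stage3"], shape)
    method = AxonCorrection(config.axon_correction)
    if method is not AxonCorrection.NONE:
        axons = [
            correct_axon(c, method) if c.state.value == "selected" else c
            for c in axons
        ]

    hier = build_hierarchy(inner, fibres, axons, config.duplicate_inner_as_axon)
    table = measure_fibres(hier)
    semantic = semantic_from_hierarchy(hier)
    return SegmentationResult(
        hierarchy=hier,
        table=table,
        semantic=semantic,
        instance_maps=hier.instance_maps(),
        stage1_candidates=inner,
        stage3_candidates=axons,
    )


def apply_stage_curation(candidates, override: CurationOverride, shape):
    from .stages import apply_curation

    return apply_curation(candidates, override, shape)
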