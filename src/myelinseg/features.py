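"""Multiscale pixel feature bank for random-forest pixel classification.

The bank mirrors the intensity / edge / texture feature families common in
interactive pixel-classification tools: per scale ``sigma`` it computes
Gaussian smoothing (intensity); Laplacian of Gaussian, Gaussian gradient
magnitude and difference of Gaussians (edge); and the eigenvalues of the
structure tensor and of the Hessian (texture).  The smallest scale
contributes smoothing only.  The channel order is deterministic and exposed
through :func:`feature_names`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import hessian_matrix, hessian_matrix_eigvals
from skimage.feature import structure_tensor, structure_tensor_eigenvalues

from .io import Image2D

logger = logging.getLogger(__name__)

DEFAULT_SIGMAS = (0.3, 0.7, 1.0, 1.6, 3.5, 5.0, 10.0, 15.0, 30.0, 50.0)

#: operators computed at every scale except the smallest (smoothing only)
_EDGE_TEXTURE_OPS = (
    "laplacian_of_gaussian",
    "gradient_magnitude",
    "difference_of_gaussians",
    "structure_tensor_eig0",
    "structure_tensor_eig1",
    "hessian_eig0",
    "hessian_eig1",
)


@dataclass(frozen=True)
class FeatureConfig:
    """Scales and families of the pixel feature bank.

    ``scales_sigma`` must be strictly increasing and positive.  Families may
    be restricted (e.g. intensity-only) for fast experiments.
    """

    scales_sigma: tuple = DEFAULT_SIGMAS
    feature_families: frozenset = frozenset({"intensity", "edge", "texture"})

    def __post_init__(self):
        s = tuple(self.scales_sigma)
        if len(s) == 0 or any(x <= 0 for x in s):
            raise ValueError("scales must be positive")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise ValueError("scales must be strictly increasing")
        unknown = set(self.feature_families) - {"intensity", "edge", "texture"}
        if unknown:
            raise ValueError(f"unknown feature families: {sorted(unknown)}")
        object.__setattr__(self, "scales_sigma", s)
        object.__setattr__(self, "feature_families", frozenset(self.feature_families))


def usable_scales(cfg: FeatureConfig, shape) -> list:
    """Scales not exceeding half the smaller image side (others warn+skip)."""
    limit = min(shape) / 2.0
    kept = []
    for s in cfg.scales_sigma:
        if s > limit:
            logger.warning("skipping sigma=%.1f: exceeds half image side %.1f", s, limit)
        else:
            kept.append(s)
    return kept


def feature_names(cfg: FeatureConfig, shape=None) -> list:
    """Deterministic channel names, in computation order."""
    scales = cfg.scales_sigma if shape is None else usable_scales(cfg, shape)
    names = []
    for i, s in enumerate(scales):
        if "intensity" in cfg.feature_families:
            names.append(f"gaussian_s{s:g}")
        if i == 0:
            continue
        for op in _EDGE_TEXTURE_OPS:
            family = (
                "edge"
                if op.startswith(("laplacian", "gradient", "difference"))
                else "texture"
            )
            if family in cfg.feature_families:
                names.append(f"{op}_s{s:g}")
    return names


def _scale_features(img: np.ndarray, sigma: float, cfg: FeatureConfig, smallest: bool):
    out = []
    smoothed = ndi.gaussian_filter(img, sigma)
    if "intensity" in cfg.feature_families:
        out.append(smoothed)
    if smallest:
        return out
    if "edge" in cfg.feature_families:
        out.append(ndi.gaussian_laplace(img, sigma))
        out.append(ndi.gaussian_gradient_magnitude(img, sigma))
        out.append(smoothed - ndi.gaussian_filter(img, 0.66 * sigma))
    if "texture" in cfg.feature_families:
        # reflect padding: no spurious responses at the image border
        st = structure_tensor(img, sigma=sigma, order="rc", mode="reflect")
        out.extend(structure_tensor_eigenvalues(st))
        hm = hessian_matrix(
            img, sigma=sigma, order="rc", use_gaussian_derivatives=True, mode="reflect"
        )
        out.extend(hessian_matrix_eigvals(hm))
    return out


def pixel_feature_stack(img: Image2D, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Compute the per-pixel feature stack, shape ``(n_features, H, W)``.

    Channel order follows :func:`feature_names` for the scales usable at this
    image size.
    """
    cfg = cfg or FeatureConfig()
    pixels = np.asarray(img.pixels, dtype=np.float32)
    scales = usable_scales(cfg, pixels.shape)
    if not scales:
        raise ValueError("no usable scales for this image size")
    channels = []
    for i, s in enumerate(scales):
        channels.extend(_scale_features(pixels, s, cfg, smallest=(i == 0)))
    stack = np.stack([np.asarray(c, dtype=np.float32) for c in channels])
    assert stack.shape[0] == len(feature_names(cfg, pixels.shape))
    return stack


def smooth_probability_channels(probs: np.ndarray, cfg: FeatureConfig, shape) -> np.ndarray:
    """Gaussian smoothings of probability channels at every usable scale.

    Used to build the autocontext input of the second pixel classifier:
    the raw stage-A probabilities plus one smoothed copy per scale.
    """
    scales = usable_scales(cfg, shape)
    out = [np.asarray(p, dtype=np.float32) for p in probs]
    for s in scales:
        for p in probs:
            out.append(ndi.gaussian_filter(np.asarray(p, dtype=np.float32), s))
    return np.stack(out)
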