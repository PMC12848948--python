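"""Droplet-edge fractional-area statistic for brightfield phase-separation
quantification.

The degree of phase separation in a brightfield field of view is scored by
(1) estimating per-pixel intensity derivatives with the 5-tap
Farid–Simoncelli optimal derivative filter pair, (2) selecting pixels whose
gradient magnitude exceeds ``k_sd`` (default 10) standard deviations of the
gradient-magnitude image — these are the sharp rims of in-focus droplets,
while out-of-focus droplets are suppressed because their gradients are
lower — and (3) dividing the selected pixel count by the field area.  The
per-sample statistic is the mean edge fraction over the fields (typically
five), with the sample standard deviation as its error, normalized by the
same statistic from a non-phase-separating reference sample to cancel the
contribution of fixed optical speckle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from condensekit.imageset import ImageSet

__all__ = [
    "FARID_SMOOTH",
    "FARID_DERIV",
    "farid_gradient",
    "edge_fraction",
    "EdgeFractionMeasurement",
    "summarize_sample",
    "NormalizedPhaseSeparation",
    "normalize_to_reference",
    "StateDiagram",
    "build_state_diagram",
]

# Farid & Simoncelli 5-tap optimal derivative pair: an interpolating
# (smoothing) kernel applied along one axis and a matched first-derivative
# kernel along the other.
FARID_SMOOTH = np.array([0.037659, 0.249153, 0.426375, 0.249153, 0.037659])
FARID_DERIV = np.array([-0.109604, -0.276691, 0.0, 0.276691, 0.109604])


def farid_gradient(image: np.ndarray) -> np.ndarray:
    """Per-pixel gradient magnitude from the 5-tap Farid–Simoncelli filters.

    Returns ``sqrt(gx**2 + gy**2)`` where ``gx`` differentiates along
    columns (x) and ``gy`` along rows (y), each smoothed along the
    orthogonal axis.  Borders are handled by reflection padding.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {image.shape}")
    if min(image.shape) < 5:
        raise ValueError(
            f"image {image.shape} smaller than the 5-tap kernel support"
        )
    gx = ndimage.correlate1d(image, FARID_DERIV, axis=1, mode="reflect")
    gx = ndimage.correlate1d(gx, FARID_SMOOTH, axis=0, mode="reflect")
    gy = ndimage.correlate1d(image, FARID_DERIV, axis=0, mode="reflect")
    gy = ndimage.correlate1d(gy, FARID_SMOOTH, axis=1, mode="reflect")
    return np.hypot(gx, gy)


def edge_fraction(image: np.ndarray, k_sd: float = 10.0) -> float:
    """Fraction of pixels whose gradient magnitude exceeds ``k_sd`` standard
    deviations of the gradient-magnitude image.

    The standard deviation is computed per field over all pixels of the
    filtered image, and the threshold is strictly greater-than.  A
    perfectly flat field (sigma = 0) returns 0.
    """
    grad = farid_gradient(image)
    sigma = grad.std()
    if sigma == 0.0:
        return 0.0
    return float(np.count_nonzero(grad > k_sd * sigma) / grad.size)


@dataclass
class EdgeFractionMeasurement:
    """Edge fractional areas of one sample's fields plus their summary."""

    per_field_fraction: list[float]
    mean: float
    sd: float  # sample SD; NaN when only one field was measured
    k_sd: float = 10.0


def summarize_sample(image_set: ImageSet, k_sd: float = 10.0) -> EdgeFractionMeasurement:
    """Edge fraction of every field plus mean and sample SD.

    A single-field set returns its value as the mean with ``sd = nan``
    (the sample SD is undefined).
    """
    fracs = [edge_fraction(f, k_sd=k_sd) for f in image_set]
    mean = float(np.mean(fracs))
    sd = float(np.std(fracs, ddof=1)) if len(fracs) > 1 else float("nan")
    return EdgeFractionMeasurement(per_field_fraction=fracs, mean=mean, sd=sd, k_sd=k_sd)


@dataclass
class NormalizedPhaseSeparation:
    """Sample edge statistic normalized by a non-phase-separating reference."""

    value: float  # sample mean / reference mean
    error: float  # sample sd / reference mean


def normalize_to_reference(
    sample: EdgeFractionMeasurement, reference: EdgeFractionMeasurement
) -> NormalizedPhaseSeparation:
    """Normalize a sample's mean edge fraction by the reference mean.

    The reference must be a non-phase-separating sample imaged with the
    same optics, so that dividing by its mean cancels the fixed speckle
    contribution.  ``normalize_to_reference(x, x).value`` is exactly 1.
    """
    if reference.mean <= 0.0:
        raise ValueError(
            "reference mean edge fraction is 0; the reference must contain the "
            "shared optical background (speckle) so its edge statistic is positive"
        )
    return NormalizedPhaseSeparation(
        value=sample.mean / reference.mean, error=sample.sd / reference.mean
    )


@dataclass
class StateDiagram:
    """Grid of normalized phase-separation values over condition axes.

    ``table`` has one row per condition: the axis coordinate columns
    followed by ``value`` and ``error``.
    """

    axes: list[str]
    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def values_along(self, axis: str) -> pd.Series:
        return self.table.sort_values(axis).set_index(axis)["value"]


def build_state_diagram(
    conditions: list[tuple[dict, ImageSet]],
    reference: ImageSet,
    k_sd: float = 10.0,
) -> StateDiagram:
    """Assemble a state diagram from (axis coordinates, image set) pairs.

    Every set is summarized with :func:`summarize_sample` and normalized by
    the shared reference.  Axis coordinates are dicts like
    ``{"peg_percent": 2.5, "protein_uM": 5.0}``; duplicate coordinates are
    rejected.
    """
    if not conditions:
        raise ValueError("no conditions given")
    ref = summarize_sample(reference, k_sd=k_sd)
    axes = list(conditions[0][0].keys())
    seen = set()
    rows = []
    for coords, image_set in conditions:
        if list(coords.keys()) != axes:
            raise ValueError(f"inconsistent axis names: {list(coords)} vs {axes}")
        if image_set.field_shape != reference.field_shape:
            raise ValueError("all image sets must share the reference field shape")
        key = tuple(coords.values())
        if key in seen:
            raise ValueError(f"duplicate grid coordinates {coords}")
        seen.add(key)
        norm = normalize_to_reference(summarize_sample(image_set, k_sd=k_sd), ref)
        rows.append({**coords, "value": norm.value, "error": norm.error})
    return StateDiagram(axes=axes, table=pd.DataFrame(rows))
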