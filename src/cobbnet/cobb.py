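"""Cobb angle from vertebral slopes.

The two end-vertebrae of a curve are the vertebrae with the maximum
absolute slopes tilting in opposite directions to the horizontal; the
Cobb angle is the sum of the absolute values of their two slopes.
Zero slopes are sign-neutral: a flat vertebra may pair with either tilt
direction, contributing 0 to the angle.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dnn import DNNParameters, predict_slope
from .exceptions import DegenerateCurveError, ValidationError
from .patches import standardize_image


@dataclass(frozen=True)
class MeasurementRecord:
    """One Cobb measurement with full provenance."""

    clicks: tuple[tuple[float, float], ...]
    slopes: tuple[float, ...]
    upper_index: int
    lower_index: int
    cobb_angle: float
    degenerate: bool = False  # all clicked vertebrae tilted the same way

    def to_dict(self) -> dict:
        return {
            "clicks": [list(c) for c in self.clicks],
            "slopes": list(self.slopes),
            "upper_index": self.upper_index,
            "lower_index": self.lower_index,
            "cobb_angle": self.cobb_angle,
            "degenerate": self.degenerate,
        }


def select_end_vertebrae(
    slopes, strict: bool = False
) -> tuple[int, int, bool]:
    """Indices of the two end-vertebrae: the maximum positive slope and
    the minimum (most negative) slope, reported as (upper, lower) by
    list position (smaller index first).

    Zeros are sign-neutral and may stand in for the missing sign.  When
    every slope has the same strict sign there is no opposite-tilt pair:
    with ``strict=True`` this raises :class:`DegenerateCurveError`; by
    default the two extreme slopes are returned with a degenerate flag
    (their difference is still a meaningful tilt span).  Ties in |slope|
    resolve to the lowest index.

    Returns ``(upper_index, lower_index, degenerate)``.
    """
    s = np.asarray(slopes, dtype=float)
    if s.ndim != 1 or s.size < 2:
        raise ValidationError("need at least 2 slopes to select end-vertebrae")
    i_max = int(np.argmax(s))   # argmax/argmin take the lowest index on ties
    i_min = int(np.argmin(s))
    degenerate = False
    if s[i_max] > 0 and s[i_min] < 0:
        pass  # opposite tilts
    elif s[i_max] == 0 and s[i_min] == 0:
        i_max, i_min = 0, 1  # flat spine: any pair, angle 0
    elif s[i_max] > 0 and s[i_min] == 0:
        pass  # zero pairs as the opposite tilt
    elif s[i_min] < 0 and s[i_max] == 0:
        pass
    else:
        # all strictly positive or all strictly negative
        if strict:
            raise DegenerateCurveError(
                "all slopes tilt in the same direction; no opposite-sign "
                "end-vertebra pair exists",
                extreme_indices=(i_max, i_min),
            )
        degenerate = True
    upper, lower = sorted((i_max, i_min))
    return upper, lower, degenerate


def cobb_angle(slopes, strict: bool = False) -> float:
    """Cobb angle in degrees: |s_upper| + |s_lower| for the selected
    end-vertebrae; for a flagged same-sign (degenerate) set, the tilt
    span max(s) - min(s)."""
    s = np.asarray(slopes, dtype=float)
    upper, lower, degenerate = select_end_vertebrae(s, strict=strict)
    if degenerate:
        return float(s.max() - s.min())
    return float(abs(s[upper]) + abs(s[lower]))


def measure(
    image: np.ndarray,
    clicks,
    model: DNNParameters,
    strict: bool = False,
) -> MeasurementRecord:
    """Measure the Cobb angle of the curve spanned by the clicked
    vertebrae: standardize the image, predict each clicked vertebra's
    slope with the network, select the end-vertebrae, and sum their
    absolute slopes.  Deterministic: no randomness at inference."""
    clicks = [tuple(float(c) for c in click) for click in clicks]
    if len(clicks) < 2:
        raise ValidationError("need at least 2 clicked vertebrae")
    std = standardize_image(image)
    slopes = []
    for k, click in enumerate(clicks):
        try:
            slopes.append(predict_slope(model, std, click))
        except ValidationError as exc:
            raise ValidationError(f"click {k} at {click}: {exc}")
    upper, lower, degenerate = select_end_vertebrae(slopes, strict=strict)
    s = np.asarray(slopes)
    if degenerate:
        warnings.warn(
            "all clicked vertebrae tilt the same way; reporting the tilt "
            "span of the two extremes",
            stacklevel=2,
        )
        angle = float(s.max() - s.min())
    else:
        angle = float(abs(s[upper]) + abs(s[lower]))
    return MeasurementRecord(
        clicks=tuple(clicks),
        slopes=tuple(float(v) for v in slopes),
        upper_index=upper,
        lower_index=lower,
        cobb_angle=angle,
        degenerate=degenerate,
    )
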