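"""Synthetic scoliotic spine-phantom radiographs with exact ground truth.

The generator emulates PA radiographs of a physical spine model: 17
vertebrae (T1-T12, L1-L5) placed along a smooth laterally-deviated
midline, each rendered as a tilted bright vertebral body with darker
endplate edges and two radio-opaque pedicle markers whose connecting
segment encodes the vertebra's slope.  Images are rendered at the
standardized height of 1000 pixels, so every ground-truth coordinate is
already expressed in the standardized frame.

Slope convention: a vertebra's slope is the angle (degrees) of its
endplate direction versus horizontal, positive when the right end of the
superior endplate is higher than the left (counterclockwise on screen,
image axes x right / y down).  This equals ``atan(dx/dy)`` of the midline
lateral deviation at the vertebra's center.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage
from skimage import measure

from .exceptions import (
    MarkerAmbiguityError,
    MarkersNotFoundError,
    ValidationError,
)

STANDARD_HEIGHT = 1000
#: vertical span occupied by vertebra centers (leaves room for jittered
#: 150x150 patch windows at the extremes)
_Y_TOP, _Y_BOTTOM = 95.0, 905.0
#: margin added on each side of the widest lateral excursion so every
#: patch window (75 px half-size plus jitter) stays inside the canvas
_X_MARGIN = 100.0

VERTEBRA_LABELS = tuple(f"T{i}" for i in range(1, 13)) + tuple(
    f"L{i}" for i in range(1, 6)
)

# rendering intensities (8-bit scale); invented phantom image model
_BG_LOW, _BG_SPAN = 60.0, 35.0
_BODY_DELTA = 80.0
_EDGE_DELTA = -45.0
_MARKER_DELTA = 150.0
_MARKER_RADIUS = 3.0
_EDGE_THICKNESS = 3.0
_CORNER_RADIUS = 6.0
_BLUR_SIGMA = 1.0


@dataclass(frozen=True)
class VertebraSpec:
    """Geometry of one phantom vertebra in the standardized frame."""

    label: str
    center: tuple[float, float]
    width: float
    height: float
    slope: float  # degrees, signed
    marker_left: tuple[float, float]
    marker_right: tuple[float, float]


@dataclass(frozen=True)
class SpineSpec:
    """Ground-truth description of a phantom spine.

    ``vertebrae`` are ordered superior to inferior (T1 first); centers are
    strictly increasing in the vertical image coordinate.  ``canvas_width``
    is the minimal image width that contains every vertebra plus the patch
    margin.
    """

    vertebrae: tuple[VertebraSpec, ...]
    curve_params: dict
    seed: int
    canvas_width: int

    @property
    def slopes(self) -> np.ndarray:
        return np.array([v.slope for v in self.vertebrae])

    @property
    def centers(self) -> np.ndarray:
        return np.array([v.center for v in self.vertebrae])

    def validate(self) -> None:
        ys = [v.center[1] for v in self.vertebrae]
        if not all(a < b for a, b in zip(ys, ys[1:])):
            raise ValidationError(
                "vertebra centers must be strictly increasing in y"
            )

    def cobb_angle_truth(self) -> float:
        """Cobb angle implied by the ground-truth slopes (sum of the two
        largest absolute slopes of opposite sign)."""
        from .cobb import cobb_angle

        return cobb_angle(list(self.slopes))


@dataclass(frozen=True)
class PhantomRadiograph:
    """A rendered phantom radiograph and the spec that produced it."""

    image: np.ndarray  # uint8, height STANDARD_HEIGHT
    truth: SpineSpec
    noise_level: float
    seed: int


def _vertebra_layout(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """y centers, widths and heights for ``n`` vertebrae.

    Sizes grow superior to inferior, mimicking thoracic-to-lumbar scaling.
    """
    ys = np.linspace(_Y_TOP, _Y_BOTTOM, n)
    widths = np.linspace(68.0, 96.0, n)
    heights = np.linspace(34.0, 50.0, n)
    return ys, widths, heights


_CURVE_CYCLES = {"single_curve": 1.0, "double_curve": 2.0}
_PHASE_HALF_RANGE = 0.45  # radians of random apex shift


@functools.lru_cache(maxsize=32)
def _calibrated_max_slope_mean(
    low: float, high: float, mean_magnitude: float, curve_family: str, n: int
) -> tuple[float, float]:
    """Center and half-width of the per-spec max-slope distribution.

    The per-spec target maximum |slope| M is drawn uniformly from
    [mu - w, mu + w] inside [low, high]; mu is calibrated by fixed-point
    iteration (deterministic quadrature over phases and M) so that the
    grand mean |slope| across specs and vertebrae equals
    ``mean_magnitude``.
    """
    cycles = _CURVE_CYCLES[curve_family]
    t = np.linspace(0.0, 1.0, n)
    phis = np.linspace(-_PHASE_HALF_RANGE, _PHASE_HALF_RANGE, 17)

    def grand_mean(mu: float) -> float:
        w = min(mu - low, high - mu)
        ms = np.linspace(mu - w, mu + w, 17)
        acc = []
        for phi in phis:
            cos_u = np.cos(cycles * np.pi * t + phi)
            peak = np.max(np.abs(cos_u))
            for m in ms:
                a = math.tan(math.radians(m)) / peak
                acc.append(np.mean(np.abs(np.degrees(np.arctan(a * cos_u)))))
        return float(np.mean(acc))

    mu = min(max(mean_magnitude / 0.64, low + 0.5), high - 0.5)
    for _ in range(6):
        g = grand_mean(mu)
        mu = mu * mean_magnitude / g
        mu = min(max(mu, low + 0.5), high - 0.5)
    w = min(mu - low, high - mu)
    return mu, w


def generate_spine_spec(
    n_vertebrae: int = 17,
    slope_magnitude_range: tuple[float, float] = (5.0, 50.0),
    mean_magnitude: float = 15.0,
    curve_family: str = "single_curve",
    seed: int = 0,
) -> SpineSpec:
    """Draw a random phantom spine whose maximum |slope| lies in
    ``slope_magnitude_range`` and whose expected mean |slope| across
    vertebrae equals ``mean_magnitude``.

    The midline lateral deviation is a sine arc (one half-period span for
    ``single_curve``, a full S for ``double_curve``) with a random phase
    shift and tilt direction; vertebral slopes are the arctangents of the
    midline's dx/dy at the vertebra centers, with the amplitude scaled so
    the maximum |slope| over the 17 centers equals the drawn target
    exactly.  Deterministic for a fixed seed.
    """
    low, high = float(slope_magnitude_range[0]), float(slope_magnitude_range[1])
    if not (0.0 <= low < high <= 89.0):
        raise ValidationError(
            f"slope_magnitude_range must satisfy 0 <= low < high <= 89, "
            f"got ({low}, {high})"
        )
    if n_vertebrae < 2:
        raise ValidationError(f"n_vertebrae must be >= 2, got {n_vertebrae}")
    if curve_family not in _CURVE_CYCLES:
        raise ValidationError(
            f"curve_family must be one of {sorted(_CURVE_CYCLES)}, "
            f"got {curve_family!r}"
        )

    rng = np.random.default_rng(seed)
    mu, w = _calibrated_max_slope_mean(
        low, high, float(mean_magnitude), curve_family, n_vertebrae
    )
    target_max = rng.uniform(mu - w, mu + w)
    phi = rng.uniform(-_PHASE_HALF_RANGE, _PHASE_HALF_RANGE)
    direction = 1.0 if rng.random() < 0.5 else -1.0

    cycles = _CURVE_CYCLES[curve_family]
    ys, widths, heights = _vertebra_layout(n_vertebrae)
    t = (ys - _Y_TOP) / (_Y_BOTTOM - _Y_TOP)
    u = cycles * np.pi * t + phi
    cos_u = np.cos(u)
    peak = np.max(np.abs(cos_u))
    # dx/dy amplitude chosen so max |slope| over centers == target_max
    a = math.tan(math.radians(target_max)) / peak
    dxdy = direction * a * cos_u
    slopes = np.degrees(np.arctan(dxdy))
    # integrate dx/dy analytically: x(t) = dir * a * L/(c*pi) * sin(u)
    span = _Y_BOTTOM - _Y_TOP
    dev = direction * a * span / (cycles * np.pi) * np.sin(u)
    dev = dev - dev.mean()

    half = float(np.max(np.abs(dev)) + widths.max() / 2.0 + _X_MARGIN)
    canvas_width = int(2 * math.ceil(half))
    xs = canvas_width / 2.0 + dev

    vertebrae = []
    for i in range(n_vertebrae):
        label = VERTEBRA_LABELS[i] if n_vertebrae == 17 else f"V{i + 1}"
        theta = math.radians(slopes[i])
        d = 0.25 * widths[i]
        ex, ey = math.cos(theta), -math.sin(theta)  # endplate direction
        cx, cy = float(xs[i]), float(ys[i])
        vertebrae.append(
            VertebraSpec(
                label=label,
                center=(cx, cy),
                width=float(widths[i]),
                height=float(heights[i]),
                slope=float(slopes[i]),
                marker_left=(cx - d * ex, cy - d * ey),
                marker_right=(cx + d * ex, cy + d * ey),
            )
        )

    spec = SpineSpec(
        vertebrae=tuple(vertebrae),
        curve_params={
            "curve_family": curve_family,
            "target_max_slope": float(target_max),
            "phase": float(phi),
            "direction": direction,
            "slope_magnitude_range": (low, high),
            "mean_magnitude": float(mean_magnitude),
        },
        seed=seed,
        canvas_width=canvas_width,
    )
    spec.validate()
    return spec


def _rounded_rect_sdf(u, v, half_w, half_h, radius):
    qx = np.abs(u) - (half_w - radius)
    qy = np.abs(v) - (half_h - radius)
    return np.hypot(np.maximum(qx, 0.0), np.maximum(qy, 0.0)) - radius


def render_radiograph(
    spec: SpineSpec,
    image_width: int | None = None,
    noise_level: float = 5.0,
    seed: int = 0,
) -> PhantomRadiograph:
    """Render a phantom radiograph at the standardized 1000-px height.

    Each vertebra is a rotated rounded rectangle of elevated intensity
    with darker endplate edges and two bright pedicle-marker disks; the
    background is a smooth gradient.  A Gaussian blur (sigma 1 px) is
    applied before optional additive Gaussian noise.  Bit-identical for a
    fixed (spec, seed, noise_level).
    """
    width = int(image_width) if image_width is not None else spec.canvas_width
    if width < spec.canvas_width:
        raise ValidationError(
            f"image_width {width} too small; need >= {spec.canvas_width} to "
            f"contain all vertebrae plus the patch margin"
        )
    if width != spec.canvas_width:
        # recenter on the wider canvas
        shift = (width - spec.canvas_width) / 2.0
        spec = shift_spec(spec, dx=shift)

    H = STANDARD_HEIGHT
    yy = np.arange(H, dtype=float)[:, None]
    xx = np.arange(width, dtype=float)[None, :]
    img = _BG_LOW + _BG_SPAN * (yy / H) + 8.0 * (xx / width)
    img = np.broadcast_to(img, (H, width)).copy()

    for i, v in enumerate(spec.vertebrae):
        cx, cy = v.center
        box = math.hypot(v.width / 2 + 6, v.height / 2 + 6)
        x0, x1 = int(cx - box), int(cx + box) + 1
        y0, y1 = int(cy - box), int(cy + box) + 1
        if x0 < 0 or y0 < 0 or x1 > width or y1 > H:
            raise ValidationError(
                f"vertebra {i} ({v.label}) exceeds the image bounds"
            )
        ly = np.arange(y0, y1, dtype=float)[:, None] - cy
        lx = np.arange(x0, x1, dtype=float)[None, :] - cx
        theta = math.radians(v.slope)
        ex, ey = math.cos(theta), -math.sin(theta)
        # u along the endplate, v_ across it
        uu = lx * ex + ly * ey
        vv = lx * (-ey) + ly * ex
        sdf = _rounded_rect_sdf(uu, vv, v.width / 2, v.height / 2, _CORNER_RADIUS)
        body = sdf <= 0.0
        patch = img[y0:y1, x0:x1]
        patch[body] += _BODY_DELTA
        edges = body & (np.abs(vv) > v.height / 2 - _EDGE_THICKNESS)
        patch[edges] += _EDGE_DELTA

        for mx, my in (v.marker_left, v.marker_right):
            gx0, gx1 = int(mx - 5), int(mx + 5) + 1
            gy0, gy1 = int(my - 5), int(my + 5) + 1
            gly = np.arange(gy0, gy1, dtype=float)[:, None] - my
            glx = np.arange(gx0, gx1, dtype=float)[None, :] - mx
            disk = glx**2 + gly**2 <= _MARKER_RADIUS**2
            img[gy0:gy1, gx0:gx1][disk] += _MARKER_DELTA

    img = ndimage.gaussian_filter(img, sigma=_BLUR_SIGMA)
    if noise_level > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_level, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)
    return PhantomRadiograph(
        image=img, truth=spec, noise_level=float(noise_level), seed=seed
    )


def shift_spec(spec: SpineSpec, dx: float = 0.0, dy: float = 0.0) -> SpineSpec:
    """Translate every ground-truth coordinate by (dx, dy)."""

    def mv(p):
        return (p[0] + dx, p[1] + dy)

    vertebrae = tuple(
        replace(
            v,
            center=mv(v.center),
            marker_left=mv(v.marker_left),
            marker_right=mv(v.marker_right),
        )
        for v in spec.vertebrae
    )
    return replace(
        spec, vertebrae=vertebrae, canvas_width=spec.canvas_width + int(2 * dx)
    )


def detect_markers_and_slope(
    image: np.ndarray,
    vertebra_center: tuple[float, float],
    window: int = 60,
) -> float:
    """Recover a vertebra's slope from its two pedicle markers.

    Thresholds the brightest blobs (99.5th intensity percentile) in the
    ``window``-sized box around ``vertebra_center``, takes the two largest
    blobs, refines each blob's position to subpixel accuracy with a local
    intensity-weighted centroid, and returns the angle of the segment
    joining the two centroids versus horizontal, in degrees, positive
    when the right end is higher on screen.
    """
    cx, cy = vertebra_center
    h = window // 2
    x0, y0 = int(round(cx)) - h, int(round(cy)) - h
    x1, y1 = x0 + window, y0 + window
    if x0 < 0 or y0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValidationError(
            f"marker window at ({cx}, {cy}) exceeds the image bounds"
        )
    win = image[y0:y1, x0:x1].astype(float)
    med = float(np.median(win))
    thr = float(np.percentile(win, 99.5))
    if thr - med < 40.0:
        raise MarkersNotFoundError(
            f"no marker-bright pixels near ({cx:.0f}, {cy:.0f}): "
            f"p99.5 - median = {thr - med:.1f} < 40"
        )
    labels = measure.label(win >= thr)
    props = [p for p in measure.regionprops(labels) if p.area >= 2]
    if len(props) < 2:
        raise MarkersNotFoundError(
            f"found {len(props)} marker blob(s) near ({cx:.0f}, {cy:.0f}); "
            "need 2"
        )
    props.sort(key=lambda p: p.area, reverse=True)
    if len(props) > 2 and props[2].area >= 0.5 * props[1].area:
        cands = [tuple(p.centroid[::-1]) for p in props[:4]]
        raise MarkerAmbiguityError(
            f"{len(props)} comparable marker blobs near ({cx:.0f}, {cy:.0f})",
            candidates=cands,
        )

    def refine(prop, radius=5, drop=60.0):
        # subpixel centroid: squared intensity-above-(peak - drop) weights
        # over a small box around the blob, robust against the darker
        # endplate edge just beside the marker
        iy, ix = (int(round(c)) for c in prop.centroid)
        y0r, y1r = max(iy - radius, 0), min(iy + radius + 1, window)
        x0r, x1r = max(ix - radius, 0), min(ix + radius + 1, window)
        loc = win[y0r:y1r, x0r:x1r]
        wgt = np.clip(loc - (loc.max() - drop), 0.0, None) ** 2
        yy, xx = np.mgrid[y0r:y1r, x0r:x1r]
        return (
            float((wgt * yy).sum() / wgt.sum()),
            float((wgt * xx).sum() / wgt.sum()),
        )

    (ay, ax), (by, bx) = refine(props[0]), refine(props[1])
    if ax > bx:
        (ay, ax), (by, bx) = (by, bx), (ay, ax)
    return math.degrees(math.atan2(ay - by, bx - ax))


def generate_dataset(
    n_radiographs: int,
    seed: int = 0,
    n_vertebrae: int = 17,
    slope_magnitude_range: tuple[float, float] = (5.0, 50.0),
    mean_magnitude: float = 15.0,
    curve_family: str = "single_curve",
    noise_level: float = 5.0,
) -> list[PhantomRadiograph]:
    """Generate ``n_radiographs`` independent phantoms from one seed."""
    children = np.random.SeedSequence(seed).spawn(n_radiographs)
    out = []
    for child in children:
        s_spec, s_render = child.generate_state(2) % np.uint64(2**31)
        spec = generate_spine_spec(
            n_vertebrae=n_vertebrae,
            slope_magnitude_range=slope_magnitude_range,
            mean_magnitude=mean_magnitude,
            curve_family=curve_family,
            seed=int(s_spec),
        )
        out.append(
            render_radiograph(
                spec, noise_level=noise_level, seed=int(s_render)
            )
        )
    return out


def truth_table(spec: SpineSpec) -> pd.DataFrame:
    """Ground-truth table in the documented CSV layout."""
    rows = [
        {
            "vertebra_label": v.label,
            "center_x": v.center[0],
            "center_y": v.center[1],
            "slope_deg": v.slope,
            "marker_lx": v.marker_left[0],
            "marker_ly": v.marker_left[1],
            "marker_rx": v.marker_right[0],
            "marker_ry": v.marker_right[1],
        }
        for v in spec.vertebrae
    ]
    return pd.DataFrame(rows)


def save_phantom(rad: PhantomRadiograph, png_path, csv_path) -> None:
    """Write the 8-bit grayscale PNG and its ground-truth CSV."""
    Image.fromarray(rad.image, mode="L").save(png_path)
    truth_table(rad.truth).to_csv(csv_path, index=False)


def load_truth(csv_path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    expected = {
        "vertebra_label", "center_x", "center_y", "slope_deg",
        "marker_lx", "marker_ly", "marker_rx", "marker_ry",
    }
    missing = expected - set(df.columns)
    if missing:
        raise ValidationError(f"truth CSV missing columns: {sorted(missing)}")
    return df
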