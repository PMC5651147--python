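"""Patch extraction pipeline: standardize, crop 150x150, downsample to 50x50.

Every training or inference sample is a 150x150-pixel window centered on
(or jittered around) a vertebra, reduced by a factor of three via 3x3
block averaging to a 50x50 grid and flattened row-major into a vector of
2500 gray levels scaled to [0, 1].
"""

from __future__ import annotations

import json
import zipfile
from dataclasses import dataclass, field

import numpy as np
from skimage.transform import resize

from .exceptions import DataIntegrityError, ValidationError
from .phantom import STANDARD_HEIGHT, PhantomRadiograph

PATCH_SIZE = 150
DOWNSAMPLED_SIZE = 50
PATCH_VECTOR_LEN = DOWNSAMPLED_SIZE * DOWNSAMPLED_SIZE
_HALF = PATCH_SIZE // 2


@dataclass(frozen=True)
class Patch:
    """One 2500-element patch vector with provenance and optional label."""

    vector: np.ndarray  # float, length 2500, values in [0, 1]
    source_radiograph: str
    vertebra_index: int
    offset: tuple[float, float]  # patch center minus vertebra center, px
    label: float | None = None  # slope in degrees


@dataclass
class PatchSet:
    """Columnar collection of patches.

    ``vectors`` is (n, 2500) float32; ``labels`` is (n,) float64 with NaN
    for unlabeled patches; provenance columns are parallel arrays.
    """

    vectors: np.ndarray
    labels: np.ndarray
    source_ids: np.ndarray
    vertebra_indices: np.ndarray
    offsets: np.ndarray  # (n, 2) dx, dy
    sampling_config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return self.vectors.shape[0]

    def __getitem__(self, i: int) -> Patch:
        lab = self.labels[i]
        return Patch(
            vector=self.vectors[i],
            source_radiograph=str(self.source_ids[i]),
            vertebra_index=int(self.vertebra_indices[i]),
            offset=tuple(self.offsets[i]),
            label=None if np.isnan(lab) else float(lab),
        )

    def validate(self) -> None:
        n = len(self)
        if self.vectors.ndim != 2 or self.vectors.shape[1] != PATCH_VECTOR_LEN:
            raise ValidationError(
                f"patch vectors must be (n, {PATCH_VECTOR_LEN}), "
                f"got {self.vectors.shape}"
            )
        if self.vectors.size and (
            self.vectors.min() < -1e-6 or self.vectors.max() > 1 + 1e-6
        ):
            raise ValidationError("patch values must lie in [0, 1]")
        for name in ("labels", "source_ids", "vertebra_indices"):
            if len(getattr(self, name)) != n:
                raise ValidationError(f"{name} length mismatch")
        if self.offsets.shape != (n, 2):
            raise ValidationError("offsets must be (n, 2)")

    def save(self, path) -> None:
        """Single-container .npz layout: arrays ``vectors`` (n,2500 f4),
        ``labels`` (n, f8, NaN = unlabeled), ``source_ids`` (n, unicode),
        ``vertebra_indices`` (n, i8), ``offsets`` (n,2 f8), plus a JSON
        ``header`` with the sampling config and format version."""
        header = json.dumps(
            {"format": "cobbnet-patchset", "version": 1,
             "sampling_config": self.sampling_config}
        )
        np.savez_compressed(
            path,
            header=np.array(header),
            vectors=self.vectors.astype(np.float32),
            labels=self.labels.astype(np.float64),
            source_ids=self.source_ids.astype(str),
            vertebra_indices=self.vertebra_indices.astype(np.int64),
            offsets=self.offsets.astype(np.float64),
        )
        # human-readable sidecar next to the container
        sidecar = str(path) + ".json"
        with open(sidecar, "w") as fh:
            json.dump({"sampling_config": self.sampling_config,
                       "n_patches": len(self)}, fh, indent=2)

    @classmethod
    def load(cls, path) -> "PatchSet":
        try:
            with np.load(path, allow_pickle=False) as z:
                header = json.loads(str(z["header"]))
                if header.get("format") != "cobbnet-patchset":
                    raise DataIntegrityError(
                        f"{path}: not a cobbnet patch container"
                    )
                ps = cls(
                    vectors=z["vectors"].astype(np.float32),
                    labels=z["labels"],
                    source_ids=z["source_ids"],
                    vertebra_indices=z["vertebra_indices"],
                    offsets=z["offsets"],
                    sampling_config=header.get("sampling_config", {}),
                )
        except (OSError, KeyError, ValueError, zipfile.BadZipFile,
                json.JSONDecodeError) as exc:
            raise DataIntegrityError(f"cannot read patch container {path}: {exc}")
        ps.validate()
        return ps


def standardize_image(image: np.ndarray) -> np.ndarray:
    """Resize a grayscale image to the standard 1000-px height, preserving
    aspect ratio (bilinear).  Identity if the image is already 1000 px
    high.  Returns uint8."""
    image = np.asarray(image)
    if image.ndim != 2 or image.size == 0:
        raise ValidationError("image must be a non-empty 2-D grayscale array")
    h, w = image.shape
    if h == STANDARD_HEIGHT:
        return image
    new_w = max(1, int(round(w * STANDARD_HEIGHT / h)))
    out = resize(
        image.astype(float), (STANDARD_HEIGHT, new_w), order=1,
        mode="edge", anti_aliasing=h > STANDARD_HEIGHT,
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def extract_patch(image: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """Exact 150x150 crop centered at ``center`` (0-based pixel indices;
    the window spans [c-75, c+75) in each axis)."""
    cx, cy = int(round(center[0])), int(round(center[1]))
    x0, y0 = cx - _HALF, cy - _HALF
    x1, y1 = x0 + PATCH_SIZE, y0 + PATCH_SIZE
    if x0 < 0 or y0 < 0 or y1 > image.shape[0] or x1 > image.shape[1]:
        raise ValidationError(
            f"patch window at ({cx}, {cy}) out of bounds; centers need a "
            f"{_HALF}-px margin on every side"
        )
    return image[y0:y1, x0:x1]


def downsample_patch(patch150: np.ndarray) -> np.ndarray:
    """Reduce a 150x150 patch by non-overlapping 3x3 block averaging to
    50x50, flatten row-major, and rescale intensities to [0, 1]."""
    patch150 = np.asarray(patch150)
    if patch150.shape != (PATCH_SIZE, PATCH_SIZE):
        raise ValidationError(
            f"expected a {PATCH_SIZE}x{PATCH_SIZE} patch, got {patch150.shape}"
        )
    blocks = patch150.astype(np.float64).reshape(
        DOWNSAMPLED_SIZE, 3, DOWNSAMPLED_SIZE, 3
    )
    small = blocks.mean(axis=(1, 3))
    return (small / 255.0).ravel()


def patch_vector(image: np.ndarray, center: tuple[float, float]) -> np.ndarray:
    """extract_patch followed by downsample_patch."""
    return downsample_patch(extract_patch(image, center))


@dataclass
class SamplingPlan:
    """All drawn patch placements for a sampling run (geometry only).

    The random part of the sampling protocol — one jittered patch center
    per requested patch — lives here; materializing pixel vectors from a
    plan is deterministic.  Patch count is exactly
    ``n_radiographs x n_vertebrae x patches_per_vertebra``.
    """

    radiograph_indices: np.ndarray
    source_ids: np.ndarray
    vertebra_indices: np.ndarray
    centers: np.ndarray  # (n, 2) jittered patch centers, pixels
    offsets: np.ndarray  # (n, 2) center minus vertebra center
    labels: np.ndarray  # ground-truth slopes, degrees
    sampling_config: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.labels)


def plan_patch_centers(
    radiographs: list[PhantomRadiograph],
    patches_per_vertebra: int = 100,
    jitter_radius: float = 15.0,
    seed: int = 0,
) -> SamplingPlan:
    """Draw every patch placement for the sampling protocol.

    For every vertebra of every radiograph, ``patches_per_vertebra``
    patch centers are drawn uniformly in the disk of radius
    ``jitter_radius`` around the vertebra center; a draw whose 150x150
    window would leave the image is re-drawn (after 100 failed draws the
    vertebra is reported).  Deterministic per seed.
    """
    if patches_per_vertebra < 1:
        raise ValidationError("patches_per_vertebra must be >= 1")
    if jitter_radius < 0:
        raise ValidationError("jitter_radius must be >= 0")
    rng = np.random.default_rng(seed)
    ridx, srcs, vidx, centers, offs, labels = [], [], [], [], [], []
    for r_i, rad in enumerate(radiographs):
        h, w = rad.image.shape
        src = f"phantom-{r_i:04d}"
        for v_i, vert in enumerate(rad.truth.vertebrae):
            cx, cy = vert.center
            for _ in range(patches_per_vertebra):
                for _attempt in range(100):
                    if jitter_radius > 0:
                        ang = rng.uniform(0, 2 * np.pi)
                        rr = jitter_radius * np.sqrt(rng.uniform())
                        dx, dy = rr * np.cos(ang), rr * np.sin(ang)
                    else:
                        dx = dy = 0.0
                    px, py = int(round(cx + dx)), int(round(cy + dy))
                    if (
                        _HALF <= px <= w - _HALF
                        and _HALF <= py <= h - _HALF
                    ):
                        break
                else:
                    raise ValidationError(
                        f"could not place a patch for vertebra {v_i} "
                        f"({vert.label}) of radiograph {r_i} after 100 draws"
                    )
                ridx.append(r_i)
                srcs.append(src)
                vidx.append(v_i)
                centers.append((cx + dx, cy + dy))
                offs.append((dx, dy))
                labels.append(vert.slope)
    return SamplingPlan(
        radiograph_indices=np.asarray(ridx, dtype=np.int64),
        source_ids=np.asarray(srcs),
        vertebra_indices=np.asarray(vidx, dtype=np.int64),
        centers=np.asarray(centers, dtype=np.float64),
        offsets=np.asarray(offs, dtype=np.float64),
        labels=np.asarray(labels, dtype=np.float64),
        sampling_config={
            "patches_per_vertebra": patches_per_vertebra,
            "jitter_radius": jitter_radius,
            "seed": seed,
            "n_radiographs": len(radiographs),
        },
    )


def materialize_plan(
    radiographs: list[PhantomRadiograph], plan: SamplingPlan
) -> PatchSet:
    """Extract and downsample every patch of a sampling plan."""
    n = len(plan)
    vectors = np.empty((n, PATCH_VECTOR_LEN), dtype=np.float32)
    for i in range(n):
        img = radiographs[plan.radiograph_indices[i]].image
        vectors[i] = patch_vector(img, plan.centers[i])
    ps = PatchSet(
        vectors=vectors,
        labels=plan.labels.copy(),
        source_ids=plan.source_ids.copy(),
        vertebra_indices=plan.vertebra_indices.copy(),
        offsets=plan.offsets.copy(),
        sampling_config=dict(plan.sampling_config),
    )
    ps.validate()
    return ps


def sample_training_patches(
    radiographs: list[PhantomRadiograph],
    patches_per_vertebra: int = 100,
    jitter_radius: float = 15.0,
    seed: int = 0,
) -> PatchSet:
    """Randomly extract labeled training patches from phantom radiographs.

    Draws a :func:`plan_patch_centers` placement plan and materializes
    it; each patch is labeled with its vertebra's ground-truth slope
    (labels are never affected by image noise).  Deterministic per seed.
    """
    plan = plan_patch_centers(
        radiographs, patches_per_vertebra=patches_per_vertebra,
        jitter_radius=jitter_radius, seed=seed,
    )
    return materialize_plan(radiographs, plan)


def centered_patches(radiographs: list[PhantomRadiograph]) -> PatchSet:
    """One exactly-centered labeled patch per vertebra (the evaluation
    protocol: n radiographs x 17 vertebrae)."""
    return sample_training_patches(
        radiographs, patches_per_vertebra=1, jitter_radius=0.0, seed=0
    )
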