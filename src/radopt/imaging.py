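"""Dataset manifests, image I/O, stochastic augmentation, ROI obfuscation.

Images are 299x299 8-bit rasters (the export size used for the radiographic
slices).  A dataset is a CSV manifest — one row per image with its patient,
modality (CT or MRI), class label (ACP or NOTACP), train/test split and file
path — plus the decoded images.  Augmented images carry a ``parent_image_id``
so provenance-aware cross-validation can keep a synthetic image and its parent
on the same side of a fold boundary.

The stochastic augmentation pipeline mirrors a standard four-stage recipe:
random grid distortion (p=0.75, 4x4 grid, magnitude 8 px), random 90-degree
rotation (p=0.75), random zoom (p=0.5, 80% area), random left-right flip
(p=0.5).  At test time the same stages are applied with all probabilities 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from PIL import Image
from scipy import ndimage

__all__ = [
    "IMAGE_SIZE",
    "ManifestRecord",
    "DatasetManifest",
    "RasterImage",
    "AugmentationStage",
    "AugmentationPipeline",
    "RegionMask",
    "build_default_pipeline",
    "grid_distort",
    "rotate90",
    "zoom",
    "flip_lr",
    "apply_pipeline",
    "oversample_class_balanced",
    "obfuscate",
    "load_dataset",
    "save_dataset",
]

IMAGE_SIZE = 299

MODALITIES = ("CT", "MRI")
CLASSES = ("ACP", "NOTACP")
SPLITS = ("train", "test")

_MANIFEST_COLUMNS = (
    "image_id",
    "patient_id",
    "modality",
    "class",
    "split",
    "path",
    "parent_image_id",
)


@dataclass(frozen=True)
class ManifestRecord:
    image_id: str
    patient_id: str
    modality: str
    class_label: str
    split: str
    path: str
    parent_image_id: str | None = None


@dataclass
class RasterImage:
    """A 299x299 grayscale (2-D) or RGB (3-plane) 8-bit image."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or px.shape[:2] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(
                f"image must be {IMAGE_SIZE}x{IMAGE_SIZE}, got shape {px.shape}"
            )
        if px.dtype != np.uint8:
            if not np.all(np.isfinite(px)):
                raise ValueError("image values must be finite")
            px = np.clip(np.rint(px), 0, 255).astype(np.uint8)
        self.pixels = px

    def copy(self) -> "RasterImage":
        return RasterImage(self.pixels.copy())


class DatasetManifest:
    """Ordered image records with structural invariants enforced on build.

    Invariants: image_ids unique; no patient appears in both train and test
    splits; every ``parent_image_id`` references an existing record.
    """

    def __init__(self, records: Sequence[ManifestRecord], check_parents: bool = True):
        self.records: tuple[ManifestRecord, ...] = tuple(records)
        self._check(check_parents)

    def _check(self, check_parents: bool = True) -> None:
        ids = [r.image_id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate image_id(s): {dupes[:5]}")
        id_set = set(ids)
        split_by_patient: dict[str, set[str]] = {}
        for r in self.records:
            if r.modality not in MODALITIES:
                raise ValueError(f"record {r.image_id}: bad modality {r.modality!r}")
            if r.class_label not in CLASSES:
                raise ValueError(f"record {r.image_id}: bad class {r.class_label!r}")
            if r.split not in SPLITS:
                raise ValueError(f"record {r.image_id}: bad split {r.split!r}")
            split_by_patient.setdefault(r.patient_id, set()).add(r.split)
            if check_parents and r.parent_image_id is not None and r.parent_image_id not in id_set:
                raise ValueError(
                    f"record {r.image_id}: parent {r.parent_image_id!r} not in manifest"
                )
        leaky = sorted(p for p, s in split_by_patient.items() if len(s) > 1)
        if leaky:
            raise ValueError(
                f"patient(s) appear in both train and test splits: {leaky[:5]}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, pred: Callable[[ManifestRecord], bool]) -> "DatasetManifest":
        # a subset is a view: parent references may point outside it
        return DatasetManifest(
            [r for r in self.records if pred(r)], check_parents=False
        )

    def split(self, which: str) -> "DatasetManifest":
        return self.subset(lambda r: r.split == which)

    @property
    def patient_ids(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.patient_id, None)
        return tuple(seen)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "image_id": [r.image_id for r in self.records],
                "patient_id": [r.patient_id for r in self.records],
                "modality": [r.modality for r in self.records],
                "class": [r.class_label for r in self.records],
                "split": [r.split for r in self.records],
                "path": [r.path for r in self.records],
                "parent_image_id": [r.parent_image_id or "" for r in self.records],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DatasetManifest":
        return cls(_records_from_frame(_require_columns(df)))


# `class` is a reserved word, so records are built via column access.
def _records_from_frame(df: pd.DataFrame) -> list[ManifestRecord]:
    records = []
    for _, row in df.iterrows():
        parent = row.get("parent_image_id", "")
        parent = None if (pd.isna(parent) or parent == "") else str(parent)
        records.append(
            ManifestRecord(
                image_id=str(row["image_id"]),
                patient_id=str(row["patient_id"]),
                modality=str(row["modality"]),
                class_label=str(row["class"]),
                split=str(row["split"]),
                path=str(row["path"]),
                parent_image_id=parent,
            )
        )
    return records


def _require_columns(df: pd.DataFrame) -> pd.DataFrame:
    missing = set(_MANIFEST_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing column(s): {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Augmentation operators
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class AugmentationStage:
    operator: str  # grid_distortion | rotate90 | zoom | flip_lr
    probability: float
    params: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must be in [0, 1]")


@dataclass(frozen=True)
class AugmentationPipeline:
    stages: tuple[AugmentationStage, ...]

    def with_all_probabilities(self, p: float) -> "AugmentationPipeline":
        return AugmentationPipeline(
            tuple(replace(s, probability=p) for s in self.stages)
        )


def build_default_pipeline() -> AugmentationPipeline:
    """The four-stage training-time augmentation recipe."""
    return AugmentationPipeline(
        (
            AugmentationStage(
                "grid_distortion", 0.75, {"grid_w": 4, "grid_h": 4, "magnitude": 8}
            ),
            AugmentationStage("rotate90", 0.75),
            AugmentationStage("zoom", 0.5, {"area_fraction": 0.8}),
            AugmentationStage("flip_lr", 0.5),
        )
    )


def build_test_pipeline() -> AugmentationPipeline:
    """Test-time sampling variant: same stages, all probabilities 1.0."""
    return build_default_pipeline().with_all_probabilities(1.0)


def _per_plane(pixels: np.ndarray, fn: Callable[[np.ndarray], np.ndarray]) -> np.ndarray:
    if pixels.ndim == 2:
        return fn(pixels)
    return np.stack([fn(pixels[..., k]) for k in range(pixels.shape[2])], axis=2)


def grid_distort(
    image: RasterImage,
    grid_w: int = 4,
    grid_h: int = 4,
    magnitude: float = 8,
    rng: np.random.Generator | None = None,
) -> RasterImage:
    """Random elastic-style distortion on a coarse control-point lattice.

    Control points sit on a (grid_w+1) x (grid_h+1) lattice spanning the
    image.  Each interior point is jittered independently and uniformly in
    [-magnitude, +magnitude] per coordinate; border points stay fixed so the
    frame is preserved.  The dense displacement field is the bilinear
    interpolation of the lattice displacements and the image is resampled
    through it bilinearly.
    """
    if grid_w < 1 or grid_h < 1:
        raise ValueError("grid must be at least 1x1")
    if magnitude < 0:
        raise ValueError("magnitude must be >= 0")
    if magnitude == 0:
        return image.copy()
    rng = np.random.default_rng() if rng is None else rng

    n = IMAGE_SIZE
    # lattice displacements: rows = grid_h+1 control rows, cols = grid_w+1
    disp = rng.uniform(-magnitude, magnitude, size=(grid_h + 1, grid_w + 1, 2))
    disp[0, :, :] = 0
    disp[-1, :, :] = 0
    disp[:, 0, :] = 0
    disp[:, -1, :] = 0

    # upsample lattice displacements to a dense per-pixel field (bilinear)
    ctrl_r = np.linspace(0, n - 1, grid_h + 1)
    ctrl_c = np.linspace(0, n - 1, grid_w + 1)
    rr = np.arange(n)
    cc = np.arange(n)
    # fractional lattice coordinates of each pixel
    fr = np.interp(rr, ctrl_r, np.arange(grid_h + 1))
    fc = np.interp(cc, ctrl_c, np.arange(grid_w + 1))
    field_r = ndimage.map_coordinates(
        disp[..., 0], np.meshgrid(fr, fc, indexing="ij"), order=1, mode="nearest"
    )
    field_c = ndimage.map_coordinates(
        disp[..., 1], np.meshgrid(fr, fc, indexing="ij"), order=1, mode="nearest"
    )

    coords_r = np.clip(rr[:, None] + field_r, 0, n - 1)
    coords_c = np.clip(cc[None, :] + field_c, 0, n - 1)

    def resample(plane: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(
            plane.astype(float), [coords_r, coords_c], order=1, mode="nearest"
        )

    return RasterImage(_per_plane(image.pixels, resample))


def rotate90(image: RasterImage, quarter_turns: int) -> RasterImage:
    """Rotate by quarter_turns x 90 degrees counterclockwise."""
    return RasterImage(np.rot90(image.pixels, k=quarter_turns % 4, axes=(0, 1)).copy())


def flip_lr(image: RasterImage) -> RasterImage:
    return RasterImage(image.pixels[:, ::-1].copy())


def zoom(
    image: RasterImage,
    area_fraction: float = 0.8,
    rng: np.random.Generator | None = None,
) -> RasterImage:
    """Crop a window of the given area fraction and rescale to full size.

    The window is centered, with its position uniformly jittered within the
    slack left by the crop; resampling back to 299x299 is bilinear.
    """
    if not 0 < area_fraction <= 1:
        raise ValueError("area_fraction must be in (0, 1]")
    rng = np.random.default_rng() if rng is None else rng
    n = IMAGE_SIZE
    side = max(1, int(round(n * math.sqrt(area_fraction))))
    if side >= n:
        return image.copy()
    slack = n - side
    r0 = int(rng.integers(0, slack + 1))
    c0 = int(rng.integers(0, slack + 1))

    def crop_and_scale(plane: np.ndarray) -> np.ndarray:
        window = plane[r0 : r0 + side, c0 : c0 + side].astype(float)
        src = np.linspace(0, side - 1, n)
        grid = np.meshgrid(src, src, indexing="ij")
        return ndimage.map_coordinates(window, grid, order=1, mode="nearest")

    return RasterImage(_per_plane(image.pixels, crop_and_scale))


def apply_pipeline(
    pipeline: AugmentationPipeline,
    image: RasterImage,
    rng: np.random.Generator,
) -> RasterImage:
    """Apply stages in order; each fires independently with its probability."""
    out = image
    for stage in pipeline.stages:
        fires = stage.probability >= 1.0 or rng.random() < stage.probability
        if not fires:
            continue
        if stage.operator == "grid_distortion":
            out = grid_distort(
                out,
                grid_w=int(stage.params.get("grid_w", 4)),
                grid_h=int(stage.params.get("grid_h", 4)),
                magnitude=float(stage.params.get("magnitude", 8)),
                rng=rng,
            )
        elif stage.operator == "rotate90":
            out = rotate90(out, int(rng.integers(1, 4)))
        elif stage.operator == "zoom":
            out = zoom(out, float(stage.params.get("area_fraction", 0.8)), rng=rng)
        elif stage.operator == "flip_lr":
            out = flip_lr(out)
        else:
            raise ValueError(f"unknown operator {stage.operator!r}")
    return out


# ---------------------------------------------------------------------------
# Oversampling and obfuscation
# ---------------------------------------------------------------------------


def oversample_class_balanced(
    manifest: DatasetManifest,
    images: Mapping[str, RasterImage],
    per_class_target: int,
    pipeline: AugmentationPipeline | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DatasetManifest, dict[str, RasterImage]]:
    """Expand the training split so each class has exactly ``per_class_target``
    images per modality.

    Originals are always retained; the remainder is filled with augmented
    copies whose parents are drawn uniformly with replacement from the
    class/modality pool.  Synthetic records inherit patient, class and
    modality from their parent and carry ``parent_image_id``.
    """
    pipeline = build_default_pipeline() if pipeline is None else pipeline
    rng = np.random.default_rng() if rng is None else rng

    train = [r for r in manifest.records if r.split == "train"]
    others = [r for r in manifest.records if r.split != "train"]
    new_records = list(manifest.records)
    new_images: dict[str, RasterImage] = dict(images)

    for modality in MODALITIES:
        for cls in CLASSES:
            pool = [
                r for r in train if r.modality == modality and r.class_label == cls
            ]
            if not pool and any(
                r.modality == modality for r in train
            ):
                raise ValueError(
                    f"no training images for class {cls} / modality {modality}"
                )
            if not pool:
                continue  # modality absent from this dataset entirely
            need = per_class_target - len(pool)
            for k in range(max(0, need)):
                parent = pool[int(rng.integers(len(pool)))]
                child_id = f"{parent.image_id}_aug{k:04d}"
                new_images[child_id] = apply_pipeline(
                    pipeline, images[parent.image_id], rng
                )
                new_records.append(
                    ManifestRecord(
                        image_id=child_id,
                        patient_id=parent.patient_id,
                        modality=modality,
                        class_label=cls,
                        split="train",
                        path="",
                        parent_image_id=parent.image_id,
                    )
                )
    return DatasetManifest(new_records), new_images


@dataclass(frozen=True)
class RegionMask:
    """Axis-aligned rectangle or ellipse region with a constant fill value."""

    shape: str  # rectangle | ellipse
    center: tuple[float, float]  # (row, col)
    half_extents: tuple[float, float]  # (rows, cols)
    fill: float = 0.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "ellipse"):
            raise ValueError(f"unknown mask shape {self.shape!r}")
        if min(self.half_extents) < 0:
            raise ValueError("half-extents must be >= 0")
        if not 0 <= self.fill <= 255:
            raise ValueError("fill value must be in [0, 255]")

    def boolean_mask(self, n: int = IMAGE_SIZE) -> np.ndarray:
        rr, cc = np.mgrid[0:n, 0:n]
        cr, ccen = self.center
        hr, hc = self.half_extents
        if self.shape == "rectangle":
            return (np.abs(rr - cr) <= hr) & (np.abs(cc - ccen) <= hc)
        if hr == 0 or hc == 0:
            return np.zeros((n, n), dtype=bool)
        return ((rr - cr) / hr) ** 2 + ((cc - ccen) / hc) ** 2 <= 1.0


def obfuscate(image: RasterImage, mask: RegionMask) -> RasterImage:
    """Set every pixel inside the mask to the fill value; others untouched."""
    out = image.pixels.copy()
    m = mask.boolean_mask(IMAGE_SIZE)
    fill = np.uint8(round(mask.fill))
    if out.ndim == 2:
        out[m] = fill
    else:
        out[m, :] = fill
    return RasterImage(out)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def load_dataset(
    manifest_path: str | Path,
) -> tuple[DatasetManifest, dict[str, RasterImage]]:
    """Load a CSV manifest and decode every referenced image file."""
    manifest_path = Path(manifest_path)
    df = pd.read_csv(manifest_path, dtype=str, keep_default_na=False)
    manifest = DatasetManifest.from_frame(df)
    images: dict[str, RasterImage] = {}
    for rec in manifest.records:
        p = Path(rec.path)
        if not p.is_absolute():
            p = manifest_path.parent / p
        if not p.is_file():
            raise FileNotFoundError(f"record {rec.image_id}: file not found: {p}")
        arr = np.asarray(Image.open(p))
        if arr.shape[:2] != (IMAGE_SIZE, IMAGE_SIZE):
            raise ValueError(
                f"record {rec.image_id}: expected {IMAGE_SIZE}x{IMAGE_SIZE}, "
                f"got {arr.shape}"
            )
        images[rec.image_id] = RasterImage(arr)
    return manifest, images


def save_dataset(
    manifest: DatasetManifest,
    images: Mapping[str, RasterImage],
    out_dir: str | Path,
    image_format: str = "png",
) -> Path:
    """Write images and a manifest CSV under ``out_dir``; returns the CSV path.

    PNG is the default on-disk format so that augmented intermediates survive
    a save/load round trip without recompression drift; JPEG is available for
    producing source-like inputs.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    img_dir.mkdir(parents=True, exist_ok=True)
    new_records = []
    for rec in manifest.records:
        fname = f"{rec.image_id}.{image_format}"
        Image.fromarray(images[rec.image_id].pixels).save(img_dir / fname)
        new_records.append(replace(rec, path=f"images/{fname}"))
    out = DatasetManifest(new_records)
    csv_path = out_dir / "manifest.csv"
    out.to_frame().to_csv(csv_path, index=False)
    return csv_path
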