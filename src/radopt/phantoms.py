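"""Patient-structured phantom image datasets and toy GA fitness landscapes.

The study cohort (preoperative CT and sagittal T1 MRI slices of sellar/
suprasellar lesions) is private, so these generators produce structurally
matched stand-ins: two classes whose difference lives inside a central
"sellar" region of interest, several images per patient per modality with
within-patient correlation, two modalities with distinct base textures, and an
optional extra-ROI confound whose sign tracks the class — the ingredient that
lets the obfuscation experiment show class signal surviving outside the ROI.

Class texture model (all on the 0-255 intensity scale):

* ACP phantoms add bright speckled blobs plus a ring inside the ROI — a crude
  analogue of calcification and a cyst rim.
* NOTACP phantoms add a single smooth Gaussian disc — a solid homogeneous mass.

Both patterns scale with ``signal_amplitude``: at amplitude 0 the classes are
identically distributed and any classifier sits at chance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np

from .imaging import (
    IMAGE_SIZE,
    DatasetManifest,
    ManifestRecord,
    RasterImage,
    RegionMask,
)
from .search_space import Genome, SearchSpace, random_genome

__all__ = [
    "PhantomConfig",
    "DEFAULT_ROI",
    "NOTACP_DIFFERENTIAL",
    "notacp_patient_total",
    "generate_phantom_dataset",
    "hidden_optimum_fitness",
]

#: Default "sellar" region of interest: a centered axis-aligned ellipse.
DEFAULT_ROI = RegionMask(
    shape="ellipse", center=(149.0, 149.0), half_extents=(55.0, 65.0), fill=0.0
)

#: Composition of the non-ACP differential diagnosis cohort the phantoms stand
#: in for: lesion type -> number of unique patients.  The total (47) matches
#: the NOTACP patient count whose train/test partition the default
#: :class:`PhantomConfig` reproduces.
NOTACP_DIFFERENTIAL: Mapping[str, int] = {
    "pilocytic astrocytoma": 12,
    "germinoma": 7,
    "pilomixoid astrocytoma": 6,
    "optic glioma": 4,
    "pituitary adenoma": 3,
    "arachnoid cyst": 3,
    "prolactinoma": 3,
    "mature teratoma": 2,
    "low grade glioma": 2,
    "renal cell carcinoma": 2,
    "Rathke's cyst": 1,
    "lipoma": 1,
    "Langerhans cell histiocytosis": 1,
}


def notacp_patient_total() -> int:
    """Total NOTACP patients implied by the differential composition."""
    return sum(NOTACP_DIFFERENTIAL.values())


@dataclass(frozen=True)
class PhantomConfig:
    """Generator settings for a two-class, two-modality phantom cohort.

    Defaults reproduce the study's dataset shape: 23 ACP + 30 NOTACP training
    patients with 3 images per patient per modality (318 training images) and
    16 ACP + 17 NOTACP test patients with 1 image per patient per modality
    (66 test images).
    """

    train_patients: Mapping[str, int] = field(
        default_factory=lambda: {"ACP": 23, "NOTACP": 30}
    )
    test_patients: Mapping[str, int] = field(
        default_factory=lambda: {"ACP": 16, "NOTACP": 17}
    )
    train_images_per_patient: int = 3
    test_images_per_patient: int = 1
    roi: RegionMask = DEFAULT_ROI
    signal_amplitude: float = 40.0
    noise_sd: float = 10.0
    confound_amplitude: float = 0.0
    modalities: tuple[str, ...] = ("CT", "MRI")
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.train_patients.values()) < 1 or min(self.test_patients.values()) < 1:
            raise ValueError("patient counts must be >= 1")
        if self.signal_amplitude < 0 or self.confound_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


def _base_texture(modality: str) -> np.ndarray:
    """Modality-specific deterministic background.

    CT: dark background with a bright circular rim (skull analogue).
    MRI: brighter background with a smooth low-frequency intensity field.
    The two differ in global statistics, so modality concatenation carries
    non-redundant information.
    """
    n = IMAGE_SIZE
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    r = np.hypot(rr - (n - 1) / 2, cc - (n - 1) / 2)
    if modality == "CT":
        base = np.full((n, n), 30.0)
        rim = np.exp(-((r - 135.0) ** 2) / (2 * 4.0**2))
        base += 110.0 * rim
        base[r > 141] = 5.0
    else:
        base = 85.0 + 15.0 * np.sin(rr / 37.0) * np.cos(cc / 53.0)
        base[r > 141] = 12.0
    return base


def _corner_gradient() -> np.ndarray:
    """Unit-amplitude wedge anchored at the top-left corner, zero near center."""
    n = IMAGE_SIZE
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    d = np.hypot(rr, cc)
    return np.maximum(0.0, 1.0 - d / 130.0)


def _render_acp(
    canvas: np.ndarray,
    roi: RegionMask,
    amplitude: float,
    blobs: np.ndarray,
    ring_radius: float,
    jitter: tuple[float, float],
) -> None:
    n = IMAGE_SIZE
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    cy = roi.center[0] + jitter[0]
    cx = roi.center[1] + jitter[1]
    r = np.hypot(rr - cy, cc - cx)
    # cyst-rim ring
    canvas += amplitude * np.exp(-((r - ring_radius) ** 2) / (2 * 2.0**2))
    # calcification speckle
    for by, bx, brad in blobs:
        d2 = (rr - (by + jitter[0])) ** 2 + (cc - (bx + jitter[1])) ** 2
        canvas += amplitude * np.exp(-d2 / (2 * brad**2))


def _render_notacp(
    canvas: np.ndarray,
    roi: RegionMask,
    amplitude: float,
    sigma: float,
    jitter: tuple[float, float],
) -> None:
    n = IMAGE_SIZE
    rr, cc = np.mgrid[0:n, 0:n].astype(float)
    cy = roi.center[0] + jitter[0]
    cx = roi.center[1] + jitter[1]
    d2 = (rr - cy) ** 2 + (cc - cx) ** 2
    canvas += amplitude * np.exp(-d2 / (2 * sigma**2))


def generate_phantom_dataset(
    config: PhantomConfig,
) -> tuple[DatasetManifest, dict[str, RasterImage]]:
    """Generate the phantom cohort: manifest plus in-memory images.

    Per-patient latent parameters (blob layout, lesion size, ROI offset) are
    drawn once per patient and shared by all of that patient's images with a
    small per-image jitter, so a patient's images are correlated — the
    property that makes patient-level cross-validation meaningfully different
    from image-level splitting.  Identical seeds regenerate byte-identical
    datasets.
    """
    rng = np.random.default_rng(config.seed)
    records: list[ManifestRecord] = []
    images: dict[str, RasterImage] = {}
    corner = _corner_gradient()
    bases = {m: _base_texture(m) for m in config.modalities}

    roi = config.roi
    hr, hc = roi.half_extents

    plan = [
        ("train", config.train_patients, config.train_images_per_patient),
        ("test", config.test_patients, config.test_images_per_patient),
    ]
    for split, patient_counts, n_images in plan:
        for cls in ("ACP", "NOTACP"):
            for p in range(patient_counts[cls]):
                pid = f"{cls.lower()}-{split}-{p:03d}"
                # patient-level latent structure
                pat_jitter = rng.uniform(-3, 3, size=2)
                if cls == "ACP":
                    n_blobs = 3 + int(rng.poisson(4))
                    # blob centers inside the ROI ellipse (rejection-free:
                    # polar sampling in the ellipse)
                    theta = rng.uniform(0, 2 * np.pi, n_blobs)
                    rad = np.sqrt(rng.uniform(0, 1, n_blobs))
                    by = roi.center[0] + 0.55 * hr * rad * np.sin(theta)
                    bx = roi.center[1] + 0.55 * hc * rad * np.cos(theta)
                    brad = rng.uniform(2.0, 4.0, n_blobs)
                    blobs = np.column_stack([by, bx, brad])
                    ring_radius = rng.uniform(0.30, 0.45) * min(hr, hc)
                else:
                    sigma = rng.uniform(10.0, 16.0)
                for m in config.modalities:
                    for k in range(n_images):
                        img_jitter = (
                            pat_jitter[0] + rng.uniform(-1.5, 1.5),
                            pat_jitter[1] + rng.uniform(-1.5, 1.5),
                        )
                        amp_scale = 1.0 + 0.05 * rng.standard_normal()
                        canvas = bases[m].copy()
                        amp = config.signal_amplitude * max(amp_scale, 0.0)
                        if cls == "ACP":
                            _render_acp(
                                canvas, roi, amp, blobs, ring_radius, img_jitter
                            )
                        else:
                            _render_notacp(canvas, roi, amp, sigma, img_jitter)
                        if config.confound_amplitude > 0:
                            sign = 1.0 if cls == "ACP" else -1.0
                            canvas += sign * config.confound_amplitude * corner
                        canvas += rng.normal(0.0, config.noise_sd, canvas.shape)
                        iid = f"{pid}-{m.lower()}-{k}"
                        images[iid] = RasterImage(canvas)
                        records.append(
                            ManifestRecord(
                                image_id=iid,
                                patient_id=pid,
                                modality=m,
                                class_label=cls,
                                split=split,
                                path="",
                                parent_image_id=None,
                            )
                        )
    return DatasetManifest(records), images


def hidden_optimum_fitness(
    space: SearchSpace, seed: int
) -> Callable[[Genome], float]:
    """Toy fitness landscape for exercising the genetic algorithm.

    Draws a secret target genome and scores any genome by the fraction of axes
    on which it matches the target (range [0, 1]); the target itself is the
    unique global optimum with fitness 1.  Deterministic per seed; the target
    is exposed as the returned function's ``target`` attribute.
    """
    rng = np.random.default_rng(seed)
    target = random_genome(space, rng)
    n_axes = len(space.axes)

    def fitness(genome: Genome) -> float:
        matches = sum(
            genome.choices[ax.name] == target.choices[ax.name] for ax in space.axes
        )
        return matches / n_axes

    fitness.target = target  # type: ignore[attr-defined]
    return fitness
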