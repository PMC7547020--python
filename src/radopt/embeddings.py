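"""Feature-embedding layer: network registry, mock extractor, adapters.

Pretrained ImageNet networks are used only as fixed feature extractors
("image signatures"): an image goes in, a dense one-dimensional vector comes
out, and a shallow classifier is trained on those vectors.  The deep networks
themselves are deliberately not bundled or executed here — the registry records
their names and output dimensions, and externally computed vectors can be read
from a delimited table.  A deterministic, locality-sensitive mock extractor
provides a fully offline backend so every downstream component (classifier,
genetic search, cross-validation, obfuscation experiments) runs end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .imaging import DatasetManifest, RasterImage

__all__ = [
    "ExtractorSpec",
    "EmbeddingMatrix",
    "extractor_registry",
    "get_extractor",
    "mock_extractor",
    "embed_dataset",
    "read_external_embeddings",
    "write_external_embeddings",
    "concat_ct_mri",
]

#: Pretrained ImageNet classification networks available as feature-vector
#: backends, with the length of the penultimate-layer embedding each produces.
_REGISTRY_ROWS: tuple[tuple[str, int], ...] = (
    ("Inception V1", 1024),
    ("Inception V2", 1024),
    ("Inception V3", 2048),
    ("Inception ResNet V2", 1536),
    ("ResNet V1 50", 2048),
    ("ResNet V1 101", 2048),
    ("ResNet V1 152", 2048),
    ("ResNet V2 50", 2048),
    ("ResNet V2 101", 2048),
    ("ResNet V2 152", 2048),
    ("NASNet-A Large", 4032),
    ("PNASNet-5 Large", 4320),
)

_MOCK_GRID = 8  # mock extractor pools statistics on an 8x8 cell grid


@dataclass(frozen=True)
class ExtractorSpec:
    """A named feature-extraction backend.

    ``backend`` is ``"external"`` for registry networks whose vectors are
    computed elsewhere and loaded from a table, or ``"mock"`` for the built-in
    deterministic extractor.
    """

    name: str
    output_dim: int
    backend: str = "external"
    params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.output_dim <= 0:
            raise ValueError("output_dim must be positive")
        if self.backend not in ("external", "mock"):
            raise ValueError(f"unknown backend {self.backend!r}")


@dataclass
class EmbeddingMatrix:
    """Per-image feature vectors, row-aligned to an ordered id index."""

    values: np.ndarray  # (n_rows, dim)
    row_index: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if self.values.shape[0] != len(self.row_index):
            raise ValueError("row count must match row_index length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("embedding values must be finite")

    @property
    def dim(self) -> int:
        return self.values.shape[1]

    def row(self, image_id: str) -> np.ndarray:
        return self.values[self.row_index.index(image_id)]

    def subset(self, ids: Sequence[str]) -> "EmbeddingMatrix":
        pos = {iid: i for i, iid in enumerate(self.row_index)}
        idx = [pos[i] for i in ids]
        return EmbeddingMatrix(self.values[idx], tuple(ids))


def extractor_registry() -> list[ExtractorSpec]:
    """The twelve pretrained networks usable as embedding backends."""
    return [ExtractorSpec(name, dim, backend="external") for name, dim in _REGISTRY_ROWS]


def get_extractor(name: str) -> ExtractorSpec:
    for spec in extractor_registry():
        if spec.name == name:
            return spec
    valid = ", ".join(n for n, _ in _REGISTRY_ROWS)
    raise KeyError(f"unknown extractor {name!r}; valid names: {valid}")


def mock_extractor(dim: int = 64, seed: int = 0) -> ExtractorSpec:
    """Deterministic offline extractor for tests and phantom experiments.

    Pools per-cell mean and standard deviation on an 8x8 grid (128 raw
    features) and projects them through a fixed seed-derived linear map to
    ``dim`` outputs.  The grid pooling makes the features locality-sensitive,
    so masking an image region visibly removes the corresponding information —
    a property the obfuscation experiments rely on.
    """
    if dim < 2:
        raise ValueError("dim must be >= 2")
    return ExtractorSpec(f"mock-{dim}-{seed}", dim, backend="mock", params={"seed": seed})


def mock_raw_features(pixels: np.ndarray) -> np.ndarray:
    """Per-cell (mean, std) on the mock extractor's grid, before projection.

    Intensities are first scaled to [0, 1] so the pooled features (and hence
    the projected embeddings) are O(1), matching the scale of real pretrained
    embedding vectors.
    """
    img = np.asarray(pixels, dtype=float) / 255.0
    if img.ndim == 3:  # average color planes
        img = img.mean(axis=2)
    h, w = img.shape
    rows = np.array_split(np.arange(h), _MOCK_GRID)
    cols = np.array_split(np.arange(w), _MOCK_GRID)
    feats = np.empty(2 * _MOCK_GRID * _MOCK_GRID)
    k = 0
    for r in rows:
        for c in cols:
            cell = img[np.ix_(r, c)]
            feats[k] = cell.mean()
            feats[k + 1] = cell.std()
            k += 2
    return feats


def _dihedral_orbits(g: int = _MOCK_GRID) -> list[list[int]]:
    """Orbits of grid cells under the 90-degree rotation / flip group."""
    seen: set[int] = set()
    orbits: list[list[int]] = []
    for i in range(g):
        for j in range(g):
            if i * g + j in seen:
                continue
            orbit: set[tuple[int, int]] = set()
            cell = (i, j)
            for _ in range(4):
                cell = (cell[1], g - 1 - cell[0])  # rotate 90
                orbit.add(cell)
                orbit.add((cell[0], g - 1 - cell[1]))  # + left-right flip
            idx = sorted(a * g + b for a, b in orbit)
            orbits.append(idx)
            seen.update(idx)
    return orbits


def _mock_projection(dim: int, seed: int) -> np.ndarray:
    """Fixed linear map from the 128 pooled statistics to ``dim`` outputs.

    The leading output dimensions are orbit averages of the cell statistics
    under the rotation/flip symmetry group — features that are (approximately)
    invariant to the right-angle rotations and flips of the augmentation
    pipeline, the way deep embeddings are largely insensitive to those
    transforms.  Remaining dimensions are seed-derived random projections of
    all 128 statistics, which keep full spatial specificity.
    """
    rng = np.random.default_rng(seed)
    raw = 2 * _MOCK_GRID * _MOCK_GRID
    proj = rng.standard_normal((raw, dim)) / np.sqrt(raw)
    orbits = _dihedral_orbits()
    col = 0
    for stat_offset in (0, 1):  # cell means, then cell stds
        for orbit in orbits:
            if col >= dim:
                break
            proj[:, col] = 0.0
            for cell in orbit:
                proj[2 * cell + stat_offset, col] = 1.0 / len(orbit)
            col += 1
    return proj


def _embed_mock(images: Mapping[str, RasterImage], ids: Sequence[str], spec: ExtractorSpec) -> np.ndarray:
    proj = _mock_projection(spec.output_dim, int(spec.params["seed"]))
    out = np.empty((len(ids), spec.output_dim))
    for i, iid in enumerate(ids):
        out[i] = mock_raw_features(images[iid].pixels) @ proj
    return out


def embed_dataset(
    images: Mapping[str, RasterImage],
    manifest: DatasetManifest,
    spec: ExtractorSpec,
    external_table: pd.DataFrame | None = None,
) -> EmbeddingMatrix:
    """Embed every manifest record, preserving manifest row order.

    For the mock backend vectors are computed directly from pixels; for an
    external backend ``external_table`` must hold one precomputed vector per
    image_id (first column image_id, remaining columns the vector).
    """
    ids = [rec.image_id for rec in manifest.records]
    if spec.backend == "mock":
        values = _embed_mock(images, ids, spec)
    else:
        if external_table is None:
            raise ValueError(
                f"extractor {spec.name!r} is external: supply a precomputed table"
            )
        table = external_table.set_index(external_table.columns[0])
        missing = [i for i in ids if i not in table.index]
        if missing:
            raise KeyError(f"external table missing image_id(s): {missing[:5]}")
        values = table.loc[ids].to_numpy(dtype=float)
        if values.shape[1] != spec.output_dim:
            raise ValueError(
                f"external vectors have dim {values.shape[1]}, "
                f"expected {spec.output_dim}"
            )
    return EmbeddingMatrix(values, tuple(ids))


def read_external_embeddings(path: str | Path) -> pd.DataFrame:
    """Read a delimited embedding table (first column image_id)."""
    return pd.read_csv(path, sep="\t")


def write_external_embeddings(emb: EmbeddingMatrix, path: str | Path, name: str) -> None:
    cols = [f"{name}_{i}" for i in range(emb.dim)]
    df = pd.DataFrame(emb.values, columns=cols)
    df.insert(0, "image_id", list(emb.row_index))
    df.to_csv(path, sep="\t", index=False)


def concat_ct_mri(
    emb_ct: EmbeddingMatrix,
    emb_mri: EmbeddingMatrix,
    manifest: DatasetManifest,
) -> EmbeddingMatrix:
    """Concatenate per-patient CT and MRI embeddings along the feature axis.

    Images are grouped by patient and, within a patient and modality, ordered
    by image_id; the k-th CT image pairs with the k-th MRI image.  Patients
    must have the same number of images in both modalities.  Output rows are
    labeled ``patient_id#k`` (just ``patient_id`` when a patient has a single
    pair, as in a one-image-per-modality test set).
    """
    by_mod: dict[str, dict[str, list[str]]] = {"CT": {}, "MRI": {}}
    for rec in manifest.records:
        by_mod[rec.modality].setdefault(rec.patient_id, []).append(rec.image_id)
    ct_pat, mri_pat = set(by_mod["CT"]), set(by_mod["MRI"])
    if not (ct_pat & mri_pat):
        raise ValueError("no patients present in both modalities")
    lonely = sorted(ct_pat ^ mri_pat)
    if lonely:
        raise ValueError(f"patient(s) present in one modality only: {lonely}")

    rows, labels = [], []
    for pid in sorted(ct_pat):
        ct_ids = sorted(by_mod["CT"][pid])
        mri_ids = sorted(by_mod["MRI"][pid])
        if len(ct_ids) != len(mri_ids):
            raise ValueError(
                f"patient {pid!r} has {len(ct_ids)} CT but {len(mri_ids)} MRI images"
            )
        for k, (cid, mid) in enumerate(zip(ct_ids, mri_ids)):
            rows.append(np.concatenate([emb_ct.row(cid), emb_mri.row(mid)]))
            labels.append(pid if len(ct_ids) == 1 else f"{pid}#{k}")
    return EmbeddingMatrix(np.vstack(rows), tuple(labels))
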