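"""End-to-end wiring: genome -> data variants -> embeddings -> trained head -> AUC.

An :class:`EvaluationBundle` owns a dataset (manifest + images), resolves the
train/test dataset variants a genome can choose ("original", "aug100",
"aug1000" for training; "original", "aug10", "aug100" for test) into embedded
matrices — materializing and caching the augmented variants on first use — and
turns a genome into a classifier config, a training run, and an AUC fitness on
the genome's test variant.

Dataset variants:

* train ``augN`` — the training split oversampled with the stochastic pipeline
  to N images per class per modality (originals retained).
* test ``augN`` — every test image replicated N times through the same pipeline
  with all stage probabilities set to 1.0.

The per-variant augmentation seeds derive from the bundle seed, so a bundle is
a fixed dataset: two evaluations of the same genome see identical data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .classifier import ClassifierConfig, predict_classes, predict_scores, train_classifier
from .embeddings import (
    EmbeddingMatrix,
    ExtractorSpec,
    concat_ct_mri,
    embed_dataset,
    mock_extractor,
)
from .evaluation import accuracy, roc_auc
from .ga import derive_eval_seed
from .imaging import (
    AugmentationPipeline,
    DatasetManifest,
    ManifestRecord,
    RasterImage,
    apply_pipeline,
    build_default_pipeline,
    build_test_pipeline,
    oversample_class_balanced,
)
from .search_space import Genome, SearchSpace

__all__ = ["EvaluationBundle", "genome_to_classifier_config"]

TRAIN_TARGETS = {"aug100": 100, "aug1000": 1000}
TEST_REPLICATES = {"aug10": 10, "aug100": 100}


def genome_to_classifier_config(
    genome: Genome, space: SearchSpace, seed: int
) -> ClassifierConfig:
    """Translate a genome's axis payloads into a classifier configuration."""
    p = genome.payloads(space)
    return ClassifierConfig(
        activation=str(p["activation"]),
        keep_prob=float(p["dropout_keep"]),
        reg_mode=str(p["regularization"]),
        optimizer=dict(p["optimizer"]),
        learning_rate=float(p["learning_rate"]),
        batch_size=int(p["batch_size"]),
        epochs=int(p["epochs"]),
        seed=seed,
    )


@dataclass
class _Resolved:
    x: np.ndarray
    labels: list[str]
    ids: list[str]


class EvaluationBundle:
    """Dataset + embedding backend that resolves genome data choices.

    Parameters
    ----------
    manifest, images:
        The base dataset (original images only; train and test splits).
    space:
        The search space the genomes belong to.
    modality:
        "CT", "MRI", or "CT-MRI" (per-patient embedding concatenation).
    extractor_factory:
        Maps a network axis label to an :class:`ExtractorSpec`.  The default
        assigns every network name its own deterministic mock extractor, so
        different network choices genuinely produce different embeddings.
    aug_targets / test_replicates:
        Per-class oversampling targets and test replication counts for the
        dataset-variant labels.  Defaults are the standard 100/1000 and
        10/100; smaller values let experiments run at reduced scale.
    """

    def __init__(
        self,
        manifest: DatasetManifest,
        images: Mapping[str, RasterImage],
        space: SearchSpace,
        modality: str = "CT",
        extractor_factory=None,
        pipeline: AugmentationPipeline | None = None,
        seed: int = 0,
        mock_dim: int = 32,
        aug_targets: Mapping[str, int] | None = None,
        test_replicates: Mapping[str, int] | None = None,
    ):
        if modality not in ("CT", "MRI", "CT-MRI"):
            raise ValueError(f"unknown modality {modality!r}")
        self.manifest = manifest
        self.images = dict(images)
        self.space = space
        self.modality = modality
        self.pipeline = build_default_pipeline() if pipeline is None else pipeline
        self.seed = seed
        self.mock_dim = mock_dim
        self.aug_targets = dict(TRAIN_TARGETS if aug_targets is None else aug_targets)
        self.test_replicates = dict(
            TEST_REPLICATES if test_replicates is None else test_replicates
        )
        self._extractor_factory = extractor_factory or self._default_extractor
        self._variant_cache: dict[tuple, tuple[DatasetManifest, dict]] = {}
        self._embed_cache: dict[tuple, _Resolved] = {}

    # -- extractors --------------------------------------------------------

    def _default_extractor(self, network: str) -> ExtractorSpec:
        # derived from the name bytes so it is stable across processes
        name_seed = int.from_bytes(network.encode(), "little") % (2**31)
        return mock_extractor(dim=self.mock_dim, seed=name_seed)

    # -- dataset variants ---------------------------------------------------

    def _train_variant(self, variant: str) -> tuple[DatasetManifest, dict]:
        key = ("train", variant)
        if key not in self._variant_cache:
            train = self.manifest.split("train")
            if variant == "original":
                self._variant_cache[key] = (train, self.images)
            else:
                target = self.aug_targets[variant]
                rng = np.random.default_rng((self.seed, 1, target))
                self._variant_cache[key] = oversample_class_balanced(
                    train, self.images, target, self.pipeline, rng
                )
        return self._variant_cache[key]

    def _test_variant(self, variant: str) -> tuple[DatasetManifest, dict]:
        key = ("test", variant)
        if key not in self._variant_cache:
            test = self.manifest.split("test")
            if variant == "original":
                self._variant_cache[key] = (test, self.images)
            else:
                reps = self.test_replicates[variant]
                rng = np.random.default_rng((self.seed, 2, reps))
                tta = build_test_pipeline()
                records = list(test.records)
                imgs: dict[str, RasterImage] = {
                    r.image_id: self.images[r.image_id] for r in test.records
                }
                for rec in test.records:
                    for k in range(reps):
                        iid = f"{rec.image_id}_tta{k:03d}"
                        imgs[iid] = apply_pipeline(
                            tta, self.images[rec.image_id], rng
                        )
                        records.append(
                            ManifestRecord(
                                image_id=iid,
                                patient_id=rec.patient_id,
                                modality=rec.modality,
                                class_label=rec.class_label,
                                split="test",
                                path="",
                                parent_image_id=rec.image_id,
                            )
                        )
                self._variant_cache[key] = (DatasetManifest(records), imgs)
        return self._variant_cache[key]

    # -- embedding ----------------------------------------------------------

    def _embed(self, side: str, variant: str, network: str) -> _Resolved:
        key = (side, variant, network)
        if key in self._embed_cache:
            return self._embed_cache[key]
        manifest, imgs = (
            self._train_variant(variant)
            if side == "train"
            else self._test_variant(variant)
        )
        if side == "test" and variant != "original":
            # replicated test sets are scored on the synthetic copies only
            manifest = manifest.subset(lambda r: r.parent_image_id is not None)
        spec = self._extractor_factory(network)

        if self.modality in ("CT", "MRI"):
            sub = manifest.subset(lambda r: r.modality == self.modality)
            emb = embed_dataset(imgs, sub, spec)
            labels = [r.class_label for r in sub.records]
            resolved = _Resolved(emb.values, labels, list(emb.row_index))
        else:
            cls_of_patient = {
                r.patient_id: r.class_label for r in manifest.records
            }
            ct = manifest.subset(lambda r: r.modality == "CT")
            mri = manifest.subset(lambda r: r.modality == "MRI")
            emb_ct = embed_dataset(imgs, ct, spec)
            emb_mri = embed_dataset(imgs, mri, spec)
            paired = _pair_truncated(emb_ct, emb_mri, manifest)
            labels = [
                cls_of_patient[rid.split("#")[0]] for rid in paired.row_index
            ]
            resolved = _Resolved(paired.values, labels, list(paired.row_index))
        self._embed_cache[key] = resolved
        return resolved

    # -- evaluation ---------------------------------------------------------

    def evaluate_genome(
        self, genome: Genome, eval_seed: int
    ) -> tuple[float, float]:
        """Train the genome's classifier and return (AUC, accuracy) on the
        genome's test-dataset variant."""
        genome.validate(self.space)
        p = genome.payloads(self.space)
        tr = self._embed("train", str(p["train_dataset"]), str(p["network"]))
        te = self._embed("test", str(p["test_dataset"]), str(p["network"]))
        config = genome_to_classifier_config(genome, self.space, eval_seed)
        clf = train_classifier(tr.x, tr.labels, config)
        scores = predict_scores(clf, te.x)
        preds = predict_classes(clf, te.x)
        return roc_auc(te.labels, scores).area, accuracy(te.labels, preds)

    def fitness_fn(self):
        """Adapter with the (genome, eval_seed) -> (fitness, accuracy) shape
        the evolutionary search expects."""

        def fn(genome: Genome, eval_seed: int):
            return self.evaluate_genome(genome, eval_seed)

        return fn


def _pair_truncated(
    emb_ct: EmbeddingMatrix, emb_mri: EmbeddingMatrix, manifest: DatasetManifest
) -> EmbeddingMatrix:
    """Per-patient CT-MRI pairing tolerant of unequal per-patient counts.

    Oversampled variants give patients random numbers of synthetic images per
    modality; images are sorted by image_id within patient and modality and
    paired index-wise up to the smaller count.
    """
    by_mod: dict[str, dict[str, list[str]]] = {"CT": {}, "MRI": {}}
    for rec in manifest.records:
        by_mod[rec.modality].setdefault(rec.patient_id, []).append(rec.image_id)
    common = sorted(set(by_mod["CT"]) & set(by_mod["MRI"]))
    if not common:
        raise ValueError("no patients present in both modalities")
    rows, labels = [], []
    for pid in common:
        ct_ids = sorted(by_mod["CT"][pid])
        mri_ids = sorted(by_mod["MRI"][pid])
        n = min(len(ct_ids), len(mri_ids))
        for k in range(n):
            rows.append(
                np.concatenate([emb_ct.row(ct_ids[k]), emb_mri.row(mri_ids[k])])
            )
            labels.append(pid if n == 1 else f"{pid}#{k}")
    return EmbeddingMatrix(np.vstack(rows), tuple(labels))
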