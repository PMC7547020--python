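"""Generate a phantom two-class cohort and oversample its training split.

The phantom generator mimics the shape of a pediatric sellar-lesion study:
23 ACP and 30 NOTACP training patients with 3 images per patient per modality
(318 training images) and 16 + 17 test patients with one image each per
modality (66 test images).  The stochastic augmentation pipeline (grid
distortion, right-angle rotation, zoom, horizontal flip) then oversamples each
class to a fixed per-class target.
"""

import numpy as np

from radopt import (
    PhantomConfig,
    build_default_pipeline,
    generate_phantom_dataset,
    oversample_class_balanced,
)

manifest, images = generate_phantom_dataset(PhantomConfig(seed=0))
train = manifest.split("train")
test = manifest.split("test")
print(f"training images: {len(train)}  test images: {len(test)}")

for cls in ("ACP", "NOTACP"):
    pats = {r.patient_id for r in train.records if r.class_label == cls}
    print(f"  train {cls}: {len(pats)} patients")

target = 100  # per class per modality; the full-scale experiments use 1000
aug_manifest, aug_images = oversample_class_balanced(
    train, images, target, build_default_pipeline(), np.random.default_rng(0)
)
print(f"\nafter oversampling to {target} per class per modality:")
for modality in ("CT", "MRI"):
    for cls in ("ACP", "NOTACP"):
        n = sum(
            1
            for r in aug_manifest.records
            if r.modality == modality and r.class_label == cls
        )
        print(f"  {modality} {cls}: {n} images")

n_synth = sum(1 for r in aug_manifest.records if r.parent_image_id is not None)
print(f"synthetic images added: {n_synth}")
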