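"""Compare the three five-fold cross-validation designs on one dataset.

Scenario 1 pools originals with augmented images and splits folds at the
image level, so synthetic descendants of a validation image can appear in its
training fold — a deliberate leak that inflates the estimate.  Scenario 2
splits folds at the patient level and admits augmented images only into
training folds; scenario 3 uses patient-level folds on originals only.
"""

import numpy as np

from radopt import (
    ClassifierConfig,
    PhantomConfig,
    build_default_pipeline,
    embed_dataset,
    find_parent_leakage,
    generate_phantom_dataset,
    make_cv_plan,
    mock_extractor,
    oversample_class_balanced,
    run_cv,
)

config = PhantomConfig(
    train_patients={"ACP": 8, "NOTACP": 8},
    test_patients={"ACP": 1, "NOTACP": 1},
    train_images_per_patient=3,
    signal_amplitude=10.0,  # moderate signal: leakage has room to inflate
    noise_sd=10.0,
    modalities=("CT",),
    seed=0,
)
manifest, images = generate_phantom_dataset(config)
aug_manifest, aug_images = oversample_class_balanced(
    manifest.split("train"), images, 96, build_default_pipeline(),
    np.random.default_rng(0),
)
emb = embed_dataset(aug_images, aug_manifest, mock_extractor(dim=128, seed=0))
clf_config = ClassifierConfig(epochs=400, learning_rate=0.1, seed=0)

print("scenario  mean AUC  pooled AUC  leaked train/val pairs")
for scenario in (1, 2, 3):
    plan = make_cv_plan(
        aug_manifest, k=5, scenario=scenario, rng=np.random.default_rng(1)
    )
    leaks = find_parent_leakage(plan, aug_manifest)
    result = run_cv(plan, emb, aug_manifest, clf_config)
    print(
        f"   {scenario}      {result.mean_auc:7.3f}   {result.pooled_auc:7.3f}"
        f"     {len(leaks)}"
    )
print(
    "\nscenario 1 shares image origins across the fold line (leaks > 0) and"
    "\nreads higher; scenarios 2-3 are patient-sound (leaks = 0)."
)
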