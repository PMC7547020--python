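"""Localize the class signal by masking the region of interest.

Every image's central "sellar" ellipse is replaced with a constant fill, and
the classifier is retrained and re-evaluated on the masked data.  When the
class difference lives only inside the ROI the AUC collapses toward chance;
when a class-correlated confound exists outside the ROI (here a corner
gradient whose sign tracks the class), the masked-data AUC stays high — the
signature of a classifier leaning on extra-ROI information.
"""

from radopt import (
    ClassifierConfig,
    DEFAULT_ROI,
    PhantomConfig,
    embed_dataset,
    generate_phantom_dataset,
    mock_extractor,
    obfuscate,
    predict_scores,
    roc_auc,
    train_classifier,
)


def holdout_auc(confound_amplitude, mask_roi, seed=0):
    config = PhantomConfig(
        train_patients={"ACP": 10, "NOTACP": 10},
        test_patients={"ACP": 8, "NOTACP": 8},
        train_images_per_patient=2,
        test_images_per_patient=1,
        signal_amplitude=40.0,
        confound_amplitude=confound_amplitude,
        noise_sd=10.0,
        modalities=("CT",),
        seed=seed,
    )
    manifest, images = generate_phantom_dataset(config)
    if mask_roi:
        images = {iid: obfuscate(img, DEFAULT_ROI) for iid, img in images.items()}
    extractor = mock_extractor(dim=32, seed=0)
    train, test = manifest.split("train"), manifest.split("test")
    emb_train = embed_dataset(images, train, extractor)
    emb_test = embed_dataset(images, test, extractor)
    clf = train_classifier(
        emb_train.values,
        [r.class_label for r in train.records],
        ClassifierConfig(epochs=200, learning_rate=0.1, seed=seed),
    )
    labels = [r.class_label for r in test.records]
    return roc_auc(labels, predict_scores(clf, emb_test.values)).area


print("condition                              AUC")
print(f"intact images, no confound           {holdout_auc(0.0, False):.3f}")
print(f"ROI masked, no confound              {holdout_auc(0.0, True):.3f}")
print(f"intact images, corner confound       {holdout_auc(30.0, False):.3f}")
print(f"ROI masked, corner confound          {holdout_auc(30.0, True):.3f}")
print(
    "\nmasking kills the AUC only when the class signal is confined to the"
    "\nROI; an extra-ROI confound keeps the masked classifier well above"
    "\nchance."
)
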