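"""Train the single-layer embedding classifier and evaluate it hold-out.

Images are reduced to fixed-length feature vectors ("image signatures") by an
extractor — here the deterministic offline mock; in a full-scale study, a
pretrained network's penultimate layer — and a one-layer softmax head is
trained on those vectors.  The test metric is the area under the ROC curve
with ACP as the positive class.
"""

from radopt import (
    ClassifierConfig,
    PhantomConfig,
    embed_dataset,
    generate_phantom_dataset,
    mock_extractor,
    predict_classes,
    predict_scores,
    roc_auc,
    train_classifier,
)
from radopt.evaluation import accuracy

manifest, images = generate_phantom_dataset(PhantomConfig(seed=0))
extractor = mock_extractor(dim=32, seed=0)

train = manifest.split("train").subset(lambda r: r.modality == "CT")
test = manifest.split("test").subset(lambda r: r.modality == "CT")
emb_train = embed_dataset(images, train, extractor)
emb_test = embed_dataset(images, test, extractor)
print(f"embedded {len(train)} train / {len(test)} test CT images, dim {emb_train.dim}")

config = ClassifierConfig(
    activation="softmax",
    optimizer={"name": "Gradient Descent"},
    learning_rate=0.1,
    epochs=200,
    seed=0,
)
clf = train_classifier(
    emb_train.values, [r.class_label for r in train.records], config
)
print(
    f"loss: {clf.loss_trace[0]:.4f} (epoch 1) -> {clf.loss_trace[-1]:.4f} "
    f"(epoch {config.epochs})"
)

labels = [r.class_label for r in test.records]
curve = roc_auc(labels, predict_scores(clf, emb_test.values))
acc = accuracy(labels, predict_classes(clf, emb_test.values))
print(f"test AUC = {curve.area:.3f}, accuracy = {acc:.3f} (n = {len(labels)})")
print("first ROC points (threshold, FPR, TPR):")
for t, f, s in curve.to_table()[:4]:
    print(f"  {t:>8.3g}  {f:.3f}  {s:.3f}")
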