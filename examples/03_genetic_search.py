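"""Run the genetic algorithm over a restricted model-feature space.

Each genome assigns one variant to every model-feature axis (network,
learning rate, batch size, epochs, optimizer, activation, dropout,
regularization, train/test dataset variant); its fitness is the test AUC of
the classifier it specifies.  The full phase-1 space has 19,051,200 genomes;
this example restricts it to 128 so the search finishes in seconds while
exercising every moving part: selection with 40% retention, 10% negative
rejection, 20% single-axis mutation, and order-independent per-genome seeds.
"""

import numpy as np

from radopt import (
    EvaluationBundle,
    GAConfig,
    PhantomConfig,
    build_phase1_space,
    cardinality,
    evolve,
    explored_fraction,
    generate_phantom_dataset,
    restrict_space,
    top_k,
)

full = build_phase1_space()
print(f"full phase-1 space: {cardinality(full):,} genomes")

space = restrict_space(
    full,
    {
        "network": ["Inception V1", "ResNet V1 50"],
        "learning_rate": ["0.01", "0.1"],
        "batch_size": ["20", "120"],
        "epochs": ["25", "50"],
        "optimizer": ["gradient_descent", "adam"],
        "activation": ["softmax", "relu"],
        "dropout_keep": ["1.0", "0.75"],
        "regularization": ["none"],
        "train_dataset": ["original"],
        "test_dataset": ["original"],
    },
)
print(f"restricted space: {cardinality(space)} genomes")

config = PhantomConfig(
    train_patients={"ACP": 8, "NOTACP": 8},
    test_patients={"ACP": 6, "NOTACP": 6},
    train_images_per_patient=2,
    test_images_per_patient=1,
    signal_amplitude=25.0,
    seed=0,
)
manifest, images = generate_phantom_dataset(config)
bundle = EvaluationBundle(manifest, images, space, modality="CT", seed=0)

ga = GAConfig(
    generations=5,
    population_size=12,
    retention_rate=0.40,
    rejection_keep_prob=0.10,
    mutation_prob=0.20,
    master_seed=0,
)
history = evolve(space, ga, bundle.fitness_fn())

print(f"\nunique evaluations: {history.evaluations} "
      f"({explored_fraction(history.evaluations, space):.1%} of the space)")
print("best fitness by generation:",
      [f"{x:.3f}" for x in history.best_fitness_trace()])
print("\ntop genomes of the final generation:")
for rank, ind in enumerate(top_k(history, 2), start=1):
    g = ind.genome.choices
    print(
        f"  #{rank} AUC={ind.fitness:.3f} acc={ind.accuracy:.3f} "
        f"net={g['network']} lr={g['learning_rate']} opt={g['optimizer']} "
        f"act={g['activation']} drop={g['dropout_keep']}"
    )
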