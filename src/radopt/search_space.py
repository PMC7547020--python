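"""Declarative categorical hyperparameter search space.

The optimization problem is posed over ten *model features* (axes), each with a
small set of categorical *feature variants*: the pretrained embedding network,
learning rate, batch size, training epochs, optimizer, activation function,
dropout keep probability, regularization mode, and the training/test dataset
variants (original or stochastically augmented).  A complete assignment of one
variant per axis is a :class:`Genome` — the unit an evolutionary search evolves.

All payloads are immutable so genomes are hashable and fitness evaluations can
be cached by genome identity.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from types import MappingProxyType
from typing import Any, Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "FeatureAxis",
    "SearchSpace",
    "Genome",
    "OPTIMIZER_BASE_NAMES",
    "PROXIMAL_OPTIMIZERS",
    "expand_optimizer_variants",
    "build_phase1_space",
    "cardinality",
    "random_genome",
    "restrict_space",
]


def _freeze(payload: Any) -> Any:
    """Recursively convert dicts/lists into hashable immutable structures."""
    if isinstance(payload, Mapping):
        return MappingProxyType({k: _freeze(v) for k, v in payload.items()})
    if isinstance(payload, (list, tuple)):
        return tuple(_freeze(v) for v in payload)
    return payload


def _thaw(payload: Any) -> Any:
    if isinstance(payload, MappingProxyType) or isinstance(payload, Mapping):
        return {k: _thaw(v) for k, v in payload.items()}
    if isinstance(payload, tuple):
        return [_thaw(v) for v in payload]
    return payload


@dataclass(frozen=True)
class FeatureAxis:
    """One model feature and its categorical variants.

    Parameters
    ----------
    name:
        Axis identifier, unique within a :class:`SearchSpace`.
    variants:
        Ordered ``(label, payload)`` pairs.  The payload carries whatever the
        downstream consumer needs (a float learning rate, an optimizer spec
        dict, a dataset-variant tag...).  Labels are unique within the axis.
    """

    name: str
    variants: tuple[tuple[str, Any], ...]

    def __post_init__(self) -> None:
        if not self.variants:
            raise ValueError(f"axis {self.name!r} must have at least one variant")
        labels = [lab for lab, _ in self.variants]
        if len(set(labels)) != len(labels):
            raise ValueError(f"axis {self.name!r} has duplicate variant labels")
        object.__setattr__(
            self, "variants", tuple((lab, _freeze(pay)) for lab, pay in self.variants)
        )

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(lab for lab, _ in self.variants)

    def payload(self, label: str) -> Any:
        for lab, pay in self.variants:
            if lab == label:
                return pay
        raise KeyError(f"axis {self.name!r} has no variant {label!r}")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass(frozen=True)
class SearchSpace:
    """Ordered collection of :class:`FeatureAxis` with unique names."""

    axes: tuple[FeatureAxis, ...]

    def __post_init__(self) -> None:
        names = [a.name for a in self.axes]
        if len(set(names)) != len(names):
            raise ValueError("axis names must be unique")
        object.__setattr__(self, "axes", tuple(self.axes))

    def axis(self, name: str) -> FeatureAxis:
        for a in self.axes:
            if a.name == name:
                return a
        raise KeyError(f"no axis named {name!r}")

    @property
    def axis_names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.axes)

    def contains(self, genome: "Genome") -> bool:
        if set(genome.choices) != set(self.axis_names):
            return False
        return all(genome.choices[a.name] in a.labels for a in self.axes)

    def enumerate_genomes(self) -> Iterator["Genome"]:
        """Yield every genome in the space (use only on small spaces)."""

        def rec(i: int, acc: dict[str, str]) -> Iterator[Genome]:
            if i == len(self.axes):
                yield Genome(dict(acc))
                return
            ax = self.axes[i]
            for lab in ax.labels:
                acc[ax.name] = lab
                yield from rec(i + 1, acc)
            del acc[ax.name]

        yield from rec(0, {})

    def to_dict(self) -> dict[str, Any]:
        return {
            "axes": [
                {"name": a.name, "variants": [[lab, _thaw(pay)] for lab, pay in a.variants]}
                for a in self.axes
            ]
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SearchSpace":
        axes = tuple(
            FeatureAxis(ax["name"], tuple((lab, pay) for lab, pay in ax["variants"]))
            for ax in d["axes"]
        )
        return cls(axes)


@dataclass(frozen=True)
class Genome:
    """One variant choice per axis of a search space (an *individual*)."""

    choices: Mapping[str, str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "choices", MappingProxyType(dict(self.choices)))

    def validate(self, space: SearchSpace) -> None:
        missing = set(space.axis_names) - set(self.choices)
        extra = set(self.choices) - set(space.axis_names)
        if missing or extra:
            raise ValueError(f"genome axes mismatch: missing={missing}, extra={extra}")
        for ax in space.axes:
            if self.choices[ax.name] not in ax.labels:
                raise ValueError(
                    f"label {self.choices[ax.name]!r} not in axis {ax.name!r}"
                )

    def payloads(self, space: SearchSpace) -> dict[str, Any]:
        """Resolve each chosen label to its payload."""
        return {ax.name: ax.payload(self.choices[ax.name]) for ax in space.axes}

    def to_dict(self) -> dict[str, str]:
        return dict(self.choices)

    @classmethod
    def from_dict(cls, d: Mapping[str, str]) -> "Genome":
        return cls(dict(d))

    def stable_hash(self) -> int:
        """Order-independent 31-bit hash, stable across processes and runs."""
        blob = json.dumps(sorted(self.choices.items())).encode()
        return int.from_bytes(hashlib.sha256(blob).digest()[:4], "big") % (2**31)

    def __hash__(self) -> int:
        return hash(tuple(sorted(self.choices.items())))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return dict(self.choices) == dict(other.choices)


# ---------------------------------------------------------------------------
# Phase-1 space
# ---------------------------------------------------------------------------

#: The nine optimizer families offered to the search.  The two proximal
#: families each expand into four regularization variants.
OPTIMIZER_BASE_NAMES: tuple[str, ...] = (
    "Gradient Descent",
    "Adam",
    "Adagrad",
    "Adadelta",
    "RMSProp",
    "Momentum",
    "FTRL",
    "Proximal Adagrad",
    "Proximal Adadelta",
)

PROXIMAL_OPTIMIZERS: frozenset[str] = frozenset({"Proximal Adagrad", "Proximal Adadelta"})

_PROXIMAL_REG_MODES: tuple[str, ...] = ("none", "l1", "l2", "l1l2")


def expand_optimizer_variants(
    base_names: Sequence[str] = OPTIMIZER_BASE_NAMES,
) -> list[dict[str, str]]:
    """Expand optimizer family names into concrete optimizer specs.

    Non-proximal families yield a single spec; each proximal family yields four
    specs, one per proximal-regularization mode (none, l1, l2, l1+l2).  The
    nine standard families therefore expand to fifteen optimizer variants.
    """
    known = set(OPTIMIZER_BASE_NAMES)
    specs: list[dict[str, str]] = []
    for name in base_names:
        if name not in known:
            raise ValueError(f"unknown optimizer name: {name!r}")
        if name in PROXIMAL_OPTIMIZERS:
            for mode in _PROXIMAL_REG_MODES:
                specs.append({"name": name, "proximal_reg": mode})
        else:
            specs.append({"name": name})
    return specs


def _optimizer_label(spec: Mapping[str, str]) -> str:
    slug = spec["name"].lower().replace(" ", "_")
    if "proximal_reg" in spec:
        slug += f"__{spec['proximal_reg']}"
    return slug


LEARNING_RATES: tuple[float, ...] = (0.00001, 0.0001, 0.001, 0.005, 0.01, 0.05, 0.1)
BATCH_SIZES: tuple[int, ...] = (5, 20, 120)
EPOCH_COUNTS: tuple[int, ...] = (10, 25, 50, 100, 125)
ACTIVATIONS: tuple[str, ...] = (
    "softmax",
    "softplus",
    "softsign",
    "relu",
    "leaky_relu",
    "log_softmax",
    "identity",
)
DROPOUT_KEEP_PROBS: tuple[float, ...] = (0.25, 0.5, 0.75, 1.0)
REGULARIZATION_MODES: tuple[str, ...] = ("none", "l1", "l2", "l1l2")
TRAIN_DATASET_VARIANTS: tuple[str, ...] = ("original", "aug100", "aug1000")
TEST_DATASET_VARIANTS: tuple[str, ...] = ("original", "aug10", "aug100")


def build_phase1_space(
    batch_sizes: Sequence[int] = BATCH_SIZES,
    epoch_counts: Sequence[int] = EPOCH_COUNTS,
    activations: Sequence[str] = ACTIVATIONS,
) -> SearchSpace:
    """Build the full first-phase search space: ten axes, 19,051,200 genomes.

    Axis sizes: 12 pretrained networks x 7 learning rates x 3 batch sizes x
    5 epoch counts x 15 optimizers x 7 activations x 4 dropout keep
    probabilities x 4 regularization modes x 3 training-dataset variants x
    3 test-dataset variants.
    """
    from .embeddings import extractor_registry  # late import to avoid a cycle

    networks = tuple(
        (spec.name, {"network": spec.name, "output_dim": spec.output_dim})
        for spec in extractor_registry()
    )
    optimizers = tuple(
        (_optimizer_label(s), s) for s in expand_optimizer_variants()
    )
    axes = (
        FeatureAxis("network", networks),
        FeatureAxis(
            "learning_rate", tuple((repr(lr), lr) for lr in LEARNING_RATES)
        ),
        FeatureAxis("batch_size", tuple((str(b), b) for b in batch_sizes)),
        FeatureAxis("epochs", tuple((str(e), e) for e in epoch_counts)),
        FeatureAxis("optimizer", optimizers),
        FeatureAxis("activation", tuple((a, a) for a in activations)),
        FeatureAxis(
            "dropout_keep", tuple((str(k), k) for k in DROPOUT_KEEP_PROBS)
        ),
        FeatureAxis(
            "regularization", tuple((m, m) for m in REGULARIZATION_MODES)
        ),
        FeatureAxis(
            "train_dataset", tuple((v, v) for v in TRAIN_DATASET_VARIANTS)
        ),
        FeatureAxis(
            "test_dataset", tuple((v, v) for v in TEST_DATASET_VARIANTS)
        ),
    )
    return SearchSpace(axes)


def cardinality(space: SearchSpace) -> int:
    """Exact number of distinct genomes (arbitrary-precision product)."""
    total = 1
    for ax in space.axes:
        total *= len(ax)
    return total


def random_genome(space: SearchSpace, rng: np.random.Generator) -> Genome:
    """Draw one variant per axis, uniformly and independently."""
    choices = {
        ax.name: ax.labels[int(rng.integers(len(ax)))] for ax in space.axes
    }
    return Genome(choices)


def restrict_space(
    space: SearchSpace, keep: Mapping[str, Iterable[str]]
) -> SearchSpace:
    """Shrink axes to the given label subsets (second-phase refinement).

    Axes absent from ``keep`` are unchanged.  Kept labels must exist in the
    parent axis; their original order is preserved.
    """
    unknown_axes = set(keep) - set(space.axis_names)
    if unknown_axes:
        raise KeyError(f"unknown axes in keep: {sorted(unknown_axes)}")
    new_axes = []
    for ax in space.axes:
        if ax.name not in keep:
            new_axes.append(ax)
            continue
        wanted = set(keep[ax.name])
        unknown = wanted - set(ax.labels)
        if unknown:
            raise KeyError(
                f"axis {ax.name!r} has no labels {sorted(unknown)}"
            )
        variants = tuple((lab, pay) for lab, pay in ax.variants if lab in wanted)
        new_axes.append(FeatureAxis(ax.name, variants))
    return SearchSpace(tuple(new_axes))
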