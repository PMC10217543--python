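"""Binary wrapper feature selection driven by the grasshopper optimizer.

Grasshoppers live in the unit box [0, 1]^D; a position binarizes into
a feature mask by thresholding at 0.5.  A mask is scored by a fitness
that trades cross-validated classification error against subset size::

    fitness(mask) = alpha * CV_error(mask) + (1 - alpha) * |mask| / D

with alpha = 0.99 by default, so error dominates and the feature
fraction acts as a tiebreaker pushing toward small subsets.  Lower is
better; the optimizer's non-increasing best-so-far trace is the
selection objective curve.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .goa import GoaConfig, optimize
from .classify import make_classifier
from .synthetic import FeatureTable

__all__ = [
    "FeatureMask",
    "FitnessSpec",
    "SelectionResult",
    "binarize",
    "fitness",
    "select_features",
]


@dataclass(frozen=True)
class FeatureMask:
    """A non-empty binary feature subset."""

    bits: tuple[int, ...]

    def __post_init__(self) -> None:
        if any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be 0 or 1")
        if self.selected_count < 1:
            raise ValueError("mask must select at least one feature")

    @property
    def selected_count(self) -> int:
        return int(sum(self.bits))

    def as_bool(self) -> np.ndarray:
        return np.asarray(self.bits, dtype=bool)

    def selected_indices(self) -> list[int]:
        return [i for i, b in enumerate(self.bits) if b]

    def __str__(self) -> str:
        return "".join(map(str, self.bits))


@dataclass(frozen=True)
class FitnessSpec:
    """How a candidate mask is scored.

    alpha weights classification error against the selected-feature
    fraction; the CV folds are shuffled with ``seed`` so the fitness
    landscape is fixed within a run.
    """

    alpha: float = 0.99
    classifier_id: str = "svm"
    n_splits: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie strictly in (0, 1)")
        if self.n_splits < 2:
            raise ValueError("n_splits must be >= 2")


@dataclass
class SelectionResult:
    mask: FeatureMask
    fitness_trace: np.ndarray
    final_fitness: float
    goa_config: GoaConfig
    fitness_spec: FitnessSpec
    seed: int

    def to_json(self) -> str:
        return json.dumps(
            {
                "mask": str(self.mask),
                "selected_count": self.mask.selected_count,
                "selected_indices": self.mask.selected_indices(),
                "final_fitness": self.final_fitness,
                "fitness_trace": [float(v) for v in self.fitness_trace],
                "goa_config": {
                    k: (list(v) if isinstance(v, tuple) else v)
                    for k, v in asdict(self.goa_config).items()
                },
                "fitness_spec": asdict(self.fitness_spec),
                "seed": self.seed,
            },
            indent=2,
        )

    def write_trace(self, path) -> None:
        """Two-column delimited trace (iteration, best_fitness)."""
        with open(path, "w") as fh:
            fh.write("iteration\tbest_fitness\n")
            for i, v in enumerate(self.fitness_trace):
                fh.write(f"{i}\t{v!r}\n")


def binarize(position: Iterable[float], threshold: float = 0.5) -> FeatureMask:
    """Threshold a continuous position into a mask.

    bit_d = 1 iff position_d >= threshold (the boundary counts as
    selected).  An all-zero result is repaired by setting the single
    largest-valued dimension, guaranteeing a non-empty mask.
    """
    x = np.asarray(list(position) if not isinstance(position, np.ndarray) else position,
                   dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("position contains non-finite components")
    bits = (x >= threshold).astype(int)
    if bits.sum() == 0:
        bits[int(np.argmax(x))] = 1
    return FeatureMask(tuple(int(b) for b in bits))


def _cv_error(
    X: np.ndarray, y: np.ndarray, spec: FitnessSpec
) -> float:
    """Pooled held-out error rate under seeded stratified k-fold CV."""
    predictions = np.empty_like(y)
    skf = StratifiedKFold(n_splits=spec.n_splits, shuffle=True, random_state=spec.seed)
    for train_idx, test_idx in skf.split(X, y):
        clf = make_classifier(spec.classifier_id, spec.seed)
        clf.fit(X[train_idx], y[train_idx])
        predictions[test_idx] = clf.predict(X[test_idx])
    return float(np.mean(predictions != y))


def fitness(mask: FeatureMask, table: FeatureTable, spec: FitnessSpec) -> float:
    """Score a mask: alpha * CV error + (1 - alpha) * feature fraction."""
    bits = mask.as_bool()
    if bits.shape != (table.n_features,):
        raise ValueError("mask length must equal the table's feature count")
    if len(table.classes()) < 2:
        raise ValueError("fitness requires both classes in the table")
    err = _cv_error(table.values[:, bits], np.asarray(table.labels), spec)
    frac = mask.selected_count / table.n_features
    return spec.alpha * err + (1.0 - spec.alpha) * frac


def select_features(
    table: FeatureTable,
    goa_cfg: GoaConfig | None = None,
    spec: FitnessSpec | None = None,
    threshold: float = 0.5,
) -> SelectionResult:
    """Wrapper selection: optimize mask fitness over the unit box.

    The GOA bounds are fixed to [0, 1] per feature; each grasshopper
    position binarizes to a mask whose fitness is the objective.
    Fitness values are cached per mask (the map position -> mask is
    many-to-one, and late-stage swarms revisit the same masks), so the
    landscape stays deterministic while avoiding redundant CV fits.
    """
    if table.n_features < 2:
        raise ValueError("need at least 2 features to select from")
    spec = spec or FitnessSpec()
    d = table.n_features
    if goa_cfg is None:
        goa_cfg = GoaConfig(lower_bounds=[0.0] * d, upper_bounds=[1.0] * d,
                            seed=spec.seed)
    if goa_cfg.dimension != d:
        raise ValueError("GOA bounds dimension must equal the feature count")

    cache: dict[tuple[int, ...], float] = {}

    def objective(x: np.ndarray) -> float:
        mask = binarize(x, threshold)
        key = mask.bits
        if key not in cache:
            try:
                cache[key] = fitness(mask, table, spec)
            except Exception as exc:
                raise RuntimeError(
                    f"fitness evaluation failed for mask {mask}"
                ) from exc
        return cache[key]

    best_pos, best_fit, trace = optimize(objective, goa_cfg)
    return SelectionResult(
        mask=binarize(best_pos, threshold),
        fitness_trace=trace,
        final_fitness=float(best_fit),
        goa_config=goa_cfg,
        fitness_spec=spec,
        seed=goa_cfg.seed,
    )
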