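"""Seeded synthetic feature tables with planted informative columns.

Emulates the shape of a deep-feature table extracted from two-class
histopathology images (cancerous vs benign): a real-valued sample x
feature matrix with binary labels, where a known subset of columns
carries a class-mean shift and the rest are class-independent noise.
The generator's only job is to exercise selection and classification
machinery with a known ground truth; it makes no claim of matching
real CNN-feature covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["SyntheticSpec", "FeatureTable", "generate", "make_fixture_suite"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a two-class planted-feature table.

    ``separation`` is the class-mean gap on informative columns in
    units of the noise standard deviation; class means sit at
    ±separation/2 so the pooled column mean is zero.
    """

    n_samples_per_class: int = 100
    n_features: int = 20
    n_informative: int = 5
    separation: float = 2.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples_per_class < 2:
            raise ValueError("need at least 2 samples per class")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative must be within [0, n_features]")
        if self.separation < 0:
            raise ValueError("separation must be >= 0")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")


@dataclass
class FeatureTable:
    """Sample x feature matrix with binary labels.

    ``informative_mask`` records the planted columns when the table
    came from the generator; None for externally loaded tables.
    """

    values: np.ndarray                 # (n, D) float
    labels: np.ndarray                 # (n,) int in {0, 1}
    feature_names: list[str] = field(default_factory=list)
    informative_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        if len(self.labels) != len(self.values):
            raise ValueError("labels length must match number of rows")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature table contains non-finite values")
        if not self.feature_names:
            self.feature_names = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_names) != self.values.shape[1]:
            raise ValueError("feature_names length must match column count")
        if len(set(self.feature_names)) != len(self.feature_names):
            raise ValueError("duplicate feature names")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


def generate(spec: SyntheticSpec) -> FeatureTable:
    """Draw a table from the class-conditional Gaussian model.

    Informative columns: N(±separation/2 · noise_sd, noise_sd²) by
    class.  Remaining columns: N(0, noise_sd²) independent of class.
    Rows are shuffled with the spec seed; the planted columns are
    recorded in ``informative_mask``.
    """
    rng = np.random.default_rng(spec.seed)
    n, d, k = spec.n_samples_per_class, spec.n_features, spec.n_informative

    labels = np.repeat([0, 1], n)
    values = rng.normal(0.0, spec.noise_sd, size=(2 * n, d))
    shift = 0.5 * spec.separation * spec.noise_sd
    signs = np.where(labels == 1, 1.0, -1.0)
    values[:, :k] += signs[:, None] * shift

    # shuffle columns so informative ones are not always leading
    col_order = rng.permutation(d)
    values = values[:, col_order]
    informative = np.zeros(d, dtype=bool)
    informative[np.isin(col_order, np.arange(k))] = True

    row_order = rng.permutation(2 * n)
    return FeatureTable(
        values=values[row_order],
        labels=labels[row_order],
        informative_mask=informative,
    )


def make_fixture_suite(seed: int = 0) -> dict[str, FeatureTable]:
    """Deterministic catalogue of test tables.

    - ``tiny``: D = 6, enabling the 63-mask exhaustive oracle.
    - ``separable``: wide class gap (delta = 6), linearly separable in
      practice.
    - ``noisy``: the standard selection benchmark (n = 100/class,
      D = 20, 5 informative columns, delta = 2).
    - ``single``: exactly one informative column among noise.
    """
    return {
        "tiny": generate(
            SyntheticSpec(n_samples_per_class=40, n_features=6, n_informative=2,
                          separation=3.0, seed=seed)
        ),
        "separable": generate(
            SyntheticSpec(n_samples_per_class=100, n_features=10, n_informative=4,
                          separation=6.0, seed=seed + 1)
        ),
        "noisy": generate(
            SyntheticSpec(n_samples_per_class=100, n_features=20, n_informative=5,
                          separation=2.0, seed=seed + 2)
        ),
        "single": generate(
            SyntheticSpec(n_samples_per_class=60, n_features=8, n_informative=1,
                          separation=5.0, seed=seed + 3)
        ),
    }
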