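"""Layered synthetic datasets for benchmarking group-wise feature selectors.

The generator emulates a multi-layer regulatory structure frequently used to
stress-test metabolomics selectors: a binary phenotype ``Y`` drives a first
layer of strongly separating variables; each first-layer variable is then
decomposed into three "child" variables whose sum reconstructs the parent
(second layer), and each of those into three more (third layer); the
remaining variables are independent standard-normal noise whose univariate
association with ``Y`` can be bounded away from significance by a p-value
floor ``delta``.

Layer-1 composition (30 variables):

* columns 1-4:  ``U(0,1) + 0.8 - 2*Y``  (strong, aligned with label 0)
* columns 5-8:  ``U(0,1) - 1.2 - 2*Y``  (strong, aligned with label 1)
* columns 9-18: five independent bivariate normal pairs,
  mean ``Y*(0, 0.5)``, covariance ``A``
* columns 19-30: four independent trivariate normal triplets,
  mean ``Y*(1, 2, 3)``, covariance ``B``

All randomness flows through one :class:`numpy.random.Generator`; draws are
made column-major in a documented order (response, layer 1 left to right,
then children of each parent in index order, then noise columns left to
right), so a seed fully determines the dataset.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from ._exceptions import GenerationError, ParameterError
from .decomposition import FeatureTable

__all__ = [
    "Structure",
    "SimulationDesign",
    "LayerStructure",
    "CovarianceBlocks",
    "generate_response",
    "generate_layer1",
    "decompose_parent",
    "generate_noise",
    "generate_dataset",
]

# Number of uniform-shift strong variables and total layer-1 size.
N_STRONG = 8
N_LAYER1 = 30
CHILDREN_PER_PARENT = 3


class Structure(str, enum.Enum):
    """Which layers are present; the remainder of the 1000 variables is noise."""

    THREE_LAYER = "three_layer"
    TWO_LAYER = "two_layer"
    ONE_LAYER = "one_layer"
    NOISE_LAYER = "noise_layer"


#: (layer1, layer2, layer3, noise) sizes for the default 1000-variable designs.
LAYER_SIZES: dict[Structure, tuple[int, int, int, int]] = {
    Structure.THREE_LAYER: (30, 90, 270, 610),
    Structure.TWO_LAYER: (30, 90, 0, 880),
    Structure.ONE_LAYER: (30, 0, 0, 930),
    Structure.NOISE_LAYER: (0, 0, 0, 1000),
}


class Layer(str, enum.Enum):
    LAYER1_STRONG = "layer1_strong"
    LAYER1_GROUP = "layer1_group"
    LAYER2 = "layer2"
    LAYER3 = "layer3"
    NOISE = "noise"


@dataclass(frozen=True)
class CovarianceBlocks:
    """Mean shifts and covariance blocks of the correlated layer-1 groups."""

    A: np.ndarray = field(
        default_factory=lambda: np.array([[1.0, 0.4], [0.4, 0.4]])
    )
    B: np.ndarray = field(
        default_factory=lambda: np.array(
            [[12.0, 10.0, 8.0], [10.0, 12.0, 10.0], [8.0, 10.0, 12.0]]
        )
    )
    pair_shift: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.5]))
    triplet_shift: np.ndarray = field(
        default_factory=lambda: np.array([1.0, 2.0, 3.0])
    )


@dataclass(frozen=True)
class SimulationDesign:
    """Parameters of one simulated dataset.

    Parameters
    ----------
    n_samples
        Number of samples (default 200).
    n_features
        Number of features; must equal the structure's layer-size sum
        (default 1000).
    structure
        Which layers are present.
    bernoulli_prob
        Success probability of the binary response (default 0.4).
    delta
        Lower bound imposed on each noise variable's univariate
        regression p-value with the response; 0 disables the constraint.
    seed
        Seed for the dataset's random generator.
    """

    n_samples: int = 200
    n_features: int = 1000
    structure: Structure = Structure.THREE_LAYER
    bernoulli_prob: float = 0.4
    delta: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0:
            raise ParameterError("n_samples must be positive")
        if not (0.0 < self.bernoulli_prob < 1.0) or not np.isfinite(
            self.bernoulli_prob
        ):
            raise ParameterError("bernoulli_prob must lie strictly in (0, 1)")
        if not (0.0 <= self.delta < 1.0):
            raise ParameterError("delta must lie in [0, 1)")
        structure = Structure(self.structure)
        object.__setattr__(self, "structure", structure)
        if self.n_features != sum(LAYER_SIZES[structure]):
            raise ParameterError(
                f"n_features must equal {sum(LAYER_SIZES[structure])} "
                f"for structure {structure.value!r}"
            )

    @property
    def layer_sizes(self) -> tuple[int, int, int, int]:
        return LAYER_SIZES[self.structure]


@dataclass(frozen=True)
class LayerStructure:
    """Ground-truth layer membership and parent links of simulated features.

    ``assignment[j]`` is the layer of feature ``j`` (0-based column index);
    ``parent_map[j]`` is the parent column of a layer-2/3 feature.
    """

    assignment: dict[int, Layer]
    parent_map: dict[int, int]

    def indices(self, *layers: Layer) -> np.ndarray:
        """Sorted feature indices belonging to any of the given layers."""
        wanted = set(layers)
        return np.array(
            sorted(j for j, lay in self.assignment.items() if lay in wanted),
            dtype=int,
        )

    def layer_of(self, j: int) -> Layer:
        return self.assignment[j]


def generate_response(
    n_samples: int, prob: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw the binary response: independent Bernoulli(``prob``) labels."""
    if not np.isfinite(prob) or not (0.0 < prob < 1.0):
        raise ParameterError("prob must be finite and strictly inside (0, 1)")
    return (rng.random(n_samples) < prob).astype(np.int64)


def generate_layer1(
    labels: np.ndarray,
    rng: np.random.Generator,
    blocks: CovarianceBlocks | None = None,
) -> np.ndarray:
    """Generate the 30 first-layer variables given the response labels.

    Columns (0-based): 0-3 uniform-shift variables ``U(0,1)+0.8-2Y``;
    4-7 uniform-shift ``U(0,1)-1.2-2Y``; 8-17 five bivariate normal pairs;
    18-29 four trivariate normal triplets.
    """
    blocks = blocks or CovarianceBlocks()
    y = np.asarray(labels, dtype=float)
    n = y.shape[0]
    X = np.empty((n, N_LAYER1))
    for p in range(4):
        X[:, p] = rng.random(n) + 0.8 - 2.0 * y
    for p in range(4, 8):
        X[:, p] = rng.random(n) + (-1.2) - 2.0 * y
    chol_a = np.linalg.cholesky(blocks.A)
    for start in range(8, 18, 2):  # pairs at 1-based 9,11,13,15,17
        z = rng.standard_normal((n, 2))
        X[:, start : start + 2] = y[:, None] * blocks.pair_shift + z @ chol_a.T
    chol_b = np.linalg.cholesky(blocks.B)
    for start in range(18, 30, 3):  # triplets at 1-based 19,22,25,28
        z = rng.standard_normal((n, 3))
        X[:, start : start + 3] = (
            y[:, None] * blocks.triplet_shift + z @ chol_b.T
        )
    return X


def decompose_parent(
    parent_values: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Split a parent column into three children summing to ``parent + eps``.

    Per sample, random proportions ``u_i/(u1+u2+u3)`` with ``u_i ~ U(0,1)``
    partition ``x + eps`` where ``eps ~ N(0, max(x, 0)/10)``; a zero parent
    yields three zero children. The noise variance convention clips negative
    parents to zero so the scale stays well defined.
    """
    x = np.asarray(parent_values, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ParameterError("parent column must be finite")
    n = x.shape[0]
    u = rng.random((n, CHILDREN_PER_PARENT))
    eps = rng.standard_normal(n) * np.sqrt(np.maximum(x, 0.0) / 10.0)
    fractions = u / u.sum(axis=1, keepdims=True)
    return fractions * (x + eps)[:, None]


def _slope_pvalues(columns: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Two-sided p-values of the slope in simple OLS of ``y`` on each column.

    Uses the algebraic identity with the correlation t-test:
    ``t = r * sqrt((n-2) / (1-r^2))``.
    """
    n = y.shape[0]
    yc = y - y.mean()
    xc = columns - columns.mean(axis=0)
    denom = np.sqrt((xc**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, xc.T @ yc / denom, 0.0)
        r = np.clip(r, -1.0, 1.0)
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, np.finfo(float).tiny))
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def generate_noise(
    labels: np.ndarray,
    count: int,
    delta: float,
    rng: np.random.Generator,
    max_attempts: int = 10_000,
) -> np.ndarray:
    """Generate ``count`` standard-normal noise columns independent of ``Y``.

    Each column is redrawn until the two-sided p-value of the slope in a
    simple linear regression of ``Y`` on the column is at least ``delta``,
    so that, at ``delta = 0.10`` say, no noise column is univariately
    significant at the 10% level. ``delta = 0`` accepts every first draw.
    """
    if not (0.0 <= delta < 1.0):
        raise ParameterError("delta must lie in [0, 1)")
    y = np.asarray(labels, dtype=float)
    n = y.shape[0]
    X = rng.standard_normal((n, count))
    if delta == 0.0 or count == 0:
        return X
    pvals = _slope_pvalues(X, y)
    attempts = np.ones(count, dtype=int)
    failing = np.flatnonzero(pvals < delta)
    while failing.size:
        over = failing[attempts[failing] >= max_attempts]
        if over.size:
            raise GenerationError(
                f"noise column {int(over[0])} exceeded {max_attempts} "
                f"redraw attempts for delta={delta}"
            )
        X[:, failing] = rng.standard_normal((n, failing.size))
        attempts[failing] += 1
        p_new = _slope_pvalues(X[:, failing], y)
        failing = failing[p_new < delta]
    return X


def generate_dataset(
    design: SimulationDesign,
) -> tuple[FeatureTable, LayerStructure]:
    """Assemble one full dataset and its ground-truth layer bookkeeping.

    Column layout matches the layer sizes of ``design.structure``: layer 1
    (when present), then layer 2 (three children per layer-1 column, in
    parent order), then layer 3 (children of layer-2 columns), then noise.
    Deterministic given ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    n1, n2, n3, n_noise = design.layer_sizes
    y = generate_response(design.n_samples, design.bernoulli_prob, rng)

    columns: list[np.ndarray] = []
    assignment: dict[int, Layer] = {}
    parent_map: dict[int, int] = {}
    offset = 0

    if n1:
        layer1 = generate_layer1(y, rng)
        columns.append(layer1)
        for j in range(N_LAYER1):
            assignment[j] = (
                Layer.LAYER1_STRONG if j < N_STRONG else Layer.LAYER1_GROUP
            )
        offset = N_LAYER1

    if n2:
        children2 = np.empty((design.n_samples, n2))
        for parent in range(n1):
            kids = decompose_parent(columns[0][:, parent], rng)
            lo = parent * CHILDREN_PER_PARENT
            children2[:, lo : lo + CHILDREN_PER_PARENT] = kids
            for k in range(CHILDREN_PER_PARENT):
                assignment[offset + lo + k] = Layer.LAYER2
                parent_map[offset + lo + k] = parent
        columns.append(children2)
        layer2_offset = offset
        offset += n2

    if n3:
        children3 = np.empty((design.n_samples, n3))
        for parent in range(n2):
            kids = decompose_parent(children2[:, parent], rng)
            lo = parent * CHILDREN_PER_PARENT
            children3[:, lo : lo + CHILDREN_PER_PARENT] = kids
            for k in range(CHILDREN_PER_PARENT):
                assignment[offset + lo + k] = Layer.LAYER3
                parent_map[offset + lo + k] = layer2_offset + parent
        columns.append(children3)
        offset += n3

    if n_noise:
        noise = generate_noise(y, n_noise, design.delta, rng)
        columns.append(noise)
        for k in range(n_noise):
            assignment[offset + k] = Layer.NOISE
        offset += n_noise

    X = np.hstack(columns)
    table = FeatureTable(
        X=X,
        sample_ids=[f"s{i + 1}" for i in range(design.n_samples)],
        feature_ids=[f"x{j + 1}" for j in range(design.n_features)],
        labels=y,
    )
    return table, LayerStructure(assignment=assignment, parent_map=parent_map)
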