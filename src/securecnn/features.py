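"""Deep-feature fusion and genetic-algorithm feature selection.

The pipeline mirrors a transfer-learning workflow: named feature layers
of three backbones yield per-sample feature vectors which are serially
fused (row-wise concatenation, so the fused width is the sum of the
per-backbone widths — 2048 + 1000 + 1000 = 4048 at full scale), ranked
by the mode of their rounded values, and pruned by a genetic algorithm
whose fitness is an entropy-gated Gaussian Naive Bayes accuracy: a
chromosome whose pooled selected-feature histogram is too disordered
(Shannon entropy above the threshold tau) scores zero, otherwise it
scores its stratified cross-validated NB accuracy.  Selection is
roulette-wheel, crossover is uniform, mutation is per-bit, and the top
``B`` chromosomes survive each generation unchanged (elitism), so the
best fitness never decreases.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import NearestCentroid

from .errors import ConfigError
from .model import LayeredModel, forward_plain

__all__ = [
    "DEFAULT_REGISTRY",
    "registry_fused_width",
    "FusedFeatureTable",
    "Chromosome",
    "GAConfig",
    "GAResult",
    "extract_features",
    "serial_fuse",
    "mode_order",
    "shannon_entropy",
    "nb_fitness",
    "ga_select",
    "classify",
    "CLASSIFIERS",
]

# backbone name -> (feature layer name, feature dimension)
DEFAULT_REGISTRY: dict[str, tuple[str, int]] = {
    "inceptionv3": ("avg pool", 2048),
    "googlenet": ("global avg pool", 1000),
    "densenet201": ("fc", 1000),
}


def registry_fused_width(registry: dict[str, tuple[str, int]] | None = None) -> int:
    """Width of the serially fused vector implied by a layer registry."""
    registry = registry if registry is not None else DEFAULT_REGISTRY
    dims = [dim for _name, dim in registry.values()]
    if any(d <= 0 for d in dims):
        raise ConfigError("registry feature dimensions must be positive")
    return int(sum(dims))


@dataclass
class FusedFeatureTable:
    """N samples x L features plus labels and the feature permutation."""

    features: np.ndarray
    labels: np.ndarray
    feature_order: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.features.ndim != 2:
            raise ConfigError("feature matrix must be 2-D")
        if len(self.labels) != self.features.shape[0]:
            raise ConfigError("label count must match the number of rows")
        if self.feature_order is None:
            self.feature_order = np.arange(self.features.shape[1])
        else:
            self.feature_order = np.asarray(self.feature_order, dtype=int)

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def to_csv(self, path) -> None:
        df = pd.DataFrame(self.features, columns=[f"f{j}" for j in self.feature_order])
        df["label"] = self.labels
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FusedFeatureTable":
        df = pd.read_csv(path)
        if "label" not in df.columns:
            raise ConfigError(f"{path}: expected a 'label' column")
        labels = df.pop("label").to_numpy()
        order = np.array([int(c.lstrip("f")) for c in df.columns])
        return cls(features=df.to_numpy(float), labels=labels, feature_order=order)


def extract_features(model: LayeredModel, layer_name: str, images) -> np.ndarray:
    """Row ``i`` = the named layer's flattened output for image ``i``."""
    model.get_layer(layer_name)  # raises with the available names
    idx = model.layer_names().index(layer_name)
    rows = [forward_plain(model, img).layer_outputs[idx].ravel() for img in images]
    return np.vstack(rows)


def serial_fuse(f1: np.ndarray, f2: np.ndarray, f3: np.ndarray, labels=None) -> FusedFeatureTable:
    """Row-wise concatenation (f1 | f2 | f3); width = sum of widths."""
    mats = [np.atleast_2d(np.asarray(f, dtype=float)) for f in (f1, f2, f3)]
    n = mats[0].shape[0]
    if any(m.shape[0] != n for m in mats):
        raise ConfigError(f"row counts differ: {[m.shape[0] for m in mats]}")
    fused = np.hstack(mats)
    if labels is None:
        labels = np.zeros(n, dtype=int)
    return FusedFeatureTable(features=fused, labels=labels)


def _column_mode(col: np.ndarray, decimals: int) -> float:
    """Mode of the rounded values; ties resolved to the smallest value."""
    vals, counts = np.unique(np.round(col, decimals), return_counts=True)
    return float(vals[counts == counts.max()].min())


def mode_order(table: FusedFeatureTable, decimals: int = 2) -> FusedFeatureTable:
    """Rank features by the mode of their rounded values, descending.

    Ties between features keep the original index order, so the result
    is a deterministic bijection recorded in ``feature_order``.
    """
    if table.n_samples == 0 or table.n_features == 0:
        raise ConfigError("cannot order an empty table")
    modes = np.array([_column_mode(table.features[:, j], decimals) for j in range(table.n_features)])
    idx = np.argsort(-modes, kind="stable")
    return FusedFeatureTable(
        features=table.features[:, idx],
        labels=table.labels,
        feature_order=table.feature_order[idx],
    )


def shannon_entropy(p) -> float:
    """Natural-log Shannon entropy of a probability vector; 0·log 0 = 0."""
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ConfigError("probabilities must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ConfigError(f"probabilities must sum to 1, got {p.sum()!r}")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def _pooled_entropy(values: np.ndarray, n_bins: int, lam: float) -> float:
    """Entropy of the Laplace-smoothed quantile-binned pooled histogram."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, n_bins + 1)))
    if len(edges) < 2:
        # all values identical: a single bin, zero entropy before smoothing
        counts = np.array([values.size], dtype=float)
    else:
        counts, _ = np.histogram(values, bins=edges)
        counts = counts.astype(float)
    counts += lam
    return shannon_entropy(counts / counts.sum())


@dataclass
class GAConfig:
    """Genetic-algorithm hyperparameters.

    Defaults follow the selection procedure's stated settings:
    population 100, up to 500 generations, mutation rate 0.001,
    crossover rate 0.8, elitism count B = 6, Laplace constant
    lambda = 1.  tau is the entropy gate on the natural-log scale; with
    10 quantile bins the pooled entropy is at most ln 10 ~= 2.303, so
    the default 2.5 leaves the gate open unless tightened.
    """

    population: int = 100
    max_iterations: int = 500
    mutation_rate: float = 0.001
    crossover_rate: float = 0.8
    elitism: int = 6
    laplace: float = 1.0
    entropy_threshold: float = 2.5
    n_bins: int = 10
    folds: int = 3
    stagnation_limit: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.mutation_rate <= 1 and 0 <= self.crossover_rate <= 1):
            raise ConfigError("rates must lie in [0, 1]")
        if not (self.population > self.elitism >= 0):
            raise ConfigError("population must exceed the elitism count")
        if self.entropy_threshold <= 0:
            raise ConfigError("entropy threshold must be positive")
        if self.folds < 2:
            raise ConfigError("cross-validation needs at least 2 folds")


@dataclass
class Chromosome:
    mask: np.ndarray
    fitness: float = 0.0

    @property
    def indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask)


def nb_fitness(table: FusedFeatureTable, mask: np.ndarray, cfg: GAConfig) -> float:
    """Entropy-gated Naive Bayes fitness of one feature subset.

    The selected features' values, pooled over all samples, are
    quantile-binned (``cfg.n_bins``); if the Laplace-smoothed histogram
    entropy exceeds tau the chromosome scores 0, otherwise it scores
    the mean stratified k-fold accuracy of a Gaussian Naive Bayes on
    the masked columns (lambda also scales the NB variance floor).
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ConfigError("a scorable chromosome needs at least one selected feature")
    classes = np.unique(table.labels)
    if len(classes) < 2:
        raise ConfigError("fitness needs at least two classes")
    selected = table.features[:, mask]
    h = _pooled_entropy(selected.ravel(), cfg.n_bins, cfg.laplace)
    if h > cfg.entropy_threshold:
        return 0.0
    y = table.labels
    skf = StratifiedKFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    accs = []
    for train, test in skf.split(selected, y):
        nb = GaussianNB(var_smoothing=1e-9 * cfg.laplace)
        nb.fit(selected[train], y[train])
        accs.append(float((nb.predict(selected[test]) == y[test]).mean()))
    return float(np.mean(accs))


@dataclass
class GAResult:
    best: Chromosome
    selected_indices: np.ndarray
    history: list[float]
    generations_run: int
    all_zero_fitness: bool = False


def _ensure_nonzero(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def ga_select(table: FusedFeatureTable, cfg: GAConfig | None = None) -> GAResult:
    """Evolve feature-subset bitmasks against the entropy-gated NB fitness.

    Per generation: roulette-wheel parent selection (uniform fallback
    when every fitness is zero), uniform crossover at
    ``crossover_rate``, per-bit mutation at ``mutation_rate``, merge of
    parents and offspring, fitness sort, survival of the top P with the
    top B elites guaranteed.  Stops at ``max_iterations`` or after
    ``stagnation_limit`` generations without improvement.
    """
    cfg = cfg or GAConfig()
    rng = np.random.default_rng(cfg.seed)
    L = table.n_features
    P = cfg.population

    cache: dict[bytes, float] = {}

    def fit(mask: np.ndarray) -> float:
        key = np.packbits(mask).tobytes()
        if key not in cache:
            cache[key] = nb_fitness(table, mask, cfg)
        return cache[key]

    pop = [_ensure_nonzero(rng.random(L) < 0.5, rng) for _ in range(P)]
    fits = np.array([fit(m) for m in pop])
    order = np.argsort(-fits, kind="stable")
    pop = [pop[i] for i in order]
    fits = fits[order]

    history = [float(fits[0])]
    best_seen = fits[0]
    stagnant = 0
    generations = 0

    for generations in range(1, cfg.max_iterations + 1):
        total = fits.sum()
        probs = fits / total if total > 0 else np.full(P, 1.0 / P)
        parent_idx = rng.choice(P, size=(P + 1) // 2 * 2, p=probs)
        offspring: list[np.ndarray] = []
        for a, b in zip(parent_idx[0::2], parent_idx[1::2]):
            pa, pb = pop[a], pop[b]
            if rng.random() < cfg.crossover_rate:
                swap = rng.random(L) < 0.5
                ca = np.where(swap, pb, pa)
                cb = np.where(swap, pa, pb)
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                if cfg.mutation_rate > 0:
                    flips = rng.random(L) < cfg.mutation_rate
                    child = np.logical_xor(child, flips)
                offspring.append(_ensure_nonzero(child, rng))
        offspring = offspring[:P]
        off_fits = np.array([fit(m) for m in offspring])

        # the top-B parents survive unconditionally; the rest of the next
        # population is the fittest of the remaining parents and offspring
        elites = pop[: cfg.elitism]
        elite_fits = fits[: cfg.elitism]
        rest = pop[cfg.elitism :] + offspring
        rest_fits = np.concatenate([fits[cfg.elitism :], off_fits])
        keep = np.argsort(-rest_fits, kind="stable")[: P - cfg.elitism]
        pop = list(elites) + [rest[i] for i in keep]
        fits = np.concatenate([elite_fits, rest_fits[keep]])
        order = np.argsort(-fits, kind="stable")
        pop = [pop[i] for i in order]
        fits = fits[order]

        history.append(float(fits[0]))
        if fits[0] > best_seen + 1e-15:
            best_seen = fits[0]
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= cfg.stagnation_limit:
            break

    all_zero = bool(fits.max() == 0.0)
    if all_zero:
        # fall back to the least-disordered chromosome with a warning flag
        entropies = [
            _pooled_entropy(table.features[:, m].ravel(), cfg.n_bins, cfg.laplace) for m in pop
        ]
        best_mask = pop[int(np.argmin(entropies))]
        best = Chromosome(mask=best_mask, fitness=0.0)
    else:
        best = Chromosome(mask=pop[0], fitness=float(fits[0]))
    return GAResult(
        best=best,
        selected_indices=best.indices,
        history=history,
        generations_run=generations,
        all_zero_fitness=all_zero,
    )


# ---------------------------------------------------------------------------
# Downstream classification
# ---------------------------------------------------------------------------

CLASSIFIERS = {
    "gnb": lambda: GaussianNB(),
    "ld": lambda: NearestCentroid(),  # nearest-centroid linear discriminant
}


def classify(
    table: FusedFeatureTable,
    indices,
    classifier_name: str = "gnb",
    train_fraction: float = 0.7,
    seed: int = 0,
) -> dict:
    """Train/test a pluggable classifier on the selected columns.

    Uses a stratified 70–30 split at a fixed seed and reports accuracy
    plus macro-averaged precision, recall and F1.
    """
    indices = np.asarray(indices, dtype=int)
    if indices.size == 0:
        raise ConfigError("no feature indices selected")
    if classifier_name not in CLASSIFIERS:
        raise ConfigError(
            f"unknown classifier {classifier_name!r}; built-ins: {', '.join(sorted(CLASSIFIERS))}"
        )
    X = table.features[:, indices]
    y = table.labels
    # canonical row order (content digest) so the split — and hence the
    # metrics — depend only on the data, not on how rows were stored
    digests = [
        hashlib.sha256(X[i].tobytes() + str(y[i]).encode()).digest() for i in range(len(y))
    ]
    order = np.argsort(np.frombuffer(b"".join(digests), dtype="S32"))
    X, y = X[order], y[order]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, train_size=train_fraction, random_state=seed, stratify=y
    )
    clf = CLASSIFIERS[classifier_name]()
    clf.fit(X_tr, y_tr)
    pred = clf.predict(X_te)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_te, pred, average="macro", zero_division=0
    )
    return {
        "classifier": classifier_name,
        "accuracy": float((pred == y_te).mean()),
        "precision": float(prec),
        "recall": float(rec),
        "f1": float(f1),
        "n_train": int(len(y_tr)),
        "n_test": int(len(y_te)),
        "n_features": int(indices.size),
    }
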