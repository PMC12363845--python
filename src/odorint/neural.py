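"""Feed-forward intensity prediction from descriptors and concentration.

The predictor is a multilayer perceptron: fully connected hidden layers
(default 4 x 300), each followed by batch normalization and a ReLU, then a
width-1 linear output regressed on intensity with MSE loss, trained by
mini-batch SGD with momentum.  The network is implemented directly on numpy:
training is single-threaded, exactly reproducible for a fixed seed, and the
per-epoch loss trace is part of the returned predictor.

Inputs are feature blocks: the molecule's preprocessed descriptor vector
concatenated with the base-10 log of its concentration.  A mixture is encoded
as the concentration-weighted average of its component descriptor vectors
concatenated with the log of the total concentration.

Numerical note: features and targets are z-scored internally (statistics fit
on the training set only, stored on the predictor) — descriptor scales span
many orders of magnitude and raw-scale SGD at the default learning rate is
unstable without it.  Predictions are returned on the original gLMS scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import pearsonr

from .exceptions import InfeasibleSplitError, TrainingDivergedError
from .psychophysics import CurveFit, hill_intensity

__all__ = [
    "NetworkConfig",
    "TrainingExample",
    "FoldAssignment",
    "TrainedPredictor",
    "GroupedRmseReport",
    "augment_curves",
    "build_single_input",
    "build_mixture_input",
    "make_folds",
    "train",
    "shuffled_label_control",
    "evaluate_grouped_rmse",
    "examples_to_matrix",
]

logger = logging.getLogger(__name__)

FOLD_SCHEMES = ("molecule_stratified", "mixture_random", "clean_component")


@dataclass(frozen=True)
class NetworkConfig:
    """Architecture and training recipe of the intensity network."""

    hidden_layers: int = 4
    hidden_width: int = 300
    batch_norm: bool = True
    activation: str = "relu"
    output_width: int = 1
    loss: str = "mse"
    optimizer: str = "sgd_momentum"
    momentum: float = 0.9
    learning_rate: float = 1e-3
    epochs: int = 80
    batch_size: int = 64
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.hidden_layers, self.hidden_width, self.output_width, self.batch_size) < 1:
            raise ValueError("layer sizes and batch size must be positive integers")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")


@dataclass(frozen=True)
class TrainingExample:
    """One (feature block, intensity) pair with provenance metadata.

    ``source_id`` identifies the molecule or mixture the example came from
    (used by fold stratification); ``components`` lists the component
    molecule ids for mixture examples (used by the clean split).
    """

    features: np.ndarray
    log10_concentration: float
    target_intensity: float
    origin: str = "measured"  # measured | augmented | mixture
    source_id: str = ""
    components: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "features", np.asarray(self.features, dtype=float))
        object.__setattr__(self, "components", tuple(self.components))

    @property
    def input_vector(self) -> np.ndarray:
        return np.concatenate([self.features, [self.log10_concentration]])


def build_single_input(features: Sequence[float], concentration: float) -> np.ndarray:
    """Descriptor vector ++ [log10 concentration]; width = len(features) + 1."""
    if not (np.isfinite(concentration) and concentration > 0):
        raise ValueError(f"concentration must be finite and > 0, got {concentration!r}")
    return np.concatenate([np.asarray(features, dtype=float), [np.log10(concentration)]])


def build_mixture_input(components: Sequence[tuple[Sequence[float], float]]) -> np.ndarray:
    """Concentration-weighted descriptor average ++ [log10 total concentration].

    Weights are each component's concentration divided by the total, so they
    sum to 1; a single component reduces exactly to build_single_input.
    """
    if not components:
        raise ValueError("mixture input needs at least one component")
    concs = np.array([c for _, c in components], dtype=float)
    if np.any(concs < 0) or not np.all(np.isfinite(concs)):
        raise ValueError("component concentrations must be finite and >= 0")
    total = concs.sum()
    if total <= 0:
        raise ValueError("all component concentrations are zero")
    feats = np.stack([np.asarray(f, dtype=float) for f, _ in components])
    weighted = (concs / total) @ feats
    return np.concatenate([weighted, [np.log10(total)]])


def augment_curves(
    fits: Sequence[CurveFit],
    n_points: int = 300,
    conc_range: tuple[float, float] = (1e-10, 1e-3),
    features: Mapping[str, Sequence[float]] | None = None,
) -> list[TrainingExample]:
    """Up-sample fitted Hill curves into noiseless training examples.

    Each converged hill fit contributes exactly ``n_points`` examples at
    log10-regular intervals spanning the closed concentration range, targets
    evaluated on the fitted curve.  Non-converged fits are skipped with a
    warning.  ``features`` optionally attaches each molecule's descriptor
    vector; otherwise the feature block is left empty for later joining.
    """
    lo, hi = conc_range
    if not (0 < lo < hi):
        raise ValueError(f"invalid concentration range {conc_range!r}")
    grid = np.logspace(np.log10(lo), np.log10(hi), n_points)
    grid[0], grid[-1] = lo, hi  # exact closed endpoints
    out: list[TrainingExample] = []
    for fit in fits:
        if fit.family != "hill":
            raise ValueError(f"augmentation needs hill fits, got {fit.family!r}")
        if not fit.converged:
            logger.warning("skipping non-converged fit for %s", fit.odorant_id)
            continue
        fv = np.asarray(features[fit.odorant_id], dtype=float) if features else np.empty(0)
        targets = hill_intensity(fit.hill, grid)
        for c, t in zip(grid, targets):
            out.append(
                TrainingExample(fv, float(np.log10(c)), float(t), "augmented", fit.odorant_id)
            )
    return out


# ---------------------------------------------------------------------------
# fold assignment


@dataclass(frozen=True)
class FoldAssignment:
    """Partition of examples into cross-validation folds.

    ``membership[i]`` is the (test) fold of example i.  For the clean
    component-overlap scheme, ``train_indices[f]`` restricts fold f's
    training set to examples sharing no component with its test mixtures;
    for the other schemes training is simply the complement of the fold.
    """

    fold_count: int
    membership: np.ndarray
    scheme: str
    train_indices: Mapping[int, np.ndarray] | None = None

    def test_idx(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.membership == fold)

    def train_idx(self, fold: int) -> np.ndarray:
        if self.train_indices is not None:
            return np.asarray(self.train_indices[fold])
        return np.flatnonzero(self.membership != fold)


def _partition_groups(keys: list, fold_count: int, rng: np.random.Generator) -> dict:
    order = list(keys)
    rng.shuffle(order)
    return {k: i % fold_count for i, k in enumerate(order)}


def make_folds(
    examples: Sequence[TrainingExample],
    scheme: str,
    fold_count: int | None = 10,
    seed: int = 0,
) -> FoldAssignment:
    """Assign every example to exactly one test fold.

    molecule_stratified  all examples of one molecule share a fold
    mixture_random       mixtures (by source_id) spread randomly over folds
    clean_component      mixtures with identical component sets are grouped
                         and co-assigned; each fold's training set keeps only
                         mixtures with zero component overlap with its test
                         mixtures.  With ``fold_count=None`` every group gets
                         its own fold (leave-one-group-out), which keeps each
                         fold's disjoint training set as large as possible.
    """
    if scheme not in FOLD_SCHEMES:
        raise ValueError(f"unknown fold scheme {scheme!r}; valid: {FOLD_SCHEMES}")
    rng = np.random.default_rng(seed)
    n = len(examples)
    if n == 0:
        raise ValueError("no examples to fold")

    if scheme in ("molecule_stratified", "mixture_random"):
        if fold_count is None:
            raise ValueError("fold_count is required for this scheme")
        ids = sorted({ex.source_id for ex in examples})
        fold_of = _partition_groups(ids, fold_count, rng)
        membership = np.array([fold_of[ex.source_id] for ex in examples])
        return FoldAssignment(fold_count, membership, scheme)

    # clean_component
    if any(not ex.components for ex in examples):
        raise ValueError("clean_component folding needs component metadata on every example")
    group_keys = sorted({frozenset(ex.components) for ex in examples}, key=sorted)
    if fold_count is None:
        fold_count = len(group_keys)
        order = list(group_keys)
        rng.shuffle(order)
        fold_of_group = {k: i for i, k in enumerate(order)}
    else:
        fold_of_group = _partition_groups(group_keys, fold_count, rng)
    membership = np.array([fold_of_group[frozenset(ex.components)] for ex in examples])

    comp_sets = [frozenset(ex.components) for ex in examples]
    train_indices: dict[int, np.ndarray] = {}
    any_feasible = False
    for f in range(fold_count):
        test_comps = frozenset().union(*(cs for cs, m in zip(comp_sets, membership) if m == f)) \
            if np.any(membership == f) else frozenset()
        tr = np.array(
            [i for i in range(n) if membership[i] != f and not (comp_sets[i] & test_comps)],
            dtype=int,
        )
        train_indices[f] = tr
        any_feasible = any_feasible or len(tr) > 0
    if not any_feasible:
        counts: dict[str, int] = {}
        for cs in comp_sets:
            for c in cs:
                counts[c] = counts.get(c, 0) + 1
        blockers = sorted(counts, key=counts.get, reverse=True)[:5]
        raise InfeasibleSplitError(
            "no fold admits component-disjoint training mixtures", blocking_components=blockers
        )
    return FoldAssignment(fold_count, membership, scheme, train_indices)


# ---------------------------------------------------------------------------
# the network


class _MLP:
    """Plain-numpy MLP with optional batch normalization. Internal."""

    BN_EPS = 1e-5
    BN_MOMENTUM = 0.1

    def __init__(self, dims: list[int], batch_norm: bool, rng: np.random.Generator):
        self.batch_norm = batch_norm
        self.W, self.b = [], []
        self.gamma, self.beta = [], []
        self.run_mean, self.run_var = [], []
        for i in range(len(dims) - 1):
            fan_in = dims[i]
            bound = 1.0 / np.sqrt(fan_in)
            self.W.append(rng.uniform(-bound, bound, size=(dims[i], dims[i + 1])))
            self.b.append(rng.uniform(-bound, bound, size=dims[i + 1]))
            is_hidden = i < len(dims) - 2
            if batch_norm and is_hidden:
                self.gamma.append(np.ones(dims[i + 1]))
                self.beta.append(np.zeros(dims[i + 1]))
                self.run_mean.append(np.zeros(dims[i + 1]))
                self.run_var.append(np.ones(dims[i + 1]))
            else:
                self.gamma.append(None)
                self.beta.append(None)
                self.run_mean.append(None)
                self.run_var.append(None)

    def parameters(self):
        for i in range(len(self.W)):
            yield from ((self.W, i), (self.b, i))
            if self.gamma[i] is not None:
                yield from ((self.gamma, i), (self.beta, i))

    def forward(self, x: np.ndarray, training: bool):
        cache = []
        h = x
        last = len(self.W) - 1
        for i in range(len(self.W)):
            z = h @ self.W[i] + self.b[i]
            layer = {"x": h, "z": z}
            if i < last:
                if self.gamma[i] is not None:
                    if training:
                        mu = z.mean(axis=0)
                        var = z.var(axis=0)
                        m = self.BN_MOMENTUM
                        self.run_mean[i] = (1 - m) * self.run_mean[i] + m * mu
                        self.run_var[i] = (1 - m) * self.run_var[i] + m * var
                    else:
                        mu, var = self.run_mean[i], self.run_var[i]
                    inv = 1.0 / np.sqrt(var + self.BN_EPS)
                    xhat = (z - mu) * inv
                    a = self.gamma[i] * xhat + self.beta[i]
                    layer.update(xhat=xhat, inv=inv)
                else:
                    a = z
                h = np.maximum(a, 0.0)
                layer["a"] = a
            else:
                h = z
            cache.append(layer)
        return h, cache

    def backward(self, cache, dout: np.ndarray):
        grads = {}
        last = len(self.W) - 1
        d = dout
        for i in range(last, -1, -1):
            layer = cache[i]
            if i < last:
                d = d * (layer["a"] > 0)  # ReLU
                if self.gamma[i] is not None:
                    xhat, inv = layer["xhat"], layer["inv"]
                    grads[("gamma", i)] = (d * xhat).sum(axis=0)
                    grads[("beta", i)] = d.sum(axis=0)
                    nb = d.shape[0]
                    dxhat = d * self.gamma[i]
                    d = inv * (
                        dxhat
                        - dxhat.mean(axis=0)
                        - xhat * (dxhat * xhat).sum(axis=0) / nb
                    )
            grads[("W", i)] = layer["x"].T @ d
            grads[("b", i)] = d.sum(axis=0)
            d = d @ self.W[i].T
        return grads

    def weight_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        for arrs in (self.W, self.b, self.gamma, self.beta):
            for a in arrs:
                if a is not None:
                    h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()


@dataclass
class TrainedPredictor:
    """A trained network plus the preprocessing state needed to apply it."""

    mlp: _MLP
    config: NetworkConfig
    feature_schema: tuple[str, ...] | None
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: float
    y_std: float
    loss_history: list[float]
    trained: bool

    def predict(self, inputs: np.ndarray) -> np.ndarray:
        """Predict intensities for rows of feature blocks (gLMS units)."""
        x = np.atleast_2d(np.asarray(inputs, dtype=float))
        xs = (x - self.x_mean) / self.x_std
        out, _ = self.mlp.forward(xs, training=False)
        return out[:, 0] * self.y_std + self.y_mean

    def predict_single(self, features: Sequence[float], concentration: float) -> float:
        return float(self.predict(build_single_input(features, concentration)[None, :])[0])

    def predict_mixture(self, components: Sequence[tuple[Sequence[float], float]]) -> float:
        return float(self.predict(build_mixture_input(components)[None, :])[0])

    def save(self, path) -> None:
        """Write a checkpoint (weights + normalization + config + schema)."""
        import json

        arrays = {
            "x_mean": self.x_mean, "x_std": self.x_std,
            "y_stats": np.array([self.y_mean, self.y_std]),
            "loss_history": np.array(self.loss_history),
        }
        for i in range(len(self.mlp.W)):
            arrays[f"W{i}"] = self.mlp.W[i]
            arrays[f"b{i}"] = self.mlp.b[i]
            if self.mlp.gamma[i] is not None:
                arrays[f"gamma{i}"] = self.mlp.gamma[i]
                arrays[f"beta{i}"] = self.mlp.beta[i]
                arrays[f"run_mean{i}"] = self.mlp.run_mean[i]
                arrays[f"run_var{i}"] = self.mlp.run_var[i]
        meta = {
            "config": {k: getattr(self.config, k) for k in self.config.__dataclass_fields__},
            "feature_schema": list(self.feature_schema) if self.feature_schema else None,
            "trained": self.trained,
            "n_layers": len(self.mlp.W),
        }
        np.savez(path, _meta=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedPredictor":
        import json

        data = np.load(path, allow_pickle=False)
        meta = json.loads(str(data["_meta"]))
        config = NetworkConfig(**meta["config"])
        dims = [data["W0"].shape[0]] + [data[f"W{i}"].shape[1] for i in range(meta["n_layers"])]
        mlp = _MLP(dims, config.batch_norm, np.random.default_rng(0))
        for i in range(meta["n_layers"]):
            mlp.W[i] = data[f"W{i}"]
            mlp.b[i] = data[f"b{i}"]
            if f"gamma{i}" in data:
                mlp.gamma[i] = data[f"gamma{i}"]
                mlp.beta[i] = data[f"beta{i}"]
                mlp.run_mean[i] = data[f"run_mean{i}"]
                mlp.run_var[i] = data[f"run_var{i}"]
        return cls(
            mlp=mlp,
            config=config,
            feature_schema=tuple(meta["feature_schema"]) if meta["feature_schema"] else None,
            x_mean=data["x_mean"],
            x_std=data["x_std"],
            y_mean=float(data["y_stats"][0]),
            y_std=float(data["y_stats"][1]),
            loss_history=[float(v) for v in data["loss_history"]],
            trained=bool(meta["trained"]),
        )


def examples_to_matrix(examples: Sequence[TrainingExample]) -> tuple[np.ndarray, np.ndarray]:
    """Stack examples into an (n, d+1) input matrix and an (n,) target vector."""
    x = np.stack([ex.input_vector for ex in examples])
    y = np.array([ex.target_intensity for ex in examples])
    return x, y


def train(
    examples: Sequence[TrainingExample],
    config: NetworkConfig = NetworkConfig(),
    feature_schema: Sequence[str] | None = None,
) -> TrainedPredictor:
    """Train the network for exactly ``config.epochs`` epochs.

    Deterministic for a fixed ``config.seed``.  The per-epoch mean training
    loss (MSE, gLMS² units) is recorded on the returned predictor.  A
    non-finite loss aborts with TrainingDivergedError naming the epoch.
    With ``epochs=0`` the predictor is returned untrained (``trained=False``)
    with initialization-dependent outputs.
    """
    if len(examples) == 0:
        raise ValueError("no training examples")
    x, y = examples_to_matrix(examples)
    if x.ndim != 2:
        raise ValueError("examples have inconsistent feature widths")
    rng = np.random.default_rng(config.seed)

    x_mean = x.mean(axis=0)
    x_std = x.std(axis=0)
    x_std[x_std < 1e-12] = 1.0
    y_mean = float(y.mean())
    y_std = float(y.std()) or 1.0
    xs = (x - x_mean) / x_std
    ys = (y - y_mean) / y_std

    dims = [x.shape[1]] + [config.hidden_width] * config.hidden_layers + [config.output_width]
    mlp = _MLP(dims, config.batch_norm, rng)
    velocity: dict = {}
    n = len(xs)
    bs = min(config.batch_size, n)
    loss_history: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for start in range(0, n, bs):
            idx = order[start : start + bs]
            if len(idx) < 2 and config.batch_norm and n > 1:
                continue  # batch statistics undefined for a single sample
            xb, yb = xs[idx], ys[idx]
            out, cache = mlp.forward(xb, training=True)
            err = out[:, 0] - yb
            loss = float(np.mean(err**2))
            epoch_loss += loss * len(idx)
            seen += len(idx)
            dout = (2.0 / len(idx)) * err[:, None]
            grads = mlp.backward(cache, dout)
            for key, g in grads.items():
                kind, i = key
                arr = getattr(mlp, kind)[i]
                v = velocity.get(key, 0.0)
                v = config.momentum * v - config.learning_rate * g
                velocity[key] = v
                getattr(mlp, kind)[i] = arr + v
        mean_loss = (epoch_loss / max(seen, 1)) * y_std**2
        if not np.isfinite(mean_loss):
            raise TrainingDivergedError(f"loss non-finite at epoch {epoch}", epoch=epoch)
        loss_history.append(mean_loss)

    return TrainedPredictor(
        mlp=mlp,
        config=config,
        feature_schema=tuple(feature_schema) if feature_schema is not None else None,
        x_mean=x_mean,
        x_std=x_std,
        y_mean=y_mean,
        y_std=y_std,
        loss_history=loss_history,
        trained=config.epochs > 0,
    )


def shuffled_label_control(
    examples: Sequence[TrainingExample],
    config: NetworkConfig = NetworkConfig(),
    seed: int = 0,
    feature_schema: Sequence[str] | None = None,
) -> TrainedPredictor:
    """Train on targets permuted across examples (negative control).

    The permutation (fixed by ``seed``) is a bijection of the original
    targets; everything else matches ``train`` exactly.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(examples))
    shuffled = [
        replace(ex, target_intensity=examples[j].target_intensity)
        for ex, j in zip(examples, perm)
    ]
    return train(shuffled, config, feature_schema)


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class GroupedRmseReport:
    per_group_rmse: Mapping[str, float]
    mean_rmse: float
    pearson_r: float  # nan when undefined (zero-variance inputs)


def evaluate_grouped_rmse(
    predictions: Sequence[float],
    truths: Sequence[float],
    group_labels: Sequence,
) -> GroupedRmseReport:
    """Per-group RMSE, their unweighted mean, and overall Pearson r.

    Grouping (e.g. by mixture size) stops abundant groups from dominating the
    summary.  With degenerate inputs (constant predictions or truths) the
    correlation is reported as NaN with a warning.
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(truths, dtype=float)
    g = np.asarray(group_labels)
    if not (len(p) == len(t) == len(g)):
        raise ValueError("predictions, truths and group_labels must be aligned")
    per_group: dict = {}
    for label in sorted(set(g.tolist()), key=str):
        mask = g == label
        if not np.any(mask):
            logger.warning("empty group %r excluded", label)
            continue
        per_group[label] = float(np.sqrt(np.mean((p[mask] - t[mask]) ** 2)))
    if np.std(p) < 1e-15 or np.std(t) < 1e-15:
        logger.warning("Pearson r undefined for constant predictions/truths")
        r = float("nan")
    else:
        r = float(pearsonr(p, t)[0])
    return GroupedRmseReport(per_group, float(np.mean(list(per_group.values()))), r)
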