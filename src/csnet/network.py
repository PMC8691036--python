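"""The class-similarity network: architecture, training, ensembling, prediction.

The classifier measures how similar an input transcript's high-level
(convolutional) features are to those of reference samples from each class,
instead of classifying the raw feature vector directly:

* **similarity measurement** — the input vector x and per-class reference
  vectors x'_pos, x'_neg each pass through a stack of 1-D convolution
  layers; the similarity maps are the differences
  f_ps = Conv(x) - Conv(x'_pos) and f_ns = Conv(x) - Conv(x'_neg);
* **fully connected branches** — each similarity map feeds an independent
  branch: dropout(r1) -> dense(hidden, ReLU) -> dense(1, sigmoid) giving
  z2, and in parallel dropout(r2) -> dense(1, sigmoid) giving z3; the
  branch's similarity node is y = z2 + z3 (bounded in [0, 2]);
* **decision** — the two nodes [y_ps, y_ns] are trained with mean squared
  error against a two-node class target; at prediction time the class with
  the larger (convention-aligned) node wins.

During training every input row is paired with rows resampled (with
replacement) from the training classes; at prediction time the resampled
references are replaced by the training-class mean vectors so predictions
are deterministic. The final classifier is an ensemble that sums the node
scores of independently trained models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from ._nn import Adamax, Conv1D, Dense, Dropout
from .features import (
    FeatureModel,
    FeatureScaler,
    N_FEATURES,
    featurize_many,
    fit_feature_model,
)
from .sequence_io import SequenceRecord

TARGET_CONVENTIONS = ("[1,0]", "[0,1]")
CONV_SHARING = ("per_channel", "per_class")
DENSE_VARIANTS = ("z2", "z3", "z2+z3")


@dataclass
class NetworkConfig:
    """Hyper-parameters of one class-similarity model.

    Defaults follow the published configuration: two 1-D convolution
    layers with kernel 2 and stride 1, Adamax, 60 epochs, batch 256,
    dropout ratios r1=0.2 / r2=0.5, hidden width 128 and a 3-model
    score-sum ensemble. The convolution width (32 filters) is a package
    default, exposed here. ``conv_sharing`` selects whether the three
    input channels have fully independent convolution stacks
    ("per_channel") or one stack per class applied to both the input and
    that class's reference ("per_class"). ``target_convention`` is the
    two-node target of the positive class: "[1,0]" trains the nodes as
    similarities, "[0,1]" as differences. ``resample_every`` re-draws the
    reference sets every n epochs when set (off by default).
    """

    n_conv_layers: int = 2
    kernel_size: int = 2
    stride: int = 1
    n_filters: int = 32
    hidden_units: int = 128
    dropout_r1: float = 0.2
    dropout_r2: float = 0.5
    optimizer: str = "adamax"
    learning_rate: float = 0.002
    epochs: int = 60
    batch_size: int = 256
    n_ensemble: int = 3
    conv_sharing: str = "per_channel"
    dense_variant: str = "z2+z3"
    target_convention: str = "[1,0]"
    resample_every: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kernel_size < 1 or self.stride < 1:
            raise ValueError("kernel_size and stride must be >= 1")
        if not (0 <= self.dropout_r1 < 1 and 0 <= self.dropout_r2 < 1):
            raise ValueError("dropout ratios must be in [0, 1)")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")
        if self.n_conv_layers < 1:
            raise ValueError("n_conv_layers must be >= 1")
        if self.conv_sharing not in CONV_SHARING:
            raise ValueError(f"conv_sharing must be one of {CONV_SHARING}")
        if self.target_convention not in TARGET_CONVENTIONS:
            raise ValueError(f"target_convention must be one of {TARGET_CONVENTIONS}")
        if self.dense_variant not in DENSE_VARIANTS:
            raise ValueError(f"dense_variant must be one of {DENSE_VARIANTS}")
        if self.optimizer != "adamax":
            raise ValueError("only the adamax optimizer is supported")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass
class ReferenceSets:
    """Per-row class references paired with an input batch.

    In "resampled" mode (training) the rows are drawn with replacement
    from the training classes and row i pairs with input row i; in "mean"
    mode (prediction) each matrix is the single class mean broadcast to
    the batch.
    """

    x_pos_ref: np.ndarray
    x_neg_ref: np.ndarray
    mode: str = "resampled"


def resample_references(
    train_pos: np.ndarray, train_neg: np.ndarray, k: int, seed: int
) -> ReferenceSets:
    """Draw k rows uniformly with replacement from each class.

    Deterministic under ``seed``; pairing with the input batch is
    positional.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    train_pos = np.atleast_2d(train_pos)
    train_neg = np.atleast_2d(train_neg)
    if train_pos.shape[0] == 0 or train_neg.shape[0] == 0:
        raise ValueError("both training classes must be non-empty")
    rng = np.random.default_rng(seed)
    ip = rng.integers(0, train_pos.shape[0], size=k)
    ineg = rng.integers(0, train_neg.shape[0], size=k)
    return ReferenceSets(x_pos_ref=train_pos[ip], x_neg_ref=train_neg[ineg], mode="resampled")


class _ConvStack:
    """Sequential 1-D conv + ReLU layers acting on a (B, L, 1) signal."""

    def __init__(self, config: NetworkConfig, n_features: int, rng: np.random.Generator, name: str):
        self.layers: list[Conv1D] = []
        length, c_in = n_features, 1
        for i in range(config.n_conv_layers):
            layer = Conv1D(config.kernel_size, c_in, config.n_filters, config.stride,
                           rng, name=f"{name}.conv{i}")
            length = layer.out_len(length)
            c_in = config.n_filters
            self.layers.append(layer)
        self.out_shape = (length, c_in)

    def forward(self, X: np.ndarray) -> np.ndarray:
        for layer in self.layers:
            X = layer.forward(X)
        return X

    def backward(self, dA: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dA = layer.backward(dA)
        return dA

    def params(self):
        out = {}
        for layer in self.layers:
            out.update(layer.params())
        return out


class _Branch:
    """One fully connected branch turning a similarity map into a node in [0,2]."""

    def __init__(self, config: NetworkConfig, flat_dim: int, rng: np.random.Generator, name: str):
        self.variant = config.dense_variant
        self.drop1 = Dropout(config.dropout_r1)
        self.drop2 = Dropout(config.dropout_r2)
        if self.variant in ("z2", "z2+z3"):
            self.dense1 = Dense(flat_dim, config.hidden_units, "relu", rng, f"{name}.dense1")
            self.dense2 = Dense(config.hidden_units, 1, "sigmoid", rng, f"{name}.dense2")
        if self.variant in ("z3", "z2+z3"):
            self.dense3 = Dense(flat_dim, 1, "sigmoid", rng, f"{name}.dense3")

    def forward(self, f: np.ndarray, train: bool, rng: np.random.Generator | None) -> np.ndarray:
        y = 0.0
        if self.variant in ("z2", "z2+z3"):
            h1 = self.drop1.forward(f, train, rng)
            z2 = self.dense2.forward(self.dense1.forward(h1))
            y = y + z2
        if self.variant in ("z3", "z2+z3"):
            h2 = self.drop2.forward(f, train, rng)
            z3 = self.dense3.forward(h2)
            y = y + z3
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        df = 0.0
        if self.variant in ("z2", "z2+z3"):
            df = df + self.drop1.backward(self.dense1.backward(self.dense2.backward(dy)))
        if self.variant in ("z3", "z2+z3"):
            df = df + self.drop2.backward(self.dense3.backward(dy))
        return df

    def params(self):
        out = {}
        if self.variant in ("z2", "z2+z3"):
            out.update(self.dense1.params())
            out.update(self.dense2.params())
        if self.variant in ("z3", "z2+z3"):
            out.update(self.dense3.params())
        return out


class ClassSimilarityModel:
    """One trained (or trainable) class-similarity network."""

    def __init__(self, config: NetworkConfig, n_features: int = N_FEATURES,
                 rng: np.random.Generator | None = None):
        if n_features < 1:
            raise ValueError("n_features must be positive")
        rng = rng or np.random.default_rng(config.seed)
        self.config = config
        self.n_features = n_features
        if config.conv_sharing == "per_channel":
            self.stack_x = _ConvStack(config, n_features, rng, "stack_x")
            self.stack_pos = _ConvStack(config, n_features, rng, "stack_pos")
            self.stack_neg = _ConvStack(config, n_features, rng, "stack_neg")
            out_shape = self.stack_x.out_shape
        else:  # per_class: one stack per class, applied to input and reference
            self.stack_pos = _ConvStack(config, n_features, rng, "stack_pos")
            self.stack_neg = _ConvStack(config, n_features, rng, "stack_neg")
            out_shape = self.stack_pos.out_shape
        self.conv_out_shape = out_shape
        flat_dim = out_shape[0] * out_shape[1]
        self.branch_ps = _Branch(config, flat_dim, rng, "branch_ps")
        self.branch_ns = _Branch(config, flat_dim, rng, "branch_ns")
        self.history: list[float] = []

    # -- forward / backward ------------------------------------------------

    def _flat(self, A: np.ndarray) -> np.ndarray:
        return A.reshape(A.shape[0], -1)

    def similarity_maps(self, X: np.ndarray, Rp: np.ndarray, Rn: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """f_ps and f_ns (flattened) for a batch; no dropout involved."""
        X3 = X[:, :, None]
        Rp3 = Rp[:, :, None]
        Rn3 = Rn[:, :, None]
        if self.config.conv_sharing == "per_channel":
            cx = self.stack_x.forward(X3)
            f_ps = self._flat(cx - self.stack_pos.forward(Rp3))
            f_ns = self._flat(cx - self.stack_neg.forward(Rn3))
        else:
            B = X.shape[0]
            outp = self.stack_pos.forward(np.concatenate([X3, Rp3], axis=0))
            f_ps = self._flat(outp[:B] - outp[B:])
            outn = self.stack_neg.forward(np.concatenate([X3, Rn3], axis=0))
            f_ns = self._flat(outn[:B] - outn[B:])
        return f_ps, f_ns

    def forward(self, X: np.ndarray, Rp: np.ndarray, Rn: np.ndarray,
                train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        """Network output [y_ps, y_ns] of shape (B, 2)."""
        f_ps, f_ns = self.similarity_maps(X, Rp, Rn)
        y_ps = self.branch_ps.forward(f_ps, train, rng)
        y_ns = self.branch_ns.forward(f_ns, train, rng)
        return np.concatenate([y_ps, y_ns], axis=1)

    def backward(self, dY: np.ndarray) -> None:
        """Accumulate parameter gradients; dY is dLoss/d[y_ps, y_ns]."""
        B = dY.shape[0]
        shape = (B, *self.conv_out_shape)
        df_ps = self.branch_ps.backward(dY[:, 0:1]).reshape(shape)
        df_ns = self.branch_ns.backward(dY[:, 1:2]).reshape(shape)
        if self.config.conv_sharing == "per_channel":
            self.stack_x.backward(df_ps + df_ns)
            self.stack_pos.backward(-df_ps)
            self.stack_neg.backward(-df_ns)
        else:
            self.stack_pos.backward(np.concatenate([df_ps, -df_ps], axis=0))
            self.stack_neg.backward(np.concatenate([df_ns, -df_ns], axis=0))

    # -- parameters --------------------------------------------------------

    def params(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        out = {}
        if self.config.conv_sharing == "per_channel":
            out.update(self.stack_x.params())
        out.update(self.stack_pos.params())
        out.update(self.stack_neg.params())
        out.update(self.branch_ps.params())
        out.update(self.branch_ns.params())
        return out

    def get_weights(self) -> dict[str, np.ndarray]:
        return {k: w.copy() for k, (w, _) in self.params().items()}

    def set_weights(self, weights: dict[str, np.ndarray]) -> None:
        for k, (w, _) in self.params().items():
            w[...] = weights[k]

    def zero_weights(self) -> None:
        """Set every weight and bias to zero (diagnostic aid)."""
        for _, (w, _) in self.params().items():
            w[...] = 0.0


def build_network(config: NetworkConfig, n_features: int = N_FEATURES,
                  rng: np.random.Generator | None = None) -> ClassSimilarityModel:
    """Construct an untrained class-similarity model."""
    return ClassSimilarityModel(config, n_features, rng)


def _targets(labels: np.ndarray, convention: str) -> np.ndarray:
    pos = np.asarray(labels).astype(bool)
    Y = np.zeros((pos.size, 2))
    if convention == "[1,0]":
        Y[pos, 0] = 1.0
        Y[~pos, 1] = 1.0
    else:
        Y[pos, 1] = 1.0
        Y[~pos, 0] = 1.0
    return Y


def train_model(
    train_features: np.ndarray,
    train_labels: np.ndarray,
    config: NetworkConfig,
    seed: int | None = None,
    ref_seed: int | None = None,
    epoch_callback=None,
) -> ClassSimilarityModel:
    """Train one model by MSE minimisation with Adamax.

    ``train_features`` must already be scaled; ``train_labels`` is binary
    with 1 = positive class. References are resampled once at the start
    (and every ``config.resample_every`` epochs when set). All randomness
    (weight init, reference resampling, batch shuffling, dropout) derives
    from one seed; ``ref_seed`` overrides the derived reference-resampling
    seed so experiments can vary the reference sets while holding
    everything else fixed. ``epoch_callback(model, epoch)``, when given,
    runs after every epoch (e.g. to record validation accuracy).
    """
    X = np.asarray(train_features, dtype=float)
    y = np.asarray(train_labels).astype(int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError("features and labels disagree in length")
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("training data must contain both classes")
    seed = config.seed if seed is None else seed
    ss = np.random.SeedSequence(seed)
    init_rng, drop_rng, shuffle_rng = (np.random.default_rng(c) for c in ss.spawn(3))
    if ref_seed is None:
        ref_seeds = ss.generate_state(max(config.epochs, 1), dtype=np.uint32)
    else:
        ref_seeds = np.random.SeedSequence(ref_seed).generate_state(
            max(config.epochs, 1), dtype=np.uint32
        )

    model = ClassSimilarityModel(config, X.shape[1], init_rng)
    opt = Adamax(model.params(), lr=config.learning_rate)

    Xpos, Xneg = X[y == 1], X[y == 0]
    n = X.shape[0]
    refs = resample_references(Xpos, Xneg, n, int(ref_seeds[0]))
    Rp, Rn = refs.x_pos_ref, refs.x_neg_ref
    Y = _targets(y, config.target_convention)

    for epoch in range(config.epochs):
        if (config.resample_every and epoch > 0
                and epoch % config.resample_every == 0):
            refs = resample_references(Xpos, Xneg, n, int(ref_seeds[epoch]))
            Rp, Rn = refs.x_pos_ref, refs.x_neg_ref
        perm = shuffle_rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            idx = perm[lo : lo + config.batch_size]
            yhat = model.forward(X[idx], Rp[idx], Rn[idx], train=True, rng=drop_rng)
            err = yhat - Y[idx]
            losses.append(float((err**2).mean()))
            model.backward(2.0 * err / err.size)
            opt.step()
            opt.zero_grad()
        model.history.append(float(np.mean(losses)))
        if epoch_callback is not None:
            epoch_callback(model, epoch)
    return model


@dataclass
class PredictionResult:
    """Ensemble scores and predicted label for one record.

    ``score_pos``/``score_neg`` are the positive/negative similarity nodes
    summed over the ensemble's models (each per-model node lies in [0, 2]).
    """

    id: str
    score_pos: float
    score_neg: float
    predicted_label: str


@dataclass
class ClassSimilarityEnsemble:
    """Trained artifact: component models, class mean references, feature model."""

    models: list[ClassSimilarityModel]
    mean_pos_ref: np.ndarray
    mean_neg_ref: np.ndarray
    feature_model: FeatureModel
    config: NetworkConfig
    positive_label: str = "lncRNA"
    negative_label: str = "mRNA"

    def decision_scores(self, score_pos: np.ndarray, score_neg: np.ndarray) -> np.ndarray:
        """Margin toward the positive class, monotone in positive confidence."""
        d = np.asarray(score_pos) - np.asarray(score_neg)
        return d if self.config.target_convention == "[1,0]" else -d

    # -- persistence -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        meta = {
            "config": self.config.to_dict(),
            "positive_label": self.positive_label,
            "negative_label": self.negative_label,
            "n_features": self.models[0].n_features,
        }
        (directory / "config.json").write_text(json.dumps(meta))
        self.feature_model.to_json(directory / "feature_model.json")
        (directory / "references.json").write_text(json.dumps({
            "mean_pos_ref": self.mean_pos_ref.tolist(),
            "mean_neg_ref": self.mean_neg_ref.tolist(),
        }))
        for i, m in enumerate(self.models):
            np.savez(directory / f"model_{i}.npz", **m.get_weights())

    @classmethod
    def load(cls, directory: str | Path) -> "ClassSimilarityEnsemble":
        directory = Path(directory)
        meta = json.loads((directory / "config.json").read_text())
        config = NetworkConfig.from_dict(meta["config"])
        feature_model = FeatureModel.from_json(directory / "feature_model.json")
        refs = json.loads((directory / "references.json").read_text())
        models = []
        for i in range(config.n_ensemble):
            m = ClassSimilarityModel(config, meta["n_features"])
            with np.load(directory / f"model_{i}.npz") as npz:
                m.set_weights({k: npz[k] for k in npz.files})
            models.append(m)
        return cls(
            models=models,
            mean_pos_ref=np.asarray(refs["mean_pos_ref"]),
            mean_neg_ref=np.asarray(refs["mean_neg_ref"]),
            feature_model=feature_model,
            config=config,
            positive_label=meta["positive_label"],
            negative_label=meta["negative_label"],
        )


def train_ensemble(
    train_pos: Sequence[SequenceRecord],
    train_neg: Sequence[SequenceRecord],
    config: NetworkConfig,
    positive_label: str = "lncRNA",
    negative_label: str = "mRNA",
    pseudocount: float = 1e-3,
    kmer_score_mode: str = "weighted",
) -> ClassSimilarityEnsemble:
    """Fit features and train the score-sum ensemble.

    ``train_pos`` is the positive class (lncRNA by the package's training
    convention) and ``train_neg`` the negative class (mRNA). The feature
    model's mRNA/lncRNA statistics are taken from the negative/positive
    sets respectively; a min-max scaler is fitted on the pooled training
    feature matrix. Each component model gets an independently resampled
    reference pairing via its own derived seed.
    """
    if not train_pos or not train_neg:
        raise ValueError("both training classes must be non-empty")
    fm = fit_feature_model(
        train_mRNA=train_neg, train_lncRNA=train_pos,
        pseudocount=pseudocount, kmer_score_mode=kmer_score_mode,
    )
    Fpos = featurize_many(train_pos, fm)
    Fneg = featurize_many(train_neg, fm)
    fm.scaler = FeatureScaler.fit(np.vstack([Fpos, Fneg]))
    Spos = fm.scaler.transform(Fpos)
    Sneg = fm.scaler.transform(Fneg)
    X = np.vstack([Spos, Sneg])
    y = np.concatenate([np.ones(len(Spos), dtype=int), np.zeros(len(Sneg), dtype=int)])

    model_seeds = np.random.SeedSequence(config.seed).generate_state(
        config.n_ensemble, dtype=np.uint32
    )
    models = [
        train_model(X, y, config, seed=int(s)) for s in model_seeds
    ]
    return ClassSimilarityEnsemble(
        models=models,
        mean_pos_ref=Spos.mean(axis=0),
        mean_neg_ref=Sneg.mean(axis=0),
        feature_model=fm,
        config=config,
        positive_label=positive_label,
        negative_label=negative_label,
    )


def predict_features(ensemble: ClassSimilarityEnsemble, X_scaled: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble-summed (score_pos, score_neg) for pre-scaled feature rows."""
    n = X_scaled.shape[0]
    Rp = np.tile(ensemble.mean_pos_ref, (n, 1))
    Rn = np.tile(ensemble.mean_neg_ref, (n, 1))
    total = np.zeros((n, 2))
    for m in ensemble.models:
        total += m.forward(X_scaled, Rp, Rn, train=False)
    return total[:, 0], total[:, 1]


def predict(ensemble: ClassSimilarityEnsemble, records: Sequence[SequenceRecord]) -> list[PredictionResult]:
    """Classify records with the trained ensemble.

    Every record is paired with the training-class mean reference vectors,
    so repeated calls are bit-for-bit identical. A record whose sequence
    violates the A/C/G/T contract is flagged (label "invalid_sequence"),
    never silently dropped. Ties on the two scores go to the positive
    class.
    """
    valid, invalid = [], []
    for i, rec in enumerate(records):
        if rec.seq and set(rec.seq) <= set("ACGT"):
            valid.append((i, rec))
        else:
            invalid.append((i, rec))
    results: list[PredictionResult | None] = [None] * len(records)
    for i, rec in invalid:
        results[i] = PredictionResult(rec.id, float("nan"), float("nan"), "invalid_sequence")
    if valid:
        fm = ensemble.feature_model
        F = featurize_many([r for _, r in valid], fm)
        Xs = fm.scaler.transform(F)
        sp, sn = predict_features(ensemble, Xs)
        pos_first = ensemble.config.target_convention == "[1,0]"
        for (i, rec), p, n_ in zip(valid, sp, sn):
            pos_wins = (p >= n_) if pos_first else (n_ >= p)
            label = ensemble.positive_label if pos_wins else ensemble.negative_label
            results[i] = PredictionResult(rec.id, float(p), float(n_), label)
    return results  # type: ignore[return-value]
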