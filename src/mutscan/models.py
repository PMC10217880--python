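"""The three recurrent base classifiers (LSTM, GRU, BLSTM).

Each model is a scikit-learn-style estimator over either

- ``input_mode="feature_vector"``: a (n_samples, n_features) matrix of
  moment features, z-scored per feature on the training data and presented
  to the recurrent stack as a length-F sequence of scalars; or
- ``input_mode="token_sequence"``: integer-encoded nucleotide sequences,
  right-truncated / zero-padded to ``fixed_length`` (default 64) and passed
  through a trainable embedding of width ``embedding_dim``.

Architectures (classification head is always a 2-unit normalized-exponential
layer trained with sparse categorical cross-entropy; the exported score is
the probability of the mutated class):

- LSTM:  lstm(128) -> dropout(0.2) -> dense(64, sigmoid) -> dropout(0.2) -> head
- GRU:   gru(256) -> simple_rnn(128) -> dropout(0.3) -> dropout(0.3)
         -> dense(10, sigmoid) -> head
- BLSTM: bidirectional lstm(128 per direction) -> dropout(0.2)
         -> dense(64, sigmoid) -> dropout(0.2) -> head

Optimization is plain SGD (learning rate 0.01, momentum 0 by default) with
global-norm gradient clipping; everything is deterministic given
``random_state``.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from . import _rnn
from .datagen import GeneSequence
from .errors import (
    DivergenceError,
    InferenceError,
    ParameterError,
    TrainingError,
)
from .features import NUC_CODE

MODEL_NAMES = ("LSTM", "GRU", "BLSTM")

_FORMAT_VERSION = 1


@dataclass(frozen=True)
class LayerSpec:
    """One layer of a base-classifier architecture."""

    kind: str  # embedding | recurrent_lstm | recurrent_gru | recurrent_simple
    #            | bidirectional_lstm | dense | dropout
    units: int | None = None
    rate: float | None = None
    activation: str = "none"  # sigmoid | tanh | softmax | none

    def __post_init__(self):
        if self.kind == "dropout":
            if self.rate is None or not 0.0 <= self.rate < 1.0:
                raise ParameterError(f"dropout layer needs rate in [0,1): {self}")
        elif self.rate is not None:
            raise ParameterError(f"rate only valid for dropout layers: {self}")
        if self.kind in ("embedding", "dense") or self.kind.startswith(
            ("recurrent", "bidirectional")
        ):
            if not self.units or self.units < 1:
                raise ParameterError(f"{self.kind} layer needs positive units: {self}")


@dataclass
class ModelSpec:
    """Layer-by-layer description of one base classifier plus training config."""

    name: str
    layers: list[LayerSpec]
    input_mode: str = "token_sequence"  # token_sequence | feature_vector
    fixed_length: int = 64
    optimizer: str = "sgd"
    learning_rate: float = 0.05
    momentum: float = 0.9
    loss: str = "sparse_categorical_crossentropy"
    epochs: int = 50
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ParameterError(f"unknown model name {self.name!r}")
        if self.input_mode not in ("feature_vector", "token_sequence"):
            raise ParameterError(f"unknown input_mode {self.input_mode!r}")
        if not self.layers or self.layers[-1].units != 2:
            raise ParameterError("last layer must be the 2-unit classification head")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["layers"] = [asdict(l) for l in self.layers]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        d = dict(d)
        d["layers"] = [LayerSpec(**l) for l in d["layers"]]
        if "fixed_length" in d:
            d["fixed_length"] = int(d["fixed_length"])
        return cls(**d)


def default_spec(name: str, input_mode: str = "token_sequence", **overrides) -> ModelSpec:
    """The stated architecture of one base model.

    LSTM has two dropout layers at 20%; GRU stacks a 256-unit GRU and a
    128-unit simple RNN with two 30% dropouts and a 10-unit dense layer
    placed penultimate (a 10-unit terminal layer cannot express two
    classes); BLSTM mirrors LSTM with a bidirectional recurrent layer.

    The GRU trains with a smaller step (0.02 vs 0.05): with two stacked
    recurrent layers, larger momentum-SGD steps destabilize it.
    """
    overrides.setdefault("learning_rate", 0.02 if name == "GRU" else 0.05)
    head = LayerSpec("dense", units=2, activation="softmax")
    if name == "LSTM":
        layers = [
            LayerSpec("embedding", units=64),
            LayerSpec("recurrent_lstm", units=128, activation="sigmoid"),
            LayerSpec("dropout", rate=0.2),
            LayerSpec("dense", units=64, activation="sigmoid"),
            LayerSpec("dropout", rate=0.2),
            head,
        ]
    elif name == "GRU":
        layers = [
            LayerSpec("embedding", units=64),
            LayerSpec("recurrent_gru", units=256, activation="sigmoid"),
            LayerSpec("recurrent_simple", units=128, activation="tanh"),
            LayerSpec("dropout", rate=0.3),
            LayerSpec("dropout", rate=0.3),
            LayerSpec("dense", units=10, activation="sigmoid"),
            head,
        ]
    elif name == "BLSTM":
        layers = [
            LayerSpec("embedding", units=64),
            LayerSpec("bidirectional_lstm", units=128, activation="sigmoid"),
            LayerSpec("dropout", rate=0.2),
            LayerSpec("dense", units=64, activation="sigmoid"),
            LayerSpec("dropout", rate=0.2),
            head,
        ]
    else:
        raise ParameterError(f"unknown model name {name!r}")
    return ModelSpec(name=name, layers=layers, input_mode=input_mode, **overrides)


# ---------------------------------------------------------------------------
# Input preparation


def tokens_from_sequences(
    sequences: Sequence[GeneSequence | str], fixed_length: int
) -> np.ndarray:
    """Integer-encode sequences, right-truncated / zero-padded to fixed_length."""
    out = np.zeros((len(sequences), fixed_length), dtype=np.int64)
    for i, seq in enumerate(sequences):
        res = seq.residues if isinstance(seq, GeneSequence) else seq
        codes = [NUC_CODE[c] for c in res[:fixed_length]]
        out[i, : len(codes)] = codes
    return out


# ---------------------------------------------------------------------------
# Estimators


class _RecurrentClassifierBase(ClassifierMixin, BaseEstimator):
    """Shared fit/predict machinery of the three recurrent classifiers."""

    _model_name: str = ""

    def __init__(
        self,
        input_mode: str = "token_sequence",
        fixed_length: int = 64,
        embedding_dim: int = 64,
        dense_units: int = 64,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        clip_norm: float = 5.0,
        standardize: bool = True,
        pooling: str = "mean",
        dtype: str = "float32",
        random_state: int = 0,
    ):
        self.input_mode = input_mode
        self.fixed_length = fixed_length
        self.embedding_dim = embedding_dim
        self.dense_units = dense_units
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.clip_norm = clip_norm
        self.standardize = standardize
        self.pooling = pooling
        self.dtype = dtype
        self.random_state = random_state

    def _aggregate(self, dtype) -> tuple[bool, list[_rnn.Layer]]:
        """How the recurrent output reaches the dense stack.

        "mean" (default): return full sequences and average them over time —
        every timestep gets a direct gradient path, which is what makes
        learning on length-F scalar feature sequences tractable.  "last":
        classical last-hidden-state readout.
        """
        if self.pooling == "mean":
            return True, [_rnn.TemporalMeanPool()]
        if self.pooling == "last":
            return False, []
        raise ParameterError(f"unknown pooling {self.pooling!r}")

    # subclass hook: recurrent + dense stack after the input stage
    def _stack(self, input_dim: int, dtype) -> list[_rnn.Layer]:
        raise NotImplementedError

    def _np_dtype(self):
        return np.dtype(self.dtype).type

    def _prepare(self, X, fit: bool):
        """Turn raw inputs into the network's (B, T, D) or token array."""
        if self.input_mode == "feature_vector":
            X = np.asarray(X, dtype=float)
            if X.ndim != 2:
                raise InferenceError(f"expected 2-D feature matrix, got {X.shape}")
            if fit:
                self.n_features_in_ = X.shape[1]
                if self.standardize:
                    self.feature_mean_ = X.mean(axis=0)
                    scale = X.std(axis=0)
                    scale[scale == 0] = 1.0
                    self.feature_scale_ = scale
            elif X.shape[1] != self.n_features_in_:
                raise InferenceError(
                    f"expected {self.n_features_in_} features, got {X.shape[1]}"
                )
            if self.standardize:
                X = (X - self.feature_mean_) / self.feature_scale_
            return X[:, :, None].astype(self._np_dtype())
        # token_sequence
        if isinstance(X, np.ndarray) and X.ndim == 2 and X.dtype.kind in "iu":
            tokens = X
            if tokens.shape[1] != self.fixed_length:
                padded = np.zeros((len(tokens), self.fixed_length), dtype=np.int64)
                w = min(self.fixed_length, tokens.shape[1])
                padded[:, :w] = tokens[:, :w]
                tokens = padded
        else:
            tokens = tokens_from_sequences(X, self.fixed_length)
        if fit:
            self.n_features_in_ = self.fixed_length
        return tokens

    def _build(self, rng) -> _rnn.Network:
        dtype = self._np_dtype()
        if self.input_mode == "feature_vector":
            layers: list[_rnn.Layer] = []
            input_dim = 1
        else:
            layers = [_rnn.Embedding(len(NUC_CODE), self.embedding_dim, dtype)]
            input_dim = self.embedding_dim
        layers += self._stack(input_dim, dtype)
        net = _rnn.Network(layers)
        net.init(rng)
        return net

    def fit(self, X, y):
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise TrainingError("training labels contain a single class")
        if len(classes) > 2:
            raise TrainingError(f"binary classifier got {len(classes)} classes")
        counts = [(y == c).sum() for c in classes]
        if min(counts) < 2:
            raise TrainingError("need at least 2 samples per class")
        self.classes_ = classes
        y01 = (y == classes[1]).astype(np.int64)

        inputs = self._prepare(X, fit=True)
        n = len(inputs)
        rng = np.random.default_rng(self.random_state)
        net = self._build(rng)
        velocity: dict = {}
        log: list[float] = []
        for epoch in range(self.epochs):
            perm = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = perm[start : start + self.batch_size]
                logits = net.forward(inputs[idx], train=True, rng=rng)
                loss, dlogits, _ = _rnn.softmax_xent(logits, y01[idx])
                if not np.isfinite(loss):
                    raise DivergenceError(epoch)
                net.backward(dlogits)
                net.sgd_step(
                    self.learning_rate,
                    momentum=self.momentum,
                    clip_norm=self.clip_norm,
                    velocity=velocity,
                )
                losses.append(loss)
            log.append(float(np.mean(losses)))
        self.network_ = net
        self.training_log_ = log
        return self

    def _forward_eval(self, inputs, batch: int = 256) -> np.ndarray:
        outs = [
            self.network_.forward(inputs[s : s + batch], train=False)
            for s in range(0, len(inputs), batch)
        ]
        return np.vstack(outs)

    def predict_proba(self, X) -> np.ndarray:
        check_is_fitted(self, "network_")
        inputs = self._prepare(X, fit=False)
        return _rnn.softmax(self._forward_eval(inputs).astype(np.float64))

    def predict_scores(self, X) -> np.ndarray:
        """Probability of the positive (mutated) class, one score per sample."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        scores = self.predict_scores(X)
        return self.classes_[(scores >= 0.5).astype(int)]


class LSTMClassifier(_RecurrentClassifierBase):
    """LSTM(128) -> dropout(0.2) -> dense(sigmoid) -> dropout(0.2) -> head."""

    _model_name = "LSTM"

    def __init__(
        self,
        units: int = 128,
        dropout: float = 0.2,
        input_mode: str = "token_sequence",
        fixed_length: int = 64,
        embedding_dim: int = 64,
        dense_units: int = 64,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        clip_norm: float = 5.0,
        standardize: bool = True,
        pooling: str = "mean",
        dtype: str = "float32",
        random_state: int = 0,
    ):
        super().__init__(
            input_mode=input_mode, fixed_length=fixed_length,
            embedding_dim=embedding_dim, dense_units=dense_units, epochs=epochs,
            batch_size=batch_size, learning_rate=learning_rate, momentum=momentum,
            clip_norm=clip_norm, standardize=standardize, pooling=pooling,
            dtype=dtype, random_state=random_state,
        )
        self.units = units
        self.dropout = dropout

    def _stack(self, input_dim, dtype):
        seq, agg = self._aggregate(dtype)
        return [
            _rnn.LSTMCell(input_dim, self.units, return_sequences=seq, dtype=dtype),
            *agg,
            _rnn.Dropout(self.dropout, dtype),
            _rnn.Dense(self.units, self.dense_units, "sigmoid", dtype),
            _rnn.Dropout(self.dropout, dtype),
            _rnn.Dense(self.dense_units, 2, "none", dtype),
        ]


class GRUClassifier(_RecurrentClassifierBase):
    """GRU(256) -> RNN(128) -> dropout(0.3) x2 -> dense(10, sigmoid) -> head."""

    _model_name = "GRU"

    def __init__(
        self,
        gru_units: int = 256,
        rnn_units: int = 128,
        dropout: float = 0.3,
        penultimate_units: int = 10,
        input_mode: str = "token_sequence",
        fixed_length: int = 64,
        embedding_dim: int = 64,
        dense_units: int = 64,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 0.02,  # two stacked recurrent layers: smaller step
        momentum: float = 0.9,
        clip_norm: float = 5.0,
        standardize: bool = True,
        pooling: str = "mean",
        dtype: str = "float32",
        random_state: int = 0,
    ):
        super().__init__(
            input_mode=input_mode, fixed_length=fixed_length,
            embedding_dim=embedding_dim, dense_units=dense_units, epochs=epochs,
            batch_size=batch_size, learning_rate=learning_rate, momentum=momentum,
            clip_norm=clip_norm, standardize=standardize, pooling=pooling,
            dtype=dtype, random_state=random_state,
        )
        self.gru_units = gru_units
        self.rnn_units = rnn_units
        self.dropout = dropout
        self.penultimate_units = penultimate_units

    def _stack(self, input_dim, dtype):
        seq, agg = self._aggregate(dtype)
        return [
            _rnn.GRUCell(input_dim, self.gru_units, return_sequences=True, dtype=dtype),
            _rnn.SimpleRNNCell(
                self.gru_units, self.rnn_units, return_sequences=seq, dtype=dtype
            ),
            *agg,
            _rnn.Dropout(self.dropout, dtype),
            _rnn.Dropout(self.dropout, dtype),
            _rnn.Dense(self.rnn_units, self.penultimate_units, "sigmoid", dtype),
            _rnn.Dense(self.penultimate_units, 2, "none", dtype),
        ]


class BiLSTMClassifier(_RecurrentClassifierBase):
    """Bidirectional LSTM(128 per direction), otherwise as LSTMClassifier."""

    _model_name = "BLSTM"

    def __init__(
        self,
        units: int = 128,
        dropout: float = 0.2,
        input_mode: str = "token_sequence",
        fixed_length: int = 64,
        embedding_dim: int = 64,
        dense_units: int = 64,
        epochs: int = 50,
        batch_size: int = 32,
        learning_rate: float = 0.05,
        momentum: float = 0.9,
        clip_norm: float = 5.0,
        standardize: bool = True,
        pooling: str = "mean",
        dtype: str = "float32",
        random_state: int = 0,
    ):
        super().__init__(
            input_mode=input_mode, fixed_length=fixed_length,
            embedding_dim=embedding_dim, dense_units=dense_units, epochs=epochs,
            batch_size=batch_size, learning_rate=learning_rate, momentum=momentum,
            clip_norm=clip_norm, standardize=standardize, pooling=pooling,
            dtype=dtype, random_state=random_state,
        )
        self.units = units
        self.dropout = dropout

    def _stack(self, input_dim, dtype):
        seq, agg = self._aggregate(dtype)
        return [
            _rnn.BiLSTM(input_dim, self.units, return_sequences=seq, dtype=dtype),
            *agg,
            _rnn.Dropout(self.dropout, dtype),
            _rnn.Dense(2 * self.units, self.dense_units, "sigmoid", dtype),
            _rnn.Dropout(self.dropout, dtype),
            _rnn.Dense(self.dense_units, 2, "none", dtype),
        ]


_ESTIMATORS = {
    "LSTM": LSTMClassifier,
    "GRU": GRUClassifier,
    "BLSTM": BiLSTMClassifier,
}


def build_estimator(spec: ModelSpec, **overrides) -> _RecurrentClassifierBase:
    """Instantiate the estimator a ModelSpec describes."""
    cls = _ESTIMATORS[spec.name]
    kwargs = dict(
        input_mode=spec.input_mode,
        fixed_length=spec.fixed_length,
        epochs=spec.epochs,
        batch_size=spec.batch_size,
        learning_rate=spec.learning_rate,
        momentum=spec.momentum,
        random_state=spec.seed,
    )
    kwargs.update(overrides)
    return cls(**kwargs)


@dataclass
class TrainedModel:
    """A fitted base classifier together with the spec that produced it."""

    spec: ModelSpec
    estimator: _RecurrentClassifierBase
    training_log: list[float] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        """Persist spec + weights (JSON sidecar + npz weight container)."""
        path = Path(path)
        meta = {
            "format_version": _FORMAT_VERSION,
            "spec": self.spec.to_dict(),
            "training_log": self.training_log,
            "estimator_params": {
                k: v for k, v in self.estimator.get_params().items()
            },
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
        state = self.estimator.network_.state()
        extras = {"classes_": self.estimator.classes_}
        if getattr(self.estimator, "standardize", False) and hasattr(
            self.estimator, "feature_mean_"
        ):
            extras["feature_mean_"] = self.estimator.feature_mean_
            extras["feature_scale_"] = self.estimator.feature_scale_
        np.savez(path.with_suffix(".npz"), **state, **extras)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta["format_version"] != _FORMAT_VERSION:
            raise ParameterError(
                f"unsupported model format version {meta['format_version']}"
            )
        spec = ModelSpec.from_dict(meta["spec"])
        est = build_estimator(spec)
        est.set_params(
            **{
                k: v
                for k, v in meta["estimator_params"].items()
                if k in est.get_params()
            }
        )
        data = np.load(path.with_suffix(".npz"))
        est.classes_ = data["classes_"]
        if "feature_mean_" in data:
            est.feature_mean_ = data["feature_mean_"]
            est.feature_scale_ = data["feature_scale_"]
            est.n_features_in_ = len(est.feature_mean_)
        else:
            est.n_features_in_ = est.fixed_length
        rng = np.random.default_rng(est.random_state)
        net = est._build(rng)
        net.load_state({k: data[k] for k in data.files if k.startswith("layer")})
        est.network_ = net
        est.training_log_ = list(meta["training_log"])
        return cls(spec, est, list(meta["training_log"]))


def train(spec: ModelSpec, X, y, **overrides) -> TrainedModel:
    """Fit the classifier a spec describes; thin wrapper over the estimator."""
    est = build_estimator(spec, **overrides)
    est.fit(X, y)
    return TrainedModel(spec, est, est.training_log_)


def predict_scores(model: TrainedModel | _RecurrentClassifierBase, X) -> np.ndarray:
    """Per-sample probability of the mutated class, in [0, 1]."""
    est = model.estimator if isinstance(model, TrainedModel) else model
    return est.predict_scores(X)
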