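"""Feed-forward interaction classifier, training loop, and threshold tuning.

The classifier is a dense network: input (the concatenated pair feature)
-> ``hidden_layers`` blocks of [linear -> ReLU -> dropout] -> a single
sigmoid output, trained with binary cross-entropy and Adam under a linear
warmup / cosine-decay learning-rate schedule with early stopping on the
validation loss. Mini-batches carry a controlled negative fraction r (see
:mod:`paircraft.sampling`), while the validation loss is plain unweighted
BCE at the natural class composition.

The decision threshold is not fixed at 0.5: it is tuned on validation data
by maximizing the Matthews correlation coefficient, which stays informative
under the 20:1 negative:positive imbalance the pipeline evaluates at.

:class:`InteractionModel` packages the whole procedure in a model/results
idiom: construct it from an :class:`~paircraft.dataset.InteractionDataset`
plus an embedder, call :meth:`~InteractionModel.fit`, and read estimates,
history and stratified test metrics off the returned
:class:`InteractionResults`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .augment import OrientedInstance, augment_split
from .dataset import InteractionDataset, PairKey, TypePair
from .embed import MoleculeEmbedder, TokenEmbedder, featurize_instances
from .metrics import MetricsReport, mcc as mcc_of_counts, ConfusionCounts, stratified_report
from .sampling import SplitBundle, make_batches, sample_negatives, stratified_split

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class ClassifierConfig:
    """Architecture of the feed-forward classifier.

    ``input_dim`` must equal 2 * d_mol: the pair feature concatenates both
    molecule embeddings, so the network always sees both molecules.
    """

    input_dim: int
    hidden_layers: int = 4
    hidden_width: int = 1024
    dropout: float = 0.2

    def __post_init__(self) -> None:
        if self.input_dim <= 0:
            raise ValueError("input_dim must be positive")
        if self.hidden_layers < 1 or self.hidden_width < 1:
            raise ValueError("need at least one hidden layer of width >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings for the classifier."""

    learning_rate: float = 5e-4
    warmup_epochs: int = 4
    max_epochs: int = 50
    patience: int = 10
    batch_size: int = 512
    negative_fraction: float = 0.7
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    adam_eps: float = 1e-8
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.warmup_epochs < self.max_epochs:
            raise ValueError("warmup_epochs must be < max_epochs")
        if self.warmup_epochs < 0:
            raise ValueError("warmup_epochs must be >= 0")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")


def lr_at(epoch: float, config: TrainConfig) -> float:
    """Learning rate at a (possibly fractional) epoch.

    Linear ramp from 0 at epoch 0 to the peak rate at ``warmup_epochs``,
    then cosine decay to 0 at ``max_epochs``; continuous at the joint.
    """
    if epoch < 0 or epoch > config.max_epochs:
        raise ValueError(f"epoch must be in [0, {config.max_epochs}]")
    eta, w, e_max = config.learning_rate, config.warmup_epochs, config.max_epochs
    if epoch <= w and w > 0:
        return eta * epoch / w
    return eta * 0.5 * (1.0 + math.cos(math.pi * (epoch - w) / (e_max - w)))


# ---------------------------------------------------------------------------
# the network

def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def bce_loss(probs: np.ndarray, labels: np.ndarray, eps: float = 1e-12) -> float:
    p = np.clip(probs, eps, 1.0 - eps)
    y = labels.astype(float)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p)))


class FeedForwardClassifier:
    """Dense ReLU network with a single sigmoid output, in plain numpy.

    Weights use fan-in-scaled (He) normal initialization from the given
    seed. Dropout is inverted dropout on the hidden activations, active
    only when a training RNG is supplied; inference is deterministic.
    """

    def __init__(self, config: ClassifierConfig, seed: int = 0) -> None:
        self.config = config
        rng = np.random.default_rng(seed)
        dims = [config.input_dim] + [config.hidden_width] * config.hidden_layers + [1]
        self.weights: List[np.ndarray] = []
        self.biases: List[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            scale = math.sqrt(2.0 / fan_in)
            self.weights.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.biases.append(np.zeros(fan_out))

    @property
    def n_parameters(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def _forward(self, X: np.ndarray, dropout_rng: Optional[np.random.Generator]):
        p_drop = self.config.dropout
        acts = [X]
        masks: List[Optional[np.ndarray]] = []
        a = X
        n_hidden = self.config.hidden_layers
        for layer in range(n_hidden):
            z = a @ self.weights[layer] + self.biases[layer]
            a = np.maximum(z, 0.0)
            if dropout_rng is not None and p_drop > 0.0:
                mask = (dropout_rng.random(a.shape) >= p_drop) / (1.0 - p_drop)
                a = a * mask
                masks.append(mask)
            else:
                masks.append(None)
            acts.append(a)
        logits = (a @ self.weights[-1] + self.biases[-1]).ravel()
        return logits, acts, masks

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Interaction probabilities in (0, 1); deterministic (no dropout)."""
        logits, _, _ = self._forward(np.atleast_2d(X), dropout_rng=None)
        return _sigmoid(logits)

    def loss_and_gradients(
        self, X: np.ndarray, y: np.ndarray,
        dropout_rng: Optional[np.random.Generator] = None,
    ) -> Tuple[float, List[np.ndarray], List[np.ndarray]]:
        """Mean BCE loss and its gradients w.r.t. every weight and bias."""
        logits, acts, masks = self._forward(X, dropout_rng)
        probs = _sigmoid(logits)
        loss = bce_loss(probs, y)
        n = X.shape[0]
        grad_w = [np.zeros_like(w) for w in self.weights]
        grad_b = [np.zeros_like(b) for b in self.biases]
        # d(mean BCE)/d(logit) = (p - y) / n
        delta = ((probs - y.astype(float)) / n)[:, None]
        grad_w[-1] = acts[-1].T @ delta
        grad_b[-1] = delta.sum(axis=0)
        upstream = delta @ self.weights[-1].T
        for layer in range(self.config.hidden_layers - 1, -1, -1):
            a = acts[layer + 1]
            d = upstream * (a > 0.0)
            if masks[layer] is not None:
                d = d * masks[layer]
            grad_w[layer] = acts[layer].T @ d
            grad_b[layer] = d.sum(axis=0)
            if layer > 0:
                upstream = d @ self.weights[layer].T
        return loss, grad_w, grad_b

    def get_state(self) -> Dict[str, List[np.ndarray]]:
        return {"weights": [w.copy() for w in self.weights],
                "biases": [b.copy() for b in self.biases]}

    def set_state(self, state: Mapping[str, List[np.ndarray]]) -> None:
        self.weights = [w.copy() for w in state["weights"]]
        self.biases = [b.copy() for b in state["biases"]]


class _Adam:
    """Adaptive-moment optimizer over the classifier's parameter lists."""

    def __init__(self, clf: FeedForwardClassifier, config: TrainConfig) -> None:
        self.cfg = config
        self.m_w = [np.zeros_like(w) for w in clf.weights]
        self.v_w = [np.zeros_like(w) for w in clf.weights]
        self.m_b = [np.zeros_like(b) for b in clf.biases]
        self.v_b = [np.zeros_like(b) for b in clf.biases]
        self.t = 0

    def step(self, clf: FeedForwardClassifier, grad_w, grad_b, lr: float) -> None:
        b1, b2, eps = self.cfg.adam_beta1, self.cfg.adam_beta2, self.cfg.adam_eps
        self.t += 1
        corr1 = 1.0 - b1 ** self.t
        corr2 = 1.0 - b2 ** self.t
        for i in range(len(clf.weights)):
            for param, grad, m, v in (
                (clf.weights[i], grad_w[i], self.m_w[i], self.v_w[i]),
                (clf.biases[i], grad_b[i], self.m_b[i], self.v_b[i]),
            ):
                m *= b1
                m += (1.0 - b1) * grad
                v *= b2
                v += (1.0 - b2) * grad * grad
                param -= lr * (m / corr1) / (np.sqrt(v / corr2) + eps)


# ---------------------------------------------------------------------------
# training with early stopping

@dataclass
class TrainHistory:
    """Per-epoch record of the training run (epochs are 1-based)."""

    train_loss: List[float] = field(default_factory=list)
    validation_loss: List[float] = field(default_factory=list)
    learning_rate: List[float] = field(default_factory=list)
    best_epoch: int = 0
    stopped_epoch: int = 0

    @property
    def best_validation_loss(self) -> float:
        return self.validation_loss[self.best_epoch - 1]


BatchProvider = Callable[[int], Iterable[Tuple[np.ndarray, np.ndarray]]]


def train(
    classifier: FeedForwardClassifier,
    train_batches: BatchProvider,
    validation_set: Tuple[np.ndarray, np.ndarray],
    config: TrainConfig,
    validation_loss_fn: Optional[Callable[[FeedForwardClassifier, int], float]] = None,
) -> Tuple[FeedForwardClassifier, TrainHistory]:
    """Train with early stopping; restore and return the best-epoch state.

    ``train_batches(epoch)`` yields (X, y) mini-batches for that 1-based
    epoch. Training stops once the validation loss has not improved
    (strictly) for ``patience`` consecutive epochs, or at ``max_epochs``;
    the classifier is reset to the parameters of the best epoch.
    ``validation_loss_fn`` overrides the default unweighted-BCE validation
    loss (used e.g. to script loss sequences when testing the stopping rule).
    """
    X_val, y_val = validation_set
    if validation_loss_fn is None:
        def validation_loss_fn(clf: FeedForwardClassifier, epoch: int) -> float:
            return bce_loss(clf.predict_proba(X_val), y_val)

    optimizer = _Adam(classifier, config)
    dropout_rng = np.random.default_rng(config.seed)
    history = TrainHistory()
    best_loss = math.inf
    best_state = classifier.get_state()
    epochs_since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        lr = lr_at(epoch, config)
        epoch_losses: List[float] = []
        for X_batch, y_batch in train_batches(epoch):
            loss, grad_w, grad_b = classifier.loss_and_gradients(
                X_batch, y_batch, dropout_rng=dropout_rng if classifier.config.dropout > 0 else None
            )
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch} "
                    f"(lr={lr:.3g}, batch size {len(y_batch)})"
                )
            optimizer.step(classifier, grad_w, grad_b, lr)
            epoch_losses.append(loss)
        val_loss = validation_loss_fn(classifier, epoch)
        if not math.isfinite(val_loss):
            raise RuntimeError(f"non-finite validation loss at epoch {epoch}")
        history.train_loss.append(float(np.mean(epoch_losses)) if epoch_losses else math.nan)
        history.validation_loss.append(val_loss)
        history.learning_rate.append(lr)

        if val_loss < best_loss:
            best_loss = val_loss
            best_state = classifier.get_state()
            history.best_epoch = epoch
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        history.stopped_epoch = epoch
        if epochs_since_best >= config.patience:
            logger.info("early stopping at epoch %d (best epoch %d)", epoch, history.best_epoch)
            break

    classifier.set_state(best_state)
    return classifier, history


# ---------------------------------------------------------------------------
# threshold tuning and prediction

@dataclass(frozen=True)
class ThresholdChoice:
    """An MCC-maximizing decision threshold and the MCC it attains."""

    t: float
    mcc_at_t: float


def tune_threshold(scores: Sequence[float], labels: Sequence[int]) -> ThresholdChoice:
    """Pick the decision threshold maximizing MCC on (scores, labels).

    Candidates are the midpoints between consecutive distinct sorted scores
    plus {0, 1}; ties in MCC break toward the smaller threshold. Requires
    both classes present (MCC is undefined otherwise).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("MCC undefined: labels contain a single class")
    uniq = np.unique(s)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    candidates = np.unique(np.concatenate([[0.0, 1.0], mids]))

    pos_sorted = np.sort(s[y == 1])
    neg_sorted = np.sort(s[y == 0])
    n_pos, n_neg = len(pos_sorted), len(neg_sorted)
    # calls use score >= t, so count scores in [t, inf)
    tp = n_pos - np.searchsorted(pos_sorted, candidates, side="left")
    fp = n_neg - np.searchsorted(neg_sorted, candidates, side="left")
    fn = n_pos - tp
    tn = n_neg - fp
    den = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    with np.errstate(invalid="ignore"):
        mcc_vals = np.where(den > 0, (tp * tn - fp * fn) / np.sqrt(den.astype(float)), 0.0)
    best = int(np.argmax(mcc_vals))  # candidates ascending, argmax takes first -> smaller t
    return ThresholdChoice(t=float(candidates[best]), mcc_at_t=float(mcc_vals[best]))


def predict(
    classifier: FeedForwardClassifier, pair_features: np.ndarray, threshold: float
) -> Tuple[np.ndarray, np.ndarray]:
    """Scores in [0,1] and binary calls with the rule call = [score >= threshold]."""
    scores = classifier.predict_proba(pair_features)
    return scores, (scores >= threshold).astype(int)


# ---------------------------------------------------------------------------
# model / results layer

@dataclass
class InteractionResults:
    """Everything estimated by one :meth:`InteractionModel.fit` run."""

    model: "InteractionModel"
    classifier: FeedForwardClassifier
    history: TrainHistory
    threshold: ThresholdChoice
    report: MetricsReport
    splits: SplitBundle
    seed: int

    @property
    def test_auroc(self) -> Optional[float]:
        return self.report.overall.auroc

    @property
    def test_auprc(self) -> Optional[float]:
        return self.report.overall.auprc

    def predict_pairs(self, instances: Sequence[OrientedInstance]) -> Tuple[np.ndarray, np.ndarray]:
        """Score arbitrary oriented instances with the fitted classifier."""
        X, _ = featurize_instances(instances, self.model.dataset.sequences,
                                   self.model.molecule_embedder)
        return predict(self.classifier, X, self.threshold.t)

    def summary(self) -> str:
        m = self.model
        o = self.report.overall
        lines = [
            "Interaction classifier results",
            "=" * 62,
            f"pooling: {m.pooling:>10}    embedder: {m.embedder.fingerprint}",
            f"augment train: {str(m.augment_train):>5}    augment eval: {m.augment_eval}",
            f"classifier: {m.classifier_config.hidden_layers} x {m.classifier_config.hidden_width} "
            f"hidden, dropout {m.classifier_config.dropout}, "
            f"{self.classifier.n_parameters:,} parameters",
            f"seed: {self.seed}",
            "-" * 62,
            f"train/val/test pairs: {len(self.splits.train)}/"
            f"{len(self.splits.validation)}/{len(self.splits.test)}",
            f"best epoch: {self.history.best_epoch}    "
            f"stopped: {self.history.stopped_epoch}    "
            f"best val loss: {self.history.best_validation_loss:.4f}",
            f"decision threshold (MCC-tuned): {self.threshold.t:.4f} "
            f"(validation MCC {self.threshold.mcc_at_t:.4f})",
            "-" * 62,
            f"test  AUROC: {o.auroc:.4f}    AUPRC: {o.auprc:.4f} "
            f"(prevalence {o.prevalence:.4f})",
            f"test  MCC: {o.mcc:.4f}    F1: {o.f1:.4f}    "
            f"balanced acc: {o.balanced_accuracy:.4f}",
            f"test  confusion: TP={o.counts.TP} FP={o.counts.FP} "
            f"FN={o.counts.FN} TN={o.counts.TN}",
            "=" * 62,
        ]
        return "\n".join(lines)


class InteractionModel:
    """End-to-end interaction prediction model over an InteractionDataset.

    Construction fixes the data and design (embedder, pooling mode,
    augmentation switches, classifier architecture, optimization settings);
    :meth:`fit` runs split -> augment -> featurize -> train -> tune
    threshold -> evaluate and returns an :class:`InteractionResults`.

    If the dataset carries no negatives yet, ``fit`` samples them first
    (type-constrained, ``negatives_per_positive`` each) so the evaluation
    imbalance matches the stated negative:positive ratio.
    """

    def __init__(
        self,
        dataset: InteractionDataset,
        embedder: TokenEmbedder,
        pooling: str = "avg",
        augment_train: bool = True,
        augment_eval: bool = True,
        augment_positives_only: bool = False,
        classifier_config: Optional[ClassifierConfig] = None,
        train_config: Optional[TrainConfig] = None,
        negatives_per_positive: int = 20,
        outer_test_fraction: float = 0.10,
        inner_validation_fraction: float = 0.20,
    ) -> None:
        self.dataset = dataset
        self.embedder = embedder
        self.pooling = pooling
        self.augment_train = augment_train
        self.augment_eval = augment_eval
        self.augment_positives_only = augment_positives_only
        self.molecule_embedder = MoleculeEmbedder(embedder, pooling)
        input_dim = 2 * self.molecule_embedder.d_mol
        if classifier_config is None:
            classifier_config = ClassifierConfig(input_dim=input_dim)
        elif classifier_config.input_dim != input_dim:
            raise ValueError(
                f"classifier input_dim {classifier_config.input_dim} inconsistent with "
                f"pair feature dimension {input_dim} ({pooling} pooling, H={embedder.H})"
            )
        self.classifier_config = classifier_config
        self.train_config = train_config or TrainConfig()
        self.negatives_per_positive = negatives_per_positive
        self.outer_test_fraction = outer_test_fraction
        self.inner_validation_fraction = inner_validation_fraction

    def _instances(self, pairs, split: str, augment: bool) -> List[OrientedInstance]:
        originals = [OrientedInstance.from_pair(p, label, split=split) for p, label in pairs]
        if augment:
            return augment_split(originals, positives_only=self.augment_positives_only)
        return originals

    def fit(self, seed: int = 0) -> InteractionResults:
        ss = np.random.SeedSequence(seed)
        seed_neg, seed_split, seed_init, seed_batch, seed_train = (
            int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(5)
        )
        ds = self.dataset
        negatives = ds.negatives
        if not negatives:
            negatives = sample_negatives(ds.positives, ds.sequences,
                                         n=self.negatives_per_positive, seed=seed_neg)
        labeled = [(p, 1) for p in sorted(ds.positives)] + [(p, 0) for p in sorted(negatives)]
        splits = stratified_split(
            labeled, ds.sequences,
            outer_test_fraction=self.outer_test_fraction,
            inner_validation_fraction=self.inner_validation_fraction,
            seed=seed_split,
        )

        train_inst = self._instances(splits.train, "train", self.augment_train)
        val_inst = self._instances(splits.validation, "validation", self.augment_eval)
        test_inst = self._instances(splits.test, "test", self.augment_eval)

        X_train, y_train = featurize_instances(train_inst, ds.sequences, self.molecule_embedder)
        X_val, y_val = featurize_instances(val_inst, ds.sequences, self.molecule_embedder)
        X_test, y_test = featurize_instances(test_inst, ds.sequences, self.molecule_embedder)

        pos_idx = [i for i, y in enumerate(y_train) if y == 1]
        neg_idx = [i for i, y in enumerate(y_train) if y == 0]
        cfg = replace(self.train_config, seed=seed_train)
        m = min(cfg.batch_size, len(pos_idx) + len(neg_idx))
        if m < cfg.batch_size:
            logger.info("batch size reduced to %d (training pool of %d instances)",
                        m, len(pos_idx) + len(neg_idx))

        def train_batches(epoch: int):
            batches = make_batches(pos_idx, neg_idx, m=m, r=cfg.negative_fraction,
                                   seed=seed_batch + epoch)
            for idx in batches:
                sel = np.asarray(idx)
                yield X_train[sel], y_train[sel]

        classifier = FeedForwardClassifier(self.classifier_config, seed=seed_init)
        classifier, history = train(classifier, train_batches, (X_val, y_val), cfg)

        val_scores = classifier.predict_proba(X_val)
        choice = tune_threshold(val_scores, y_val)

        test_scores, _ = predict(classifier, X_test, choice.t)
        type_pairs = [ds.type_pair(inst.origin) for inst in test_inst]
        report = stratified_report(test_scores, y_test, type_pairs, choice.t)

        return InteractionResults(
            model=self, classifier=classifier, history=history,
            threshold=choice, report=report, splits=splits, seed=seed,
        )
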